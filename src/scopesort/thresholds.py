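"""Score-to-category thresholding with Youden-index cut-point support.

Each category model emits a continuous score in [0, 1]; a report is
declared positive for a category when its score is greater than or equal
to that category's cut point (the comparison is closed at the cut).  Cut
points are chosen empirically from a threshold curve over the test-set
scores; the Youden index J = sensitivity + specificity - 1 provides the
default automatic choice, with ties resolved toward the larger threshold
(favouring specificity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import CATEGORIES, NeoplasiaLabels


@dataclass
class CutPoints:
    adenoma: float
    serrated: float
    advanced: float
    method: str = "youden_max"
    provenance: str = ""

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            v = getattr(self, c)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{c} cut point {v} outside [0, 1]")
        if self.method not in ("youden_max", "manual"):
            raise ValueError(f"unknown cut-point method {self.method!r}")

    def get(self, category: str) -> float:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return getattr(self, category)

    def as_dict(self) -> dict:
        return {
            **{c: getattr(self, c) for c in CATEGORIES},
            "method": self.method,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutPoints":
        return cls(
            adenoma=float(d["adenoma"]),
            serrated=float(d["serrated"]),
            advanced=float(d["advanced"]),
            method=d.get("method", "youden_max"),
            provenance=d.get("provenance", ""),
        )


@dataclass
class ThresholdCurve:
    """Exact confusion metrics at every candidate threshold.

    Candidates are the midpoints between consecutive distinct sorted
    scores plus the sentinels 0 and 1, so every achievable confusion
    table appears exactly once.  As the threshold increases sensitivity
    is non-increasing and specificity non-decreasing.
    """

    table: pd.DataFrame  # columns: threshold, sensitivity, specificity, ppv, npv, youden

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()


def threshold_curve(scores: Sequence[float], labels: Sequence[bool]) -> ThresholdCurve:
    """Sweep all candidate thresholds; positive means score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold_curve requires both classes present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.unique(np.concatenate(([0.0], mids, [1.0])))
    # positives with score >= t, via sorted cumulative counts
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    tp = n_pos - np.searchsorted(pos_sorted, candidates, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, candidates, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    sens = tp / n_pos
    spec = tn / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        npv = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
    table = pd.DataFrame(
        {
            "threshold": candidates,
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "youden": sens + spec - 1.0,
        }
    )
    return ThresholdCurve(table=table)


def choose_cutpoint(
    curve: ThresholdCurve,
    method: str = "youden_max",
    manual_value: Optional[float] = None,
) -> float:
    """Pick a cut point from a threshold curve.

    ``youden_max`` returns the threshold maximizing J; ties go to the
    larger threshold.  ``manual`` returns ``manual_value`` unchanged.
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual method requires manual_value")
        return float(manual_value)
    if method != "youden_max":
        raise ValueError(f"unknown cut-point method {method!r}")
    t = curve.table
    if len(t) == 0:
        raise ValueError("empty threshold curve")
    best_j = t["youden"].max()
    winners = t.loc[t["youden"] >= best_j - 1e-12, "threshold"]
    return float(winners.max())


def classify(
    scores: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    cuts: CutPoints,
) -> list[NeoplasiaLabels]:
    """Apply the three cut points independently to three score vectors.

    Accepts either a dict keyed by category or a sequence of three
    vectors in (adenoma, serrated, advanced) order.  Output is
    multi-label; a report is negative iff all three flags are false.
    """
    if isinstance(scores, dict):
        vectors = [np.asarray(scores[c], dtype=float) for c in CATEGORIES]
    else:
        vectors = [np.asarray(v, dtype=float) for v in scores]
        if len(vectors) != 3:
            raise ValueError("expected exactly three score vectors")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("score vectors must have equal length")
    flags = [v >= cuts.get(c) for c, v in zip(CATEGORIES, vectors)]
    return [
        NeoplasiaLabels(adenoma=bool(flags[0][i]), serrated=bool(flags[1][i]), advanced=bool(flags[2][i]))
        for i in range(n)
    ]
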