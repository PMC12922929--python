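"""Classifier evaluation: confusion metrics, AUC with bootstrap CIs, and
a keyword/regular-expression baseline.

AUC uses the Mann-Whitney rank formulation — the probability that a
random positive outscores a random negative, with ties counted half —
computed exactly over all positive-negative pairs.  Confidence intervals
are stratified percentile bootstrap (resampling positives and negatives
separately, so every resample retains both classes), 2,000 resamples by
default, deterministic under a seed.

Metrics with zero denominators are reported as missing (None), never as
zero, and JSON output carries them as null.

The rule-based baseline classifies a report per category from ordered
include/exclude regular-expression patterns: a category fires when at
least one include pattern matches and no exclude pattern matches within
a +/-5-word context window around the matched span.  The shipped default
ruleset is a synthetic stand-in written for this package (no published
ruleset was reused); it is an editable JSON file under
``scopesort/data/default_rules.json``.  Rule predictions and forest
predictions are evaluated through the identical reporting path, so
comparisons differ only in the classifier.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np
from scipy.stats import rankdata

from .corpus import CATEGORIES, LabeledCorpus, NeoplasiaLabels, PathologyReport
from .featurization import featurize_corpus, normalize
from .thresholds import classify

if TYPE_CHECKING:  # pragma: no cover
    from .modeling import ModelBundle


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionMatrix(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


@dataclass
class MetricSet:
    """Point metrics in [0, 1]; None marks an undefined (0/0) metric."""

    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    f1: Optional[float] = None
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "auc": self.auc,
        }
        if self.auc_ci is not None:
            d["auc_ci_low"], d["auc_ci_high"] = self.auc_ci
        else:
            d["auc_ci_low"] = d["auc_ci_high"] = None
        return d


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and F1 from exact counts."""

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    npv = ratio(cm.tn, cm.tn + cm.fn)
    f1 = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return MetricSet(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1)


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Exact rank-statistic AUC: P(score+ > score-) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC, clipped to [0, 1]."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC CI requires both classes present")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        resampled = np.concatenate([bp, bn])
        lab = np.concatenate([np.ones(len(bp), bool), np.zeros(len(bn), bool)])
        stats[b] = auc(resampled, lab)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


@dataclass
class EvaluationReport:
    """Per-category confusion matrices and metric sets for one evaluation."""

    confusions: dict[str, ConfusionMatrix]
    metric_sets: dict[str, MetricSet]
    n_reports: int
    locked: Optional[bool] = None
    classifier: str = "random_forest"

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "n_reports": self.n_reports,
            "locked": self.locked,
            "categories": {
                c: {
                    "confusion": self.confusions[c].as_dict(),
                    "metrics": self.metric_sets[c].as_dict(),
                }
                for c in CATEGORIES
            },
        }

    def to_json(self) -> str:
        """Deterministic JSON (sorted keys, no timestamps)."""
        return json.dumps(self.as_dict(), sort_keys=True, indent=2)


def _report_from_predictions(
    truth: dict[str, np.ndarray],
    preds: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    n_boot: int,
    ci_level: float,
    seed: int,
    locked: Optional[bool],
    classifier: str,
) -> EvaluationReport:
    confusions: dict[str, ConfusionMatrix] = {}
    metric_sets: dict[str, MetricSet] = {}
    for i, c in enumerate(CATEGORIES):
        cm = confusion(preds[c], truth[c])
        ms = metrics(cm)
        ms.auc = auc(scores[c], truth[c])
        ms.auc_ci = auc_ci(
            scores[c], truth[c], n_boot=n_boot, level=ci_level, seed=seed + i
        )
        confusions[c] = cm
        metric_sets[c] = ms
    n = next(iter(confusions.values())).n
    return EvaluationReport(
        confusions=confusions,
        metric_sets=metric_sets,
        n_reports=n,
        locked=locked,
        classifier=classifier,
    )


def evaluate_bundle(
    bundle: "ModelBundle",
    corpus: LabeledCorpus,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Featurize, score, classify and measure a corpus with a model bundle."""
    if not corpus.is_labeled:
        raise ValueError("evaluate_bundle requires a labeled corpus")
    features = featurize_corpus(corpus, bundle.vocabulary, mode=bundle.count_mode)
    scores = {c: bundle.models[c].score(features) for c in CATEGORIES}
    predicted = classify(scores, bundle.cutpoints)
    truth: dict[str, np.ndarray] = {}
    preds: dict[str, np.ndarray] = {}
    for c in CATEGORIES:
        t = np.asarray(corpus.labels_for(c), dtype=bool)
        if t.sum() == 0:
            raise ValueError(f"no positive reports for category {c!r} in evaluation corpus")
        if (~t).sum() == 0:
            raise ValueError(f"no negative reports for category {c!r} in evaluation corpus")
        truth[c] = t
        preds[c] = np.asarray([p.get(c) for p in predicted], dtype=bool)
    return _report_from_predictions(
        truth, preds, scores, n_boot, ci_level, seed, bundle.locked, "random_forest"
    )


# ---------------------------------------------------------------------------
# Keyword / regular-expression baseline


@dataclass(frozen=True)
class CategoryRule:
    pattern: str
    polarity: str  # include | exclude

    def __post_init__(self) -> None:
        if self.polarity not in ("include", "exclude"):
            raise ValueError(f"polarity must be include or exclude, got {self.polarity!r}")
        try:
            re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"invalid pattern {self.pattern!r}: {exc}") from exc


@dataclass
class RuleSet:
    """Ordered include/exclude patterns per category."""

    rules: dict[str, list[CategoryRule]]

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            cat_rules = self.rules.get(c, [])
            if not any(r.polarity == "include" for r in cat_rules):
                raise ValueError(f"category {c!r} has no include pattern")

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "RuleSet":
        rules = {
            c: [CategoryRule(r["pattern"], r["polarity"]) for r in raw[c]]
            for c in CATEGORIES
        }
        return cls(rules=rules)

    @classmethod
    def default(cls) -> "RuleSet":
        raw = json.loads(
            resources.files("scopesort").joinpath("data/default_rules.json").read_text()
        )
        return cls._from_raw({c: raw[c] for c in CATEGORIES})


def _context_window(words: list[str], start_word: int, end_word: int, radius: int = 5) -> str:
    lo = max(0, start_word - radius)
    hi = min(len(words), end_word + radius)
    return " ".join(words[lo:hi])


def rule_classify(report: PathologyReport, rules: RuleSet) -> NeoplasiaLabels:
    """Apply include/exclude patterns to the normalized note text.

    Patterns match against the normalized text (lowercased words joined
    by single spaces).  An include match is suppressed when any exclude
    pattern of the same category matches within a +/-5-word window
    around the matched span.
    """
    words = normalize(report.text)
    joined = " ".join(words)
    flags = {}
    for c in CATEGORIES:
        cat_rules = rules.rules[c]
        includes = [r for r in cat_rules if r.polarity == "include"]
        excludes = [r for r in cat_rules if r.polarity == "exclude"]
        fired = False
        for rule in includes:
            for m in re.finditer(rule.pattern, joined, re.IGNORECASE):
                start_word = joined[: m.start()].count(" ")
                end_word = joined[: m.end()].count(" ") + 1
                window = _context_window(words, start_word, end_word)
                if not any(
                    re.search(x.pattern, window, re.IGNORECASE) for x in excludes
                ):
                    fired = True
                    break
            if fired:
                break
        flags[c] = fired
    return NeoplasiaLabels(**flags)


def evaluate_rules(
    rules: RuleSet,
    corpus: LabeledCorpus,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate the rule baseline through the same reporting path as the
    forest pipeline; binary predictions double as (degenerate) scores."""
    if not corpus.is_labeled:
        raise ValueError("evaluate_rules requires a labeled corpus")
    predicted = [rule_classify(r, rules) for r in corpus]
    truth: dict[str, np.ndarray] = {}
    preds: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for c in CATEGORIES:
        t = np.asarray(corpus.labels_for(c), dtype=bool)
        if t.sum() == 0 or (~t).sum() == 0:
            raise ValueError(f"category {c!r} needs both classes in evaluation corpus")
        truth[c] = t
        preds[c] = np.asarray([p.get(c) for p in predicted], dtype=bool)
        scores[c] = preds[c].astype(float)
    return _report_from_predictions(
        truth, preds, scores, n_boot, ci_level, seed, None, "rule_baseline"
    )
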