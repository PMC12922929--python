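"""Domain types and table I/O for pathology-report corpora.

A corpus is an ordered collection of free-text pathology reports, each
optionally carrying ground-truth neoplasia labels (adenoma / serrated /
advanced, three independent booleans) and a flag marking combination
procedures (colonoscopy performed together with an upper endoscopy, whose
notes mix gastric and colorectal specimen parts).

Tables are exchanged as CSV or JSON-lines; the dialect is inferred from
the file extension and can be forced explicitly.  Booleans are serialized
as 0/1 in CSV and as native true/false in JSONL so that round-trips are
unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

CATEGORIES = ("adenoma", "serrated", "advanced")

_LABEL_COLUMNS = list(CATEGORIES)
_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no", ""}


class CorpusError(ValueError):
    """Raised for malformed corpora or tables."""


@dataclass(frozen=True)
class NeoplasiaLabels:
    """Three independent category flags; multi-label, not mutually exclusive.

    A villous adenoma is both ``adenoma`` and ``advanced``.  The derived
    "negative" category is simply the joint absence of all three flags.
    """

    adenoma: bool
    serrated: bool
    advanced: bool

    @property
    def negative(self) -> bool:
        return not (self.adenoma or self.serrated or self.advanced)

    def get(self, category: str) -> bool:
        if category not in CATEGORIES:
            raise KeyError(f"unknown category {category!r}")
        return getattr(self, category)

    def as_dict(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CATEGORIES}


@dataclass(frozen=True)
class PathologyReport:
    """One free-text pathology note.

    ``text`` may span multiple lettered specimen parts ("A.", "B.", ...)
    and may be empty (a degenerate but processable input).
    """

    report_id: str
    text: str
    labels: Optional[NeoplasiaLabels] = None
    combination_procedure: bool = False

    def __post_init__(self) -> None:
        if not self.report_id:
            raise CorpusError("report_id must be non-empty")


@dataclass
class LabeledCorpus:
    """Ordered collection of reports with distinct identifiers."""

    reports: list[PathologyReport]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise CorpusError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)
        n_labeled = sum(r.labels is not None for r in self.reports)
        if n_labeled not in (0, len(self.reports)):
            raise CorpusError(
                "label completeness must be all-or-none per corpus "
                f"({n_labeled} of {len(self.reports)} reports labeled)"
            )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[PathologyReport]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> PathologyReport:
        return self.reports[i]

    @property
    def is_labeled(self) -> bool:
        return len(self.reports) > 0 and self.reports[0].labels is not None

    @property
    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def labels_for(self, category: str) -> list[bool]:
        if not self.is_labeled:
            raise CorpusError("corpus is unlabeled")
        return [r.labels.get(category) for r in self.reports]  # type: ignore[union-attr]

    def subset(self, report_ids: Sequence[str], provenance: str = "") -> "LabeledCorpus":
        wanted = set(report_ids)
        return LabeledCorpus(
            [r for r in self.reports if r.report_id in wanted],
            provenance=provenance or self.provenance,
        )

    def without_labels(self) -> "LabeledCorpus":
        return LabeledCorpus(
            [replace(r, labels=None) for r in self.reports], provenance=self.provenance
        )


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "jsonl"):
            raise CorpusError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    raise CorpusError(f"cannot infer dialect from extension of {path.name!r}")


def _parse_bool(value: object, column: str, report_id: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _TRUE_STRINGS:
            return True
        if v in _FALSE_STRINGS:
            return False
    raise CorpusError(
        f"cannot parse {column}={value!r} as boolean (report_id {report_id!r})"
    )


def _records_to_corpus(records: list[dict], provenance: str) -> LabeledCorpus:
    if records:
        present = [c for c in _LABEL_COLUMNS if c in records[0]]
    else:
        present = []
    if present and len(present) != 3:
        missing = sorted(set(_LABEL_COLUMNS) - set(present))
        raise CorpusError(
            f"partial label columns: found {present}, missing {missing}; "
            "provide all three of adenoma/serrated/advanced or none"
        )
    reports: list[PathologyReport] = []
    seen: set[str] = set()
    for rec in records:
        if "report_id" not in rec or "text" not in rec:
            raise CorpusError("each record needs report_id and text")
        rid = str(rec["report_id"])
        if rid in seen:
            raise CorpusError(f"duplicate report_id {rid!r}")
        seen.add(rid)
        labels = None
        if present:
            labels = NeoplasiaLabels(
                *(_parse_bool(rec[c], c, rid) for c in _LABEL_COLUMNS)
            )
        combo = rec.get("combination_procedure")
        combo_flag = False if combo is None else _parse_bool(combo, "combination_procedure", rid)
        reports.append(
            PathologyReport(
                report_id=rid,
                text="" if rec["text"] is None else str(rec["text"]),
                labels=labels,
                combination_procedure=combo_flag,
            )
        )
    return LabeledCorpus(reports, provenance=provenance)


def read_corpus(path: str | Path, dialect: Optional[str] = None) -> LabeledCorpus:
    """Read a report table, preserving input order.

    Required columns/keys: ``report_id``, ``text``.  Optional: the three
    label columns (all or none) and ``combination_procedure`` (defaults to
    false; the training data this system targets are colonoscopy-paired
    reports).
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such file: {path}")
    fmt = _infer_dialect(path, dialect)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = df.to_dict(orient="records")
    else:
        records = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
    return _records_to_corpus(records, provenance=str(path))


def write_corpus(corpus: LabeledCorpus, path: str | Path, dialect: Optional[str] = None) -> None:
    """Write a corpus; ``read_corpus(write_corpus(c)) == c`` field-exact."""
    path = Path(path)
    fmt = _infer_dialect(path, dialect)
    rows = []
    for r in corpus:
        row: dict[str, object] = {"report_id": r.report_id, "text": r.text}
        if r.labels is not None:
            if fmt == "csv":
                row.update({c: int(r.labels.get(c)) for c in CATEGORIES})
            else:
                row.update(r.labels.as_dict())
        row["combination_procedure"] = (
            int(r.combination_procedure) if fmt == "csv" else r.combination_procedure
        )
        rows.append(row)
    if fmt == "csv":
        columns = ["report_id", "text"]
        if corpus.is_labeled:
            columns += list(CATEGORIES)
        columns.append("combination_procedure")
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=False) + "\n")


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: report_id, then one column per feature.

    Column names must equal the vocabulary's dot-joined feature names in
    vocabulary order (checked against the matrix's own vocabulary hash at
    construction time); a mismatch between the matrix columns and its
    vocabulary is a hard error.
    """
    path = Path(path)
    matrix.validate()
    df = matrix.to_frame()
    df.to_csv(path, index=False)


def read_feature_matrix(path: str | Path):
    """Read back a feature matrix written by :func:`write_feature_matrix`."""
    from .featurization import FeatureMatrix  # local import avoids a cycle

    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"report_id": str}, keep_default_na=False)
    if "report_id" not in df.columns:
        raise CorpusError("feature matrix file lacks a report_id column")
    feature_names = [c for c in df.columns if c != "report_id"]
    values = df[feature_names].to_numpy(dtype=int) if feature_names else None
    import numpy as np

    if values is None:
        values = np.zeros((len(df), 0), dtype=int)
    return FeatureMatrix(
        report_ids=list(df["report_id"]),
        feature_names=feature_names,
        values=values,
    )
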