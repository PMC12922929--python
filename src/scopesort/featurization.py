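"""Text normalization, n-gram tokenization and bag-of-n-grams featurization.

The feature space is a frequency-ranked vocabulary of the 100 most common
unigrams, 200 most common bigrams and 300 most common trigrams in the
training corpus (600 structured features in total when the corpus is rich
enough).  Feature values are raw occurrence counts of each vocabulary
n-gram in the normalized note (a binary presence mode is also offered).

Normalization is deliberately minimal: lowercase, split on any
non-alphanumeric character, drop empty fragments, keep numerals (size
tokens such as "10" and "mm" can carry signal).  No stop-word removal, no
stemming, no sentence segmentation: a note is tokenized as one stream, so
n-grams cross sentence and specimen-part boundaries but never report
boundaries.
"""

from __future__ import annotations

import hashlib
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .corpus import LabeledCorpus, PathologyReport

DEFAULT_LIMITS = (100, 200, 300)

_WORD_RE = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric character.

    Empty fragments are dropped; numerals are retained as words.
    """
    return _WORD_RE.findall(text.lower())


def ngrams(words: Sequence[str], n: int) -> list[tuple[str, ...]]:
    """Contiguous n-grams of ``words`` for n in {1, 2, 3}.

    Returns exactly ``max(0, len(words) - n + 1)`` tuples, in order.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    return [tuple(words[i : i + n]) for i in range(len(words) - n + 1)]


@dataclass(frozen=True)
class VocabularyEntry:
    tokens: tuple[str, ...]
    n: int
    feature_name: str
    corpus_count: int
    rank_within_n: int


@dataclass
class NgramVocabulary:
    """Ranked n-gram features, sorted by (n, rank within n).

    ``feature_name`` is the dot-joined token sequence, e.g.
    ``sessile.serrated.polyp``.  Within each order the corpus counts are
    non-increasing; count ties at the cutoff are broken lexicographically
    on the feature name so the vocabulary is deterministic.
    """

    entries: list[VocabularyEntry]
    limits: tuple[int, int, int] = DEFAULT_LIMITS

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.feature_name != ".".join(e.tokens):
                raise ValueError(f"feature_name mismatch for {e.tokens}")
        key = [(e.n, e.rank_within_n) for e in self.entries]
        if key != sorted(key):
            raise ValueError("entries must be sorted by (n, rank_within_n)")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_names(self) -> list[str]:
        return [e.feature_name for e in self.entries]

    @property
    def digest(self) -> str:
        """Stable hash of the ordered feature names, used to guard scoring."""
        joined = "\n".join(self.feature_names).encode("utf-8")
        return hashlib.sha256(joined).hexdigest()

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "feature_name": [e.feature_name for e in self.entries],
                "n": [e.n for e in self.entries],
                "rank_within_n": [e.rank_within_n for e in self.entries],
                "corpus_count": [e.corpus_count for e in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, limits: tuple[int, int, int] = DEFAULT_LIMITS) -> "NgramVocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"feature_name": str})
        entries = [
            VocabularyEntry(
                tokens=tuple(row.feature_name.split(".")),
                n=int(row.n),
                feature_name=row.feature_name,
                corpus_count=int(row.corpus_count),
                rank_within_n=int(row.rank_within_n),
            )
            for row in df.itertuples()
        ]
        return cls(entries=entries, limits=limits)


def build_vocabulary(
    corpus: LabeledCorpus,
    limits: tuple[int, int, int] = DEFAULT_LIMITS,
    count: Literal["tf", "df"] = "tf",
) -> NgramVocabulary:
    """Select the most common n-grams per order from a corpus.

    "Most common" defaults to total term frequency across the corpus
    (``count="tf"``); a document-frequency mode (``count="df"``, number of
    notes containing the n-gram) is available behind the flag.  Ties are
    broken lexicographically on the dot-joined name.  The result is
    invariant to the order of reports in the corpus.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counters: dict[int, Counter] = {1: Counter(), 2: Counter(), 3: Counter()}
    for report in corpus:
        words = normalize(report.text)
        for n in (1, 2, 3):
            grams = ngrams(words, n)
            if count == "df":
                counters[n].update(set(grams))
            else:
                counters[n].update(grams)
    entries: list[VocabularyEntry] = []
    for n, k in zip((1, 2, 3), limits):
        ranked = sorted(
            counters[n].items(), key=lambda kv: (-kv[1], ".".join(kv[0]))
        )[:k]
        for rank, (tokens, cnt) in enumerate(ranked, start=1):
            entries.append(
                VocabularyEntry(
                    tokens=tokens,
                    n=n,
                    feature_name=".".join(tokens),
                    corpus_count=cnt,
                    rank_within_n=rank,
                )
            )
    return NgramVocabulary(entries=entries, limits=tuple(limits))


def vectorize(
    report: PathologyReport,
    vocab: NgramVocabulary,
    mode: Literal["count", "binary"] = "count",
) -> np.ndarray:
    """Occurrence counts (or presence indicators) of vocabulary n-grams."""
    words = normalize(report.text)
    gram_counts: dict[int, Counter] = {
        n: Counter(ngrams(words, n)) for n in (1, 2, 3)
    }
    row = np.zeros(len(vocab), dtype=int)
    for j, e in enumerate(vocab.entries):
        c = gram_counts[e.n][e.tokens]
        row[j] = (1 if c > 0 else 0) if mode == "binary" else c
    return row


@dataclass
class FeatureMatrix:
    """Count-valued report × feature matrix in vocabulary order."""

    report_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    vocabulary: NgramVocabulary | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.report_ids),
            len(self.feature_names),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.report_ids)} reports x {len(self.feature_names)} features"
            )
        self.validate()

    def validate(self) -> None:
        if (self.values < 0).any():
            raise ValueError("feature values must be nonnegative")
        if self.vocabulary is not None and self.feature_names != self.vocabulary.feature_names:
            raise ValueError("matrix columns do not match the vocabulary")

    @property
    def digest(self) -> str | None:
        return self.vocabulary.digest if self.vocabulary is not None else None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "report_id", self.report_ids)
        return df


def featurize_corpus(
    corpus: LabeledCorpus,
    vocab: NgramVocabulary,
    mode: Literal["count", "binary"] = "count",
) -> FeatureMatrix:
    """Vectorize every report in the corpus against a fitted vocabulary."""
    rows = np.zeros((len(corpus), len(vocab)), dtype=int)
    for i, report in enumerate(corpus):
        rows[i] = vectorize(report, vocab, mode=mode)
    return FeatureMatrix(
        report_ids=corpus.report_ids,
        feature_names=vocab.feature_names,
        values=rows,
        vocabulary=vocab,
    )
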