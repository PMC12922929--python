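from collections import Counter

import pytest
from hypothesis import HealthCheck, settings

import scopesort as ss
from scopesort.featurization import NgramVocabulary, VocabularyEntry, ngrams, normalize

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The printed multi-specimen note style this package targets, with its
# six-feature output row, used across featurization tests.
WORKED_NOTE = (
    "A. Colon, sigmoid, polyp, endoscopic biopsy: The specimens examined "
    "contained both adenoma and sessile serrated polyp. Multiple levels examined"
)
WORKED_FEATURES = [
    "sessile",
    "sessile.serrated",
    "sessile.serrated.polyp",
    "adenoma",
    "polyp",
    "adenoma.polyp",
]


def vocab_from_names(names: list[str]) -> NgramVocabulary:
    """Build a vocabulary directly from dot-joined feature names."""
    entries = []
    rank = {1: 0, 2: 0, 3: 0}
    for name in sorted(names, key=lambda s: s.count(".") + 1):
        tokens = tuple(name.split("."))
        n = len(tokens)
        rank[n] += 1
        entries.append(VocabularyEntry(tokens, n, name, 1, rank[n]))
    return NgramVocabulary(entries)


def brute_force_vocabulary(corpus, limits=(100, 200, 300)):
    """Independent oracle: exhaustively enumerate and sort all n-grams."""
    out = {}
    for n, k in zip((1, 2, 3), limits):
        counts: Counter = Counter()
        for report in corpus:
            counts.update(ngrams(normalize(report.text), n))
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], ".".join(kv[0])))
        out[n] = ranked[:k]
    return out


@pytest.fixture
def worked_report():
    return ss.PathologyReport(report_id="100", text=WORKED_NOTE)


@pytest.fixture
def worked_vocab():
    return vocab_from_names(WORKED_FEATURES)


@pytest.fixture
def tiny_labeled_corpus():
    mk = ss.NeoplasiaLabels
    return ss.LabeledCorpus(
        [
            ss.PathologyReport("r1", "tubular adenoma measuring 4 mm", mk(True, False, False)),
            ss.PathologyReport("r2", "sessile serrated polyp", mk(False, True, False)),
            ss.PathologyReport("r3", "benign colonic mucosa", mk(False, False, False)),
        ]
    )


@pytest.fixture(scope="session")
def noiseless_corpus():
    """Noise-free synthetic corpus: keywords appear iff labels hold."""
    cfg = ss.SyntheticConfig(
        n_reports=240, synonym_rate=0.0, filler_rate=0.0, combination_rate=0.0, seed=42
    )
    return ss.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_default_corpus():
    """Default-noise synthetic corpus at desk scale."""
    return ss.generate_corpus(ss.SyntheticConfig(n_reports=400, seed=9))
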