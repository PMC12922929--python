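import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

import scopesort as ss
from scopesort.synthetic import (
    ADENOMATOUS,
    LOCATIONS,
    PolypFinding,
    SyntheticConfig,
    expected_prevalence,
    label_oracle,
    render_report,
)


def finding(histology, size=4.0, location="sigmoid", hgd=False):
    return PolypFinding(location=location, size_mm=size, histology=histology,
                        high_grade_dysplasia=hgd)


@pytest.mark.parametrize(
    "findings,expected",
    [
        # large hyperplastic: advanced by size alone, never serrated
        ([finding("hyperplastic", size=12)], (False, False, True)),
        ([finding("sessile_serrated", size=4, location="ascending")], (False, True, False)),
        ([], (False, False, False)),
        # villous component makes an adenoma advanced regardless of size
        ([finding("tubulovillous_adenoma", size=6, location="cecum")], (True, False, True)),
        ([finding("villous_adenoma", size=3)], (True, False, True)),
        ([finding("tubular_adenoma", size=4)], (True, False, False)),
        ([finding("tubular_adenoma", size=4, hgd=True)], (True, False, True)),
        ([finding("tubular_adenoma", size=10)], (True, False, True)),
        # plain adenocarcinoma is advanced-only
        ([finding("adenocarcinoma", size=15)], (False, False, True)),
        ([finding("hyperplastic", size=4)], (False, False, False)),
        ([finding("normal", size=1)], (False, False, False)),
        ([finding("traditional_serrated", size=3), finding("tubular_adenoma", size=2)],
         (True, True, False)),
    ],
)
def test_label_oracle_category_definitions(findings, expected):
    labels = label_oracle(findings)
    assert (labels.adenoma, labels.serrated, labels.advanced) == expected


def test_gastric_findings_never_change_colorectal_labels():
    gastric = PolypFinding(location="stomach", size_mm=14, histology="hyperplastic")
    assert label_oracle([gastric]).negative
    base = [finding("tubular_adenoma")]
    assert label_oracle(base) == label_oracle(base + [gastric])


findings_st = st.lists(
    st.builds(
        lambda h, s, loc, g: PolypFinding(
            location=loc,
            size_mm=s,
            histology=h,
            high_grade_dysplasia=g and h in (ADENOMATOUS | {"adenocarcinoma"}),
        ),
        h=st.sampled_from(list(ss.synthetic.HISTOLOGIES)),
        s=st.floats(min_value=1.0, max_value=30.0, allow_nan=False),
        loc=st.sampled_from(list(LOCATIONS)),
        g=st.booleans(),
    ),
    max_size=5,
)


@given(base=findings_st, extra=findings_st)
def test_label_oracle_is_monotone(base, extra):
    before = label_oracle(base)
    after = label_oracle(base + extra)
    for c in ss.CATEGORIES:
        assert after.get(c) >= before.get(c)


def test_hgd_invariant_enforced():
    with pytest.raises(ValueError, match="high_grade_dysplasia"):
        PolypFinding(location="sigmoid", size_mm=4, histology="hyperplastic",
                     high_grade_dysplasia=True)
    with pytest.raises(ValueError, match="positive"):
        PolypFinding(location="sigmoid", size_mm=0, histology="tubular_adenoma")


def test_render_mentions_each_histology_term_once():
    cfg = SyntheticConfig(synonym_rate=0.0, filler_rate=0.0, combination_rate=0.0)
    rng = np.random.default_rng(0)
    text = render_report([finding("tubular_adenoma", size=6)], cfg, rng)
    assert text.count("tubular adenoma") == 1
    assert "6 mm" in text
    two = render_report(
        [finding("tubular_adenoma"), finding("tubular_adenoma", location="cecum")],
        cfg, rng,
    )
    assert two.count("tubular adenoma") == 2
    assert two.startswith("A.") and " B. " in two


def test_render_size_always_present_for_large_polyps():
    cfg = SyntheticConfig()
    rng = np.random.default_rng(1)
    for _ in range(20):
        text = render_report([finding("hyperplastic", size=12)], cfg, rng)
        assert "12 mm" in text


def test_render_empty_findings_is_normal_mucosa():
    cfg = SyntheticConfig(synonym_rate=0.0, filler_rate=0.0)
    text = render_report([], cfg, np.random.default_rng(2))
    assert "mucosa" in text.lower()
    for phrase in ("adenoma", "serrated", "adenocarcinoma", "dysplasia", "hyperplastic"):
        assert phrase not in text.lower()


def test_render_gastric_part_contains_fundic_gland_polyp():
    cfg = SyntheticConfig()
    gastric = PolypFinding(location="stomach", size_mm=3, histology="normal")
    text = render_report([finding("tubular_adenoma"), gastric], cfg,
                         np.random.default_rng(3))
    assert "fundic gland polyp" in text.lower()
    assert "Stomach" in text


def test_generate_corpus_deterministic_under_seed():
    cfg = SyntheticConfig(n_reports=100, seed=7)
    a = ss.generate_corpus(cfg)
    b = ss.generate_corpus(cfg)
    assert a.reports == b.reports
    c = ss.generate_corpus(SyntheticConfig(n_reports=100, seed=8))
    assert a.reports != c.reports


def test_degenerate_normal_prevalence_gives_all_negative():
    prev = {h: 0.0 for h in ss.synthetic.HISTOLOGIES}
    prev["normal"] = 1.0
    corpus = ss.generate_corpus(
        SyntheticConfig(n_reports=50, histology_prevalence=prev, combination_rate=0.0, seed=1)
    )
    assert all(r.labels.negative for r in corpus)


def test_noiseless_keywords_track_labels(noiseless_corpus):
    for r in noiseless_corpus:
        text = r.text.lower()
        assert ("sessile serrated" in text or "traditional serrated" in text) == r.labels.serrated
        has_adenomatous = any(
            p in text for p in ("tubular adenoma", "tubulovillous adenoma", "villous adenoma")
        )
        assert has_adenomatous == r.labels.adenoma


def test_invalid_probability_vector_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SyntheticConfig(polyp_count_distribution=(0.5, 0.4))
    bad = {h: 1.0 / 7 for h in ss.synthetic.HISTOLOGIES if h != "normal"}
    with pytest.raises(ValueError, match="histology"):
        SyntheticConfig(histology_prevalence=bad)


def _analytic_prevalence(cfg: SyntheticConfig) -> dict[str, float]:
    """Independent enumeration of the per-report positive probabilities."""
    p_large = 1.0 - norm.cdf((math.log(9.5) - cfg.size_log_mean) / cfg.size_log_sd)
    per_polyp = {"adenoma": 0.0, "serrated": 0.0, "advanced": 0.0}
    for h, p in cfg.histology_prevalence.items():
        adenomatous = h in ("tubular_adenoma", "tubulovillous_adenoma", "villous_adenoma")
        villous = h in ("tubulovillous_adenoma", "villous_adenoma")
        if adenomatous:
            per_polyp["adenoma"] += p
        if h in ("sessile_serrated", "traditional_serrated"):
            per_polyp["serrated"] += p
        if h == "normal":
            continue
        if h == "adenocarcinoma" or villous:
            adv = 1.0
        else:
            hgd = cfg.hgd_rate if adenomatous else 0.0
            adv = p_large + (1 - p_large) * hgd
        per_polyp["advanced"] += p * adv
    return {
        c: 1.0 - sum(
            pk * (1 - q) ** k for k, pk in enumerate(cfg.polyp_count_distribution)
        )
        for c, q in per_polyp.items()
    }


def test_empirical_prevalence_matches_analytic_model():
    cfg = SyntheticConfig(n_reports=2000, seed=7)
    corpus = ss.generate_corpus(cfg)
    analytic = _analytic_prevalence(cfg)
    # the package's own calculator must agree with the independent enumeration
    packaged = expected_prevalence(cfg)
    for c in ss.CATEGORIES:
        assert packaged[c] == pytest.approx(analytic[c], abs=1e-12)
    for c in ss.CATEGORIES:
        p = analytic[c]
        se = math.sqrt(p * (1 - p) / cfg.n_reports)
        observed = np.mean(corpus.labels_for(c))
        assert abs(observed - p) <= 3 * se


def test_default_conditions_have_enough_positives():
    prev = expected_prevalence(SyntheticConfig())
    assert all(p >= 0.10 for p in prev.values())
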