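"""Synthetic pathology-report generator with a deterministic label oracle.

Real colonoscopy pathology notes are private EHR data, so training and
evaluation exercises run on simulated notes.  Generation is
latent-findings-first: each report draws a set of polyp findings
(histology, size, location, dysplasia), the ground-truth labels are
computed from those latent findings by :func:`label_oracle` — never from
the rendered text — and only then is the note text rendered with
configurable noise (phrase synonyms, boilerplate filler, and
combination-procedure gastric segments).  This keeps classifier-recovery
experiments well posed: rendering noise can obscure the signal in the
text but can never change the ground truth.

Category definitions implemented by the oracle:

* adenoma — any colorectal adenomatous histology (tubular, tubulovillous
  or villous adenoma);
* serrated — any colorectal sessile serrated or traditional serrated
  lesion; hyperplastic polyps are excluded from this category;
* advanced — any colorectal adenocarcinoma, OR any colorectal polyp
  measuring >= 10 mm regardless of histology (hyperplastic included), OR
  any villous component (villous or tubulovillous histology), OR any
  high-grade dysplasia.

A report is "negative" when all three flags are false.  Gastric findings
(injected as combination-procedure noise) never contribute to the
colorectal labels; they are a pure text confounder, mimicking the
fundic-gland-polyp trap that combination procedures pose for text
classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import LabeledCorpus, NeoplasiaLabels, PathologyReport

LOCATIONS = ("cecum", "ascending", "transverse", "descending", "sigmoid", "rectum")
GASTRIC_LOCATION = "stomach"

HISTOLOGIES = (
    "tubular_adenoma",
    "tubulovillous_adenoma",
    "villous_adenoma",
    "sessile_serrated",
    "traditional_serrated",
    "hyperplastic",
    "adenocarcinoma",
    "normal",
)

ADENOMATOUS = {"tubular_adenoma", "tubulovillous_adenoma", "villous_adenoma"}
SERRATED = {"sessile_serrated", "traditional_serrated"}
VILLOUS = {"tubulovillous_adenoma", "villous_adenoma"}
_HGD_ELIGIBLE = ADENOMATOUS | {"adenocarcinoma"}

ADVANCED_SIZE_MM = 10.0


@dataclass(frozen=True)
class PolypFinding:
    """One latent specimen-level finding."""

    location: str
    size_mm: float
    histology: str
    high_grade_dysplasia: bool = False

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS + (GASTRIC_LOCATION,):
            raise ValueError(f"unknown location {self.location!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if self.high_grade_dysplasia and self.histology not in _HGD_ELIGIBLE:
            raise ValueError(
                "high_grade_dysplasia only occurs with adenomatous or "
                "adenocarcinoma histologies"
            )

    @property
    def gastric(self) -> bool:
        return self.location == GASTRIC_LOCATION

    @property
    def is_polyp(self) -> bool:
        """Normal-histology findings are mucosal biopsies, not polyps."""
        return self.histology != "normal"


def label_oracle(findings: Sequence[PolypFinding]) -> NeoplasiaLabels:
    """Ground-truth labels from latent findings (total, deterministic).

    Gastric findings are ignored.  Plain adenocarcinoma sets only the
    advanced flag; the adenoma flag requires an adenomatous histology.
    The >= 10 mm size rule applies to any colorectal polyp, hyperplastic
    included, but not to normal-mucosa biopsies.  The oracle is monotone:
    adding a finding can only turn flags on, never off.
    """
    colorectal = [f for f in findings if not f.gastric]
    adenoma = any(f.histology in ADENOMATOUS for f in colorectal)
    serrated = any(f.histology in SERRATED for f in colorectal)
    advanced = any(
        f.histology == "adenocarcinoma"
        or (f.is_polyp and f.size_mm >= ADVANCED_SIZE_MM)
        or f.histology in VILLOUS
        or f.high_grade_dysplasia
        for f in colorectal
    )
    return NeoplasiaLabels(adenoma=adenoma, serrated=serrated, advanced=advanced)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the study conditions.

    Polyp counts follow ``polyp_count_distribution`` over 0..P findings
    per report.  Histologies are drawn i.i.d. from
    ``histology_prevalence``.  Sizes are lognormal in millimetres
    (log-mean ln 4 mm, log-sd 0.6 — a clinically plausible small-polyp
    skew giving roughly 7% of polyps >= 10 mm) and rounded the way
    endoscopists report them — whole millimetres below 10 mm, multiples
    of 5 above (terminal-digit preference) — so the rendered size and
    the latent size agree exactly.
    The three noise rates control phrase-variant substitution, boilerplate
    filler sentences, and injection of a gastric-biopsy segment
    (combination procedure).  All randomness comes from one stream seeded
    by ``seed``; identical seeds give byte-identical corpora.
    """

    n_reports: int = 2000
    polyp_count_distribution: tuple[float, ...] = (0.25, 0.35, 0.22, 0.12, 0.06)
    histology_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "tubular_adenoma": 0.40,
            "tubulovillous_adenoma": 0.08,
            "villous_adenoma": 0.02,
            "sessile_serrated": 0.12,
            "traditional_serrated": 0.03,
            "hyperplastic": 0.25,
            "adenocarcinoma": 0.02,
            "normal": 0.08,
        }
    )
    size_log_mean: float = math.log(4.0)
    size_log_sd: float = 0.6
    hgd_rate: float = 0.05
    combination_rate: float = 0.05
    synonym_rate: float = 0.2
    filler_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if abs(sum(self.polyp_count_distribution) - 1.0) > 1e-9:
            raise ValueError("polyp_count_distribution must sum to 1")
        if any(p < 0 for p in self.polyp_count_distribution):
            raise ValueError("polyp_count_distribution must be nonnegative")
        if set(self.histology_prevalence) != set(HISTOLOGIES):
            raise ValueError("histology_prevalence must cover every histology")
        if abs(sum(self.histology_prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("histology_prevalence must sum to 1")
        for name in ("hgd_rate", "combination_rate", "synonym_rate", "filler_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


# Canonical phrase per histology (used when no synonym substitution fires)
# followed by its accepted variants.  Canonical rendering mentions each
# finding's histology term exactly once.
_PHRASES: dict[str, tuple[str, ...]] = {
    "tubular_adenoma": (
        "tubular adenoma",
        "adenomatous polyp, tubular type",
    ),
    "tubulovillous_adenoma": (
        "tubulovillous adenoma",
        "adenoma with tubulovillous architecture",
    ),
    "villous_adenoma": (
        "villous adenoma",
        "adenoma with villous architecture",
    ),
    "sessile_serrated": (
        "sessile serrated polyp",
        "sessile serrated adenoma",
        "sessile serrated lesion",
    ),
    "traditional_serrated": (
        "traditional serrated adenoma",
        "serrated adenoma, traditional type",
    ),
    "hyperplastic": (
        "hyperplastic polyp",
        "hyperplastic mucosal polyp",
    ),
    "adenocarcinoma": (
        "invasive adenocarcinoma",
        "moderately differentiated adenocarcinoma",
    ),
}

_HGD_SENTENCES = (
    "High-grade dysplasia is identified.",
    "Focal high grade dysplasia is present.",
)

_FILLER_SENTENCES = (
    "Clinical history reviewed.",
    "The findings were discussed with the clinical team.",
    "Immunohistochemical stains were not required for diagnosis.",
    "Cautery artifact is noted at the margin.",
    "Specimen received in formalin and labeled with the patient name.",
    "Gross description: tan pink soft tissue fragments measuring up to 0.5 cm in aggregate.",
    "Sections show unremarkable crypt architecture without active inflammation.",
    "There is no evidence of granulomas, viral inclusions, or parasitic organisms.",
    "The lamina propria contains a normal complement of chronic inflammatory cells.",
    "Electronic signature applied by the reviewing pathologist.",
    "Correlation with endoscopic impression and clinical presentation is recommended.",
    "Representative sections submitted entirely in one cassette.",
)

_NORMAL_BODY = "Benign colonic mucosa with no diagnostic abnormality."

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _part_header(letter: str, finding: PolypFinding) -> str:
    if finding.gastric:
        return f"{letter}. Stomach, body, polyp, cold biopsy:"
    loc = finding.location
    if finding.is_polyp:
        return f"{letter}. Colon, {loc}, polyp, endoscopic biopsy:"
    return f"{letter}. Colon, {loc}, biopsy:"


def render_report(
    findings: Sequence[PolypFinding],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> str:
    """Render findings as a multi-part pathology note.

    Each finding becomes one lettered specimen part.  Polyp sizes are
    always rendered as "<n> mm" (so every finding >= 10 mm carries its
    size in the text).  With probability ``synonym_rate`` a finding's
    canonical histology phrase is replaced by a field-typical variant;
    with probability ``filler_rate`` a part gains a boilerplate sentence.
    An empty findings list renders as a single normal-mucosa part.
    """
    parts: list[str] = []
    effective = list(findings)
    if not effective:
        loc = LOCATIONS[rng.integers(len(LOCATIONS))]
        effective = [PolypFinding(location=loc, size_mm=1.0, histology="normal")]
    for idx, f in enumerate(effective):
        letter = _LETTERS[idx % len(_LETTERS)]
        sentences: list[str] = []
        if f.gastric:
            sentences.append("Fundic gland polyp.")
            sentences.append("No dysplasia identified.")
        elif not f.is_polyp:
            sentences.append(_NORMAL_BODY)
        else:
            variants = _PHRASES[f.histology]
            phrase = variants[0]
            if len(variants) > 1 and rng.random() < config.synonym_rate:
                phrase = variants[1 + rng.integers(len(variants) - 1)]
            size = int(round(f.size_mm))
            sentences.append(
                f"The specimen contains a {phrase} measuring {size} mm."
            )
            if f.high_grade_dysplasia:
                hgd = _HGD_SENTENCES[0]
                if rng.random() < config.synonym_rate:
                    hgd = _HGD_SENTENCES[1]
                sentences.append(hgd)
        if rng.random() < config.filler_rate:
            sentences.append(_FILLER_SENTENCES[rng.integers(len(_FILLER_SENTENCES))])
        sentences.append("Multiple levels examined.")
        parts.append(_part_header(letter, f) + " " + " ".join(sentences))
    return " ".join(parts)


def _draw_findings(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[PolypFinding], bool]:
    counts = np.asarray(config.polyp_count_distribution, dtype=float)
    k = int(rng.choice(len(counts), p=counts / counts.sum()))
    hist_names = list(HISTOLOGIES)
    hist_p = np.asarray([config.histology_prevalence[h] for h in hist_names])
    findings: list[PolypFinding] = []
    for _ in range(k):
        h = hist_names[int(rng.choice(len(hist_names), p=hist_p / hist_p.sum()))]
        loc = LOCATIONS[int(rng.integers(len(LOCATIONS)))]
        if h == "normal":
            findings.append(PolypFinding(location=loc, size_mm=1.0, histology=h))
            continue
        raw = rng.lognormal(mean=config.size_log_mean, sigma=config.size_log_sd)
        # clinicians report sizes with terminal-digit preference: whole mm
        # below 10, multiples of 5 above; the label uses the reported size
        size = int(round(raw))
        if size >= 10:
            size = int(round(raw / 5.0)) * 5
        size = float(min(max(size, 1), 60))
        hgd = bool(h in _HGD_ELIGIBLE and rng.random() < config.hgd_rate)
        findings.append(
            PolypFinding(location=loc, size_mm=size, histology=h, high_grade_dysplasia=hgd)
        )
    combination = bool(rng.random() < config.combination_rate)
    if combination:
        findings.append(
            PolypFinding(location=GASTRIC_LOCATION, size_mm=3.0, histology="normal")
        )
    return findings, combination


def generate_corpus(config: SyntheticConfig) -> LabeledCorpus:
    """Generate ``config.n_reports`` labeled synthetic reports.

    Labels come from :func:`label_oracle` applied to the latent findings,
    before any rendering noise.  Identical configs (including seed)
    produce byte-identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    reports: list[PathologyReport] = []
    for i in range(config.n_reports):
        findings, combination = _draw_findings(config, rng)
        labels = label_oracle(findings)
        text = render_report(findings, config, rng)
        reports.append(
            PathologyReport(
                report_id=f"SYN-{i:06d}",
                text=text,
                labels=labels,
                combination_procedure=combination,
            )
        )
    return LabeledCorpus(reports, provenance=f"synthetic(seed={config.seed})")


def expected_prevalence(config: SyntheticConfig) -> dict[str, float]:
    """Analytic per-report probability that each category flag is positive.

    Computed by enumeration over the latent generative model: per-polyp
    positive probabilities from the histology prevalences, the rounded
    lognormal size model and the dysplasia rate, then 1 - E[(1-q)^K] over
    the polyp-count distribution.  Useful for calibrating configurations.
    """
    from scipy.stats import norm

    # rounding to whole mm makes the >=10 mm event equivalent to raw >= 9.5
    p_large = float(
        1.0 - norm.cdf((math.log(9.5) - config.size_log_mean) / config.size_log_sd)
    )
    prev = config.histology_prevalence
    q = {"adenoma": 0.0, "serrated": 0.0, "advanced": 0.0}
    for h, p_h in prev.items():
        if h in ADENOMATOUS:
            q["adenoma"] += p_h
        if h in SERRATED:
            q["serrated"] += p_h
        if h == "normal":
            continue
        if h == "adenocarcinoma" or h in VILLOUS:
            p_adv = 1.0
        else:
            hgd = config.hgd_rate if h in _HGD_ELIGIBLE else 0.0
            p_adv = p_large + (1.0 - p_large) * hgd
        q["advanced"] += p_h * p_adv
    out = {}
    for cat, q_cat in q.items():
        miss = sum(
            p_k * (1.0 - q_cat) ** k
            for k, p_k in enumerate(config.polyp_count_distribution)
        )
        out[cat] = 1.0 - miss
    return out
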