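# Methods

## Classification model

`scopesort` classifies a free-text colonoscopy pathology note with three
independent one-vs-rest binary classifiers, one per neoplasia category
(adenoma, serrated lesion, advanced lesion).  The categories are defined
as:

* *adenoma*: any colorectal adenomatous histology — tubular,
  tubulovillous or villous adenoma.  Plain adenocarcinoma does **not**
  set this flag (an invasive cancer is advanced, not an adenoma).
* *serrated*: sessile serrated adenoma/polyp or traditional serrated
  adenoma.  Hyperplastic polyps are deliberately excluded; including them
  only when large would make detection-rate reporting gameable by
  specimen-jar ambiguity.
* *advanced*: colorectal adenocarcinoma, any polyp ≥ 10 mm regardless of
  histology (hyperplastic included), any villous component, or
  high-grade dysplasia.

"Negative" is derived, never predicted: it holds when all three flags
are false.  The flags are not mutually exclusive.

### Featurization

Normalization is intentionally minimal — lowercase, split on any
non-alphanumeric character, drop empty fragments, keep numerals.  There
is no stop-word removal, stemming, negation handling or sentence
segmentation; a note is tokenized as one word stream, so n-grams cross
sentence and specimen-part boundaries but never note boundaries.  The
specimen headers ("A. Colon, sigmoid, …") are tokenized along with the
body.

The feature space is the frequency-ranked top 100 unigrams, 200 bigrams
and 300 trigrams of the training corpus (600 features when the corpus is
rich enough; a sparser corpus yields fewer).  "Most frequent" means
total term frequency across the corpus by default; a document-frequency
mode is available (`count="df"`).  Ties at the cutoff rank are broken
lexicographically on the dot-joined feature name, making the vocabulary
deterministic and order-independent.  Feature values are occurrence
counts of the vocabulary n-gram in the note (default) or presence
indicators (`mode="binary"`); counts are the primary semantics, the
binary mode exists because presence and count disagree only for repeated
n-grams and some report styles repeat boilerplate heavily.

### Forests, tuning, scores

Each category model is a bootstrap-aggregated decision-tree ensemble
(scikit-learn's `RandomForestClassifier`; the contribution of this
package is the surrounding pipeline contract, not tree induction).
The tuned hyperparameters, with defaults mirroring the reference
workflow, are:

| parameter | grid | maps to |
|---|---|---|
| minimum node size | {2, 3, 4, 5} | `min_samples_split` — a node with fewer points is not split; depth is otherwise unconstrained |
| predictors sampled per split | {1, 2, 3, 4, 5} | `max_features` (absolute count) |
| number of trees | 500 by 200 up to 2,000 | `n_estimators` |

The tree-count sequence 500, 700, …, 1900 never lands on 2,000, so 2,000
is appended to the default grid; the endpoint is otherwise unreachable
yet final models are expected to use it.

Tuning is 5-fold cross-validation maximizing mean out-of-fold AUC over
the Cartesian grid.  Fold assignment is stratified and keyed by a seeded
hash of each `report_id` (within each class, ids are ordered by hash and
dealt round-robin), so CV results are invariant to row permutation of
the corpus.  Each (category, grid point, fold) combination draws its
forest seed from an independent substream, so results do not depend on
evaluation order.  AUC ties are broken for parsimony: fewest trees, then
largest minimum node size, then fewest predictors.

A report's category score is the forest's mean terminal-node positive
rate, bounded in [0, 1].  Scoring verifies a SHA-256 digest of the
ordered vocabulary names against the model's training vocabulary; a
mismatch is a hard error rather than a silently misaligned prediction.

### Train/test split and cut points

The labeled corpus is split 75/25 (train fraction configurable); the
train size is round-half-up of n × fraction, which maps 35,953 records
to 26,965/8,988.  Assignment is by seeded report-id hash (deterministic,
order-independent); an optional stratified mode preserves one category's
class proportions within ±1 report via largest-remainder allocation.
The n-gram vocabulary is fitted on the training half only, preventing
feature-selection leakage into test metrics; a `vocab_on_full`
compatibility switch exists for pipelines that fitted the vocabulary
before splitting.

Cut points convert scores to flags: positive iff score ≥ cut (closed at
the cut; a convention had to be fixed).  The default chooser maximizes
the Youden index J = sensitivity + specificity − 1 over a threshold
curve whose candidates are the midpoints between consecutive distinct
test-set scores plus sentinels 0 and 1 — every achievable confusion
table appears exactly once.  Youden ties go to the **larger** threshold,
favouring specificity.  Because the upper sentinel is 1 and the
comparison is closed, a score of exactly 1.0 remains positive at every
threshold; the empty-prediction ROC vertex is therefore not on the curve
in that degenerate case (the AUC itself is computed by rank statistic
and unaffected).  Cut points are data products and carry a provenance
note; a manual mode passes user-supplied values through unchanged.

After cut points are chosen on the test half, a final model is refit per
category on the full corpus with the tuned hyperparameters and locked
into a bundle (three forests + vocabulary + cut points + metadata).  The
test metrics reported by the pipeline come from the train-half models
scored on the test half — the unbiased estimate the locked bundle
inherits — never from resubstitution.

### Evaluation

AUC is the exact Mann–Whitney rank statistic, P(score⁺ > score⁻) +
½P(tie) over all positive–negative pairs.  Confidence intervals are
stratified percentile bootstrap: positives and negatives are resampled
separately (every resample keeps both classes), 2,000 resamples and
level 0.95 by default, deterministic under a seed, clipped to [0, 1].
The bootstrap was chosen because it is assumption-light and seedable; a
DeLong analytic interval is a possible future flag.  Sensitivity,
specificity, PPV, NPV and F1 come from exact confusion counts; a metric
with a zero denominator is reported as missing (`None`/`null`), never
as 0, so summaries are not silently biased.

A keyword/regular-expression baseline ships for comparison: per
category, ordered include/exclude patterns; an include match is
suppressed when an exclude pattern matches within ±5 words of the
matched span.  The default ruleset
(`src/scopesort/data/default_rules.json`) is a synthetic stand-in
written for this package and clearly marked as such in the file — no
published ruleset was available to reuse.  It is evaluated through the
identical reporting path as the forests, so any comparison differs only
in the classifier.

## Synthetic report generator

Real pathology reports are private EHR data, so development and
evaluation run on simulated notes.  Generation is latent-findings-first:

1. Draw a polyp count K from `polyp_count_distribution`
   (default (0.25, 0.35, 0.22, 0.12, 0.06) over 0–4 findings).
2. Per finding: histology from `histology_prevalence` (defaults: tubular
   adenoma .40, tubulovillous .08, villous .02, sessile serrated .12,
   traditional serrated .03, hyperplastic .25, adenocarcinoma .02,
   normal mucosa .08), uniform colorectal location, size lognormal
   (log-mean ln 4 mm, log-sd 0.6) and high-grade dysplasia at rate .05
   for adenomatous/adenocarcinoma findings.
3. Compute ground-truth labels from the findings with the deterministic
   label oracle implementing the category definitions above.
4. Render the note: one lettered specimen part per finding in the
   "A. Colon, sigmoid, polyp, endoscopic biopsy: …" style, histology
   phrase and "\<n\> mm" size always present, then apply noise — phrase
   synonyms at rate .20, boilerplate filler sentences at rate .30 per
   part, and a gastric fundic-gland-polyp segment at rate .05
   (combination procedures, a known text confounder).

Labels are computed **before** rendering and never from the text, so
rendering noise can obscure signal but cannot change ground truth; the
oracle is monotone (adding findings never clears a flag) and ignores
gastric findings entirely.  With all noise rates at zero, label-relevant
keywords appear in the text iff the label condition holds, which makes
near-perfect classifier recovery the expected outcome and turns the
pipeline into a falsifiable end-to-end test.

Sizes are reported the way endoscopists report them: whole millimetres
below 10 mm and multiples of 5 above (terminal-digit preference).  The
label oracle uses the reported size, so text and ground truth agree
exactly, and the analytic probability of the ≥ 10 mm event is unchanged
(reported ≥ 10 ⟺ raw ≥ 9.5).  An exact-millimetre rendering was
rejected: it scatters the large-size evidence across ~50 rare tokens
that a 100-unigram vocabulary cannot retain, leaving a tranche of
advanced lesions textually unlabelable — an artifact of the simulation,
not a property of clinical text.

The default rates give analytic per-report prevalences of about .50
(adenoma), .19 (serrated) and .24 (advanced) — each category has
comfortably more than 10% positives at n = 2,000, enough for stable AUC
estimation at desk scale (`expected_prevalence()` computes these
analytically for any configuration).

What the generator does *not* emulate: real clinical language variety
(templated phrases with a fixed synonym pool only), misspellings, OCR
noise, negation ("no adenoma seen"), inter-institution format drift,
multi-polyp specimen jars with ambiguous size attribution, and
inflammatory-bowel-disease reporting.  Passing recovery tests therefore
demonstrates that the pipeline is implemented correctly and can extract
signal a bag-of-n-grams can represent — not that the classifier reaches
any particular accuracy on real EHR text.

## Numerical and design choices

* All randomness flows from explicit integer seeds; corpora, splits,
  folds, forests, bootstraps and reports are byte-reproducible.
* Train-size rounding is half-up (floor rounding fails to reproduce the
  26,965/8,988 reference partition).
* Degenerate inputs: empty note texts featurize to all-zero rows and are
  scoreable; an empty corpus cannot fit a vocabulary (hard error);
  single-class label vectors are hard errors for fitting, tuning, AUC
  and threshold curves; a category with no positives in an evaluation
  corpus is a hard error naming the category.
* Desk-scale problem sizes used by the test suite and the acceptance
  script: 2,000-report corpora and a reduced 2×2×2 grid
  ({2,5} × {3,5} × {500,700}) for pipeline recovery, a 600-report corpus
  with a single-point grid for the end-to-end determinism check.  These
  sizes give stable results while keeping a full run in minutes on one
  CPU; the grid, corpus size and all rates are configurable.
* Bundle persistence stores the vocabulary as TSV, hyperparameters and
  cut points as JSON, forests via joblib, and a manifest of SHA-256 file
  hashes; loading verifies completeness and re-checks the vocabulary
  digest at scoring time.

## Known limitations

* The bag-of-n-grams representation is blind to negation and to any
  size token rarer than the vocabulary cutoff; advanced-lesion recall is
  correspondingly the weakest of the three categories in recovery runs.
* The rule baseline's default patterns are a constructed stand-in, not a
  validated clinical ruleset; treat its numbers as a floor, not a
  benchmark.
* Scores are vote fractions, not calibrated probabilities; cut points
  chosen on one population need not transfer to another.
* The generator embeds polyp size in the pathology text; in real
  workflows size often lives in the colonoscopy (procedure) report and
  would require record linkage upstream of this package.
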