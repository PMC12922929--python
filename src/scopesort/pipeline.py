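"""End-to-end run configuration and orchestration.

``run_pipeline`` chains the whole workflow: split the labeled corpus,
fit the n-gram vocabulary on the training half (leakage-free; a
vocab-on-full compatibility switch exists), tune each category model by
5-fold CV, fit on the training half, choose cut points on the held-out
test half, report test metrics, then retrain a final locked bundle on
the full corpus with the tuned hyperparameters.

Identical config + corpus + seed gives byte-identical evaluation
reports and bundle scores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .corpus import CATEGORIES, LabeledCorpus
from .evaluation import EvaluationReport, evaluate_bundle
from .featurization import DEFAULT_LIMITS, build_vocabulary, featurize_corpus
from .modeling import (
    HyperParams,
    ModelBundle,
    TuningGrid,
    _forest_seed,
    fit,
    split_corpus,
    tune,
)
from .thresholds import CutPoints, choose_cutpoint, threshold_curve


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the reference workflow
    (vocabulary limits 100/200/300, train fraction 0.75, 5 folds,
    the full hyperparameter grid, Youden-maximizing cut points)."""

    seed: int
    vocab_limits: tuple[int, int, int] = DEFAULT_LIMITS
    train_fraction: float = 0.75
    folds: int = 5
    grid: TuningGrid = field(default_factory=TuningGrid)
    cutpoint_method: str = "youden_max"
    count_mode: str = "count"
    vocab_on_full: bool = False
    stratify_by: Optional[str] = None
    n_boot: int = 2000
    ci_level: float = 0.95

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {
            "min_node_sizes": list(self.grid.min_node_sizes),
            "n_predictors": list(self.grid.n_predictors),
            "n_trees_values": list(self.grid.n_trees_values),
        }
        d["vocab_limits"] = list(self.vocab_limits)
        return d

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()


def run_pipeline(
    config: RunConfig, corpus: LabeledCorpus
) -> tuple[ModelBundle, EvaluationReport]:
    """Run split -> vocabulary -> tune -> fit -> cut points -> evaluate ->
    final locked bundle.  Any stage failure aborts with the stage name."""
    if not corpus.is_labeled:
        raise PipelineError("input", "pipeline requires a labeled corpus")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrap

    train, test = stage("split")(
        split_corpus, corpus, config.train_fraction, config.seed, config.stratify_by
    )
    vocab_source = corpus if config.vocab_on_full else train
    vocab = stage("vocabulary")(
        build_vocabulary, vocab_source, limits=config.vocab_limits
    )
    X_train = stage("featurize")(featurize_corpus, train, vocab, mode=config.count_mode)
    X_test = stage("featurize")(featurize_corpus, test, vocab, mode=config.count_mode)

    best_params: dict[str, HyperParams] = {}
    test_scores: dict[str, np.ndarray] = {}
    interim_models = {}
    cv_tables = {}
    for c in CATEGORIES:
        y_train = train.labels_for(c)
        best, cv_table = stage("tune")(
            tune, X_train, y_train, c, config.grid, config.folds, config.seed
        )
        best_params[c] = best
        cv_tables[c] = cv_table
        model = stage("fit")(
            fit,
            X_train,
            y_train,
            best,
            seed=_forest_seed(config.seed, c, best, config.folds),
            category=c,
        )
        interim_models[c] = model
        test_scores[c] = stage("score")(model.score, X_test)

    cut_values = {}
    for c in CATEGORIES:
        curve = stage("cutpoints")(threshold_curve, test_scores[c], test.labels_for(c))
        cut_values[c] = stage("cutpoints")(choose_cutpoint, curve, config.cutpoint_method)
    cutpoints = CutPoints(
        adenoma=cut_values["adenoma"],
        serrated=cut_values["serrated"],
        advanced=cut_values["advanced"],
        method=config.cutpoint_method,
        provenance=f"chosen on held-out test half (n={len(test)}, seed={config.seed})",
    )

    X_full = stage("featurize")(featurize_corpus, corpus, vocab, mode=config.count_mode)
    final_models = {}
    for c in CATEGORIES:
        final_models[c] = stage("final_fit")(
            fit,
            X_full,
            corpus.labels_for(c),
            best_params[c],
            seed=_forest_seed(config.seed, c, best_params[c], config.folds + 1),
            category=c,
        )
    bundle = ModelBundle(
        models=final_models,
        vocabulary=vocab,
        cutpoints=cutpoints,
        locked=True,
        count_mode=config.count_mode,
        metadata={
            "seed": config.seed,
            "config_hash": config.digest,
            "train_size": len(train),
            "test_size": len(test),
            "hyperparams": {c: best_params[c].as_dict() for c in CATEGORIES},
        },
    )

    # test metrics come from the train-half models' scores at the chosen cuts,
    # the unbiased estimate the final locked bundle inherits
    interim = ModelBundle(
        models=interim_models,
        vocabulary=vocab,
        cutpoints=cutpoints,
        locked=False,
        count_mode=config.count_mode,
    )
    report = stage("evaluate")(
        evaluate_bundle,
        interim,
        test,
        n_boot=config.n_boot,
        ci_level=config.ci_level,
        seed=config.seed,
    )
    return bundle, report


def log_manifest(
    config: RunConfig,
    input_paths: dict[str, str | Path] | None = None,
    output_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Machine-readable run record: config and its hash, input/output
    file hashes, and library versions."""

    def file_hash(p: str | Path) -> str:
        return hashlib.sha256(Path(p).read_bytes()).hexdigest()

    import sklearn

    return {
        "config": config.as_dict(),
        "config_hash": config.digest,
        "inputs": {k: file_hash(v) for k, v in (input_paths or {}).items()},
        "outputs": {k: file_hash(v) for k, v in (output_paths or {}).items()},
        "versions": {
            "scopesort": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
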