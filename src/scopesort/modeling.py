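"""Train/test splitting, cross-validated tuning and the three one-vs-rest
random-forest category models.

Each category (adenoma / serrated / advanced) gets its own binary forest
over the shared n-gram feature space; a report's category score is the
forest's mean terminal-node positive rate in [0, 1].  Hyperparameters are
tuned by 5-fold cross-validation over a grid of minimum node size
{2,3,4,5}, predictors sampled per split {1..5}, and tree counts stepping
from 500 by 200 (with 2,000 appended), selecting the grid point with the
best mean out-of-fold AUC.

The forest itself is scikit-learn's ensemble implementation; this module
owns the surrounding contract: order-independent seeded fold assignment,
the tuning grid and its parsimony tie-break, score semantics, and
reproducible bundle persistence.  Minimum node size maps to the minimum
number of data points a node needs to be split further (tree depth is
otherwise unconstrained).

Fold and split assignment key each report by a seeded hash of its
report_id, so cross-validation results are invariant to row permutation
of the corpus.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
import pandas as pd

from .corpus import CATEGORIES, LabeledCorpus
from .evaluation import auc
from .featurization import FeatureMatrix, NgramVocabulary
from .thresholds import CutPoints


@dataclass(frozen=True)
class HyperParams:
    min_node_size: int
    n_predictors_sampled: int
    n_trees: int

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.n_predictors_sampled < 1:
            raise ValueError("n_predictors_sampled must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def as_dict(self) -> dict[str, int]:
        return {
            "min_node_size": self.min_node_size,
            "n_predictors_sampled": self.n_predictors_sampled,
            "n_trees": self.n_trees,
        }


def _default_trees() -> tuple[int, ...]:
    trees = list(range(500, 2000, 200))
    if trees[-1] != 2000:
        trees.append(2000)
    return tuple(trees)


@dataclass
class TuningGrid:
    """Cartesian hyperparameter grid.

    The default tree-count sequence steps from 500 by 200; because that
    never lands on 2,000, the endpoint is appended explicitly so final
    models with 2,000 trees are reachable.
    """

    min_node_sizes: tuple[int, ...] = (2, 3, 4, 5)
    n_predictors: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_trees_values: tuple[int, ...] = field(default_factory=_default_trees)

    def points(self) -> list[HyperParams]:
        return [
            HyperParams(m, p, t)
            for m in self.min_node_sizes
            for p in self.n_predictors
            for t in self.n_trees_values
        ]


def _id_hash(seed: int, report_id: str) -> int:
    h = hashlib.blake2b(f"{seed}:{report_id}".encode("utf-8"), digest_size=8)
    return int.from_bytes(h.digest(), "big")


def split_corpus(
    corpus: LabeledCorpus,
    train_fraction: float,
    seed: int,
    stratify_by: Optional[str] = None,
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Disjoint, exhaustive train/test partition.

    The train size is round-half-up of n * train_fraction (35,953 at 0.75
    gives 26,965 / 8,988).  Assignment orders report ids by a seeded hash,
    so the partition is deterministic and independent of row order.  With
    ``stratify_by`` set to a category, per-class proportions are preserved
    within one report via largest-remainder allocation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    target = int(np.floor(n * train_fraction + 0.5))
    ids = corpus.report_ids
    if stratify_by is None:
        ordered = sorted(ids, key=lambda r: _id_hash(seed, r))
        train_ids = set(ordered[:target])
    else:
        if not corpus.is_labeled:
            raise ValueError("stratified split requires a labeled corpus")
        if stratify_by not in CATEGORIES:
            raise ValueError(f"unknown category {stratify_by!r}")
        flags = corpus.labels_for(stratify_by)
        strata: dict[bool, list[str]] = {True: [], False: []}
        for rid, flag in zip(ids, flags):
            strata[flag].append(rid)
        exact = {k: len(v) * train_fraction for k, v in strata.items()}
        base = {k: int(np.floor(x)) for k, x in exact.items()}
        remaining = target - sum(base.values())
        order = sorted(strata, key=lambda k: exact[k] - base[k], reverse=True)
        for k in order:
            if remaining <= 0:
                break
            if base[k] < len(strata[k]):
                base[k] += 1
                remaining -= 1
        train_ids = set()
        for k, members in strata.items():
            ordered = sorted(members, key=lambda r: _id_hash(seed, r))
            train_ids.update(ordered[: base[k]])
    train = corpus.subset([r for r in ids if r in train_ids], provenance="train")
    test = corpus.subset([r for r in ids if r not in train_ids], provenance="test")
    return train, test


def _fold_assignment(
    report_ids: Sequence[str], labels: Sequence[bool], k: int, seed: int
) -> np.ndarray:
    """Stratified fold labels keyed by seeded report-id hashes.

    Within each class, ids are ordered by hash and dealt round-robin, so
    every fold contains both classes whenever each class has >= k members
    and the assignment does not depend on row order.
    """
    y = np.asarray(labels, dtype=bool)
    if int(y.sum()) < k or int((~y).sum()) < k:
        raise ValueError(
            f"need at least {k} positives and {k} negatives for {k}-fold CV "
            f"(have {int(y.sum())} / {int((~y).sum())})"
        )
    folds = np.empty(len(report_ids), dtype=int)
    for cls in (True, False):
        idx = [i for i, v in enumerate(y) if v == cls]
        idx.sort(key=lambda i: _id_hash(seed, report_ids[i]))
        for j, i in enumerate(idx):
            folds[i] = j % k
    return folds


def _forest_seed(seed: int, category: str, hp: HyperParams, fold: int) -> int:
    """Independent substream per (category, grid point, fold)."""
    ss = np.random.SeedSequence(
        [
            abs(int(seed)),
            CATEGORIES.index(category),
            hp.min_node_size,
            hp.n_predictors_sampled,
            hp.n_trees,
            fold,
        ]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _as_array(features: "FeatureMatrix | np.ndarray") -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values.astype(np.float32)
    return np.asarray(features, dtype=np.float32)


@dataclass
class CategoryModel:
    """One fitted binary forest; maps feature rows to scores in [0, 1]."""

    category: str
    forest: RandomForestClassifier
    hyperparams: HyperParams
    training_vocab_hash: Optional[str] = None

    def score(self, features: "FeatureMatrix | np.ndarray") -> np.ndarray:
        if (
            isinstance(features, FeatureMatrix)
            and self.training_vocab_hash is not None
            and features.digest is not None
            and features.digest != self.training_vocab_hash
        ):
            raise ValueError(
                f"feature columns do not match the {self.category} model's "
                "training vocabulary (hash mismatch)"
            )
        X = _as_array(features)
        if X.shape[0] == 0:
            return np.empty(0, dtype=float)
        proba = self.forest.predict_proba(X)
        pos_col = list(self.forest.classes_).index(True)
        return proba[:, pos_col]


def fit(
    features: "FeatureMatrix | np.ndarray",
    labels: Sequence[bool],
    hp: HyperParams,
    seed: int,
    category: str = "adenoma",
) -> CategoryModel:
    """Fit a bootstrap-aggregated tree ensemble for one category.

    Trees grow until nodes fall below the minimum node size (no depth
    cap); ``n_predictors_sampled`` candidate features are examined per
    split.  Reproducible under a fixed seed.
    """
    X = _as_array(features)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("fit requires at least one positive and one negative label")
    if hp.n_predictors_sampled > X.shape[1]:
        raise ValueError(
            f"n_predictors_sampled={hp.n_predictors_sampled} exceeds "
            f"{X.shape[1]} features"
        )
    forest = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_features=hp.n_predictors_sampled,
        min_samples_split=max(2, hp.min_node_size),
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    digest = features.digest if isinstance(features, FeatureMatrix) else None
    return CategoryModel(
        category=category, forest=forest, hyperparams=hp, training_vocab_hash=digest
    )


def tune(
    features: FeatureMatrix,
    labels: Sequence[bool],
    category: str,
    grid: Optional[TuningGrid] = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Grid search by mean out-of-fold AUC over seeded stratified folds.

    Returns the maximizing grid point and a cv_table recording fold-wise
    and mean AUC for every point.  AUC ties are broken for parsimony:
    fewer trees, then larger minimum node size, then fewer predictors.
    """
    grid = grid or TuningGrid()
    y = np.asarray(labels, dtype=bool)
    folds = _fold_assignment(features.report_ids, y, k_folds, seed)
    X = features.values.astype(np.float32)
    rows = []
    for hp in grid.points():
        fold_aucs = []
        for f in range(k_folds):
            mask = folds == f
            model = fit(
                X[~mask],
                y[~mask],
                hp,
                seed=_forest_seed(seed, category, hp, f),
                category=category,
            )
            fold_aucs.append(auc(model.score(X[mask]), y[mask]))
        rows.append(
            {
                **hp.as_dict(),
                **{f"auc_fold_{f + 1}": a for f, a in enumerate(fold_aucs)},
                "mean_auc": float(np.mean(fold_aucs)),
            }
        )
    cv_table = pd.DataFrame(rows)
    best_auc = cv_table["mean_auc"].max()
    winners = cv_table[cv_table["mean_auc"] >= best_auc - 1e-12]
    chosen = winners.sort_values(
        ["n_trees", "min_node_size", "n_predictors_sampled"],
        ascending=[True, False, True],
    ).iloc[0]
    best = HyperParams(
        int(chosen["min_node_size"]),
        int(chosen["n_predictors_sampled"]),
        int(chosen["n_trees"]),
    )
    return best, cv_table


@dataclass
class ModelBundle:
    """Three category models sharing one vocabulary, plus cut points.

    Once ``locked`` is true the bundle is frozen for validation: classify
    and evaluate never refit anything.
    """

    models: dict[str, CategoryModel]
    vocabulary: NgramVocabulary
    cutpoints: CutPoints
    locked: bool = False
    count_mode: str = "count"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.models) != set(CATEGORIES):
            raise ValueError(f"bundle needs exactly the models {CATEGORIES}")

    def score_corpus(self, corpus: LabeledCorpus) -> dict[str, np.ndarray]:
        from .featurization import featurize_corpus

        features = featurize_corpus(corpus, self.vocabulary, mode=self.count_mode)
        return {c: self.models[c].score(features) for c in CATEGORIES}

    def classify_corpus(self, corpus: LabeledCorpus):
        from .thresholds import classify

        return classify(self.score_corpus(corpus), self.cutpoints)


_BUNDLE_FILES = ("vocab.tsv", "params.json", "cutpoints.json", "manifest.json") + tuple(
    f"forest_{c}.joblib" for c in CATEGORIES
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Persist a bundle: vocabulary TSV, JSON params/cutpoints, one
    serialized forest per category, and a manifest with file hashes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.vocabulary.to_tsv(directory / "vocab.tsv")
    params = {
        "locked": bundle.locked,
        "count_mode": bundle.count_mode,
        "metadata": bundle.metadata,
        "vocab_hash": bundle.vocabulary.digest,
        "hyperparams": {c: bundle.models[c].hyperparams.as_dict() for c in CATEGORIES},
    }
    (directory / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True))
    (directory / "cutpoints.json").write_text(
        json.dumps(bundle.cutpoints.as_dict(), indent=2, sort_keys=True)
    )
    for c in CATEGORIES:
        joblib.dump(bundle.models[c].forest, directory / f"forest_{c}.joblib")
    manifest = {
        "files": {
            name: _sha256(directory / name)
            for name in _BUNDLE_FILES
            if name != "manifest.json"
        }
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_bundle(directory: str | Path) -> ModelBundle:
    """Load a saved bundle; missing component files are a hard error."""
    directory = Path(directory)
    missing = [n for n in _BUNDLE_FILES if not (directory / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"bundle at {directory} is missing: {', '.join(sorted(missing))}"
        )
    vocab = NgramVocabulary.from_tsv(directory / "vocab.tsv")
    params = json.loads((directory / "params.json").read_text())
    cutpoints = CutPoints.from_dict(json.loads((directory / "cutpoints.json").read_text()))
    models = {}
    for c in CATEGORIES:
        forest = joblib.load(directory / f"forest_{c}.joblib")
        hp = HyperParams(**params["hyperparams"][c])
        models[c] = CategoryModel(
            category=c,
            forest=forest,
            hyperparams=hp,
            training_vocab_hash=params.get("vocab_hash"),
        )
    return ModelBundle(
        models=models,
        vocabulary=vocab,
        cutpoints=cutpoints,
        locked=bool(params["locked"]),
        count_mode=params.get("count_mode", "count"),
        metadata=params.get("metadata", {}),
    )
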