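import random

import numpy as np
import pytest

import scopesort as ss
from scopesort.modeling import (
    HyperParams,
    TuningGrid,
    _fold_assignment,
    fit,
    load_bundle,
    save_bundle,
    split_corpus,
    tune,
)
from scopesort.thresholds import CutPoints


def _plain_corpus(n, labeled=False):
    labels = ss.NeoplasiaLabels(False, False, False) if labeled else None
    return ss.LabeledCorpus(
        [ss.PathologyReport(f"r{i:05d}", f"note {i}", labels) for i in range(n)]
    )


# --- splitting --------------------------------------------------------------


def test_split_exact_arithmetic():
    train, test = split_corpus(_plain_corpus(100), 0.75, seed=1)
    assert (len(train), len(test)) == (75, 25)


def test_split_round_half_up():
    # 30 * 0.75 = 22.5 rounds up to 23
    train, test = split_corpus(_plain_corpus(30), 0.75, seed=1)
    assert (len(train), len(test)) == (23, 7)


def test_split_disjoint_exhaustive_and_deterministic():
    corpus = _plain_corpus(50)
    t1a, t2a = split_corpus(corpus, 0.6, seed=9)
    t1b, t2b = split_corpus(corpus, 0.6, seed=9)
    assert t1a.report_ids == t1b.report_ids and t2a.report_ids == t2b.report_ids
    assert set(t1a.report_ids) | set(t2a.report_ids) == set(corpus.report_ids)
    assert not set(t1a.report_ids) & set(t2a.report_ids)
    t1c, _ = split_corpus(corpus, 0.6, seed=10)
    assert t1c.report_ids != t1a.report_ids  # seed matters


def test_split_invariant_to_row_order():
    corpus = _plain_corpus(40)
    shuffled_reports = list(corpus)
    random.Random(0).shuffle(shuffled_reports)
    shuffled = ss.LabeledCorpus(shuffled_reports)
    a, _ = split_corpus(corpus, 0.75, seed=5)
    b, _ = split_corpus(shuffled, 0.75, seed=5)
    assert set(a.report_ids) == set(b.report_ids)


def test_stratified_split_preserves_proportions(small_default_corpus):
    train, test = split_corpus(small_default_corpus, 0.75, seed=2, stratify_by="adenoma")
    n_pos = sum(small_default_corpus.labels_for("adenoma"))
    train_pos = sum(train.labels_for("adenoma"))
    assert abs(train_pos - 0.75 * n_pos) <= 1.0
    assert len(train) == round(0.75 * len(small_default_corpus))


def test_stratified_split_requires_labels():
    with pytest.raises(ValueError, match="labeled"):
        split_corpus(_plain_corpus(20), 0.75, seed=1, stratify_by="adenoma")


def test_split_fraction_bounds():
    with pytest.raises(ValueError, match="train_fraction"):
        split_corpus(_plain_corpus(10), 1.0, seed=0)


# --- grid and folds ---------------------------------------------------------


def test_default_grid_matches_printed_ranges():
    grid = TuningGrid()
    assert grid.min_node_sizes == (2, 3, 4, 5)
    assert grid.n_predictors == (1, 2, 3, 4, 5)
    # 500 by 200 never reaches 2,000, so the endpoint is appended
    assert grid.n_trees_values == (500, 700, 900, 1100, 1300, 1500, 1700, 1900, 2000)
    assert len(grid.points()) == 4 * 5 * 9


def test_fold_assignment_stratified_and_order_independent():
    ids = [f"r{i}" for i in range(40)]
    labels = [i % 4 == 0 for i in range(40)]  # 10 positives
    folds = _fold_assignment(ids, labels, 5, seed=3)
    y = np.array(labels)
    for f in range(5):
        assert y[folds == f].any() and (~y[folds == f]).any()
    order = np.random.default_rng(0).permutation(40)
    folds_perm = _fold_assignment([ids[i] for i in order], [labels[i] for i in order], 5, seed=3)
    assert all(folds_perm[np.where(order == i)[0][0]] == folds[i] for i in range(40))


def test_fold_assignment_insufficient_class_error():
    with pytest.raises(ValueError, match="at least 5"):
        _fold_assignment(["a", "b", "c", "d", "e", "f"], [True] + [False] * 5, 5, seed=0)


# --- fitting and scoring ----------------------------------------------------


@pytest.fixture(scope="module")
def separable():
    """Noise-free synthetic corpus, featurized: text determines labels."""
    cfg = ss.SyntheticConfig(
        n_reports=200, synonym_rate=0.0, filler_rate=0.0, combination_rate=0.0, seed=13
    )
    corpus = ss.generate_corpus(cfg)
    vocab = ss.build_vocabulary(corpus)
    return corpus, vocab, ss.featurize_corpus(corpus, vocab)


def test_fit_separable_training_auc_is_one(separable):
    corpus, _, features = separable
    for c in ss.CATEGORIES:
        y = corpus.labels_for(c)
        model = fit(features, y, HyperParams(2, 5, 100), seed=1, category=c)
        scores = model.score(features)
        assert ss.auc(scores, y) == 1.0
        assert scores.min() >= 0.0 and scores.max() <= 1.0
        # separable fit ranks every positive above every negative
        assert min(s for s, t in zip(scores, y) if t) > max(
            s for s, t in zip(scores, y) if not t
        )


def test_fit_deterministic_under_seed(separable):
    corpus, _, features = separable
    y = corpus.labels_for("adenoma")
    a = fit(features, y, HyperParams(2, 3, 50), seed=7).score(features)
    b = fit(features, y, HyperParams(2, 3, 50), seed=7).score(features)
    assert np.array_equal(a, b)


def test_fit_single_class_error(separable):
    _, _, features = separable
    with pytest.raises(ValueError, match="positive and one negative"):
        fit(features, [True] * len(features.report_ids), HyperParams(2, 3, 10), seed=0)


def test_permuted_labels_give_chance_auc():
    corpus = ss.generate_corpus(ss.SyntheticConfig(n_reports=500, seed=21))
    vocab = ss.build_vocabulary(corpus)
    features = ss.featurize_corpus(corpus, vocab)
    y = np.array(corpus.labels_for("adenoma"))
    y = y[np.random.default_rng(5).permutation(len(y))]
    model = fit(features.values[:250], y[:250], HyperParams(2, 5, 200), seed=3)
    out_auc = ss.auc(model.score(features.values[250:].astype(float)), y[250:])
    assert abs(out_auc - 0.5) <= 0.1


def test_score_vocab_hash_mismatch_error(separable):
    corpus, _, features = separable
    model = fit(features, corpus.labels_for("adenoma"), HyperParams(2, 3, 20), seed=0)
    other_vocab = ss.build_vocabulary(
        ss.LabeledCorpus(corpus.reports[:50]), limits=(10, 10, 10)
    )
    other = ss.featurize_corpus(corpus, other_vocab)
    with pytest.raises(ValueError, match="hash"):
        model.score(other)


def test_score_zero_rows_and_all_zero_row(separable):
    corpus, _, features = separable
    model = fit(features, corpus.labels_for("adenoma"), HyperParams(2, 3, 20), seed=0)
    assert model.score(np.zeros((0, features.values.shape[1]))).shape == (0,)
    s = model.score(np.zeros((1, features.values.shape[1])))
    assert 0.0 <= s[0] <= 1.0


def test_adding_trees_moves_scores_by_at_most_tree_weight(separable):
    corpus, _, features = separable
    y = corpus.labels_for("advanced")
    base = fit(features, y, HyperParams(2, 3, 50), seed=7).score(features)
    grown = fit(features, y, HyperParams(2, 3, 60), seed=7).score(features)
    assert np.abs(grown - base).max() <= 10 / 60 + 1e-12


# --- tuning -----------------------------------------------------------------


def test_tune_tie_break_prefers_parsimony(separable):
    corpus, _, features = separable
    grid = TuningGrid(min_node_sizes=(2, 5), n_predictors=(5,), n_trees_values=(40, 80))
    best, cv_table = tune(features, corpus.labels_for("adenoma"), "adenoma",
                          grid, k_folds=5, seed=1)
    assert len(cv_table) == 4
    # among the AUC maximizers, the tie-break picks fewest trees, then
    # largest node size, then fewest predictors
    winners = cv_table[cv_table["mean_auc"] >= cv_table["mean_auc"].max() - 1e-12]
    expected = min(
        winners.itertuples(),
        key=lambda r: (r.n_trees, -r.min_node_size, r.n_predictors_sampled),
    )
    assert (best.min_node_size, best.n_predictors_sampled, best.n_trees) == (
        expected.min_node_size, expected.n_predictors_sampled, expected.n_trees,
    )
    assert len(winners) > 1  # the tie-break actually had to choose
    assert {f"auc_fold_{i}" for i in range(1, 6)} <= set(cv_table.columns)


def test_tune_single_point_grid_returns_it(separable):
    corpus, _, features = separable
    grid = TuningGrid(min_node_sizes=(3,), n_predictors=(2,), n_trees_values=(15,))
    best, cv_table = tune(features, corpus.labels_for("serrated"), "serrated",
                          grid, k_folds=5, seed=1)
    assert best == HyperParams(3, 2, 15)
    assert len(cv_table) == 1


def test_tune_insufficient_positives_error(separable):
    corpus, _, features = separable
    labels = [False] * len(features.report_ids)
    labels[:3] = [True, True, True]
    with pytest.raises(ValueError, match="at least 5"):
        tune(features, labels, "adenoma",
             TuningGrid((2,), (2,), (10,)), k_folds=5, seed=1)


# --- persistence ------------------------------------------------------------


def _make_bundle(separable, locked=True):
    corpus, vocab, features = separable
    models = {
        c: fit(features, corpus.labels_for(c), HyperParams(2, 3, 25), seed=i, category=c)
        for i, c in enumerate(ss.CATEGORIES)
    }
    return ss.ModelBundle(
        models=models, vocabulary=vocab,
        cutpoints=CutPoints(0.5, 0.5, 0.5), locked=locked,
        metadata={"seed": 0},
    )


def test_bundle_round_trip_identical_scores(separable, tmp_path):
    corpus, _, _ = separable
    bundle = _make_bundle(separable)
    probe = ss.LabeledCorpus(corpus.reports[:50])
    before = bundle.score_corpus(probe)
    save_bundle(bundle, tmp_path / "model")
    loaded = load_bundle(tmp_path / "model")
    after = loaded.score_corpus(probe)
    for c in ss.CATEGORIES:
        assert np.array_equal(before[c], after[c])
    assert [p.as_dict() for p in loaded.classify_corpus(probe)] == [
        p.as_dict() for p in bundle.classify_corpus(probe)
    ]


def test_bundle_load_missing_files_listed(tmp_path):
    (tmp_path / "empty").mkdir()
    with pytest.raises(FileNotFoundError) as err:
        load_bundle(tmp_path / "empty")
    for name in ("vocab.tsv", "params.json", "cutpoints.json", "forest_adenoma.joblib"):
        assert name in str(err.value)


def test_bundle_locked_flag_preserved(separable, tmp_path):
    bundle = _make_bundle(separable, locked=False)
    save_bundle(bundle, tmp_path / "m")
    assert load_bundle(tmp_path / "m").locked is False
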