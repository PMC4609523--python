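import numpy as np
import pytest

from ctcnoise import (
    AnnotationMatrix,
    ClassifierSpec,
    ConsensusConfig,
    ExperimentGrid,
    build_partition,
    compare_test_references,
    make_folds,
    run_consensus_eval,
    run_cross_observer,
    run_noise_grid,
)

FAST_SPECS = [
    ClassifierSpec("random_forest", n_trees=30),
    ClassifierSpec("svm_rbf", C=2.0, gamma=0.05),
]


class TestMakeFolds:
    def test_even_split(self):
        folds = make_folds(np.arange(10), 5, seed=0)
        assert folds.sizes() == [2, 2, 2, 2, 2]

    def test_study_scale_split(self):
        folds = make_folds(np.arange(617), 5, seed=0)
        assert sorted(folds.sizes()) == [123, 123, 123, 124, 124]
        assert sorted(np.concatenate([folds.fold(k) for k in range(5)])) == list(
            range(617)
        )

    def test_reproducible(self):
        a = make_folds(np.arange(40), 4, seed=3)
        b = make_folds(np.arange(40), 4, seed=3)
        assert np.array_equal(a.fold_id, b.fold_id)
        assert np.array_equal(a.indices, b.indices)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.arange(3), 5, seed=0)


def _informative_panel(n=120, m=5, flip=0.0, seed=0):
    """Feature matrix carrying the label signal, observers = truth with
    optional symmetric flip noise."""
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 6))
    X[:, 0] += np.where(truth == 1, 2.5, -2.5)
    labels = np.tile(truth[:, None], (1, m))
    if flip > 0:
        noise = rng.random((n, m)) < flip
        labels = np.where(noise, 1 - labels, labels)
    ann = AnnotationMatrix(labels, tuple(f"O{i}" for i in range(m)))
    return X, ann, truth


class TestCrossObserver:
    def test_identical_observers_perfect_features(self):
        X, ann, _ = _informative_panel(n=100, m=3)
        reports = run_cross_observer(X, ann, FAST_SPECS[:1], seed=1)
        rep = reports["random_forest"]
        assert rep.accuracy == pytest.approx(1.0, abs=0.02)
        assert rep.accuracy_sd == pytest.approx(0.0, abs=0.02)

    def test_noisier_observers_lower_measured_accuracy(self):
        X, ann_clean, _ = _informative_panel(n=150, m=3, flip=0.0, seed=2)
        _, ann_noisy, _ = _informative_panel(n=150, m=3, flip=0.25, seed=2)
        clean = run_cross_observer(X, ann_clean, FAST_SPECS[:1], seed=1)
        noisy = run_cross_observer(X, ann_noisy, FAST_SPECS[:1], seed=1)
        assert noisy["random_forest"].accuracy < clean["random_forest"].accuracy - 0.05

    def test_alignment_checked(self):
        X, ann, _ = _informative_panel(n=50, m=3)
        with pytest.raises(ValueError):
            run_cross_observer(X[:40], ann, FAST_SPECS[:1])


@pytest.fixture(scope="module")
def grid_setup():
    X, ann, truth = _informative_panel(n=160, m=11, flip=0.12, seed=4)
    part = build_partition(ann, ConsensusConfig(11))
    return X, ann, part


class TestNoiseGrid:
    def test_conditions_and_reproducibility(self, grid_setup):
        X, ann, part = grid_setup
        grid = ExperimentGrid(n_repetitions_gt=2, n_repetitions_noise=3, seed=9)
        r1 = run_noise_grid(X, part, ann, FAST_SPECS[:1], grid)
        r2 = run_noise_grid(X, part, ann, FAST_SPECS[:1], grid)
        assert set(r1.reports) == {
            (c, "random_forest")
            for c in ("train_2GT", "train_1GT_1probGT", "train_2probGT")
        }
        for key in r1.reports:
            assert r1.reports[key] == r2.reports[key]  # fixed seeds, identical table

    def test_all_unanimous_collapses_to_pure_gt(self):
        X, ann, _ = _informative_panel(n=80, m=11, flip=0.0, seed=5)
        part = build_partition(ann, ConsensusConfig(11))
        assert part.probgt_indices.size == 0
        grid = ExperimentGrid(n_repetitions_gt=2, n_repetitions_noise=2, seed=1)
        res = run_noise_grid(X, part, ann, FAST_SPECS[:1], grid)
        accs = [r.accuracy for r in res.reports.values()]
        assert max(accs) - min(accs) <= 0.05  # all conditions agree within SD

    def test_randomized_probgt_labels_hurt_accuracy(self, grid_setup):
        X, ann, part = grid_setup
        grid = ExperimentGrid(n_repetitions_gt=2, n_repetitions_noise=4, seed=9)
        res = run_noise_grid(X, part, ann, FAST_SPECS[:1], grid)
        acc = {c: res.reports[(c, "random_forest")].accuracy for c, _ in res.reports}
        assert acc["train_2GT"] >= acc["train_2probGT"] - 0.02


class TestConsensusEval:
    def test_observer_matching_consensus_scores_one(self):
        X, ann, _ = _informative_panel(n=90, m=11, flip=0.1, seed=6)
        part = build_partition(ann, ConsensusConfig(11))
        cls_reports, obs_reports = run_consensus_eval(X, part, ann, FAST_SPECS[:1], seed=2)
        # plant a perfect observer: replace one column by the consensus labels
        cons_idx = part.consensus_indices
        labels = ann.labels.copy()
        labels[cons_idx, 0] = part.consensus_labels[cons_idx]
        ann2 = AnnotationMatrix(labels, ann.observer_ids)
        part2 = build_partition(ann2, ConsensusConfig(11))
        # re-evaluate against the original partition's labels
        _, obs2 = run_consensus_eval(X, part, ann2, FAST_SPECS[:1], seed=2)
        rep = obs2[ann.observer_ids[0]]
        assert (rep.accuracy, rep.precision, rep.recall) == (1.0, 1.0, 1.0)

    def test_classifier_accuracy_high_on_separable_consensus_data(self):
        X, ann, _ = _informative_panel(n=120, m=11, flip=0.05, seed=7)
        part = build_partition(ann, ConsensusConfig(11))
        cls_reports, _ = run_consensus_eval(X, part, ann, FAST_SPECS[:1], seed=3)
        assert cls_reports["random_forest"].accuracy >= 0.9

    def test_small_consensus_set_rejected(self):
        X, ann, _ = _informative_panel(n=8, m=11, flip=0.0, seed=8)
        part = build_partition(ann, ConsensusConfig(11))
        with pytest.raises(ValueError):
            run_consensus_eval(X, part, ann, FAST_SPECS[:1], n_folds=10)


class TestCompareTestReferences:
    def test_consensus_reference_scores_higher(self):
        X, ann, _ = _informative_panel(n=200, m=11, flip=0.15, seed=9)
        part = build_partition(ann, ConsensusConfig(11))
        out = compare_test_references(
            X, part, ann, FAST_SPECS[0], n_repetitions=5, seed=4
        )
        assert out["accuracy_vs_consensus"] > out["accuracy_vs_probabilistic"]
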