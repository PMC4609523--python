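import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcnoise import (
    AnnotationMatrix,
    agreement_matrix,
    agreement_ttest,
    bernoulli_estimate,
    count_statistics,
    expected_unanimous,
    observer_summaries,
    pairwise_agreement,
)

binary_vectors = st.integers(2, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


class TestPairwiseAgreement:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 0, 1, 0], [1, 0, 1, 0], 1.0),  # identical annotation
            ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),  # total disagreement
            ([1, 1, 0, 0], [1, 0, 0, 1], 0.5),  # 2 of 4 disagreements
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_agreement(a, b) == expected

    @settings(derandomize=True, max_examples=60)
    @given(binary_vectors)
    def test_equals_one_minus_normalised_hamming(self, ab):
        a, b = (np.array(v) for v in ab)
        hamming = sum(int(x != y) for x, y in zip(a, b))  # brute-force count
        assert pairwise_agreement(a, b) == pytest.approx(1 - hamming / len(a))

    @settings(derandomize=True, max_examples=30)
    @given(binary_vectors)
    def test_symmetric_and_bounded(self, ab):
        a, b = (np.array(v) for v in ab)
        p = pairwise_agreement(a, b)
        assert p == pairwise_agreement(b, a)
        assert 0.0 <= p <= 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pairwise_agreement([1, 0], [1, 0, 1])
        with pytest.raises(ValueError):
            pairwise_agreement([1, 2], [1, 0])


class TestAgreementMatrix:
    def test_identical_observers_give_all_ones(self):
        ann = AnnotationMatrix(np.tile([[1], [0], [1]], (1, 2)), ("A", "B"))
        assert np.allclose(agreement_matrix(ann).values, 1.0)

    def test_complementary_pair_entry_zero(self):
        labels = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1], [0, 1, 1]])
        agr = agreement_matrix(AnnotationMatrix(labels, ("A", "B", "C")))
        assert agr.values[0, 1] == 0.0
        assert np.allclose(agr.values, agr.values.T)
        assert np.allclose(np.diag(agr.values), 1.0)

    def test_off_diagonal_has_one_entry_per_pair(self, tiny_ann):
        assert agreement_matrix(tiny_ann).off_diagonal().size == 3


class TestObserverSummaries:
    def test_identical_observers(self):
        ann = AnnotationMatrix(np.tile([[1], [0], [1], [1]], (1, 3)), ("A", "B", "C"))
        for s in observer_summaries(ann):
            assert s.mean_agreement == 1.0
            assert s.delta_ctc == 0.0

    def test_delta_ctc_sums_to_zero(self, rng):
        labels = rng.integers(0, 2, size=(25, 7))
        ann = AnnotationMatrix(labels, tuple("ABCDEFG"))
        total = sum(s.delta_ctc for s in observer_summaries(ann))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_against_brute_force_pair_loop(self, rng):
        labels = rng.integers(0, 2, size=(30, 5))
        ann = AnnotationMatrix(labels, tuple("ABCDE"))
        summaries = observer_summaries(ann)
        counts = labels.sum(axis=0)
        for i, s in enumerate(summaries):
            # oracle: explicit double loop over observer pairs
            agrs = [
                pairwise_agreement(labels[:, i], labels[:, j])
                for j in range(5)
                if j != i
            ]
            delta = np.mean([counts[i] - counts[j] for j in range(5) if j != i])
            assert s.mean_agreement == pytest.approx(np.mean(agrs))
            assert s.delta_ctc == pytest.approx(delta)
            assert s.se_agreement == pytest.approx(np.std(agrs, ddof=1) / np.sqrt(4))
            assert s.n_ctc == counts[i]


class TestCountStatistics:
    def test_study_counts(self, observer_counts):
        ids, counts, _ = observer_counts
        cs = count_statistics(counts, ids)
        assert round(cs.mean) == 300
        # largest ordered-list gap is MB(223) -> MP(281)
        assert cs.sorted_gaps[0][0] == 58
        assert set(cs.sorted_gaps[0][1:]) == {"MB", "MP"}
        # second-largest gap: 17 between JP(330) and CMS(347)
        assert cs.sorted_gaps[1][0] == 17
        assert set(cs.sorted_gaps[1][1:]) == {"JP", "CMS"}
        assert cs.median == 307  # standard convention on the sorted counts

    def test_constant_counts(self):
        cs = count_statistics([5, 5, 5])
        assert cs.mean == cs.median == 5
        assert all(g[0] == 0 for g in cs.sorted_gaps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_statistics([])


class TestBernoulliEstimate:
    def test_known_agreement_level(self):
        # mean pairwise agreement 0.85 -> per-observer p ~ 0.92,
        # expected unanimity 617 * p^11 ~ 252.4
        assert np.sqrt(0.85) == pytest.approx(0.922, abs=5e-4)
        assert expected_unanimous(617, 0.85, 11) == pytest.approx(252.4, abs=0.05)

    def test_perfect_agreement(self):
        ann = AnnotationMatrix(np.tile([[1], [0]], (1, 3)), ("A", "B", "C"))
        est = bernoulli_estimate(ann)
        assert est.p == 1.0
        assert est.expected_unanimous == ann.n_points

    def test_monotone_in_agreement(self):
        values = [expected_unanimous(617, a, 11) for a in np.linspace(0.5, 1.0, 20)]
        assert np.all(np.diff(values) > 0)


class TestAgreementTTest:
    def test_symmetric_sample_gives_t_zero(self):
        res = agreement_ttest([0.8, 0.9], 0.85)
        assert res["t_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_detects_unanimity_implied_agreement_gap(self, rng):
        # agreements ~ N(0.85, 0.03^2), n = 55, tested against 0.91:
        # the test should be overwhelmingly significant nearly always
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            sample = rng.normal(0.85, 0.03, size=55)
            if agreement_ttest(sample, 0.91)["p_value"] < 1e-6:
                hits += 1
        assert hits >= 0.99 * n_rep

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            agreement_ttest([0.8, 0.8, 0.8], 0.85)


class TestAnnotationMatrixIO:
    def test_csv_round_trip(self, tmp_path, tiny_ann):
        path = tmp_path / "ann.csv"
        tiny_ann.to_csv(path, cutout_ids=[f"c{i}" for i in range(tiny_ann.n_points)])
        back = AnnotationMatrix.from_csv(path)
        assert back.observer_ids == tiny_ann.observer_ids
        assert np.array_equal(back.labels, tiny_ann.labels)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AnnotationMatrix(np.array([[0, 2], [1, 0]]), ("A", "B"))
        with pytest.raises(ValueError):
            AnnotationMatrix(np.array([[0, 1], [1, 0]]), ("A", "A"))
        with pytest.raises(ValueError):
            AnnotationMatrix(np.array([[0], [1]]), ("A",))
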