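"""Feature definitions, identities and the syntax-asymmetry permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegmicrostates import LabelSequence
from eegmicrostates.features import (
    FEATURE_NAMES,
    PREDOMINANCE_PAIRS,
    TRANSITION_PAIRS,
    assemble_feature_vector,
    directional_predominance,
    expected_transition_percentages,
    extract_segments,
    microstate_features,
    permutation_test_asymmetry,
    transition_percentages,
)

LETTER = {"A": 0, "B": 1, "C": 2, "D": 3}


def seq_from(letters, rate=500.0):
    return LabelSequence(
        labels=np.array([LETTER[c] for c in letters], dtype=np.int8), rate_hz=rate
    )


def seq_from_runs(run_spec, rate=500.0):
    """run_spec: sequence of (letter, length)."""
    return seq_from("".join(c * n for c, n in run_spec), rate=rate)


label_lists = st.lists(st.integers(0, 3), min_size=2, max_size=400)


class TestSegments:
    def test_run_length_encoding(self):
        seg = extract_segments(seq_from("AABBBA"))
        np.testing.assert_array_equal(seg.classes, [0, 1, 0])
        np.testing.assert_array_equal(seg.lengths, [2, 3, 1])
        np.testing.assert_array_equal(seg.interior(), [False, True, False])

    def test_constant_and_alternating(self):
        seg = extract_segments(seq_from("CCCC"))
        assert seg.n_runs == 1 and seg.lengths[0] == 4
        seg = extract_segments(seq_from("ABABAB"))
        assert seg.n_runs == 6 and (seg.lengths == 1).all()

    @settings(deadline=None, max_examples=50)
    @given(label_lists)
    def test_runs_tile_epoch(self, labs):
        seg = extract_segments(
            LabelSequence(labels=np.array(labs, dtype=np.int8), rate_hz=500.0)
        )
        assert seg.lengths.sum() == len(labs)
        assert (np.diff(seg.classes) != 0).all()


class TestMicrostateFeatures:
    def test_hand_worked_two_interior_runs(self):
        """2-s epoch at 500 Hz, class A in two interior 50-sample runs."""
        runs = [("B", 100), ("A", 50), ("C", 400), ("A", 50), ("D", 400)]
        seg = extract_segments(seq_from_runs(runs))
        assert seg.n_samples == 1000
        ms = microstate_features(seg)
        assert ms.duration_ms[0] == pytest.approx(100.0)  # 50 samples = 100 ms
        assert ms.occurrence_hz[0] == pytest.approx(1.0)  # 2 runs / 2 s
        assert ms.coverage_pct[0] == pytest.approx(10.0)  # 100 / 1000
        assert not ms.missing[0]

    def test_single_class_epoch(self):
        seg = extract_segments(seq_from("C" * 1000))
        ms = microstate_features(seg)
        assert ms.coverage_pct[2] == pytest.approx(100.0)
        assert ms.occurrence_hz[[0, 1, 3]].sum() == 0
        assert ms.coverage_pct[[0, 1, 3]].sum() == 0
        assert np.isnan(ms.duration_ms[2])  # the single run is truncated
        assert ms.missing[[0, 1, 3]].all()

    def test_constant_gfp_mean(self):
        seg = extract_segments(seq_from_runs([("A", 100), ("B", 300), ("A", 100)]))
        ms = microstate_features(seg, gfp=np.full(500, 2.0))
        assert ms.gfp_uv[0] == pytest.approx(2.0)
        assert ms.gfp_uv[1] == pytest.approx(2.0)
        assert np.isnan(ms.gfp_uv[2])

    def test_gfp_weighting_is_per_sample(self):
        gfp = np.concatenate([np.full(100, 1.0), np.full(100, 3.0)])
        seg = extract_segments(seq_from_runs([("A", 100), ("B", 100)]))
        ms = microstate_features(seg, gfp=gfp)
        assert ms.gfp_uv[0] == pytest.approx(1.0)
        assert ms.gfp_uv[1] == pytest.approx(3.0)

    @settings(deadline=None, max_examples=50)
    @given(label_lists)
    def test_identities(self, labs):
        """Coverage sums to 100 %; mean occurrence equals summed occurrences."""
        seq = LabelSequence(labels=np.array(labs, dtype=np.int8), rate_hz=500.0)
        ms = microstate_features(extract_segments(seq))
        assert ms.coverage_pct.sum() == pytest.approx(100.0, abs=0.01)
        assert ms.mean_occurrence_hz == pytest.approx(ms.occurrence_hz.sum(), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(label_lists)
    def test_symmetric_policy_identity_exact(self, labs):
        """Interior-run statistics satisfy coverage = occurrence * duration / 10."""
        seq = LabelSequence(labels=np.array(labs, dtype=np.int8), rate_hz=500.0)
        seg = extract_segments(seq)
        ms = microstate_features(seg, policy="symmetric")
        for k in range(4):
            if not np.isnan(ms.duration_ms[k]):
                assert ms.coverage_pct[k] == pytest.approx(
                    ms.occurrence_hz[k] * ms.duration_ms[k] / 10.0, rel=1e-9
                )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            extract_segments(LabelSequence(labels=np.array([]), rate_hz=500.0))


class TestTransitions:
    def test_hand_counted_three_boundaries(self):
        seg = extract_segments(seq_from_runs([("A", 2), ("B", 2), ("A", 2), ("C", 2)]))
        tr = transition_percentages(seg)
        pct = dict(zip(TRANSITION_PAIRS, tr.percentages))
        assert pct[(0, 1)] == pytest.approx(100 / 3)
        assert pct[(1, 0)] == pytest.approx(100 / 3)
        assert pct[(0, 2)] == pytest.approx(100 / 3)
        assert sum(tr.percentages) == pytest.approx(100.0)

    def test_periodic_alternation(self):
        seg = extract_segments(seq_from("AB" * 10))
        tr = transition_percentages(seg)
        pct = dict(zip(TRANSITION_PAIRS, tr.percentages))
        assert pct[(0, 1)] == pytest.approx(1000 / 19)  # 10 of 19 boundaries
        assert pct[(1, 0)] == pytest.approx(900 / 19)

    def test_single_run_flagged(self):
        tr = transition_percentages(extract_segments(seq_from("AAAA")))
        assert tr.no_transitions
        assert (tr.percentages == 0).all()

    @settings(deadline=None, max_examples=50)
    @given(label_lists)
    def test_percentages_sum_to_100(self, labs):
        seq = LabelSequence(labels=np.array(labs, dtype=np.int8), rate_hz=500.0)
        tr = transition_percentages(extract_segments(seq))
        if not tr.no_transitions:
            assert tr.percentages.sum() == pytest.approx(100.0, abs=0.01)


class TestPredominance:
    def test_symmetric_transitions_give_zero(self):
        seg = extract_segments(seq_from("ABAB" * 5 + "A"))
        tr = transition_percentages(seg)
        assert tr.predominance[0] == pytest.approx(0.0)

    def test_reported_scale_difference(self):
        """P(A->C) - P(C->A): 8.11 % vs 7.27 % gives 0.84."""
        pct = np.zeros(12)
        pct[TRANSITION_PAIRS.index((0, 2))] = 8.11
        pct[TRANSITION_PAIRS.index((2, 0))] = 7.27
        dp = directional_predominance(pct)
        assert dp[PREDOMINANCE_PAIRS.index((0, 2))] == pytest.approx(0.84)

    @settings(deadline=None, max_examples=50)
    @given(label_lists)
    def test_time_reversal_negates_predominance(self, labs):
        seq = LabelSequence(labels=np.array(labs, dtype=np.int8), rate_hz=500.0)
        rev = LabelSequence(labels=np.array(labs[::-1], dtype=np.int8), rate_hz=500.0)
        a = transition_percentages(extract_segments(seq))
        b = transition_percentages(extract_segments(rev))
        np.testing.assert_allclose(a.predominance, -b.predominance, atol=1e-9)

    def test_antisymmetry_by_construction(self):
        rng = np.random.default_rng(0)
        pct = rng.uniform(0, 10, 12)
        dp = directional_predominance(pct)
        idx = {p: i for i, p in enumerate(TRANSITION_PAIRS)}
        for (a, b), d in zip(PREDOMINANCE_PAIRS, dp):
            assert d == pytest.approx(pct[idx[(a, b)]] - pct[idx[(b, a)]])


class TestAsymmetryPermutationTest:
    def test_cyclic_sequence_extreme_p(self):
        """A strictly cyclic A->B->C->D chain is maximally asymmetric."""
        seg = extract_segments(seq_from_runs([("ABCD"[i % 4], 2) for i in range(200)]))
        for pair in [("A", "B"), ("B", "C"), ("C", "D")]:
            assert permutation_test_asymmetry(seg, pair, 10_000, seed=0) <= 0.001

    def test_zero_observed_difference(self):
        seg = extract_segments(seq_from_runs([("A", 2), ("B", 2), ("A", 2)]))
        # one A->B and one B->A boundary: observed difference 0
        p = permutation_test_asymmetry(seg, ("A", "B"), 1000, seed=1,
                                       estimator="add-one")
        assert p == 1.0
        # mid-p halves the all-tied point mass but stays non-significant
        p_mid = permutation_test_asymmetry(seg, ("A", "B"), 1000, seed=1)
        assert p_mid >= 0.5

    def test_preserves_run_multiset(self):
        """The shuffle null only reorders runs, so microstate features are
        unaffected by the permutation scheme (checked via invariance of the
        observed statistic under seed)."""
        seg = extract_segments(seq_from_runs([("A", 3), ("C", 2)] * 30))
        p1 = permutation_test_asymmetry(seg, ("A", "C"), 2000, seed=3)
        p2 = permutation_test_asymmetry(seg, ("A", "C"), 2000, seed=3)
        assert p1 == p2

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            permutation_test_asymmetry(
                extract_segments(seq_from("AAA")), ("A", "B"), 10
            )

    def test_shuffle_scheme_still_available(self):
        seg = extract_segments(seq_from_runs([("ABCD"[i % 4], 2) for i in range(100)]))
        p = permutation_test_asymmetry(seg, ("A", "B"), 2000, seed=2, scheme="shuffle")
        assert p <= 0.01

    def test_analytic_expectation_close_to_shuffle_mean(self):
        """The independence expectation approximates the shuffle-null mean."""
        rng = np.random.default_rng(4)
        labs = rng.integers(0, 4, size=300)
        seq = LabelSequence(labels=labs.astype(np.int8), rate_hz=500.0)
        seg = extract_segments(seq)
        exp = expected_transition_percentages(seg)
        classes = seg.classes
        perm = np.random.default_rng(5).permuted(
            np.broadcast_to(classes, (2000, len(classes))).copy(), axis=1
        )
        counts = np.zeros(12)
        for i, (a, b) in enumerate(TRANSITION_PAIRS):
            counts[i] = ((perm[:, :-1] == a) & (perm[:, 1:] == b)).sum()
        shuffle_mean = counts / counts.sum() * 100
        np.testing.assert_allclose(exp, shuffle_mean, atol=0.5)


class TestAssembly:
    def test_vector_length_names_and_imputation(self):
        seg = extract_segments(seq_from_runs([("A", 300), ("C", 400), ("A", 300)]))
        ms = microstate_features(seg, gfp=np.full(1000, 2.0))
        tr = transition_percentages(seg)
        vec = assemble_feature_vector(ms, tr)
        assert vec.shape == (36,)
        assert len(FEATURE_NAMES) == len(set(FEATURE_NAMES)) == 36
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["duration_B"] == 0.0  # absent class imputed
        assert named["coverage_C"] == pytest.approx(40.0)
        assert named["duration_C"] == pytest.approx(800.0)
        assert np.isfinite(vec).all()
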