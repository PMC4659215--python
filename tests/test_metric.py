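"""Restricted mutual information: defining equations, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import mutual_info_score

from specreg.metric import (
    JointDistribution,
    adjust_distribution,
    adjusted_joint,
    joint_histogram,
    restricted_mi,
    standard_mi,
)
from specreg.segmentation import IndexImage

WORKED_P = np.array([[0.4, 0.1], [0.1, 0.4]])


def jd_from_p(p, scale=1000):
    return JointDistribution(np.round(np.asarray(p) * scale).astype(int))


count_tables = arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(2, 6), st.integers(2, 7)),
    elements=st.integers(0, 50),
).filter(lambda a: a.sum() > 0)


class TestAdjustment:
    def test_worked_example(self):
        adj = adjust_distribution(jd_from_p(WORKED_P), 0.5)
        np.testing.assert_allclose(adj.p_alpha, [[0.5, 0.05], [0.05, 0.4]], atol=1e-12)

    def test_alpha_zero_is_identity(self):
        jd = jd_from_p(WORKED_P)
        np.testing.assert_allclose(adjust_distribution(jd, 0.0).p_alpha, jd.p, atol=0)

    def test_alpha_one_moves_all_mismatch_mass(self):
        adj = adjust_distribution(jd_from_p(WORKED_P), 1.0)
        np.testing.assert_allclose(adj.p_alpha, [[0.6, 0.0], [0.0, 0.4]], atol=1e-12)

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            adjust_distribution(jd_from_p(WORKED_P), alpha)


class TestScores:
    def test_worked_example_values(self):
        jd = jd_from_p(WORKED_P)
        # hand arithmetic: H(X)=H(Y)=1; H_a = 0.4+2*0.1*log2(20)+0.4*log2(2.5)
        h_a = 0.4 + 2 * 0.1 * math.log2(20) + 0.4 * math.log2(2.5)
        assert restricted_mi(jd, 0.5) == pytest.approx(2.0 - h_a, abs=1e-12)
        assert restricted_mi(jd, 0.5) == pytest.approx(0.206843, abs=1e-6)
        assert standard_mi(jd) == pytest.approx(0.278072, abs=1e-6)

    def test_independent_uniform_is_zero(self):
        jd = jd_from_p([[0.25, 0.25], [0.25, 0.25]])
        assert standard_mi(jd) == pytest.approx(0.0, abs=1e-12)

    def test_identity_images_score_marginal_entropy(self, rng):
        labels = rng.integers(0, 4, size=(15, 15)).astype(np.int32)
        img = IndexImage(labels, k=3)
        jd = joint_histogram(img, img)
        assert standard_mi(jd) == pytest.approx(jd.entropy_x, abs=1e-12)
        # diagonal concentration: p(x, x) = P(X=x)
        np.testing.assert_allclose(np.diag(jd.p), jd.marginal_x)

    def test_standard_mi_against_sklearn(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 5))
            counts[0, 0] += 1
            jd = JointDistribution(counts)
            oracle = mutual_info_score(None, None, contingency=counts) / math.log(2)
            assert standard_mi(jd) == pytest.approx(oracle, abs=1e-12)

    def test_alpha_one_with_border_mass_is_minus_inf(self):
        jd = jd_from_p([[0.4, 0.2], [0.1, 0.3]])
        assert restricted_mi(jd, 1.0) == -math.inf

    def test_log_base_changes_units(self):
        jd = jd_from_p(WORKED_P)
        nats = JointDistribution(jd.counts, log_base=math.e)
        assert standard_mi(nats) == pytest.approx(standard_mi(jd) * math.log(2), rel=1e-12)


class TestJointHistogram:
    def test_small_example(self):
        fixed = IndexImage(np.array([[1, 1], [0, 2]]), k=2)
        moving = IndexImage(np.array([[1, 2], [0, 2]]), k=2)
        jd = joint_histogram(fixed, moving)
        assert jd.m == 4
        expected = np.zeros((3, 3), dtype=int)
        expected[1, 1] = expected[1, 2] = expected[0, 0] = expected[2, 2] = 1
        np.testing.assert_array_equal(jd.counts, expected)

    def test_matches_bruteforce_tally(self, rng):
        a = rng.integers(0, 5, size=(20, 20)).astype(np.int32)
        b = rng.integers(0, 7, size=(20, 20)).astype(np.int32)
        jd = joint_histogram(IndexImage(a, k=4), IndexImage(b, k=6))
        brute = np.zeros((5, 7), dtype=int)
        for i in range(20):
            for j in range(20):
                brute[a[i, j], b[i, j]] += 1
        np.testing.assert_array_equal(jd.counts, brute)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            joint_histogram(
                IndexImage(np.zeros((2, 2), int), k=1), IndexImage(np.zeros((3, 2), int), k=1)
            )


class TestInvariants:
    @settings(max_examples=60, derandomize=True)
    @given(counts=count_tables, alpha=st.floats(0.0, 1.0))
    def test_adjusted_table_is_normalized(self, counts, alpha):
        p_a = adjusted_joint(JointDistribution(counts).p, alpha)
        assert p_a.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p_a >= 0).all()

    @settings(max_examples=60, derandomize=True)
    @given(counts=count_tables, alpha=st.floats(0.0, 1.0))
    def test_restricted_never_exceeds_standard(self, counts, alpha):
        jd = JointDistribution(counts)
        assert restricted_mi(jd, alpha) <= standard_mi(jd) + 1e-12

    @settings(max_examples=40, derandomize=True)
    @given(counts=count_tables)
    def test_permutation_of_foreground_labels(self, counts):
        """Relabelling nonzero clusters must leave I_alpha unchanged."""
        jd = JointDistribution(counts)
        perm_rows = counts.copy()
        perm_rows[1:] = perm_rows[1:][::-1]  # reverse foreground rows
        perm = JointDistribution(perm_rows)
        for alpha in (0.0, 0.25, 1.0):
            a, b = restricted_mi(jd, alpha), restricted_mi(perm, alpha)
            assert a == pytest.approx(b, abs=1e-12) or (a == b == -math.inf)

    @settings(max_examples=60, derandomize=True)
    @given(counts=count_tables, alpha=st.floats(0.01, 0.99))
    def test_adjustment_term_closed_form(self, counts, alpha):
        """I_alpha - I_0 depends only on the background-mismatch mass
        mm = P(X=0) + P(Y=0) - 2 p(0,0) and on p(0,0):

            I_alpha - I_0 = mm log2(1-a) + p00 log2(1 + a mm / p00)
        """
        jd = JointDistribution(counts)
        p = jd.p
        p00 = p[0, 0]
        mm = p[0, :].sum() + p[:, 0].sum() - 2 * p00
        expected = mm * math.log2(1 - alpha)
        if p00 > 0:
            expected += p00 * math.log2(1 + alpha * mm / p00)
        observed = restricted_mi(jd, alpha) - standard_mi(jd)
        assert observed == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(counts=count_tables, alpha=st.floats(0.01, 1.0))
    def test_background_match_rewarded_by_adjustment(self, counts, alpha):
        """Moving a pair from foreground-on-background to background-on-
        background never increases the adjustment penalty I_0 - I_alpha.
        (The full scores are not comparable across the move because the
        standard-MI part changes with the marginals.)"""
        if counts[1, 0] == 0:
            counts = counts.copy()
            counts[1, 0] = 3
        moved = counts.copy()
        moved[1, 0] -= 1
        moved[0, 0] += 1

        def penalty(c):
            jd = JointDistribution(c)
            return standard_mi(jd) - restricted_mi(jd, alpha)

        before, after = penalty(counts), penalty(moved)
        if math.isfinite(before) and math.isfinite(after):
            assert after <= before + 1e-9
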