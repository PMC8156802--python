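"""Fuzzy membership transformation and decision-fusion rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitfuse import (
    baseline_fuse,
    consistency_matrix,
    fuse,
    fuzzy_membership,
    membership_matrix,
    reliability_weights,
    rws_fuse,
)
from gaitfuse.datasets import (
    EXAMPLE_REL_LOWER,
    EXAMPLE_REL_SPAN,
    example_kelm_output,
    example_memberships,
)

memberships = arrays(float, (6, 4), elements=st.floats(0.01, 1.0, allow_nan=False))


class TestMembership:
    def test_worked_five_class_example(self):
        mu = fuzzy_membership(example_kelm_output(), gamma=0.5)
        np.testing.assert_allclose(
            mu, [0.0005, 0.6913, 0.2284, 0.0027, 0.0002], atol=1e-4
        )
        assert np.all((mu > 0) & (mu <= 1))

    def test_constant_output_maps_to_inverse_e(self):
        mu = fuzzy_membership(np.full(4, 0.7))
        np.testing.assert_allclose(mu, np.exp(-1.0))

    def test_permutation_equivariance(self, rng):
        o = rng.normal(size=6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            fuzzy_membership(o)[perm], fuzzy_membership(o[perm])
        )

    def test_degenerate_denominator_falls_back_to_uniform(self):
        o = np.array([1.0, -1.0])  # mean 0, gamma=-...: force mean+gamma*sd=0
        gamma = -o.mean() / o.std(ddof=1)
        with pytest.warns(UserWarning, match="degenerate"):
            mu = fuzzy_membership(o, gamma=gamma)
        assert mu[0] == mu[1]


class TestConsistency:
    def test_worked_example_inner_products(self):
        A = consistency_matrix(example_memberships())
        assert round(A[0, 1], 2) == 0.53
        assert round(A[1, 3], 2) == 0.72
        assert round(A[0, 0], 2) == 0.40  # diagonal included

    def test_orthogonal_decisions_have_zero_consistency(self):
        M = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert consistency_matrix(M)[0, 1] == 0.0

    @given(M=memberships)
    def test_gram_structure(self, M):
        A = consistency_matrix(M)
        np.testing.assert_allclose(A, A.T)
        assert np.all(A >= 0)
        eigvals = np.linalg.eigvalsh(A)
        assert eigvals.min() > -1e-8  # positive semidefinite

    @given(
        base=arrays(float, 5, elements=st.floats(0.01, 0.5)),
        bump=arrays(float, 5, elements=st.floats(0.0, 0.5)),
        probe=arrays(float, 5, elements=st.floats(0.0, 1.0)),
    )
    def test_elementwise_dominance_is_monotone(self, base, bump, probe):
        # mu1 >= mu2 elementwise implies <mu1, t> >= <mu2, t> for t >= 0
        mu2, mu1 = base, base + bump
        assert np.dot(mu1, probe) >= np.dot(mu2, probe) - 1e-12


class TestReliability:
    def test_worked_example_eigenvector(self):
        A = consistency_matrix(example_memberships())
        rel = reliability_weights(A, a=EXAMPLE_REL_LOWER, b=EXAMPLE_REL_SPAN)
        assert rel.eigenvector[1] == pytest.approx(0.44, abs=0.005)
        assert np.all(rel.eigenvector >= 0)
        assert np.linalg.norm(rel.eigenvector) == pytest.approx(1.0)

    def test_affine_range_endpoints(self, rng):
        M = rng.uniform(0.05, 1.0, size=(8, 5))
        rel = reliability_weights(consistency_matrix(M), a=0.6, b=0.4)
        assert rel.weights.min() == pytest.approx(0.6)
        assert rel.weights.max() == pytest.approx(1.0)
        assert np.all((rel.weights >= 0.6) & (rel.weights <= 1.0))

    def test_identical_frames_all_get_top_reliability(self):
        M = np.tile([0.2, 0.7, 0.1], (5, 1))
        rel = reliability_weights(consistency_matrix(M), a=0.6, b=0.4)
        np.testing.assert_allclose(rel.weights, 1.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            reliability_weights(np.empty((0, 0)))


class TestRws:
    def test_worked_ten_frame_example(self):
        dec = rws_fuse(example_memberships(), a=EXAMPLE_REL_LOWER, b=EXAMPLE_REL_SPAN)
        np.testing.assert_allclose(
            dec.membership, [0.11, 0.27, 0.16, 0.14, 0.14], atol=0.0051
        )
        assert dec.class_index == 1  # class 2 wins

    def test_single_frame_reduces_to_argmax(self):
        mu = np.array([[0.1, 0.8, 0.3]])
        dec = rws_fuse(mu, a=0.6, b=0.4)
        assert dec.class_index == 1
        np.testing.assert_allclose(dec.membership, 1.0 * mu[0])  # r = a+b = 1

    def test_frame_permutation_invariance(self, rng):
        M = rng.uniform(0.05, 1.0, size=(9, 4))
        perm = rng.permutation(9)
        d1, d2 = rws_fuse(M), rws_fuse(M[perm])
        np.testing.assert_allclose(d1.membership, d2.membership, atol=1e-10)
        assert d1.class_index == d2.class_index

    def test_equal_reliabilities_reduce_to_sum_rule(self):
        M = np.tile([0.3, 0.5, 0.2], (4, 1))  # identical frames -> equal r
        assert rws_fuse(M).class_index == baseline_fuse(M, "sum").class_index


class TestBaselines:
    def test_sum_of_identical_decisions_is_that_decision(self):
        mu = np.array([0.2, 0.6, 0.4])
        dec = baseline_fuse(np.tile(mu, (2, 1)), "sum")
        np.testing.assert_allclose(dec.membership, mu)

    def test_majority_tie_falls_back_to_mean_membership_then_index(self):
        M = np.array([[0.9, 0.1], [0.1, 0.9]])
        dec = baseline_fuse(M, "majority")
        assert dec.class_index == 0  # symmetric tie -> lowest index

    def test_majority_counts_hard_votes(self):
        M = np.array([[0.9, 0.1], [0.8, 0.3], [0.2, 0.6]])
        dec = baseline_fuse(M, "majority")
        assert dec.class_index == 0
        np.testing.assert_allclose(dec.membership, [2 / 3, 1 / 3])

    def test_belief_rule_single_decision(self):
        dec = baseline_fuse(np.array([[0.5, 0.25]]), "belief", delta=1e-3)
        np.testing.assert_allclose(
            dec.membership, [1 / (0.5 + 1e-3), 1 / (0.75 + 1e-3)]
        )
        assert dec.class_index == 0

    def test_weighted_belief_computes_reliabilities_when_missing(self, rng):
        M = rng.uniform(0.05, 1.0, size=(5, 3))
        dec = baseline_fuse(M, "weighted_belief")
        assert dec.membership.shape == (3,)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown fusion rule"):
            baseline_fuse(np.ones((2, 2)) / 2, "median")

    @given(M=memberships, scale=st.floats(0.1, 1.0))
    def test_winner_scale_invariance_of_scale_free_rules(self, M, scale):
        # memberships scaled by a common positive constant: sum, rws and
        # majority keep their winner (delta breaks this for product/belief);
        # floating-point near-ties are excluded — the property concerns
        # clear winners, not ulp-level tie-breaking
        for rule in ("sum", "rws", "majority"):
            a = fuse(M, rule)
            mu = np.sort(a.membership)
            if mu[-1] - mu[-2] <= 1e-6 * mu[-1]:
                continue
            if rule == "majority":
                rows = np.sort(M, axis=1)
                if np.any(rows[:, -1] - rows[:, -2] <= 1e-6 * rows[:, -1]):
                    continue
            b = fuse(M * scale, rule)
            assert a.class_index == b.class_index, rule


def test_membership_matrix_maps_rows(rng):
    O = rng.normal(size=(6, 5))
    M = membership_matrix(O, gamma=0.5)
    np.testing.assert_allclose(M[2], fuzzy_membership(O[2], 0.5))
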