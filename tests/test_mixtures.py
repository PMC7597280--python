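"""Unit and property tests for the Gaussian-mixture information measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from gtmsel import (
    HALF_LOG_2PI_E,
    DomainError,
    MixtureSpec,
    QuadratureConfig,
    h,
    interaction_information,
    mc_entropy,
    mi_with_label,
    mixture_entropy,
    subset_entropy_mi,
    total_correlation,
)

LOG2 = math.log(2.0)


class TestH:
    def test_zero_separation_is_standard_normal_entropy(self):
        assert h(0.0) == pytest.approx(HALF_LOG_2PI_E, abs=1e-12)

    def test_large_separation_reaches_upper_bound(self):
        # disjoint components: entropy of one component plus one bit
        assert h(50.0) == pytest.approx(HALF_LOG_2PI_E + LOG2, abs=1e-9)

    def test_limits_at_both_ends(self):
        assert h(1e-6) == pytest.approx(HALF_LOG_2PI_E, abs=1e-6)
        assert h(50.0) == pytest.approx(HALF_LOG_2PI_E + LOG2, abs=1e-6)

    def test_unit_separation_against_monte_carlo_oracle(self):
        # independent route: average of -log f over draws from the mixture
        est, se = mc_entropy(MixtureSpec([1.0], [[1.0]]), 10**6, seed=7)
        assert abs(h(1.0) - est) < 3 * se
        # the corresponding label MI is the model's strongest-predictor relevance
        assert h(1.0) - HALF_LOG_2PI_E == pytest.approx(0.1114, abs=5e-5)

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(0.0, 10.0, 200)
        values = [h(a) for a in grid]
        assert all(v1 < v2 for v1, v2 in zip(values, values[1:]))

    def test_bounds_on_grid(self):
        for a in np.linspace(0.0, 10.0, 200):
            assert HALF_LOG_2PI_E - 1e-12 <= h(a) <= HALF_LOG_2PI_E + LOG2 + 1e-12

    @pytest.mark.parametrize("a", [0.0, 0.5, 1.0, 2.0, 5.0])
    def test_matches_symmetric_mixture_entropy(self, a):
        # the centered mixture (N(-a/2,1)+N(a/2,1))/2 has the same entropy;
        # computed here by its own quadrature, not through h
        def neg_f_log_f(x):
            f = (
                math.exp(-0.5 * (x + a / 2) ** 2) + math.exp(-0.5 * (x - a / 2) ** 2)
            ) / (2.0 * math.sqrt(2.0 * math.pi))
            return 0.0 if f < 1e-300 else -f * math.log(f)

        ref, _ = quad(neg_f_log_f, -14 - a, 14 + a, epsabs=1e-12, epsrel=1e-12, limit=400)
        assert h(a) == pytest.approx(ref, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            h(-0.5)
        with pytest.raises(DomainError):
            h(float("nan"))
        with pytest.raises(DomainError):
            QuadratureConfig(abs_tol=0.0)


class TestMixtureSpec:
    def test_rejects_asymmetric_sigma(self):
        with pytest.raises(DomainError):
            MixtureSpec([0.0, 0.0], [[1.0, 0.5], [0.2, 1.0]])

    def test_rejects_singular_sigma(self):
        with pytest.raises(DomainError):
            MixtureSpec([0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])

    def test_rejects_nonfinite_mu(self):
        with pytest.raises(DomainError):
            MixtureSpec([np.inf], [[1.0]])

    def test_separation_is_mahalanobis_distance(self):
        spec = MixtureSpec([1.0, 1.0], [[1.0, 1.0], [1.0, 2.0]])
        expected = math.sqrt(spec.mu @ np.linalg.solve(spec.sigma, spec.mu))
        assert spec.separation == pytest.approx(expected, rel=1e-12)


class TestMixtureEntropy:
    def test_degenerate_is_gaussian(self):
        assert mixture_entropy(MixtureSpec([0.0], [[1.0]])) == pytest.approx(
            HALF_LOG_2PI_E, abs=1e-10
        )
        assert mixture_entropy(MixtureSpec([0.0, 0.0], np.eye(2))) == pytest.approx(
            2 * HALF_LOG_2PI_E, abs=1e-10
        )

    def test_rotation_reduces_to_one_dimension(self):
        # mu=(3,4) has norm 5; the orthogonal coordinate is pure N(0,1)
        spec = MixtureSpec([3.0, 4.0], np.eye(2))
        assert mixture_entropy(spec) == pytest.approx(h(5.0) + HALF_LOG_2PI_E, abs=1e-10)
        est, se = mc_entropy(spec, 10**6, seed=17)
        assert abs(mixture_entropy(spec) - est) < 3 * se

    def test_at_least_gaussian_entropy(self):
        spec = MixtureSpec([0.3, -0.2], [[2.0, 0.3], [0.3, 1.0]])
        gaussian = spec.d * HALF_LOG_2PI_E + 0.5 * spec.log_det_sigma
        assert mixture_entropy(spec) >= gaussian - 1e-12

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        mu=st.lists(st.floats(-4, 4), min_size=1, max_size=3),
        scale=st.lists(st.floats(0.3, 3), min_size=3, max_size=3),
        seed=st.integers(0, 10**6),
    )
    def test_scaling_property(self, mu, scale, seed):
        # H(X) = H(Sigma^{-1/2} X) + (1/2) log det Sigma
        d = len(mu)
        rng = np.random.default_rng(seed)
        A = rng.uniform(-1, 1, (d, d))
        sigma = A @ A.T + np.diag(scale[:d])
        spec = MixtureSpec(mu, sigma)
        lhs = mixture_entropy(spec)
        rhs = mixture_entropy(spec.whitened()) + 0.5 * spec.log_det_sigma
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestMiWithLabel:
    def test_zero_iff_identical_components(self):
        assert mi_with_label(
            MixtureSpec([0.0, 0.0], [[2.0, 0.5], [0.5, 1.0]])
        ) == pytest.approx(0.0, abs=1e-12)
        assert mi_with_label(MixtureSpec([0.1], [[1.0]])) > 0.0

    def test_printed_marginal_relevances(self):
        # strongest active and the child of X_1 in the tree model
        assert mi_with_label(MixtureSpec([1.0], [[1.0]])) == pytest.approx(0.1114, abs=5e-5)
        assert mi_with_label(MixtureSpec([1.0], [[2.0]])) == pytest.approx(0.0589, abs=5e-5)

    def test_bounded_by_one_bit(self):
        for sep in (0.5, 2.0, 10.0, 60.0):
            assert mi_with_label(MixtureSpec([sep], [[1.0]])) <= LOG2 + 1e-9

    def test_entropy_difference_route(self):
        # I(X,Y) = H(X) - H(X|Y) with the conditional entropy exact Gaussian
        spec = MixtureSpec([0.7, -1.2], [[1.5, 0.4], [0.4, 0.9]])
        route = mixture_entropy(spec) - (
            spec.d * HALF_LOG_2PI_E + 0.5 * spec.log_det_sigma
        )
        assert mi_with_label(spec) == pytest.approx(route, abs=1e-9)


class TestSubsetEntropyMi:
    def test_independent_blocks_have_zero_mi(self):
        specA = MixtureSpec([0.0], [[1.0]])
        specB = MixtureSpec([0.0], [[2.0]])
        specAB = MixtureSpec([0.0, 0.0], [[1.0, 0.0], [0.0, 2.0]])
        assert subset_entropy_mi(specA, specB, specAB) == pytest.approx(0.0, abs=1e-8)

    def test_parent_child_pair_strictly_positive(self):
        specA = MixtureSpec([1.0], [[1.0]])
        specB = MixtureSpec([1.0], [[2.0]])
        specAB = MixtureSpec([1.0, 1.0], [[1.0, 1.0], [1.0, 2.0]])
        value = subset_entropy_mi(specA, specB, specAB)
        assert value > 0.0
        # independent Monte-Carlo route on the joint
        estAB, seAB = mc_entropy(specAB, 10**6, seed=23)
        mc = mixture_entropy(specA) + mixture_entropy(specB) - estAB
        assert abs(value - mc) < 3 * seAB

    def test_two_active_pair_closed_form(self):
        g = 2.0 / 3.0
        specA = MixtureSpec([1.0], [[1.0]])
        specB = MixtureSpec([g], [[1.0]])
        specAB = MixtureSpec([1.0, g], np.eye(2))
        expected = h(1.0) + h(g) - h(math.sqrt(1 + g**2)) - HALF_LOG_2PI_E
        assert subset_entropy_mi(specA, specB, specAB) == pytest.approx(expected, abs=1e-8)

    def test_inconsistent_marginals_rejected(self):
        specA = MixtureSpec([1.0], [[1.0]])
        specB = MixtureSpec([0.5], [[1.0]])
        specAB = MixtureSpec([1.0, 0.6], np.eye(2))
        with pytest.raises(DomainError):
            subset_entropy_mi(specA, specB, specAB)


class TestInteractionInformation:
    def test_two_way_reduces_to_mi(self):
        ents = {
            frozenset({1}): HALF_LOG_2PI_E,
            frozenset({2}): HALF_LOG_2PI_E,
            frozenset({1, 2}): 2 * HALF_LOG_2PI_E,
        }
        assert interaction_information(ents) == pytest.approx(0.0, abs=1e-12)

    def test_parent_child_label_triple_is_pure_redundancy(self):
        # II(X_1, X1^(1), Y) = -I(X1^(1), Y): once X_1 is known the child
        # carries nothing further about the label
        child = MixtureSpec([1.0], [[2.0]])
        parent = MixtureSpec([1.0], [[1.0]])
        joint = MixtureSpec([1.0, 1.0], [[1.0, 1.0], [1.0, 2.0]])
        log_det = {1: 0.0, 2: math.log(2.0), 12: 0.0}
        ents = {
            frozenset({1}): mixture_entropy(parent),
            frozenset({2}): mixture_entropy(child),
            frozenset({3}): LOG2,  # H(Y)
            frozenset({1, 2}): mixture_entropy(joint),
            # H(X_T, Y) = H(Y) + H(X_T | Y), the conditional being Gaussian
            frozenset({1, 3}): LOG2 + HALF_LOG_2PI_E + 0.5 * log_det[1],
            frozenset({2, 3}): LOG2 + HALF_LOG_2PI_E + 0.5 * log_det[2],
            frozenset({1, 2, 3}): LOG2 + 2 * HALF_LOG_2PI_E + 0.5 * log_det[12],
        }
        assert interaction_information(ents) == pytest.approx(
            -mi_with_label(child), abs=1e-9
        )

    def test_three_way_agrees_with_mi_difference_route(self):
        # II(X1, X2, Y) = I((X1,X2),Y) - I(X1,Y) - I(X2,Y), each via h(separation)
        g = 0.55
        x1 = MixtureSpec([1.0], [[1.0]])
        x2 = MixtureSpec([g], [[1.0]])
        pair = MixtureSpec([1.0, g], np.eye(2))
        ents = {
            frozenset({1}): mixture_entropy(x1),
            frozenset({2}): mixture_entropy(x2),
            frozenset({3}): LOG2,
            frozenset({1, 2}): mixture_entropy(pair),
            frozenset({1, 3}): LOG2 + HALF_LOG_2PI_E,
            frozenset({2, 3}): LOG2 + HALF_LOG_2PI_E,
            frozenset({1, 2, 3}): LOG2 + 2 * HALF_LOG_2PI_E,
        }
        route = (
            mi_with_label(pair) - mi_with_label(x1) - mi_with_label(x2)
        )
        assert interaction_information(ents) == pytest.approx(route, abs=1e-9)

    def test_missing_subset_and_size_limits(self):
        with pytest.raises(DomainError):
            interaction_information({frozenset({1}): 1.0, frozenset({1, 2}): 2.0})
        with pytest.raises(DomainError):
            interaction_information({frozenset({i}): 0.0 for i in range(5)})


class TestTotalCorrelation:
    def test_single_variable_is_zero(self):
        assert total_correlation(MixtureSpec([1.3], [[1.0]])) == pytest.approx(0.0, abs=1e-8)

    def test_axis_aligned_separation_is_independent(self):
        spec = MixtureSpec([2.0, 0.0, 0.0], np.eye(3))
        assert total_correlation(spec) == pytest.approx(0.0, abs=1e-8)

    def test_diagonal_separation_matches_pair_mi(self):
        spec = MixtureSpec([1.0, 1.0], np.eye(2))
        expected = 2 * h(1.0) - h(math.sqrt(2.0)) - HALF_LOG_2PI_E
        assert total_correlation(spec) == pytest.approx(expected, abs=1e-10)
        # for two variables, total correlation IS their mutual information
        pair = subset_entropy_mi(
            MixtureSpec([1.0], [[1.0]]), MixtureSpec([1.0], [[1.0]]), spec
        )
        assert total_correlation(spec) == pytest.approx(pair, abs=1e-8)

    def test_non_identity_sigma_rejected(self):
        with pytest.raises(DomainError):
            total_correlation(MixtureSpec([1.0, 1.0], [[1.0, 0.2], [0.2, 1.0]]))
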