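"""Scoring-chain primitives: pseudo-observations, tau, theta, lambda_U."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailsel import (
    DomainError,
    InvalidInputError,
    UndefinedStatisticError,
    kendall_tau,
    lambda_u_score,
    pseudo_observations,
    tau_to_theta,
    theta_to_lambda_u,
)
from tailsel.copula import kendall_tau_counted, lambda_u_from_tau

from conftest import brute_force_tau

TOL = 1e-12


class TestPseudoObservations:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([3, 1, 2], [0.75, 0.25, 0.50]),
            ([1, 1, 2], [0.375, 0.375, 0.75]),  # average ranks (1.5, 1.5, 3)/4
        ],
    )
    def test_rank_over_n_plus_one(self, x, expected):
        assert np.allclose(pseudo_observations(np.array(x, float)), expected, rtol=TOL)

    @given(st.lists(st.integers(-1000, 1000), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_strictly_increasing_transform(self, xs):
        # integer grid keeps exp() injective in floating point, so the
        # transform is strictly increasing and tie structure is preserved
        x = np.asarray(xs, dtype=float)
        np.testing.assert_allclose(
            pseudo_observations(np.exp(x / 100)), pseudo_observations(x), rtol=1e-9
        )

    def test_outputs_strictly_inside_unit_interval(self, rng):
        u = pseudo_observations(rng.integers(0, 3, 50).astype(float))
        assert np.all((u > 0) & (u < 1))

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            pseudo_observations(np.array([1.0, np.nan]))


class TestKendallTau:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [0, 0, 1, 1], 4 / np.sqrt(24)),
        ],
    )
    def test_known_values(self, u, v, expected):
        assert kendall_tau(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected, rel=TOL
        )

    def test_matches_brute_force_with_and_without_ties(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 50))
            if rng.random() < 0.5:
                u = rng.integers(0, 4, n).astype(float)
                v = rng.integers(0, 3, n).astype(float)
            else:
                u = rng.standard_normal(n)
                v = rng.standard_normal(n)
            if np.ptp(u) == 0 or np.ptp(v) == 0:
                continue
            assert kendall_tau(u, v) == pytest.approx(brute_force_tau(u, v), abs=1e-12)

    def test_rank_invariance(self, rng):
        x = rng.standard_normal(40)
        y = rng.integers(0, 2, 40).astype(float)
        assert kendall_tau(x, y) == pytest.approx(
            kendall_tau(pseudo_observations(x), pseudo_observations(y)), abs=1e-12
        )

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kendall_tau(np.ones(5), np.arange(5.0))

    def test_counted_variant_agrees_with_fast_path(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 60))
            u = rng.integers(0, 5, n).astype(float)
            v = rng.standard_normal(n)
            if np.ptp(u) == 0:
                continue
            tau, _ = kendall_tau_counted(u, v)
            assert tau == pytest.approx(kendall_tau(u, v), abs=1e-12)

    def test_merge_comparisons_scale_subquadratically(self, rng):
        """Doubling n should roughly double (not quadruple) the comparison
        count of the tau kernel — the O(n log n) contract."""
        ops = {}
        for n in (512, 1024, 2048):
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            _, ops[n] = kendall_tau_counted(u, v)
        assert ops[1024] / ops[512] < 2.5
        assert ops[2048] / ops[1024] < 2.5
        # far below the all-pairs count
        assert ops[2048] < 0.05 * 2048 * 2047 / 2


class TestClosedFormMaps:
    def test_tau_half_gives_theta_two(self):
        assert tau_to_theta(0.5) == pytest.approx(2.0, rel=TOL)

    def test_independence_limit(self):
        assert tau_to_theta(1e-9) == pytest.approx(1.0, rel=1e-8)
        assert theta_to_lambda_u(1.0) == pytest.approx(0.0, abs=TOL)

    def test_theta_two_lambda(self):
        assert theta_to_lambda_u(2.0) == pytest.approx(2 - np.sqrt(2), rel=TOL)

    def test_chained_derived_value(self):
        tau = 4 / np.sqrt(24)
        theta = tau_to_theta(tau)
        assert theta == pytest.approx(1 / (1 - tau), rel=TOL)
        assert theta_to_lambda_u(theta) == pytest.approx(2 - 2 ** (1 - tau), rel=TOL)

    def test_monotonicity(self):
        taus = np.linspace(0.01, 0.99, 50)
        lams = [theta_to_lambda_u(tau_to_theta(t)) for t in taus]
        assert np.all(np.diff(lams) > 0)
        assert all(0 <= l < 1 for l in lams)

    @pytest.mark.parametrize("bad", [-0.1, 0.0, 1.0, 1.5])
    def test_tau_domain(self, bad):
        with pytest.raises(DomainError):
            tau_to_theta(bad)

    def test_theta_domain(self):
        with pytest.raises(DomainError):
            theta_to_lambda_u(0.99)

    def test_zeroing_rule_and_clamp(self):
        assert lambda_u_from_tau(-0.3) == 0.0
        assert lambda_u_from_tau(0.0) == 0.0
        assert 0.0 < lambda_u_from_tau(1.0) < 1.0  # clamped, finite


class TestLambdaUScore:
    def test_feature_equal_to_label_scores_positive(self, rng):
        y = rng.integers(0, 2, 100)
        s = lambda_u_score(y.astype(float), y)
        assert s.lambda_u > 0 and s.theta is not None

    def test_anti_concordant_feature_zeroed(self, rng):
        y = rng.integers(0, 2, 100)
        s = lambda_u_score(1.0 - y, y)
        assert s.lambda_u == 0.0 and s.tau < 0 and s.theta is None

    def test_derived_chain_value(self):
        s = lambda_u_score(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        tau = 4 / np.sqrt(24)
        assert s.tau == pytest.approx(tau, rel=1e-12)
        assert s.lambda_u == pytest.approx(2 - 2 ** (1 - tau), rel=1e-12)

    def test_constant_feature_flagged_degenerate(self, rng):
        y = rng.integers(0, 2, 50)
        s = lambda_u_score(np.full(50, 7.0), y)
        assert s.degenerate and s.tau == 0.0 and s.lambda_u == 0.0

    def test_monotone_transform_leaves_score_unchanged(self, rng):
        y = rng.integers(0, 2, 120)
        x = rng.standard_normal(120)
        a = lambda_u_score(x, y)
        b = lambda_u_score(np.exp(2 * x) + 5, y)
        assert a.tau == pytest.approx(b.tau, abs=1e-12)
        assert a.lambda_u == pytest.approx(b.lambda_u, abs=1e-12)
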