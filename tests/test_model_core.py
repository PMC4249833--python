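"""System-matrix assembly, spectral analysis and regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenokin import (
    ConvergenceError,
    GrowthTransitionModel,
    ModelValidationError,
    build_system_matrix,
    classify_regime,
    spectral_summary,
    stationary_composition,
    survivability,
)
from phenokin.simulate import integrate

from conftest import random_model


class TestBuildSystemMatrix:
    def test_two_state_bookkeeping(self):
        model = GrowthTransitionModel.two_state(0.7, 0.5, k_xy=0.1, k_yx=0.05)
        sm = build_system_matrix(model)
        np.testing.assert_allclose(sm.T, [[0.6, 0.05], [0.1, 0.45]])
        np.testing.assert_allclose(sm.G, np.diag([0.7, 0.5]))
        np.testing.assert_allclose(sm.T, sm.G + sm.K)

    def test_no_transitions_reduces_to_growth_diagonal(self):
        model = GrowthTransitionModel(
            labels=("a", "b", "c"), growth=[0.3, -0.1, 0.8],
            transitions=np.zeros((3, 3)),
        )
        sm = build_system_matrix(model)
        np.testing.assert_array_equal(sm.T, np.diag([0.3, -0.1, 0.8]))
        np.testing.assert_array_equal(sm.K, np.zeros((3, 3)))

    def test_transition_part_columns_sum_to_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sm = build_system_matrix(random_model(rng, m=4))
            np.testing.assert_allclose(sm.K.sum(axis=0), 0.0, atol=1e-12)
            off = sm.T - np.diag(np.diagonal(sm.T))
            assert np.all(off >= 0)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(growth=[0.1], labels=("a",), transitions=np.zeros((1, 1))),
             "at least 2"),
            (dict(growth=[0.1, np.nan], labels=("a", "b"),
                  transitions=np.zeros((2, 2))), "non-finite"),
            (dict(growth=[0.1, 0.2], labels=("a", "b"),
                  transitions=[[0, -0.1], [0, 0]]), "negative transition"),
            (dict(growth=[0.1, 0.2], labels=("a", "b"),
                  transitions=[[0.3, 0], [0, 0]]), "self-transition"),
        ],
    )
    def test_invalid_models_rejected(self, kwargs, match):
        with pytest.raises(ModelValidationError, match=match):
            GrowthTransitionModel(**kwargs)


class TestSpectralSummary:
    def test_diagonal_matrix(self):
        model = GrowthTransitionModel(
            labels=("x", "y"), growth=[0.6, 0.45],
            transitions=np.zeros((2, 2)),
        )
        s = spectral_summary(build_system_matrix(model))
        np.testing.assert_allclose(s.eigenvalues.real, [0.6, 0.45])
        np.testing.assert_allclose(s.leading_composition, [1.0, 0.0],
                                   atol=1e-12)
        assert not s.irreducible

    def test_two_state_matches_characteristic_quadratic(self):
        # oracle: roots of x^2 - tr x + det for T = [[0.6, 0.05], [0.1, 0.45]]
        tr, det = 0.6 + 0.45, 0.6 * 0.45 - 0.05 * 0.1
        disc = np.sqrt(tr**2 - 4 * det)
        expected = [(tr + disc) / 2, (tr - disc) / 2]
        model = GrowthTransitionModel.two_state(0.7, 0.5, 0.1, 0.05)
        s = spectral_summary(build_system_matrix(model))
        np.testing.assert_allclose(s.eigenvalues.real, expected, rtol=1e-12)
        np.testing.assert_allclose(s.eigenvalues.imag, 0.0, atol=1e-14)

    def test_sum159_supports_three_way_coexistence(self, sum159):
        s = spectral_summary(build_system_matrix(sum159))
        assert s.irreducible
        assert np.all(s.eigenvalues.real > 0)

    def test_perron_leading_mode_on_random_irreducible_models(self):
        # leading eigenvalue real, simple, dominant; eigenvector positive
        rng = np.random.default_rng(42)
        for _ in range(1000):
            m = int(rng.integers(2, 6))
            s = spectral_summary(build_system_matrix(random_model(rng, m=m)))
            assert s.irreducible
            assert abs(s.eigenvalues[0].imag) < 1e-10
            assert s.spectral_gap > 0
            assert s.lambda_max >= np.max(s.eigenvalues.real) - 1e-12
            assert np.all(s.leading_composition > 0)
            assert not s.fallback_used

    def test_rejects_nonsquare_input(self):
        from phenokin.model import _coerce_system_matrix
        from phenokin import SystemMatrix

        bad = SystemMatrix(labels=("a", "b"), T=np.ones((2, 3)),
                           G=np.zeros((2, 2)), K=np.zeros((2, 2)))
        with pytest.raises(ModelValidationError, match="square"):
            _coerce_system_matrix(bad)


class TestStationaryComposition:
    def test_symmetric_two_state_is_even_split(self):
        model = GrowthTransitionModel.two_state(0.4, 0.4, 0.2, 0.2)
        np.testing.assert_allclose(
            stationary_composition(build_system_matrix(model)), [0.5, 0.5],
            atol=1e-12,
        )

    def test_zero_growth_reduces_to_markov_stationary_ratio(self):
        model = GrowthTransitionModel.two_state(0.0, 0.0, k_xy=0.2, k_yx=0.1)
        comp = stationary_composition(build_system_matrix(model))
        np.testing.assert_allclose(comp, [1 / 3, 2 / 3], rtol=1e-10)

    def test_matches_long_time_integration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = random_model(rng, m=3)
            sm = build_system_matrix(model)
            comp = stationary_composition(sm)
            s = spectral_summary(sm)
            horizon = 200.0 / s.spectral_gap
            # integrate the growth-shifted model (identical fractions)
            shifted = model.with_growth_shift(-s.lambda_max)
            traj = integrate(shifted, np.ones(3), [horizon])
            np.testing.assert_allclose(traj.fractions[-1], comp, atol=1e-9)

    def test_fixed_point_under_renormalised_map(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            model = random_model(rng, m=int(rng.integers(2, 5)))
            sm = build_system_matrix(model)
            x = stationary_composition(sm)
            y = x + 1e-3 * (sm.T @ x)  # small Euler step of the flow
            y = y / y.sum()
            np.testing.assert_allclose(y, x, atol=1e-10)

    def test_reducible_without_fallback_raises(self):
        model = GrowthTransitionModel(
            labels=("a", "b"), growth=[0.5, 0.5],
            transitions=np.zeros((2, 2)),
        )
        with pytest.raises(ConvergenceError):
            stationary_composition(build_system_matrix(model), fallback=False)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c=st.floats(-2.0, 2.0, allow_nan=False),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_growth_shift_invariance(self, c, seed):
        """T + cI shifts eigenvalues by c and keeps the composition."""
        model = random_model(np.random.default_rng(seed), m=3)
        s0 = spectral_summary(build_system_matrix(model))
        s1 = spectral_summary(build_system_matrix(model.with_growth_shift(c)))
        np.testing.assert_allclose(s1.lambda_max, s0.lambda_max + c,
                                   atol=1e-9)
        np.testing.assert_allclose(
            s1.leading_composition, s0.leading_composition, atol=1e-9
        )


class TestRegimeAndSurvivability:
    def test_slow_transitions_give_coexistent_growth(self):
        model = GrowthTransitionModel.two_state(0.7, 0.5, 0.01, 0.01)
        assert classify_regime(model).regime == "coexistent_growth"

    def test_negative_growth_gives_coexistent_extinction(self):
        model = GrowthTransitionModel.two_state(-0.2, -0.3, 0.01, 0.01)
        assert classify_regime(model).regime == "coexistent_extinction"

    def test_backflow_dependent_phenotype_flagged_derivative(self):
        model = GrowthTransitionModel.two_state(0.5, 0.1, k_xy=0.01, k_yx=0.4)
        report = classify_regime(model)
        assert report.survivability["Y"].independent is False
        assert report.survivability["X"].independent is True
        assert report.regime == "derived_survival"

    def test_dominant_transitions_blur_phenotypes(self):
        model = GrowthTransitionModel.two_state(0.01, 0.02, k_xy=1.0, k_yx=1.2)
        assert classify_regime(model).regime == "blurred_single_type"

    def test_marginal_eigenvalue_blocks_classification(self):
        model = GrowthTransitionModel(
            labels=("a", "b"), growth=[0.0, 0.0],
            transitions=[[0.0, 0.2], [0.1, 0.0]],
        )
        report = classify_regime(model)
        assert report.marginal
        assert report.regime is None

    def test_two_state_sign_condition_equals_determinant_sign(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            model = random_model(rng, m=2, g_low=-1.0, g_high=1.0)
            report = classify_regime(model)
            if report.marginal or report.regime == "blurred_single_type":
                continue
            same_sign = report.regime in (
                "coexistent_growth", "coexistent_extinction"
            )
            assert same_sign == (report.det_T > 0)

    def test_survivability_examples(self, sum159):
        flags = survivability(sum159)
        assert all(f.independent for f in flags.values())

        no_transitions = GrowthTransitionModel(
            labels=("a", "b"), growth=[0.5, -0.1],
            transitions=np.zeros((2, 2)),
        )
        assert all(f.independent
                   for f in survivability(no_transitions).values())

        model = GrowthTransitionModel.two_state(0.5, 0.1, k_xy=0.01, k_yx=0.4)
        flags = survivability(model)
        assert flags["Y"].independent is False

    def test_dominance_factor_must_be_positive(self):
        model = GrowthTransitionModel.two_state(0.5, 0.5, 0.1, 0.1)
        with pytest.raises(ModelValidationError):
            survivability(model, dominance_factor=0.0)
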