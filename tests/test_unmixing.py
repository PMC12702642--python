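"""Least-squares weight estimation, reconstruction, and the SD-envelope check."""

import numpy as np
import pytest

from chromounmix import (
    AbsorptionSpectrum,
    NegativeWeightWarning,
    RankDeficiencyWarning,
    SpectralLibrary,
    WavelengthGrid,
    WeightVector,
    build_design_matrix,
    check_within_sd,
    ensemble_stats,
    fit_condition,
    reconstruct,
    solve_weights,
)
from chromounmix.spectral_library import ComponentSpectrum
from chromounmix.synthetic_data import SyntheticScenario, generate_cohort


def normal_equations_oracle(X, y):
    """Literal normal-equations solution b = (X^T X)^{-1} X^T y."""
    return np.linalg.inv(X.T @ X) @ X.T @ y


class TestSolveWeights:
    def test_single_column_exact_scaling(self):
        x = np.linspace(1.0, 2.0, 30)
        w = solve_weights(x[:, None], 3.7 * x)
        assert w.weights[0] == pytest.approx(3.7, abs=1e-12)

    def test_orthogonal_columns_project_independently(self):
        u = np.array([1.0, 0.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0, 0.0])
        w = solve_weights(np.column_stack([u, v]), 2.0 * u + 5.0 * v)
        np.testing.assert_allclose(w.weights, [2.0, 5.0], atol=1e-12)

    def test_recovers_drawn_weights_and_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.0, 1.0, size=(801, 8))
        w_true = rng.uniform(0.1, 20.0, size=8)
        w = solve_weights(X, X @ w_true)
        np.testing.assert_allclose(w.weights, w_true, atol=1e-8)
        np.testing.assert_allclose(
            w.weights, np.linalg.pinv(X) @ (X @ w_true), atol=1e-10
        )

    def test_residual_orthogonality_at_solution(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.0, 1.0, size=(200, 5))
        y = rng.uniform(0.0, 10.0, size=200)
        w = solve_weights(X, y)
        r = y - X @ w.weights
        assert np.abs(X.T @ r).max() / np.abs(X.T @ y).max() <= 1e-8

    def test_column_scaling_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0.1, 1.0, size=(100, 4))
        y = rng.uniform(0.0, 5.0, size=100)
        w = solve_weights(X, y)
        X2 = X.copy()
        X2[:, 2] *= 10.0
        w2 = solve_weights(X2, y)
        expected = w.weights.copy()
        expected[2] /= 10.0
        np.testing.assert_allclose(w2.weights, expected, rtol=1e-8)
        np.testing.assert_allclose(X2 @ w2.weights, X @ w.weights, rtol=1e-8)

    def test_rank_deficient_design_minimum_norm_with_warning(self):
        x = np.linspace(1.0, 2.0, 20)
        X = np.column_stack([x, x])  # duplicate columns, rank 1
        with pytest.warns(RankDeficiencyWarning):
            w = solve_weights(X, 4.0 * x)
        # minimum-norm solution splits the weight equally
        np.testing.assert_allclose(w.weights, [2.0, 2.0], atol=1e-10)

    def test_negative_weights_warned(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 5.0 - 2.0 * np.arange(10.0)
        with pytest.warns(NegativeWeightWarning):
            w = solve_weights(X, y)
        assert w.has_negative

    def test_nonneg_constraint_clamps_at_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 5.0 - 2.0 * np.arange(10.0)
        w = solve_weights(X, y, nonneg=True)
        assert np.all(w.weights >= 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            solve_weights(np.ones((5, 2)), np.ones(4))


class TestReconstruct:
    def test_zero_weights_give_zero_spectrum(self, default_library):
        w = WeightVector(tuple(default_library.names), np.zeros(8))
        spec, raw = reconstruct(default_library, w)
        np.testing.assert_array_equal(spec.mua, 0.0)
        np.testing.assert_array_equal(raw, 0.0)

    def test_basis_vector_returns_that_component(self, default_library):
        weights = np.zeros(8)
        weights[4] = 1.0  # HbO2
        w = WeightVector(tuple(default_library.names), weights)
        spec, _ = reconstruct(default_library, w)
        np.testing.assert_allclose(
            spec.mua, default_library["HbO2"].values, atol=1e-15
        )

    def test_closure_with_solve_weights(self, default_library):
        rng = np.random.default_rng(8)
        design = build_design_matrix(default_library)
        w_true = rng.uniform(0.01, 10.0, size=8)
        y = design.matrix @ w_true
        w = solve_weights(design, y)
        spec, raw = reconstruct(default_library, w)
        np.testing.assert_allclose(raw, y, atol=1e-8)
        np.testing.assert_allclose(spec.mua, y, atol=1e-8)

    def test_negative_sum_clipped_with_annotation(self, default_library):
        weights = np.zeros(8)
        weights[1] = -1.0  # negative melanin
        w = WeightVector(tuple(default_library.names), weights)
        spec, raw = reconstruct(default_library, w)
        assert raw.min() < 0
        assert spec.mua.min() == 0.0
        assert spec.clipped.any()

    def test_order_mismatch_rejected(self, default_library):
        w = WeightVector(tuple(reversed(default_library.names)), np.zeros(8))
        with pytest.raises(ValueError, match="order"):
            reconstruct(default_library, w)


class TestCheckWithinSd:
    def make_ensemble(self, mean, sd_scale, seed=0, n=5):
        grid = WavelengthGrid(500.0 + np.arange(len(mean)))
        rng = np.random.default_rng(seed)
        members = [
            AbsorptionSpectrum(
                grid, np.clip(mean + rng.normal(0, sd_scale, len(mean)), 0, None)
            )
            for _ in range(n)
        ]
        return ensemble_stats(members, "c")

    def test_reconstruction_equal_to_mean_is_fully_within(self):
        ens = self.make_ensemble(np.full(50, 5.0), 0.5)
        frac, mask = check_within_sd(ens, ens.mean)
        assert frac == 1.0 and mask.all()

    def test_two_sd_offset_is_fully_outside(self):
        ens = self.make_ensemble(np.full(50, 5.0), 0.5)
        assert ens.sd.min() > 0
        shifted = AbsorptionSpectrum(ens.grid, ens.mean.mua + 2.0 * ens.sd)
        frac, mask = check_within_sd(ens, shifted)
        assert frac == 0.0 and not mask.any()

    def test_matches_brute_force_mask(self):
        ens = self.make_ensemble(np.full(80, 3.0), 0.3, seed=4)
        recon = AbsorptionSpectrum(
            ens.grid,
            np.clip(
                ens.mean.mua
                + np.random.default_rng(5).normal(0, 0.2, len(ens.grid)),
                0,
                None,
            ),
        )
        frac, mask = check_within_sd(ens, recon)
        brute = []
        for i in range(len(ens.grid)):
            dev = abs(ens.mean.mua[i] - recon.mua[i])
            brute.append(dev <= ens.sd[i] if ens.sd[i] > 0 else dev <= 1e-9)
        assert mask.tolist() == brute
        assert frac == pytest.approx(sum(brute) / len(brute))

    def test_zero_sd_wavelengths_require_exact_equality(self):
        grid = WavelengthGrid(np.array([500.0, 501.0]))
        members = [AbsorptionSpectrum(grid, np.array([1.0, 2.0]))] * 3
        ens = ensemble_stats(members, "c")
        near = AbsorptionSpectrum(grid, np.array([1.0, 2.0 + 1e-6]))
        frac, mask = check_within_sd(ens, near)
        assert mask.tolist() == [True, False]

    def test_single_member_ensemble_rejected(self):
        grid = WavelengthGrid(np.array([500.0]))
        ens = ensemble_stats([AbsorptionSpectrum(grid, np.ones(1))], "c")
        with pytest.raises(ValueError, match="single-member"):
            check_within_sd(ens, ens.mean)


class TestFitCondition:
    def test_noiseless_cohort_recovers_truth(
        self, noiseless_cohort, default_library, physical_healthy_weights
    ):
        samples, _ = noiseless_cohort
        fit = fit_condition(samples, default_library)
        np.testing.assert_allclose(
            fit.unmixing.weights.weights,
            physical_healthy_weights.weights,
            atol=1e-6,
        )
        assert fit.unmixing.rmse < 1e-10
        assert fit.concentrations is not None

    def test_single_sample_cohort_skips_sd_check(
        self, default_library, physical_healthy_weights
    ):
        scenario = SyntheticScenario(
            seed=2, true_weights=physical_healthy_weights, n_samples=1,
            noise_sd=0.0,
        )
        samples, _ = generate_cohort(scenario, default_library)
        fit = fit_condition(samples, default_library)
        assert fit.ensemble.single_member
        assert fit.unmixing.within_sd_fraction is None

    def test_empty_cohort_rejected(self, default_library):
        with pytest.raises(ValueError, match="no measurements"):
            fit_condition([], default_library)

    def test_stage_labels_propagate(self, noiseless_cohort):
        samples, _ = noiseless_cohort
        off_grid = SpectralLibrary(
            [
                ComponentSpectrum(
                    name="water",
                    grid=WavelengthGrid(np.array([500.0, 501.0])),
                    values=np.array([0.0, 1.0]),
                )
            ]
        )
        with pytest.raises(RuntimeError, match="solve_weights"):
            fit_condition(samples, off_grid)


def test_normal_equations_equivalence_on_well_conditioned_designs():
    """The stable solver and the literal normal-equations inversion agree
    whenever the design is well conditioned."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.0, 1.0, size=(801, 8))
        assert np.linalg.cond(X) < 1e6
        y = rng.uniform(0.0, 20.0, size=801)
        w = solve_weights(X, y)
        np.testing.assert_allclose(
            w.weights, normal_equations_oracle(X, y), atol=1e-8
        )
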