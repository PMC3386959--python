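"""Parameter estimation: zero-noise fixed points, noise calibration,
invariances, and profile confidence limits."""

import lmfit
import numpy as np
import pytest

from memphase.fitting import (
    _profile_interval,
    confidence_limits,
    fit_anisotropy,
    fit_lifetime,
    profile_threshold,
)
from memphase.freqdomain import FrequencyDomainDataset
from memphase.models import (
    HinderedRotatorModel,
    LorentzianLifetimeModel,
    render_derived_params,
)
from memphase.simulate import SimulationRecipe, simulate_frequency_dataset


def noiseless(intensity, anisotropy=None, mode="magic_angle", index=0):
    recipe = SimulationRecipe(truth_intensity=intensity,
                              truth_anisotropy=anisotropy,
                              noise_phase_sigma=0.0, noise_modulation_sigma=0.0)
    return simulate_frequency_dataset(recipe, mode, index=index)


def noisy(intensity, anisotropy=None, mode="magic_angle", seed=0, index=0,
          sp=0.2, sm=0.004):
    recipe = SimulationRecipe(truth_intensity=intensity,
                              truth_anisotropy=anisotropy,
                              noise_phase_sigma=sp, noise_modulation_sigma=sm,
                              seed=seed)
    return simulate_frequency_dataset(recipe, mode, index=index)


class TestLifetimeFit:
    def test_zero_noise_recovers_truth(self, lifetime_truth):
        ds = noiseless(lifetime_truth)
        start = LorentzianLifetimeModel(tau_center=2.0, width=0.2, main_fraction=0.9)
        fit = fit_lifetime(ds, start, seed=1)
        assert fit.converged
        for name, truth in [("tau_center", 3.45), ("width", 0.4),
                            ("main_fraction", 0.98)]:
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-4)
        assert fit.reduced_chi_squared < 1e-10

    def test_scatter_lifetime_never_moves(self, lifetime_truth):
        ds = noiseless(lifetime_truth)
        fit = fit_lifetime(ds, LorentzianLifetimeModel(2.0, 0.2, 0.9), seed=1)
        assert fit.fixed["scatter_lifetime"] == 0.01
        assert "scatter_lifetime" not in fit.estimates

    def test_mode_mismatch_rejected(self, lifetime_truth, anisotropy_truth):
        ds = noiseless(lifetime_truth, anisotropy_truth, mode="polarized")
        with pytest.raises(ValueError, match="magic_angle"):
            fit_lifetime(ds, lifetime_truth)

    def test_row_permutation_leaves_estimates_identical(self, lifetime_truth):
        ds = noisy(lifetime_truth, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds))
        shuffled = FrequencyDomainDataset(
            frequencies=ds.frequencies[perm], mode=ds.mode,
            phase=ds.phase[perm], modulation=ds.modulation[perm],
            phase_sigma=ds.phase_sigma[perm],
            modulation_sigma=ds.modulation_sigma[perm])
        f1 = fit_lifetime(ds, lifetime_truth, n_starts=1, seed=0)
        f2 = fit_lifetime(shuffled, lifetime_truth, n_starts=1, seed=0)
        assert f1.estimates == f2.estimates

    def test_recovery_error_shrinks_as_noise_halves(self, lifetime_truth):
        """Estimator consistency: tau_center RMSE decreases monotonically
        (within Monte-Carlo slack) over three halving noise levels."""
        rmses = []
        for level, (sp, sm) in enumerate([(0.4, 0.008), (0.2, 0.004), (0.1, 0.002)]):
            errs = []
            for i in range(40):
                ds = noisy(lifetime_truth, seed=77 + level, index=i, sp=sp, sm=sm)
                fit = fit_lifetime(ds, lifetime_truth, n_starts=1, seed=i)
                errs.append(fit.estimates["tau_center"] - 3.45)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[2] < rmses[1] < rmses[0]

    def test_estimates_respect_bounds_from_random_starts(self, lifetime_truth):
        ds = noisy(lifetime_truth, seed=9)
        rng = np.random.default_rng(2024)
        for _ in range(150):
            start = LorentzianLifetimeModel(
                tau_center=float(rng.uniform(0.1, 20.0)),
                width=float(rng.uniform(0.0, 5.0)),
                main_fraction=float(rng.uniform(0.5, 1.0)))
            fit = fit_lifetime(ds, start, n_starts=1, seed=0)
            assert 1e-3 <= fit.estimates["tau_center"] <= 1e3
            assert 0.0 <= fit.estimates["width"] <= 1e3
            assert 0.0 <= fit.estimates["main_fraction"] <= 1.0


class TestAnisotropyFit:
    def test_zero_noise_recovers_truth(self, lifetime_truth):
        truth = HinderedRotatorModel(r0=0.40, r_inf=0.36, theta1=0.80)
        ds = noiseless(lifetime_truth, truth, mode="polarized")
        fit = fit_anisotropy(ds, lifetime_truth,
                             HinderedRotatorModel(r0=0.3, r_inf=0.15, theta1=2.0),
                             seed=1)
        assert fit.converged
        assert fit.estimates["r0"] == pytest.approx(0.40, rel=1e-4)
        assert fit.estimates["r_inf"] == pytest.approx(0.36, rel=1e-4)
        assert fit.estimates["theta1"] == pytest.approx(0.80, rel=1e-4)
        assert fit.derived["S"] == pytest.approx(np.sqrt(0.36 / 0.40), rel=1e-5)

    def test_published_row_derived_values_round_trip(self, lifetime_truth):
        """Noiseless data from the fluid-DOPC reference row refits to values
        whose derived parameters round to the printed (0.94, 0.048, 0.25)."""
        truth = HinderedRotatorModel(r0=0.32, r_inf=0.02, theta1=3.45)
        ds = noiseless(lifetime_truth, truth, mode="polarized")
        fit = fit_anisotropy(ds, lifetime_truth,
                             HinderedRotatorModel(r0=0.35, r_inf=0.1, theta1=2.0),
                             seed=1)
        from memphase.models import DerivedAnisotropyParams
        rendered = render_derived_params(DerivedAnisotropyParams(**fit.derived))
        assert rendered == {"f1": 0.94, "R1": 0.048, "S": 0.25}

    def test_theta2_never_moves(self, lifetime_truth, anisotropy_truth):
        ds = noiseless(lifetime_truth, anisotropy_truth, mode="polarized")
        start = HinderedRotatorModel(r0=0.3, r_inf=0.1, theta1=2.0, theta2=5e5)
        fit = fit_anisotropy(ds, lifetime_truth, start, seed=1)
        assert fit.fixed["theta2"] == 5e5

    def test_fully_hindered_flagged(self, lifetime_truth):
        truth = HinderedRotatorModel(r0=0.35, r_inf=0.35, theta1=1.0)
        ds = noiseless(lifetime_truth, truth, mode="polarized")
        fit = fit_anisotropy(ds, lifetime_truth,
                             HinderedRotatorModel(r0=0.3, r_inf=0.28, theta1=1.0),
                             seed=1)
        assert "fully hindered" in fit.flags

    def test_noisy_theta1_recovery(self, lifetime_truth, anisotropy_truth):
        """theta1 RMSE over replicates stays below a Monte-Carlo bound
        commensurate with the injected noise."""
        errs = []
        for i in range(40):
            ds = noisy(lifetime_truth, anisotropy_truth, mode="polarized",
                       seed=7, index=i)
            fit = fit_anisotropy(ds, lifetime_truth, anisotropy_truth,
                                 n_starts=1, seed=i)
            errs.append(fit.estimates["theta1"] - 3.45)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.25


class TestNoiseCalibration:
    def test_reduced_chi_squared_near_one(self, lifetime_truth):
        """Correctly specified Gaussian noise gives mean reduced chi^2 ~ 1."""
        vals = []
        for i in range(60):
            ds = noisy(lifetime_truth, seed=1337, index=i)
            fit = fit_lifetime(ds, lifetime_truth, n_starts=1, seed=i)
            vals.append(fit.reduced_chi_squared)
        assert 0.8 <= float(np.mean(vals)) <= 1.2


class TestConfidenceLimits:
    def test_quadratic_toy_interval_symmetric(self):
        """chi2(x) = (x-1)^2 + (x-3)^2 has its minimum at 2; the profile
        interval must be symmetric about it."""
        params = lmfit.Parameters()
        params.add("x", value=2.0, min=-10, max=10)

        def residual(p):
            return np.array([p["x"].value - 1.0, p["x"].value - 3.0])

        low, high, open_ended = _profile_interval(
            residual, params, "x", chi2_min=2.0, dof=1,
            bound_lo=-10, bound_hi=10)
        assert not open_ended
        assert (2.0 - low) == pytest.approx(high - 2.0, rel=1e-3)
        assert low < 2.0 < high

    def test_noiseless_interval_collapses(self, lifetime_truth):
        ds = noiseless(lifetime_truth)
        fit = fit_lifetime(ds, lifetime_truth, n_starts=1)
        low, high = confidence_limits(fit, "tau_center")
        est = fit.estimates["tau_center"]
        assert low <= est <= high
        assert (high - low) < 1e-3 * est

    def test_noisy_interval_contains_estimate(self, lifetime_truth,
                                              anisotropy_truth):
        """With instrument-level noise the theta1 half-width lands at the
        few-hundredths-of-ns order of published uncertainties."""
        ds = noisy(lifetime_truth, anisotropy_truth, mode="polarized", seed=21)
        fit = fit_anisotropy(ds, lifetime_truth, anisotropy_truth,
                             n_starts=1, seed=0)
        low, high = confidence_limits(fit, "theta1")
        est = fit.estimates["theta1"]
        assert low <= est <= high
        half_width = (high - low) / 2
        assert 0.003 <= half_width <= 0.3

    def test_threshold_matches_delta_chi2_for_calibrated_data(self):
        # chi2_min ~ dof makes the F threshold the familiar +1 excursion
        assert profile_threshold(27.0, 27) - 27.0 == pytest.approx(1.0, abs=0.1)
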