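"""Frequency-domain forward models: magic-angle phase/modulation, polarized
differential phase / modulation ratio, reference correction, CSV I/O."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from memphase.freqdomain import (
    FrequencyDomainDataset,
    ReferenceStandard,
    mhz_to_rad_per_ns,
    phase_and_modulation,
    polarized_observables,
    reference_correction,
)
from memphase.models import HinderedRotatorModel, LorentzianLifetimeModel


def single_exp_phase_mod(tau, f_mhz):
    """Closed forms phi = atan(w tau), m = (1 + w^2 tau^2)^(-1/2)."""
    wt = 2 * np.pi * np.asarray(f_mhz) * 1e-3 * tau
    return np.degrees(np.arctan(wt)), 1.0 / np.sqrt(1.0 + wt ** 2)


class TestMagicAngle:
    def test_single_exponential_closed_form(self):
        f = np.geomspace(2.0, 250.0, 25)
        model = LorentzianLifetimeModel(tau_center=1.45)
        phase, mod = phase_and_modulation(model, f)
        exp_phase, exp_mod = single_exp_phase_mod(1.45, f)
        np.testing.assert_allclose(phase, exp_phase, atol=1e-9)
        np.testing.assert_allclose(mod, exp_mod, atol=1e-12)

    def test_reference_lifetime_at_100mhz(self):
        phase, mod = phase_and_modulation(LorentzianLifetimeModel(1.45), [100.0])
        assert phase[0] == pytest.approx(42.34, abs=5e-3)
        assert mod[0] == pytest.approx(0.7392, abs=5e-5)

    def test_zero_frequency_limit(self):
        model = LorentzianLifetimeModel(3.0, 0.5, 0.97)
        phase, mod = phase_and_modulation(model, [1e-6])
        assert phase[0] == pytest.approx(0.0, abs=1e-4)
        assert mod[0] == pytest.approx(1.0, abs=1e-6)

    def test_lorentzian_matches_dense_quadrature_oracle(self):
        """tau_c = 4 ns, width = 1 ns at 30 MHz against an adaptive-quadrature
        transform of the truncated renormalised density."""
        tau_c, width, f = 4.0, 1.0, 30.0
        gamma = width / 2.0
        hi = tau_c + 50.0 * width
        omega = 2 * np.pi * f * 1e-3

        def dens(tau):
            return gamma / math.pi / ((tau - tau_c) ** 2 + gamma ** 2)

        z = quad(dens, 0, hi, limit=500, points=[tau_c])[0]
        n = quad(lambda t: dens(t) / z * omega * t ** 2 / (1 + (omega * t) ** 2),
                 0, hi, limit=500, points=[tau_c])[0]
        d = quad(lambda t: dens(t) / z * t / (1 + (omega * t) ** 2),
                 0, hi, limit=500, points=[tau_c])[0]
        j = quad(lambda t: dens(t) / z * t, 0, hi, limit=500, points=[tau_c])[0]
        phase, mod = phase_and_modulation(
            LorentzianLifetimeModel(tau_c, width, 1.0), [f])
        assert phase[0] == pytest.approx(math.degrees(math.atan2(n, d)), abs=1e-6)
        assert mod[0] == pytest.approx(math.hypot(n, d) / j, abs=1e-8)

    @pytest.mark.parametrize("model", [
        LorentzianLifetimeModel(1.45),
        LorentzianLifetimeModel(3.45, 0.4, 0.98),
    ])
    def test_phase_increases_modulation_decreases(self, model):
        f = np.geomspace(2.0, 250.0, 40)
        phase, mod = phase_and_modulation(model, f)
        assert np.all(np.diff(phase) > 0)
        assert np.all(np.diff(mod) < 0)
        assert np.all((phase > 0) & (phase < 90))
        assert np.all((mod > 0) & (mod <= 1))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            phase_and_modulation(LorentzianLifetimeModel(2.0), [10.0, -5.0])


def polarized_oracle(tau, r0, theta1, f_mhz):
    """Independent closed-form assembly for a single-exponential intensity
    decay with an unhindered rotator (r_inf = 0): per-component sine/cosine
    transforms of I_par and I_perp."""
    omega = 2 * np.pi * f_mhz * 1e-3
    tau1 = 1.0 / (1.0 / tau + 1.0 / theta1)

    def nd(components):
        n = sum(a * omega * t * t / (1 + (omega * t) ** 2) for t, a in components)
        d = sum(a * t / (1 + (omega * t) ** 2) for t, a in components)
        return n, d

    n_par, d_par = nd([(tau, 1.0), (tau1, 2 * r0)])
    n_perp, d_perp = nd([(tau, 1.0), (tau1, -r0)])
    dphi = math.degrees(math.atan2(n_perp, d_perp) - math.atan2(n_par, d_par))
    lam = math.hypot(n_par, d_par) / math.hypot(n_perp, d_perp)
    return dphi, lam


class TestPolarized:
    def test_unpolarized_emission(self, freq_grid):
        dphi, lam = polarized_observables(
            LorentzianLifetimeModel(2.0),
            HinderedRotatorModel(r0=0.0, r_inf=0.0, theta1=1.0), freq_grid)
        np.testing.assert_allclose(dphi, 0.0, atol=1e-12)
        np.testing.assert_allclose(lam, 1.0, atol=1e-12)

    def test_time_constant_anisotropy(self, freq_grid):
        """A constant r(t) keeps both polarised decays the same shape: the
        differential phase vanishes and the AC ratio is (1+2r)/(1-r)."""
        r = 0.3
        dphi, lam = polarized_observables(
            LorentzianLifetimeModel(2.0),
            HinderedRotatorModel(r0=r, r_inf=r, theta1=1.0, theta2=1e12),
            freq_grid)
        np.testing.assert_allclose(dphi, 0.0, atol=1e-5)
        np.testing.assert_allclose(lam, (1 + 2 * r) / (1 - r), rtol=1e-6)

    def test_single_exponential_rotator_closed_form(self):
        tau, r0, theta1, f = 2.0, 0.4, 1.0, 50.0
        dphi, lam = polarized_observables(
            LorentzianLifetimeModel(tau),
            HinderedRotatorModel(r0=r0, r_inf=0.0, theta1=theta1), [f])
        exp_dphi, exp_lam = polarized_oracle(tau, r0, theta1, f)
        assert dphi[0] == pytest.approx(exp_dphi, abs=1e-9)
        assert lam[0] == pytest.approx(exp_lam, rel=1e-12)

    def test_narrow_width_matches_single_exponential_forms(self):
        """width -> 0 polarized observables match the analytic
        single-exponential + rotator assembly within 1e-6."""
        f = np.geomspace(2.0, 250.0, 15)
        dphi, lam = polarized_observables(
            LorentzianLifetimeModel(2.0, width=1e-9),
            HinderedRotatorModel(r0=0.4, r_inf=0.0, theta1=1.0), f)
        expected = [polarized_oracle(2.0, 0.4, 1.0, fi) for fi in f]
        np.testing.assert_allclose(dphi, [e[0] for e in expected], atol=1e-6)
        np.testing.assert_allclose(lam, [e[1] for e in expected], atol=1e-6)

    def test_modulation_ratio_at_least_one_at_low_frequency(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            r0 = rng.uniform(0.05, 0.4)
            model = HinderedRotatorModel(
                r0=r0, r_inf=rng.uniform(0.0, r0), theta1=rng.uniform(0.2, 5.0))
            intensity = LorentzianLifetimeModel(
                rng.uniform(1.0, 5.0), rng.uniform(0.0, 0.5), rng.uniform(0.9, 1.0))
            _, lam = polarized_observables(intensity, model, [2.0])
            assert lam[0] >= 1.0


class TestReferenceCorrection:
    def test_closed_form_terms(self):
        phase, mod = reference_correction(
            np.array([0.0]), np.array([1.0]), ReferenceStandard(1.45), [100.0])
        assert phase[0] == pytest.approx(42.34, abs=5e-3)
        assert mod[0] == pytest.approx(0.7392, abs=5e-5)

    def test_vanishing_reference_lifetime_is_identity(self, freq_grid):
        raw_p = np.linspace(5, 60, len(freq_grid))
        raw_m = np.linspace(0.9, 0.3, len(freq_grid))
        phase, mod = reference_correction(raw_p, raw_m,
                                          ReferenceStandard(1e-9), freq_grid)
        np.testing.assert_allclose(phase, raw_p, atol=1e-6)
        np.testing.assert_allclose(mod, raw_m, rtol=1e-9)

    def test_round_trip_identity(self, lifetime_truth, freq_grid):
        """Observables measured against the reference, then corrected,
        equal the absolute observables."""
        ref = ReferenceStandard(1.45)
        abs_phase, abs_mod = phase_and_modulation(lifetime_truth, freq_grid)
        wt = mhz_to_rad_per_ns(freq_grid) * ref.lifetime
        rel_phase = abs_phase - np.degrees(np.arctan(wt))
        rel_mod = abs_mod * np.sqrt(1.0 + wt ** 2)
        phase, mod = reference_correction(rel_phase, rel_mod, ref, freq_grid)
        np.testing.assert_allclose(phase, abs_phase, atol=1e-9)
        np.testing.assert_allclose(mod, abs_mod, atol=1e-9)


class TestDataset:
    def test_csv_round_trip(self, tmp_path, lifetime_truth, freq_grid):
        phase, mod = phase_and_modulation(lifetime_truth, freq_grid)
        ds = FrequencyDomainDataset(
            frequencies=freq_grid, mode="magic_angle", phase=phase,
            modulation=mod, metadata={"sample": "DOPC", "temperature": 25})
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = FrequencyDomainDataset.from_csv(path)
        np.testing.assert_allclose(back.frequencies, ds.frequencies)
        np.testing.assert_allclose(back.phase, ds.phase)
        np.testing.assert_allclose(back.modulation, ds.modulation)
        assert back.mode == "magic_angle"
        assert back.metadata["sample"] == "DOPC"

    def test_rows_sorted_by_frequency(self):
        ds = FrequencyDomainDataset(
            frequencies=[50.0, 10.0, 100.0], mode="magic_angle",
            phase=[30.0, 10.0, 50.0], modulation=[0.7, 0.95, 0.4])
        assert list(ds.frequencies) == [10.0, 50.0, 100.0]
        assert list(ds.phase) == [10.0, 30.0, 50.0]

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(frequencies=[10, 20], phase=[1, 2], modulation=[0.9, 0.8]),
         "at least 3"),
        (dict(frequencies=[10, 10, 20], phase=[1, 1, 2], modulation=[0.9, 0.9, 0.8]),
         "distinct"),
        (dict(frequencies=[10, 20, 30], phase=[1, 2, 3], modulation=[0.9, 0.8, 0.7],
              phase_sigma=[0.1, -0.1, 0.1], modulation_sigma=[0.004] * 3),
         "sigmas"),
    ])
    def test_validation(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            FrequencyDomainDataset(mode="magic_angle", **kwargs)
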