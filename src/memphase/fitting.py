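"""Weighted least-squares estimation from frequency-domain datasets.

Two fits mirror the two measurement modes:

* :func:`fit_lifetime` — magic-angle phase/modulation data -> Lorentzian
  lifetime distribution (tau_center, width, main_fraction), with the
  scatter-term lifetime held fixed at 0.01 ns.
* :func:`fit_anisotropy` — differential-phase / modulation-ratio data ->
  hindered rotator (r0, r_inf, theta1), with the intensity decay supplied
  from a prior lifetime fit and theta2 held fixed.

Both minimise chi^2 = sum (phase residual / sigma_phi)^2
                    + sum (modulation residual / sigma_m)^2
with lmfit's bounded trust-region least squares, from a small set of
deterministic multi-starts around the supplied start model (the chi^2
surface in width / main_fraction is shallow).  Goodness of fit is the
reduced chi^2; parameter uncertainty is the correlated (profile) 67%
confidence interval: the named parameter is scanned while all other free
parameters are re-optimised, and the interval is where the profile chi^2
stays below chi2_min * (1 + F_{0.67}(1, nu)/nu), the one-parameter
F-statistic threshold on the chi^2 ratio (nu = degrees of freedom).  For
correctly weighted data (chi2_min ~ nu) this is numerically the familiar
delta-chi^2 ~ 1 rule; for an exact fit (chi2_min -> 0) the interval
collapses, as it should when the data carry no residual scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import f as f_dist

from .freqdomain import (
    MAGIC_ANGLE,
    POLARIZED,
    FrequencyDomainDataset,
    phase_and_modulation,
    polarized_observables,
)
from .models import (
    HinderedRotatorModel,
    LorentzianLifetimeModel,
    derive_anisotropy_parameters,
)

__all__ = ["FitResult", "fit_lifetime", "fit_anisotropy", "confidence_limits"]

#: Confidence level of the profile (correlated) intervals.
CONFIDENCE_LEVEL = 0.67

N_STARTS_DEFAULT = 5


def profile_threshold(chi2_min: float, dof: int) -> float:
    """chi^2 value bounding the one-parameter 67% confidence region."""
    return chi2_min * (1.0 + f_dist.ppf(CONFIDENCE_LEVEL, 1, dof) / dof) + 1e-12


@dataclass
class FitResult:
    """Outcome of a weighted least-squares fit."""

    estimates: dict
    fixed: dict
    reduced_chi_squared: float
    chi_squared: float
    confidence_67: dict
    n_obs: int
    n_free: int
    converged: bool
    start: dict
    flags: list = field(default_factory=list)
    derived: dict = field(default_factory=dict)
    _profiler: object = field(default=None, repr=False, compare=False)

    def model(self):
        """Rebuild the fitted model object from the estimates."""
        if "tau_center" in self.estimates:
            return LorentzianLifetimeModel(**self.estimates, **self.fixed)
        return HinderedRotatorModel(**self.estimates, **self.fixed)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "fixed": self.fixed,
            "reduced_chi_squared": self.reduced_chi_squared,
            "chi_squared": self.chi_squared,
            "confidence_67": self.confidence_67,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "converged": self.converged,
            "start": self.start,
            "flags": self.flags,
            "derived": self.derived,
        }


def _chi2(result: lmfit.minimizer.MinimizerResult) -> float:
    return float(np.sum(result.residual ** 2))


def _run_multistart(params: lmfit.Parameters, residual, n_starts: int, seed: int,
                    perturb: dict):
    """Minimise from the given start plus ``n_starts - 1`` seeded perturbations.

    Returns the best result by chi^2; ties (within 1e-9 relative) broken by
    the smallest value of the parameter named in ``perturb['tie_break']``.
    """
    rng = np.random.default_rng(seed)
    tie_break = perturb.get("tie_break")
    candidates = []
    for k in range(n_starts):
        p = params.copy()
        if k > 0:
            for name in p:
                par = p[name]
                if not par.vary:
                    continue
                lo, hi = par.min, par.max
                if par.value > 0 and (not np.isfinite(hi) or hi > 10 * max(par.value, 1e-12)):
                    val = par.value * float(np.exp(rng.normal(0.0, 0.25)))
                else:
                    span = (hi - lo) if np.isfinite(hi - lo) else max(abs(par.value), 1.0)
                    val = par.value + float(rng.normal(0.0, 0.15 * span))
                par.value = float(np.clip(val, lo + 1e-12 if np.isfinite(lo) else val,
                                          hi - 1e-12 if np.isfinite(hi) else val))
        try:
            res = lmfit.minimize(residual, p, method="least_squares",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        candidates.append(res)
    if not candidates:
        raise RuntimeError("all optimiser starts failed")
    best = min(candidates, key=_chi2)
    best_chi2 = _chi2(best)
    if tie_break is not None:
        tied = [c for c in candidates
                if _chi2(c) <= best_chi2 * (1 + 1e-9) + 1e-12]
        best = min(tied, key=lambda c: c.params[tie_break].value)
    return best, candidates


def _profile_interval(residual, best_params: lmfit.Parameters, name: str,
                      chi2_min: float, dof: int,
                      bound_lo: float, bound_hi: float):
    """Profile-scan confidence interval for one parameter.

    Walks outward from the estimate, re-optimising all other free parameters
    at each fixed value, until the profile chi^2 exceeds the F-statistic
    threshold or a bound is reached; the crossing is located by linear
    interpolation.  Returns (low, high, open_ended_flag).
    """
    est = best_params[name].value

    def profile_chi2(value: float) -> float:
        p = best_params.copy()
        p[name].set(value=value, vary=False)
        res = lmfit.minimize(residual, p, method="least_squares",
                             xtol=1e-10, ftol=1e-10, gtol=1e-10)
        return _chi2(res)

    threshold = profile_threshold(chi2_min, dof)
    step0 = max(abs(est) * 1e-3, 1e-6)

    def scan(direction: int, bound: float):
        step = step0
        prev_v, prev_c = est, chi2_min
        for _ in range(60):
            v = prev_v + direction * step
            if (direction < 0 and v <= bound) or (direction > 0 and v >= bound):
                v = bound + direction * (-1e-12)
                c = profile_chi2(v)
                if c < threshold:
                    return bound, True
                # crossing between prev_v and bound
                if c > prev_c:
                    frac = (threshold - prev_c) / (c - prev_c)
                    return prev_v + frac * (v - prev_v), False
                return v, False
            c = profile_chi2(v)
            if c >= threshold:
                if c > prev_c:
                    frac = (threshold - prev_c) / (c - prev_c)
                    return prev_v + frac * (v - prev_v), False
                return v, False
            prev_v, prev_c = v, c
            step *= 2.0
        return prev_v, True

    low, open_lo = scan(-1, bound_lo)
    high, open_hi = scan(+1, bound_hi)
    return float(low), float(high), (open_lo or open_hi)


def confidence_limits(fit: FitResult, parameter: str, objective=None):
    """Correlated 67% confidence limits for one fitted parameter.

    ``objective`` may override the stored re-optimisation closure; by default
    the fit's own profiler (dataset + model structure) is used.
    """
    if not fit.converged:
        raise ValueError("confidence limits require a converged fit")
    profiler = objective if objective is not None else fit._profiler
    if profiler is None:
        raise ValueError("fit carries no profiler and no objective was supplied")
    return profiler(parameter)


def _make_profiler(residual, best_params, chi2_min, dof, bounds, fit_holder: dict):
    def profiler(name: str):
        if name not in bounds:
            raise KeyError(f"unknown free parameter {name!r}")
        lo, hi = bounds[name]
        low, high, open_ended = _profile_interval(residual, best_params, name,
                                                  chi2_min, dof, lo, hi)
        if open_ended and "open-ended confidence interval" not in fit_holder["flags"]:
            fit_holder["flags"].append("open-ended confidence interval")
        return low, high
    return profiler


def fit_lifetime(dataset: FrequencyDomainDataset,
                 start: LorentzianLifetimeModel,
                 *, n_starts: int = N_STARTS_DEFAULT, seed: int = 0,
                 compute_ci: bool = False) -> FitResult:
    """Fit a Lorentzian lifetime distribution to magic-angle data."""
    if dataset.mode != MAGIC_ANGLE:
        raise ValueError(f"fit_lifetime needs a magic_angle dataset, got {dataset.mode!r}")
    n_obs = 2 * len(dataset)
    n_free = 3
    if n_obs <= n_free:
        raise ValueError("fewer observations than free parameters")

    params = lmfit.Parameters()
    params.add("tau_center", value=start.tau_center, min=1e-3, max=1e3)
    params.add("width", value=max(start.width, 1e-6), min=0.0, max=1e3)
    params.add("main_fraction", value=start.main_fraction, min=0.0, max=1.0)

    def residual(p):
        model = LorentzianLifetimeModel(
            tau_center=p["tau_center"].value, width=p["width"].value,
            main_fraction=p["main_fraction"].value,
            scatter_lifetime=start.scatter_lifetime)
        phase, mod = phase_and_modulation(model, dataset.frequencies)
        return np.concatenate([
            (phase - dataset.phase) / dataset.phase_sigma,
            (mod - dataset.modulation) / dataset.modulation_sigma,
        ])

    try:
        best, _ = _run_multistart(params, residual, n_starts, seed,
                                  {"tie_break": "width"})
        converged = bool(best.success)
    except RuntimeError:
        best, converged = None, False

    flags: list = []
    if best is None:
        return FitResult(estimates={}, fixed={"scatter_lifetime": start.scatter_lifetime},
                         reduced_chi_squared=np.nan, chi_squared=np.nan,
                         confidence_67={}, n_obs=n_obs, n_free=n_free,
                         converged=False, start=start.to_dict(),
                         flags=["optimisation failed"])
    chi2 = _chi2(best)
    estimates = {k: float(best.params[k].value) for k in ("tau_center", "width", "main_fraction")}
    fixed = {"scatter_lifetime": start.scatter_lifetime}
    holder = {"flags": flags}
    bounds = {k: (best.params[k].min, best.params[k].max) for k in estimates}
    profiler = _make_profiler(residual, best.params, chi2, n_obs - n_free, bounds, holder)
    fit = FitResult(
        estimates=estimates, fixed=fixed,
        reduced_chi_squared=chi2 / (n_obs - n_free), chi_squared=chi2,
        confidence_67={}, n_obs=n_obs, n_free=n_free, converged=converged,
        start=start.to_dict(), flags=flags, _profiler=profiler,
    )
    if not converged:
        flags.append("optimiser did not report convergence")
    if compute_ci and converged:
        for name in estimates:
            fit.confidence_67[name] = profiler(name)
    return fit


def fit_anisotropy(dataset: FrequencyDomainDataset,
                   intensity: LorentzianLifetimeModel,
                   start: HinderedRotatorModel,
                   *, n_starts: int = N_STARTS_DEFAULT, seed: int = 0,
                   compute_ci: bool = False) -> FitResult:
    """Fit a hindered rotator to polarized (differential phase / modulation
    ratio) data, with the intensity decay held fixed.

    Internally r_inf is parameterised as ``r0 * hindrance`` with hindrance in
    [0, 1], which enforces 0 <= r_inf <= r0 <= 0.4 as simple box bounds.
    """
    if dataset.mode != POLARIZED:
        raise ValueError(f"fit_anisotropy needs a polarized dataset, got {dataset.mode!r}")
    n_obs = 2 * len(dataset)
    n_free = 3
    if n_obs <= n_free:
        raise ValueError("fewer observations than free parameters")

    params = lmfit.Parameters()
    params.add("r0", value=start.r0, min=1e-4, max=0.4)
    params.add("hindrance", value=min(start.r_inf / max(start.r0, 1e-9), 1.0),
               min=0.0, max=1.0)
    params.add("theta1", value=start.theta1, min=1e-3, max=1e4)

    def to_model(p) -> HinderedRotatorModel:
        r0 = p["r0"].value
        return HinderedRotatorModel(r0=r0, r_inf=r0 * p["hindrance"].value,
                                    theta1=p["theta1"].value, theta2=start.theta2)

    def residual(p):
        dphi, lam = polarized_observables(intensity, to_model(p), dataset.frequencies)
        return np.concatenate([
            (dphi - dataset.phase) / dataset.phase_sigma,
            (lam - dataset.modulation) / dataset.modulation_sigma,
        ])

    try:
        best, _ = _run_multistart(params, residual, n_starts, seed,
                                  {"tie_break": "theta1"})
        converged = bool(best.success)
    except RuntimeError:
        best, converged = None, False

    fixed = {"theta2": start.theta2}
    if best is None:
        return FitResult(estimates={}, fixed=fixed, reduced_chi_squared=np.nan,
                         chi_squared=np.nan, confidence_67={}, n_obs=n_obs,
                         n_free=n_free, converged=False, start=start.to_dict(),
                         flags=["optimisation failed"])
    chi2 = _chi2(best)
    model = to_model(best.params)
    estimates = {"r0": model.r0, "r_inf": model.r_inf, "theta1": model.theta1}
    flags: list = []
    if best.params["hindrance"].value > 1.0 - 1e-6:
        flags.append("fully hindered")
    holder = {"flags": flags}
    bounds = {"r0": (1e-4, 0.4), "hindrance": (0.0, 1.0), "theta1": (1e-3, 1e4)}
    profiler = _make_profiler(residual, best.params, chi2, n_obs - n_free, bounds, holder)
    derived = derive_anisotropy_parameters(model)
    fit = FitResult(
        estimates=estimates, fixed=fixed,
        reduced_chi_squared=chi2 / (n_obs - n_free), chi_squared=chi2,
        confidence_67={}, n_obs=n_obs, n_free=n_free, converged=converged,
        start=start.to_dict(), flags=flags,
        derived={"f1": derived.f1, "R1": derived.R1, "S": derived.S},
        _profiler=profiler,
    )
    if not converged:
        flags.append("optimiser did not report convergence")
    if compute_ci and converged:
        for name in ("r0", "hindrance", "theta1"):
            key = "r_inf/r0" if name == "hindrance" else name
            fit.confidence_67[key] = profiler(name)
    return fit
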