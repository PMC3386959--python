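"""Synthetic measurements for the two experimental arms.

The generators stand in for the wet-lab inputs:

* cuvette arm — frequency-domain datasets (magic-angle or polarized) from a
  known intensity + anisotropy truth, with independent Gaussian noise on
  phase and modulation (the noise model of a cross-correlation phase
  fluorometer at good signal);
* imaging arm — two-channel giant-vesicle images: a bright equatorial ring
  on a dark background carrying one or two contiguous angular domains of
  distinct GP, with Poisson counting noise applied per channel (which is how
  two-channel photon noise actually propagates into GP), and thermotropic
  series of such images crossing a coexistence onset.

Every generator is a pure function of (recipe, seed): per-element
sub-streams are derived from the seed and the element index, so series are
reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .freqdomain import (
    DEFAULT_MODULATION_SIGMA,
    DEFAULT_PHASE_SIGMA_DEG,
    MAGIC_ANGLE,
    POLARIZED,
    FrequencyDomainDataset,
    phase_and_modulation,
    polarized_observables,
)
from .models import HinderedRotatorModel, LorentzianLifetimeModel

__all__ = [
    "SimulationRecipe",
    "VesicleImageRecipe",
    "default_frequency_grid",
    "simulate_frequency_dataset",
    "simulate_guv_image",
    "simulate_thermotropic_series",
]


def default_frequency_grid() -> np.ndarray:
    """15 log-spaced modulation frequencies, 2-250 MHz: spans the phase
    sensitivity of 0.5-5 ns lifetimes."""
    return np.geomspace(2.0, 250.0, 15)


def _rng(seed: int, *index) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, index)]))


@dataclass(frozen=True)
class SimulationRecipe:
    """Truth models + noise levels for one cuvette dataset."""

    truth_intensity: LorentzianLifetimeModel
    truth_anisotropy: HinderedRotatorModel | None = None
    frequency_grid: np.ndarray = field(default_factory=default_frequency_grid)
    noise_phase_sigma: float = DEFAULT_PHASE_SIGMA_DEG
    noise_modulation_sigma: float = DEFAULT_MODULATION_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_phase_sigma < 0 or self.noise_modulation_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


def simulate_frequency_dataset(recipe: SimulationRecipe, mode: str = MAGIC_ANGLE,
                               index: int = 0) -> FrequencyDomainDataset:
    """Forward-model observables on the recipe grid plus Gaussian noise.

    With zero noise sigmas the stored observables equal the forward model
    exactly.  The stored per-point sigmas are the noise sigmas (or the
    instrument defaults when a noise sigma is zero) so downstream fits are
    correctly weighted.  ``index`` selects the per-element sub-stream.
    """
    freqs = np.asarray(recipe.frequency_grid, dtype=float)
    if mode == MAGIC_ANGLE:
        phase, modulation = phase_and_modulation(recipe.truth_intensity, freqs)
    elif mode == POLARIZED:
        if recipe.truth_anisotropy is None:
            raise ValueError("polarized simulation needs truth_anisotropy")
        phase, modulation = polarized_observables(
            recipe.truth_intensity, recipe.truth_anisotropy, freqs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(recipe.seed, 0 if mode == MAGIC_ANGLE else 1, index)
    if recipe.noise_phase_sigma > 0:
        phase = phase + rng.normal(0.0, recipe.noise_phase_sigma, size=freqs.shape)
    if recipe.noise_modulation_sigma > 0:
        modulation = modulation + rng.normal(0.0, recipe.noise_modulation_sigma,
                                             size=freqs.shape)
    metadata = {
        "mode": mode,
        "seed": recipe.seed,
        "index": index,
        **{f"truth_{k}": v for k, v in recipe.truth_intensity.to_dict().items()},
    }
    if recipe.truth_anisotropy is not None:
        metadata.update({f"truth_{k}": v
                         for k, v in recipe.truth_anisotropy.to_dict().items()})
    return FrequencyDomainDataset(
        frequencies=freqs, mode=mode, phase=phase, modulation=modulation,
        phase_sigma=np.full_like(freqs, recipe.noise_phase_sigma
                                 or DEFAULT_PHASE_SIGMA_DEG),
        modulation_sigma=np.full_like(freqs, recipe.noise_modulation_sigma
                                      or DEFAULT_MODULATION_SIGMA),
        metadata=metadata,
    )


@dataclass(frozen=True)
class VesicleImageRecipe:
    """Geometry, GP domains and noise of one synthetic GUV equatorial image.

    ``total_intensity_per_pixel`` is the expected summed photon count per
    ring pixel; with Poisson noise the per-pixel GP standard deviation is
    roughly sqrt((1 - GP^2)/N), so the default N = 400 gives sigma_GP ~ 0.05.
    """

    domain_gps: tuple
    domain_fractions: tuple = None
    image_size: int = 256
    ring_radius: float = 80.0
    ring_width: float = 12.0
    total_intensity_per_pixel: float = 400.0
    noise_model: str = "poisson"
    background: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        gps = tuple(float(g) for g in np.atleast_1d(self.domain_gps))
        object.__setattr__(self, "domain_gps", gps)
        if self.domain_fractions is None:
            fracs = tuple([1.0 / len(gps)] * len(gps))
        else:
            fracs = tuple(float(f) for f in np.atleast_1d(self.domain_fractions))
        object.__setattr__(self, "domain_fractions", fracs)
        if len(fracs) != len(gps):
            raise ValueError("domain_fractions must align with domain_gps")
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("domain_fractions must be positive and sum to 1")
        if any(abs(g) > 1 for g in gps):
            raise ValueError("domain GPs must lie in [-1, 1]")
        if self.ring_radius + self.ring_width / 2 >= self.image_size / 2:
            raise ValueError("ring does not fit in the image")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.total_intensity_per_pixel <= 0:
            raise ValueError("total_intensity_per_pixel must be > 0")


def simulate_guv_image(recipe: VesicleImageRecipe, index: int = 0):
    """Render one vesicle image; returns (blue, red, truth_record).

    Ring pixels are assigned to contiguous angular sectors per
    ``domain_fractions``; channel expectations solve I_b + I_r = N and
    (I_b - I_r)/(I_b + I_r) = GP of the pixel's domain.  The truth record
    carries per-pixel domain labels (-1 off ring).
    """
    size = recipe.image_size
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    on_ring = np.abs(r - recipe.ring_radius) <= recipe.ring_width / 2.0
    angle = (np.arctan2(yy - c, xx - c) + np.pi) / (2.0 * np.pi)  # [0, 1)

    edges = np.concatenate([[0.0], np.cumsum(recipe.domain_fractions)])
    edges[-1] = 1.0 + 1e-12
    labels = np.full((size, size), -1, dtype=int)
    labels[on_ring] = np.searchsorted(edges, angle[on_ring], side="right") - 1

    gp_map = np.zeros((size, size))
    for k, g in enumerate(recipe.domain_gps):
        gp_map[labels == k] = g
    n = recipe.total_intensity_per_pixel
    blue = np.where(on_ring, n * (1.0 + gp_map) / 2.0, 0.0) + recipe.background * (~on_ring)
    red = np.where(on_ring, n * (1.0 - gp_map) / 2.0, 0.0) + recipe.background * (~on_ring)
    if recipe.noise_model == "poisson":
        rng = _rng(recipe.seed, 2, index)
        blue = rng.poisson(blue).astype(float)
        red = rng.poisson(red).astype(float)
    truth = {
        "domain_gps": recipe.domain_gps,
        "domain_fractions": recipe.domain_fractions,
        "labels": labels,
        "on_ring": on_ring,
        "seed": recipe.seed,
        "index": index,
    }
    return blue, red, truth


def _as_linear(spec):
    """A GP-vs-temperature spec: a callable, or (intercept, slope) for
    intercept + slope * T."""
    if callable(spec):
        return spec
    a, b = spec
    return lambda t: a + b * t


#: Default thermotropic GP trends: constant separation 0.5, passing through
#: ~0.45 (ordered) and ~-0.05 (fluid) near a low-30s onset.
GP_HIGH_DEFAULT = (0.61, -0.005)
GP_LOW_DEFAULT = (0.11, -0.005)


def simulate_thermotropic_series(t_grid, t_onset: float,
                                 gp_high=GP_HIGH_DEFAULT,
                                 gp_low=GP_LOW_DEFAULT,
                                 recipe: VesicleImageRecipe | None = None):
    """Image pairs across a temperature grid crossing a coexistence onset.

    Below ``t_onset`` each image carries two angular domains at
    ``gp_high(T)`` and ``gp_low(T)``; at and above it, a single domain at
    the fraction-weighted mean GP.  Returns ``(entries, truth)`` where
    ``entries`` is a list of ``(temperature, blue, red)`` and ``truth``
    records the onset and per-temperature domain GPs.
    """
    temps = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if not (temps[0] - np.diff(temps).max() <= t_onset <= temps[-1] + np.diff(temps).max()):
        raise ValueError("t_onset must lie within or adjacent to the grid")
    high, low = _as_linear(gp_high), _as_linear(gp_low)
    if recipe is None:
        recipe = VesicleImageRecipe(domain_gps=(0.0,))
    fracs = recipe.domain_fractions if len(recipe.domain_fractions) == 2 else (0.5, 0.5)
    entries, per_t = [], []
    for i, t in enumerate(temps):
        if t < t_onset:
            gps, fr = (high(t), low(t)), fracs
        else:
            mean = fracs[0] * high(t) + fracs[1] * low(t)
            gps, fr = (mean,), (1.0,)
        r = replace(recipe, domain_gps=gps, domain_fractions=fr)
        blue, red, _ = simulate_guv_image(r, index=i)
        entries.append((float(t), blue, red))
        per_t.append({"temperature": float(t), "domain_gps": gps})
    truth = {"t_onset": float(t_onset), "per_temperature": per_t,
             "seed": recipe.seed}
    return entries, truth
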