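"""Laurdan generalized polarization (GP) analysis of two-channel images.

Laurdan's emission shifts red as water penetrates the bilayer interface, so
the ratiometric index

    GP = (I_blue - I_red) / (I_blue + I_red)

(blue ~440 nm, red ~490 nm) reports membrane packing per pixel: ordered,
dehydrated bilayers give high GP, fluid hydrated ones low GP.  A giant
vesicle imaged at its equator appears as a bright ring; when two liquid
phases coexist the ring carries two GP populations and the pixel histogram
becomes bimodal.

This module computes pixel-wise GP maps with an intensity mask, fits the
smoothed peak-normalised GP histogram with one or two Gaussians, decides
between one and two phases, and extracts the immiscibility transition
temperature from a thermotropic series of such decisions (two populations
below the transition, one above).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.optimize import least_squares

__all__ = [
    "GPConfig",
    "GPImage",
    "GPHistogram",
    "ThermotropicSeries",
    "generalized_polarization",
    "gp_image",
    "fit_gp_histogram",
    "detect_phase_coexistence",
    "immiscibility_transition_temperature",
    "analyze_thermotropic_series",
    "read_channel_tiff",
    "write_gp_tiff",
]


class InsufficientDataError(ValueError):
    """Too few valid pixels to form a GP histogram."""


@dataclass(frozen=True)
class GPConfig:
    """Tunables of the GP histogram / coexistence analysis.

    The imaging literature leaves these unspecified; defaults were chosen
    for robustness on synthetic vesicles and are all overridable.
    """

    bin_width: float = 0.02
    smoothing_window: int = 5          # moving-average window, bins (odd)
    relative_intensity_threshold: float = 0.02  # fraction of joint-channel max
    min_separation: float = 0.15       # GP units between the two centres
    rss_ratio_threshold: float = 0.5   # 2-comp RSS must be < 50% of 1-comp RSS
    amplitude_floor: float = 0.1       # of the (peak-normalised) maximum

    def __post_init__(self) -> None:
        if not 0 < self.bin_width <= 0.2:
            raise ValueError(f"bin_width must be in (0, 0.2], got {self.bin_width}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


def generalized_polarization(intensity_blue, intensity_red):
    """GP = (I_blue - I_red)/(I_blue + I_red); scalar or elementwise."""
    b = np.asarray(intensity_blue, dtype=float)
    r = np.asarray(intensity_red, dtype=float)
    total = b + r
    if np.any(total <= 0):
        raise ZeroDivisionError("GP undefined where I_blue + I_red <= 0")
    out = (b - r) / total
    return float(out) if out.ndim == 0 else out


@dataclass
class GPImage:
    """Pixel-wise GP map with a validity mask and its source channels."""

    gp: np.ndarray
    mask: np.ndarray
    source_channels: tuple
    intensity_threshold: float

    def valid_values(self) -> np.ndarray:
        return self.gp[self.mask]


def gp_image(blue: np.ndarray, red: np.ndarray,
             intensity_threshold: float | None = None,
             config: GPConfig = GPConfig()) -> GPImage:
    """Build a GP map: GP per pixel where blue + red exceeds the threshold.

    ``intensity_threshold`` defaults to ``config.relative_intensity_threshold``
    times the maximum of the summed channels, which keeps the vesicle ring
    and rejects dark background.
    """
    blue = np.asarray(blue, dtype=float)
    red = np.asarray(red, dtype=float)
    if blue.shape != red.shape:
        raise ValueError(f"channel shapes differ: {blue.shape} vs {red.shape}")
    total = blue + red
    if intensity_threshold is None:
        intensity_threshold = config.relative_intensity_threshold * float(total.max(initial=0.0))
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    mask = total > intensity_threshold
    gp = np.zeros_like(total)
    np.divide(blue - red, total, out=gp, where=mask)
    gp = np.clip(gp, -1.0, 1.0)
    return GPImage(gp=gp, mask=mask, source_channels=(blue, red),
                   intensity_threshold=float(intensity_threshold))


@dataclass
class GPHistogram:
    """Smoothed, peak-normalised GP histogram and its Gaussian fit.

    ``fitted_components`` holds (center, width, amplitude) per Gaussian;
    the centre is the reported GP value of that population.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    fitted_components: list
    n_components: int
    fit_rss: float

    @property
    def centers(self) -> list:
        return [c[0] for c in self.fitted_components]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "fit_rss": self.fit_rss,
            "components": [
                {"center": c, "width": w, "amplitude": a}
                for c, w, a in self.fitted_components
            ],
        }


def _gaussian_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for c, s, a in params.reshape(-1, 3):
        out += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return out


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(counts, kernel, mode="same")


def fit_gp_histogram(image: GPImage, n_components: int = 1,
                     bin_width: float | None = None,
                     smoothing_window: int | None = None,
                     config: GPConfig = GPConfig()) -> GPHistogram:
    """Histogram the masked GP values and fit one or two Gaussians.

    The histogram on [-1, 1] is moving-average smoothed and normalised to a
    peak of 1 before a bounded least-squares Gaussian fit.  Returns centres,
    widths, amplitudes and the residual sum of squares.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    bin_width = config.bin_width if bin_width is None else bin_width
    smoothing_window = (config.smoothing_window if smoothing_window is None
                        else smoothing_window)
    if not 0 < bin_width <= 0.2:
        raise ValueError(f"bin_width must be in (0, 0.2], got {bin_width}")
    values = image.valid_values()
    if values.size < 50:
        raise InsufficientDataError(
            f"only {values.size} valid pixels; at least 50 required")

    n_bins = max(int(round(2.0 / bin_width)), 1)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])
    smoothed = _smooth(counts, smoothing_window)
    peak = smoothed.max()
    if peak <= 0:
        raise InsufficientDataError("empty histogram after masking")
    y = smoothed / peak

    sample_std = max(float(values.std()), bin_width / 2.0)
    if n_components == 1:
        p0 = np.array([float(centers[np.argmax(y)]), sample_std, 1.0])
    else:
        lo, hi = np.quantile(values, [0.2, 0.8])
        if hi - lo < bin_width:
            hi = lo + bin_width
        p0 = np.array([lo, sample_std / 2.0, 0.8, hi, sample_std / 2.0, 0.8])
    lower = np.tile([-1.0, bin_width / 4.0, 0.0], n_components)
    upper = np.tile([1.0, 2.0, 2.0], n_components)
    p0 = np.clip(p0, lower + 1e-9, upper - 1e-9)
    sol = least_squares(lambda p: _gaussian_sum(centers, p) - y, p0,
                        bounds=(lower, upper), method="trf")
    comps = sorted(
        (tuple(map(float, sol.x[i:i + 3])) for i in range(0, 3 * n_components, 3)),
        key=lambda c: c[0])
    return GPHistogram(bin_centers=centers, counts=y,
                       fitted_components=list(comps),
                       n_components=n_components,
                       fit_rss=float(np.sum(sol.fun ** 2)))


def detect_phase_coexistence(image: GPImage,
                             config: GPConfig = GPConfig()) -> tuple[int, GPHistogram]:
    """Decide whether a GP image shows one or two liquid phases.

    Both a one- and a two-Gaussian model are fitted; two phases are declared
    only if the two-component fit reduces the residual sum of squares below
    ``rss_ratio_threshold`` times the one-component RSS, the centres are
    farther apart than ``min_separation`` and both amplitudes exceed
    ``amplitude_floor``.  Returns (n_phases, winning histogram fit).
    """
    h1 = fit_gp_histogram(image, 1, config=config)
    h2 = fit_gp_histogram(image, 2, config=config)
    (c1, _, a1), (c2, _, a2) = h2.fitted_components
    two = (
        h2.fit_rss < config.rss_ratio_threshold * h1.fit_rss
        and abs(c2 - c1) > config.min_separation
        and min(a1, a2) > config.amplitude_floor
    )
    return (2, h2) if two else (1, h1)


@dataclass
class ThermotropicSeries:
    """Per-temperature coexistence calls and the extracted transition."""

    temperatures: np.ndarray
    histograms: list
    n_phases: list
    transition_temperature: float | None
    gp_at_transition: float | None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "temperatures": list(map(float, self.temperatures)),
            "n_phases": list(map(int, self.n_phases)),
            "transition_temperature": self.transition_temperature,
            "gp_at_transition": self.gp_at_transition,
            "flags": self.flags,
            "histograms": [h.to_dict() for h in self.histograms],
        }


def immiscibility_transition_temperature(temperatures, n_phases, histograms):
    """Transition temperature from per-temperature coexistence calls.

    T_mix is the midpoint between the highest temperature called two-phase
    and the lowest one-phase temperature above it; the GP at the transition
    is the single-component centre at that one-phase temperature.  Returns
    ``(t_mix, gp_at_transition, flags)``; ``t_mix`` is None when no
    two-phase call exists, and equals the maximum temperature with an
    ``open-ended`` flag when every temperature is two-phase (censored).
    A non-monotone call pattern is flagged ambiguous with every candidate
    two-to-one midpoint reported.
    """
    temps = np.asarray(temperatures, dtype=float)
    if len(temps) < 4:
        raise ValueError("a thermotropic series needs at least 4 temperatures")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    calls = list(n_phases)
    flags: list = []
    two_idx = [i for i, c in enumerate(calls) if c == 2]
    if not two_idx:
        return None, None, ["no coexistence observed"]
    if all(c == 2 for c in calls):
        return float(temps[-1]), None, ["open-ended: coexistence at all temperatures"]

    boundaries = [i for i in range(len(calls) - 1)
                  if calls[i] == 2 and calls[i + 1] == 1]
    monotone = all(calls[i] == 2 for i in range(max(two_idx) + 1)) and len(boundaries) == 1
    if not monotone:
        candidates = [float(0.5 * (temps[i] + temps[i + 1])) for i in boundaries]
        flags.append(f"ambiguous transition; candidate midpoints: {candidates}")
    hi2 = max(two_idx)
    above_one = [i for i in range(hi2 + 1, len(calls)) if calls[i] == 1]
    if not above_one:  # 1-phase only below 2-phase: fully ambiguous
        candidates = [float(0.5 * (temps[i] + temps[i + 1])) for i in boundaries]
        flags.append("no one-phase call above the last two-phase call")
        return None, None, flags
    lo1 = min(above_one)
    t_mix = float(0.5 * (temps[hi2] + temps[lo1]))
    h = histograms[lo1]
    gp_at = float(h.fitted_components[0][0]) if h.n_components == 1 else None
    return t_mix, gp_at, flags


def analyze_thermotropic_series(temperatures, images,
                                config: GPConfig = GPConfig()) -> ThermotropicSeries:
    """Coexistence calls per temperature, then transition extraction.

    ``images`` is a sequence of :class:`GPImage` aligned with
    ``temperatures`` (strictly increasing, at least 4 points).
    """
    temps = np.asarray(temperatures, dtype=float)
    if len(temps) != len(images):
        raise ValueError("temperatures and images must align")
    calls, hists = [], []
    for img in images:
        n, h = detect_phase_coexistence(img, config)
        calls.append(n)
        hists.append(h)
    t_mix, gp_at, flags = immiscibility_transition_temperature(temps, calls, hists)
    return ThermotropicSeries(temperatures=temps, histograms=hists,
                              n_phases=calls, transition_temperature=t_mix,
                              gp_at_transition=gp_at, flags=flags)


# -- TIFF I/O ---------------------------------------------------------------

def read_channel_tiff(path, second_path=None) -> tuple[np.ndarray, np.ndarray]:
    """Read the blue (~440 nm) and red (~490 nm) channels.

    Either a single two-page TIFF (first page = blue by convention) or a
    pair of single-page TIFFs.
    """
    if second_path is not None:
        return (tifffile.imread(path).astype(float),
                tifffile.imread(second_path).astype(float))
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"{path}: expected a 2-page TIFF, got shape {stack.shape}")
    return stack[0].astype(float), stack[1].astype(float)


def write_gp_tiff(image: GPImage, tiff_path, report_path=None) -> None:
    """Write the GP map as 32-bit float TIFF (NaN off-mask) and, optionally,
    a JSON report of the mask and threshold."""
    gp = image.gp.astype(np.float32).copy()
    gp[~image.mask] = np.nan
    tifffile.imwrite(tiff_path, gp)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump({
                "intensity_threshold": image.intensity_threshold,
                "n_valid_pixels": int(image.mask.sum()),
                "shape": list(image.gp.shape),
            }, fh, indent=2)
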