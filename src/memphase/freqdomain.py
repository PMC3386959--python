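"""Frequency-domain (phase/modulation) observables of the decay models.

A multifrequency phase fluorometer excites with sinusoidally modulated light
and records, per modulation frequency f, the phase delay and demodulation of
the emission.  For a decay written as a sum of exponentials
``I(t) = sum_k a_k exp(-t/tau_k)`` the sine and cosine transforms have closed
forms per component,

    N(w) = sum_k a_k * w * tau_k^2 / (1 + w^2 tau_k^2)
    D(w) = sum_k a_k * tau_k   / (1 + w^2 tau_k^2)
    J    = sum_k a_k * tau_k              (steady-state intensity)

with w = 2*pi*f; then phase = atan2(N, D) and modulation = sqrt(N^2+D^2)/J.
The Lorentzian lifetime distribution enters through its quadrature
discretisation (see :mod:`memphase.models`), so every transform here is an
exact closed form over the discretised components.

Polarised (anisotropy) measurements use the parallel/perpendicular decays

    I_par(t)  = (1/3) I(t) [1 + 2 r(t)],   I_perp(t) = (1/3) I(t) [1 - r(t)]

whose products of exponentials are again exponentials.  The observables are
the differential phase  dphi = phi_perp - phi_par  (positive while the
anisotropy is decaying) and the modulation ratio  Lambda = AC_par / AC_perp,
the ratio of modulated (AC) amplitudes — the standard frequency-domain
anisotropy convention.  Note Lambda is *not* DC-normalised: for a
time-constant anisotropy r it tends to (1 + 2r)/(1 - r), not 1.

Phase is in degrees at every interface; radians are internal only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import HinderedRotatorModel, LorentzianLifetimeModel, ModelValidationError

__all__ = [
    "FrequencyDomainDataset",
    "ReferenceStandard",
    "mhz_to_rad_per_ns",
    "phase_and_modulation",
    "polarized_observables",
    "reference_correction",
]

#: Default per-point measurement uncertainties when a dataset carries none,
#: typical of a multifrequency cross-correlation instrument.
DEFAULT_PHASE_SIGMA_DEG = 0.2
DEFAULT_MODULATION_SIGMA = 0.004

MAGIC_ANGLE = "magic_angle"
POLARIZED = "polarized"


def mhz_to_rad_per_ns(frequencies_mhz) -> np.ndarray:
    """Angular frequency in rad/ns for modulation frequencies in MHz."""
    return 2.0 * np.pi * np.asarray(frequencies_mhz, dtype=float) * 1.0e-3


def _transforms(taus: np.ndarray, amps: np.ndarray, omega: np.ndarray):
    """Sine/cosine transforms N, D and total intensity J for a sum of
    exponentials with lifetimes ``taus`` and amplitudes ``amps``."""
    wt = omega[:, None] * taus[None, :]
    denom = 1.0 + wt * wt
    n = (amps[None, :] * wt * taus[None, :] / denom).sum(axis=1)
    d = (amps[None, :] * taus[None, :] / denom).sum(axis=1)
    j = float(np.dot(amps, taus))
    return n, d, j


def phase_and_modulation(model: LorentzianLifetimeModel, frequencies_mhz):
    """Magic-angle phase (degrees) and modulation at the given frequencies."""
    f = np.asarray(frequencies_mhz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive (MHz)")
    omega = mhz_to_rad_per_ns(f)
    taus, amps = model.components()
    n, d, j = _transforms(taus, amps, omega)
    phase = np.degrees(np.arctan2(n, d))
    modulation = np.sqrt(n * n + d * d) / j
    return phase, modulation


def _polarized_components(intensity: LorentzianLifetimeModel,
                          anisotropy: HinderedRotatorModel):
    """Exponential components of I_par and I_perp.

    Multiplying I(t) by exp(-t/theta) shifts each lifetime to
    1/tau' = 1/tau + 1/theta, so both polarised decays stay sums of
    exponentials (amplitudes may be negative for I_perp)."""
    taus, amps = intensity.components()
    t1 = 1.0 / (1.0 / taus + 1.0 / anisotropy.theta1)
    t2 = 1.0 / (1.0 / taus + 1.0 / anisotropy.theta2)
    dr = anisotropy.r0 - anisotropy.r_inf
    ri = anisotropy.r_inf
    par_taus = np.concatenate([taus, t1, t2])
    par_amps = np.concatenate([amps, 2.0 * dr * amps, 2.0 * ri * amps]) / 3.0
    perp_taus = par_taus
    perp_amps = np.concatenate([amps, -dr * amps, -ri * amps]) / 3.0
    return (par_taus, par_amps), (perp_taus, perp_amps)


def polarized_observables(intensity: LorentzianLifetimeModel,
                          anisotropy: HinderedRotatorModel,
                          frequencies_mhz):
    """Differential phase (degrees) and modulation ratio Lambda = AC_par/AC_perp."""
    if not isinstance(anisotropy, HinderedRotatorModel):
        raise ModelValidationError("anisotropy must be a HinderedRotatorModel")
    f = np.asarray(frequencies_mhz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive (MHz)")
    omega = mhz_to_rad_per_ns(f)
    (pt, pa), (st, sa) = _polarized_components(intensity, anisotropy)
    n_par, d_par, _ = _transforms(pt, pa, omega)
    n_perp, d_perp, _ = _transforms(st, sa, omega)
    delta_phase = np.degrees(np.arctan2(n_perp, d_perp) - np.arctan2(n_par, d_par))
    modulation_ratio = np.hypot(n_par, d_par) / np.hypot(n_perp, d_perp)
    return delta_phase, modulation_ratio


@dataclass(frozen=True)
class ReferenceStandard:
    """Lifetime reference compound for the intensity-decay measurement.

    Default 1.45 ns (dimethyl-POPOP in ethanol)."""

    lifetime: float = 1.45

    def __post_init__(self) -> None:
        if not self.lifetime > 0:
            raise ModelValidationError(f"reference lifetime must be > 0, got {self.lifetime}")


def reference_correction(raw_phase_deg, raw_modulation,
                         reference: ReferenceStandard, frequencies_mhz):
    """Convert reference-relative observables to absolute ones.

    A single-exponential reference of lifetime tau delays the phase by
    atan(w*tau) and demodulates by (1 + w^2 tau^2)^(-1/2); measured values
    relative to it are corrected back by adding/multiplying those terms.
    """
    omega = mhz_to_rad_per_ns(frequencies_mhz)
    wt = omega * reference.lifetime
    phase = np.asarray(raw_phase_deg, dtype=float) + np.degrees(np.arctan(wt))
    modulation = np.asarray(raw_modulation, dtype=float) / np.sqrt(1.0 + wt * wt)
    return phase, modulation


@dataclass
class FrequencyDomainDataset:
    """One multifrequency measurement: phase/modulation observables vs frequency.

    In ``magic_angle`` mode ``phase``/``modulation`` are the intensity-decay
    observables; in ``polarized`` mode they are the differential phase (deg)
    and the modulation ratio Lambda.  Rows are stored sorted by frequency.
    """

    frequencies: np.ndarray
    mode: str
    phase: np.ndarray
    modulation: np.ndarray
    phase_sigma: np.ndarray | None = None
    modulation_sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in (MAGIC_ANGLE, POLARIZED):
            raise ValueError(f"mode must be '{MAGIC_ANGLE}' or '{POLARIZED}', got {self.mode!r}")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        if self.phase_sigma is None:
            self.phase_sigma = np.full_like(self.frequencies, DEFAULT_PHASE_SIGMA_DEG)
        if self.modulation_sigma is None:
            self.modulation_sigma = np.full_like(self.frequencies, DEFAULT_MODULATION_SIGMA)
        self.phase_sigma = np.asarray(self.phase_sigma, dtype=float)
        self.modulation_sigma = np.asarray(self.modulation_sigma, dtype=float)
        n = len(self.frequencies)
        if n < 3:
            raise ValueError("dataset needs at least 3 frequencies")
        for name in ("phase", "modulation", "phase_sigma", "modulation_sigma"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n}")
        order = np.argsort(self.frequencies, kind="stable")
        for name in ("frequencies", "phase", "modulation", "phase_sigma", "modulation_sigma"):
            setattr(self, name, getattr(self, name)[order])
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be distinct and positive")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive (MHz)")
        if np.any(self.phase_sigma <= 0) or np.any(self.modulation_sigma <= 0):
            raise ValueError("sigmas must be > 0")
        if np.any(self.modulation <= 0):
            raise ValueError("modulation values must be > 0")
        # allow a noise margin above the ideal m <= 1 at low frequency
        if self.mode == MAGIC_ANGLE and np.any(self.modulation > 1.0 + 5.0 * self.modulation_sigma):
            raise ValueError("magic-angle modulation must lie in (0, 1] up to noise")

    def __len__(self) -> int:
        return len(self.frequencies)

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "frequency_MHz": self.frequencies,
            "phase_deg": self.phase,
            "phase_sigma_deg": self.phase_sigma,
            "modulation": self.modulation,
            "modulation_sigma": self.modulation_sigma,
            "mode": self.mode,
        })
        with open(path, "w") as fh:
            for key, value in sorted(self.metadata.items()):
                fh.write(f"# {key}={value}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrequencyDomainDataset":
        metadata: dict = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    metadata[key.strip()] = value.strip()
                else:
                    lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)))
        mode = str(df["mode"].iloc[0]) if "mode" in df else metadata.get("mode", MAGIC_ANGLE)
        return cls(
            frequencies=df["frequency_MHz"].to_numpy(),
            mode=mode,
            phase=df["phase_deg"].to_numpy(),
            modulation=df["modulation"].to_numpy(),
            phase_sigma=df["phase_sigma_deg"].to_numpy() if "phase_sigma_deg" in df else None,
            modulation_sigma=df["modulation_sigma"].to_numpy() if "modulation_sigma" in df else None,
            metadata=metadata,
        )
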