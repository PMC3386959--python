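"""Configuration-driven runs over sample series.

Two arms mirror the two experimental designs:

* spectroscopy — per (sample, temperature, cholesterol) entry: a magic-angle
  CSV and a polarized CSV; lifetime fit, then anisotropy fit with the fitted
  intensity decay held fixed, then the closed-form derived parameters.  The
  report is a table of tau_center, width, r0, r_inf, theta1, f1, R1, S and
  reduced chi^2 per entry.
* imaging — per cholesterol group: a thermotropic series of two-channel
  images; GP maps, coexistence calls, and the immiscibility transition
  temperature per group.

Failures are isolated per entry: a corrupt input yields a failure record,
never an aborted series.  Reports carry a provenance block (config hash,
seed, package version) and are deterministic for a fixed config + seed.
Stored values are full precision; rounding to the 2-decimal (3 for R1)
table style is presentation only (``render_spectroscopy_table``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import fit_anisotropy, fit_lifetime
from .freqdomain import FrequencyDomainDataset, mhz_to_rad_per_ns
from .gp import GPConfig, analyze_thermotropic_series, gp_image, read_channel_tiff
from .models import (
    HinderedRotatorModel,
    LorentzianLifetimeModel,
    round_half_away,
)

__all__ = [
    "PipelineConfig",
    "SeriesReport",
    "load_config",
    "run_spectroscopy_series",
    "run_imaging_series",
    "render_spectroscopy_table",
]


@dataclass
class PipelineConfig:
    """One declarative run: arm, input manifest, overrides, seed."""

    run_name: str
    arm: str  # spectroscopy | imaging | simulate
    entries: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("spectroscopy", "imaging", "simulate"):
            raise ValueError(f"unknown arm {self.arm!r}")
        keys = [(e.get("sample"), e.get("temperature"), e.get("cholesterol"))
                for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("manifest entries must be unique per "
                             "(sample, temperature, cholesterol)")

    def content_hash(self) -> str:
        canon = json.dumps(
            {"run_name": self.run_name, "arm": self.arm, "entries": self.entries,
             "parameters": self.parameters, "seed": self.seed},
            sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(
        run_name=raw.get("run_name", "run"),
        arm=raw["arm"],
        entries=raw.get("entries", []),
        parameters=raw.get("parameters", {}),
        output_dir=raw.get("output_dir", "."),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class SeriesReport:
    """Per-entry results table + isolated failures + provenance."""

    table: pd.DataFrame
    failures: list
    provenance: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "provenance": self.provenance,
                "failures": self.failures,
                "rows": self.table.to_dict(orient="records"),
            }, fh, indent=2, default=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def initial_lifetime_guess(dataset: FrequencyDomainDataset) -> LorentzianLifetimeModel:
    """Start model from the data: tau from tan(phase)/omega at mid-band."""
    i = len(dataset) // 2
    omega = mhz_to_rad_per_ns(dataset.frequencies[i])
    tau = float(np.tan(np.radians(np.clip(dataset.phase[i], 1.0, 85.0))) / omega)
    tau = float(np.clip(tau, 0.05, 50.0))
    return LorentzianLifetimeModel(tau_center=tau, width=0.1 * tau, main_fraction=0.98)


def initial_anisotropy_guess() -> HinderedRotatorModel:
    return HinderedRotatorModel(r0=0.35, r_inf=0.1, theta1=2.0)


def _provenance(config: PipelineConfig) -> dict:
    return {"run_name": config.run_name, "arm": config.arm,
            "config_hash": config.content_hash(), "seed": config.seed,
            "memphase_version": __version__}


def run_spectroscopy_series(config: PipelineConfig,
                            compute_ci: bool = False) -> SeriesReport:
    """Lifetime + anisotropy fits for every manifest entry.

    Each entry needs ``magic_angle`` and ``polarized`` CSV paths plus the
    (sample, temperature, cholesterol) labels.
    """
    rows, failures = [], []
    n_starts = int(config.parameters.get("n_starts", 5))
    for k, entry in enumerate(config.entries):
        label = {key: entry.get(key) for key in ("sample", "temperature", "cholesterol")}
        try:
            ds_ma = FrequencyDomainDataset.from_csv(entry["magic_angle"])
            ds_pol = FrequencyDomainDataset.from_csv(entry["polarized"])
            start_l = (LorentzianLifetimeModel.from_dict(entry["start_lifetime"])
                       if "start_lifetime" in entry else initial_lifetime_guess(ds_ma))
            lifetime_fit = fit_lifetime(ds_ma, start_l, n_starts=n_starts,
                                        seed=config.seed + k, compute_ci=compute_ci)
            intensity = lifetime_fit.model()
            start_a = (HinderedRotatorModel.from_dict(entry["start_anisotropy"])
                       if "start_anisotropy" in entry else initial_anisotropy_guess())
            aniso_fit = fit_anisotropy(ds_pol, intensity, start_a,
                                       n_starts=n_starts, seed=config.seed + k,
                                       compute_ci=compute_ci)
            rows.append({
                **label,
                "tau_center_ns": lifetime_fit.estimates["tau_center"],
                "width_ns": lifetime_fit.estimates["width"],
                "main_fraction": lifetime_fit.estimates["main_fraction"],
                "lifetime_reduced_chi2": lifetime_fit.reduced_chi_squared,
                "theta1_ns": aniso_fit.estimates["theta1"],
                "r_inf": aniso_fit.estimates["r_inf"],
                "r0": aniso_fit.estimates["r0"],
                "f1": aniso_fit.derived["f1"],
                "R1_rad_per_ns": aniso_fit.derived["R1"],
                "S": aniso_fit.derived["S"],
                "anisotropy_reduced_chi2": aniso_fit.reduced_chi_squared,
                "lifetime_ci": lifetime_fit.confidence_67,
                "anisotropy_ci": aniso_fit.confidence_67,
                "flags": lifetime_fit.flags + aniso_fit.flags,
            })
        except Exception as exc:  # crash isolation per entry
            failures.append({**label, "reason": f"{type(exc).__name__}: {exc}"})
    columns = ["sample", "temperature", "cholesterol", "tau_center_ns", "width_ns",
               "main_fraction", "lifetime_reduced_chi2", "theta1_ns", "r_inf",
               "r0", "f1", "R1_rad_per_ns", "S", "anisotropy_reduced_chi2",
               "lifetime_ci", "anisotropy_ci", "flags"]
    table = pd.DataFrame(rows, columns=columns)
    return SeriesReport(table=table, failures=failures,
                        provenance=_provenance(config))


def render_spectroscopy_table(report: SeriesReport) -> pd.DataFrame:
    """Presentation rounding: 2 decimals everywhere, 3 for R1."""
    df = report.table.copy()
    for col in ("theta1_ns", "f1", "r_inf", "r0", "S", "tau_center_ns"):
        if col in df:
            df[col] = df[col].map(lambda x: round_half_away(float(x), 2))
    if "R1_rad_per_ns" in df:
        df["R1_rad_per_ns"] = df["R1_rad_per_ns"].map(
            lambda x: round_half_away(float(x), 3))
    return df[["sample", "temperature", "cholesterol", "theta1_ns", "f1",
               "R1_rad_per_ns", "r_inf", "r0", "S"]]


def run_imaging_series(config: PipelineConfig) -> SeriesReport:
    """Thermotropic GP analysis per cholesterol group.

    Entries need ``cholesterol``, ``temperature`` and image paths (``image``
    for a 2-page TIFF or ``blue``/``red`` for a pair).
    """
    gp_params = {k: v for k, v in config.parameters.items()
                 if k in GPConfig.__dataclass_fields__}
    gp_config = GPConfig(**gp_params)
    groups: dict = {}
    for entry in config.entries:
        groups.setdefault(entry.get("cholesterol"), []).append(entry)

    rows, failures = [], []
    for chol, entries in sorted(groups.items(), key=lambda kv: (kv[0] is None, kv[0])):
        try:
            entries = sorted(entries, key=lambda e: e["temperature"])
            temps, images = [], []
            for e in entries:
                if "image" in e:
                    blue, red = read_channel_tiff(e["image"])
                else:
                    blue, red = read_channel_tiff(e["blue"], e["red"])
                images.append(gp_image(blue, red, config=gp_config))
                temps.append(float(e["temperature"]))
            series = analyze_thermotropic_series(temps, images, gp_config)
            rows.append({
                "cholesterol": chol,
                "t_mix_C": series.transition_temperature,
                "gp_at_transition": series.gp_at_transition,
                "n_phases_by_temperature": dict(zip(map(float, temps), series.n_phases)),
                "flags": series.flags,
            })
        except Exception as exc:
            failures.append({"cholesterol": chol,
                             "reason": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows, columns=["cholesterol", "t_mix_C", "gp_at_transition",
                                        "n_phases_by_temperature", "flags"])
    return SeriesReport(table=table, failures=failures,
                        provenance=_provenance(config))
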