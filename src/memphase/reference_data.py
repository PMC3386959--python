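"""Published anisotropy-decay parameters for DPH and Laurdan in vesicles.

One row per (probe, lipid system, temperature, cholesterol content) for
large unilamellar vesicles of DPPC, DOPC and the 1:1 DOPC/DPPC mixture at
25 and 50 degC with 0-40 mol% cholesterol.  The printed columns are the fast
rotational correlation time theta1 (ns), the fast fractional amplitude f1,
the fast rotational rate R1 (rad/ns), the residual and time-zero
anisotropies r_inf and r0, and the order parameter S.

Because f1, R1 and S follow from (theta1, r_inf, r0) in closed form
(f1 = 1 - r_inf/r0, R1 = 1/(6 theta1), S = sqrt(r_inf/r0)), the table
doubles as a consistency check of the derived-parameter relations: rows are
"consistent" when all three printed derived values reproduce after rounding
to printed precision (two decimals; three for R1).  Not every published row
is — the printed derived values were evidently rounded from unrounded fit
output, so some cells are off by one unit in the last digit.

Used as worked-example inputs; never used to calibrate any fit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import (
    HinderedRotatorModel,
    derive_anisotropy_parameters,
    render_derived_params,
)

__all__ = ["ReferenceRow", "REFERENCE_ROWS", "consistent_rows", "row"]


@dataclass(frozen=True)
class ReferenceRow:
    probe: str
    lipid: str
    temperature_C: float
    cholesterol_mol_pct: float
    theta1_ns: float
    f1: float
    R1_rad_per_ns: float
    r_inf: float
    r0: float
    S: float

    def inputs(self) -> HinderedRotatorModel:
        """The fitted-model inputs (theta1, r_inf, r0) of this row."""
        return HinderedRotatorModel(r0=self.r0, r_inf=self.r_inf,
                                    theta1=self.theta1_ns)

    def printed_derived(self) -> dict:
        return {"f1": self.f1, "R1": self.R1_rad_per_ns, "S": self.S}

    def is_consistent(self) -> bool:
        """True when the printed f1, R1, S reproduce from (theta1, r_inf, r0)
        after rounding to printed precision."""
        rendered = render_derived_params(derive_anisotropy_parameters(self.inputs()))
        return (rendered["f1"] == self.f1
                and rendered["R1"] == self.R1_rad_per_ns
                and rendered["S"] == self.S)


def _rows(probe, lipid, temp, data):
    return [ReferenceRow(probe, lipid, temp, chol, th, f1, r1, ri, r0, s)
            for chol, th, f1, r1, ri, r0, s in data]


REFERENCE_ROWS: list = (
    _rows("DPH", "DPPC", 25, [
        (0.0, 0.80, 0.11, 0.208, 0.36, 0.40, 0.95),
        (15.0, 0.71, 0.08, 0.235, 0.34, 0.40, 0.96),
        (22.2, 0.78, 0.04, 0.214, 0.37, 0.38, 0.98),
        (33.3, 0.99, 0.09, 0.168, 0.31, 0.37, 0.91),
        (40.0, 0.85, 0.13, 0.196, 0.33, 0.38, 0.93),
    ])
    + _rows("DPH", "DPPC", 50, [
        (0.0, 0.89, 0.79, 0.187, 0.08, 0.40, 0.46),
        (15.0, 0.58, 0.69, 0.287, 0.12, 0.38, 0.55),
        (22.2, 0.73, 0.51, 0.228, 0.14, 0.28, 0.70),
        (33.3, 0.89, 0.19, 0.187, 0.27, 0.32, 0.91),
        (40.0, 0.85, 0.23, 0.196, 0.23, 0.30, 0.88),
    ])
    + _rows("DPH", "DOPC", 25, [
        (0.0, 3.45, 0.94, 0.048, 0.02, 0.32, 0.25),
        (15.0, 3.74, 0.84, 0.045, 0.05, 0.31, 0.40),
        (22.2, 2.65, 0.65, 0.063, 0.11, 0.34, 0.60),
        (33.3, 3.00, 0.45, 0.056, 0.17, 0.31, 0.74),
        (40.0, 2.51, 0.44, 0.066, 0.18, 0.32, 0.75),
    ])
    + _rows("DPH", "DOPC", 50, [
        (0.0, 1.48, 0.97, 0.113, 0.01, 0.30, 0.18),
        (15.0, 1.39, 0.88, 0.120, 0.04, 0.33, 0.35),
        (22.2, 1.14, 0.79, 0.146, 0.06, 0.29, 0.46),
        (33.3, 1.61, 0.60, 0.104, 0.12, 0.30, 0.63),
        (40.0, 1.27, 0.61, 0.131, 0.12, 0.31, 0.62),
    ])
    + _rows("DPH", "DOPC/DPPC", 25, [
        (0.0, 2.98, 0.62, 0.056, 0.13, 0.34, 0.62),
        (15.0, 2.10, 0.46, 0.079, 0.20, 0.37, 0.74),
        (22.2, 2.50, 0.41, 0.067, 0.22, 0.37, 0.77),
        (33.3, 2.16, 0.29, 0.077, 0.24, 0.34, 0.71),
        (40.0, 2.40, 0.26, 0.069, 0.25, 0.34, 0.86),
    ])
    + _rows("DPH", "DOPC/DPPC", 50, [
        (0.0, 1.07, 0.90, 0.156, 0.03, 0.31, 0.31),
        (15.0, 0.93, 0.79, 0.179, 0.08, 0.39, 0.45),
        (22.2, 0.99, 0.78, 0.168, 0.09, 0.40, 0.47),
        (33.3, 0.82, 0.61, 0.203, 0.15, 0.39, 0.62),
        (40.0, 1.28, 0.37, 0.130, 0.19, 0.30, 0.80),
    ])
    + _rows("Laurdan", "DPPC", 25, [
        (0.0, 1.02, 0.27, 0.163, 0.27, 0.37, 0.85),
        (15.0, 2.59, 0.28, 0.064, 0.26, 0.35, 0.85),
        (22.2, 2.70, 0.32, 0.062, 0.23, 0.33, 0.82),
        (33.3, 2.32, 0.41, 0.072, 0.20, 0.34, 0.77),
        (40.0, 2.38, 0.38, 0.070, 0.21, 0.34, 0.79),
    ])
    + _rows("Laurdan", "DPPC", 50, [
        (0.0, 1.27, 0.89, 0.131, 0.04, 0.33, 0.35),
        (15.0, 1.77, 0.59, 0.094, 0.14, 0.33, 0.65),
        (22.2, 2.02, 0.59, 0.083, 0.13, 0.32, 0.64),
        (33.3, 1.66, 0.68, 0.100, 0.10, 0.34, 0.54),
        (40.0, 1.71, 0.67, 0.097, 0.11, 0.35, 0.57),
    ])
    + _rows("Laurdan", "DOPC", 25, [
        (0.0, 2.05, 0.78, 0.081, 0.07, 0.33, 0.46),
        (15.0, 2.04, 0.85, 0.082, 0.05, 0.34, 0.38),
        (22.2, 2.20, 0.78, 0.076, 0.07, 0.32, 0.47),
        (33.3, 2.27, 0.68, 0.073, 0.11, 0.34, 0.56),
        (40.0, 2.41, 0.76, 0.069, 0.07, 0.34, 0.45),
    ])
    + _rows("Laurdan", "DOPC", 50, [
        (0.0, 1.15, 0.89, 0.145, 0.03, 0.31, 0.33),
        (15.0, 1.09, 0.94, 0.152, 0.02, 0.31, 0.24),
        (22.2, 1.11, 0.93, 0.150, 0.02, 0.31, 0.26),
        (33.3, 1.21, 0.91, 0.138, 0.03, 0.33, 0.30),
        (40.0, 1.25, 0.87, 0.133, 0.04, 0.31, 0.36),
    ])
    + _rows("Laurdan", "DOPC/DPPC", 25, [
        (0.0, 2.23, 0.76, 0.075, 0.09, 0.36, 0.50),
        (15.0, 2.91, 0.77, 0.057, 0.09, 0.36, 0.50),
        (22.2, 2.73, 0.72, 0.061, 0.10, 0.37, 0.52),
        (33.3, 2.37, 0.61, 0.070, 0.14, 0.35, 0.63),
        (40.0, 2.92, 0.61, 0.057, 0.14, 0.36, 0.62),
    ])
    + _rows("Laurdan", "DOPC/DPPC", 50, [
        (0.0, 1.23, 0.83, 0.136, 0.06, 0.33, 0.43),
        (15.0, 1.60, 0.90, 0.104, 0.03, 0.34, 0.30),
        (22.2, 1.60, 0.91, 0.104, 0.03, 0.34, 0.30),
        (33.3, 1.34, 0.84, 0.124, 0.05, 0.34, 0.38),
        (40.0, 1.40, 0.81, 0.119, 0.07, 0.35, 0.45),
    ])
)


def consistent_rows() -> list:
    """Rows whose printed derived values reproduce at printed precision."""
    return [r for r in REFERENCE_ROWS if r.is_consistent()]


def row(probe: str, lipid: str, temperature_C: float,
        cholesterol_mol_pct: float) -> ReferenceRow:
    for r in REFERENCE_ROWS:
        if (r.probe == probe and r.lipid == lipid
                and r.temperature_C == temperature_C
                and r.cholesterol_mol_pct == cholesterol_mol_pct):
            return r
    raise KeyError((probe, lipid, temperature_C, cholesterol_mol_pct))
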