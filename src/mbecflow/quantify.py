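"""Bench-side quantification: OD420 standard curve, CFU arithmetic, dye mass.

UV-killed *E. coli* are normally quantified by OD600, a wavelength methylene
blue absorbs; quantification of the labeled bacteria therefore uses a 420 nm
standard curve (CFU/mL vs OD420).  Dye bound to the bacteria is inferred from
the fall in dye concentration across the labeling/washing supernatants using
mass = concentration x volume, with the pharmaceutical %w/v convention
(1% = 10 g/L).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ODStandardCurve",
    "LabelLedger",
    "fit_od_curve",
    "cfu_from_dilution",
    "mb_bound_mass",
    "solution_mass_g",
    "orders_of_magnitude",
    "compute_moi",
    "PCT_WV_G_PER_UL",
]

#: 1% w/v = 1 g / 100 mL = 1e-5 g per microliter.
PCT_WV_G_PER_UL = 1e-5


@dataclass(frozen=True)
class ODStandardCurve:
    """Linear CFU/mL vs OD420 calibration with its fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    od_range: tuple[float, float]

    def cfu_from_od(self, od: float) -> float:
        if not self.od_range[0] <= od <= self.od_range[1]:
            warnings.warn(
                f"OD {od:g} outside the calibrated range {self.od_range}; extrapolating",
                stacklevel=2)
        return self.slope * od + self.intercept

    def od_from_cfu(self, cfu_per_ml: float) -> float:
        return (cfu_per_ml - self.intercept) / self.slope


def fit_od_curve(od_values, cfu_values) -> ODStandardCurve:
    """Ordinary least-squares line CFU/mL = slope * OD420 + intercept."""
    od = np.asarray(od_values, dtype=float)
    cfu = np.asarray(cfu_values, dtype=float)
    if od.shape != cfu.shape or od.ndim != 1:
        raise ValueError("od_values and cfu_values must be 1-D and paired")
    if od.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(od) == 0:
        raise ValueError("OD values must vary")
    res = stats.linregress(od, cfu)
    if res.slope <= 0:
        raise ValueError("calibration slope must be positive (more bacteria, more OD)")
    return ODStandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2), n_points=int(od.size),
                           od_range=(float(od.min()), float(od.max())))


def cfu_from_dilution(colonies: int, dilution_factor: float, plated_volume_ml: float) -> float:
    """Colony count x dilution factor / plated volume -> CFU/mL."""
    if colonies < 0:
        raise ValueError("colony count must be nonnegative")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    return colonies * dilution_factor / plated_volume_ml


def solution_mass_g(concentration_pct_wv: float, volume_ul: float) -> float:
    """Dye mass (g) in a solution: mass = concentration x volume."""
    if concentration_pct_wv < 0 or volume_ul < 0:
        raise ValueError("concentration and volume must be nonnegative")
    return concentration_pct_wv * PCT_WV_G_PER_UL * volume_ul


@dataclass(frozen=True)
class LabelLedger:
    """Input labeling solution and the ordered post-labeling supernatants."""

    label_concentration_pct: float
    label_volume_ul: float
    residuals: tuple[tuple[float, float], ...] = ()  # (pct w/v, uL) per wash

    def __post_init__(self) -> None:
        if self.label_concentration_pct < 0 or self.label_volume_ul < 0:
            raise ValueError("ledger concentrations/volumes must be nonnegative")
        for pct, vol in self.residuals:
            if pct < 0 or vol < 0:
                raise ValueError("residual concentrations/volumes must be nonnegative")


def mb_bound_mass(ledger: LabelLedger) -> float:
    """Dye mass (g) bound to the bacteria: input minus all residual masses.

    A negative balance means the ledger is inconsistent (more dye recovered
    than was added) and raises rather than silently clipping.
    """
    input_mass = solution_mass_g(ledger.label_concentration_pct, ledger.label_volume_ul)
    residual = sum(solution_mass_g(p, v) for p, v in ledger.residuals)
    bound = input_mass - residual
    if bound < 0:
        raise ValueError(
            f"residual mass {residual:.3e} g exceeds input {input_mass:.3e} g: "
            "inconsistent ledger")
    return bound


def orders_of_magnitude(a: float, b: float) -> int:
    """round(log10(a / b)): how many decades a sits above b (negative if below)."""
    if a <= 0 or b <= 0:
        raise ValueError("orders_of_magnitude needs positive inputs")
    return int(round(math.log10(a / b)))


def compute_moi(bacteria: float, cells: float) -> float:
    """Multiplicity of infection: bacteria per cell."""
    if cells <= 0:
        raise ValueError("cell count must be positive")
    if bacteria < 0:
        raise ValueError("bacteria count must be nonnegative")
    return bacteria / cells
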