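"""Derived metabolic quantities from gas exchange.

Substrate oxidation uses protein-free Frayn stoichiometry (no urinary
nitrogen is assumed available): with gas volumes in L·min⁻¹,

    fat  [g·min⁻¹] = 1.67·(VO2 − VCO2)
    cho  [g·min⁻¹] = 4.55·VCO2 − 3.21·VO2

energy densities 9.0 kcal/g fat and 4.0 kcal/g carbohydrate.  Resting
metabolic rate uses the Weir equation on mean resting gas exchange,
RMR [kcal·day⁻¹] = (3.941·VO2 + 1.106·VCO2)·1.44 with gases in mL·min⁻¹.
Constants are exposed so alternative stoichiometries can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .io import BreathSeries

# Frayn (protein-free) coefficients, gas volumes in L/min
FAT_COEF = (1.67, -1.67)     # · (VO2, VCO2)
CHO_COEF = (-3.21, 4.55)
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_CHO = 4.0
# Weir coefficients, gas volumes in mL/min, factor 1.44 converts kcal/min·1000 to kcal/day
WEIR_O2 = 3.941
WEIR_CO2 = 1.106
WEIR_DAY = 1.44

RQ_PHYSIOLOGICAL = (0.6, 1.3)
O2_PER_MET = 3.5  # mL O2 · kg⁻¹ · min⁻¹ per metabolic equivalent


@dataclass
class SubstrateResult:
    """Fat/carbohydrate oxidation rates and their energy shares."""

    fat_g_min: float
    cho_g_min: float
    fat_kcal_day: float
    cho_kcal_day: float
    fat_pct: float
    cho_pct: float
    rq: float
    clamped: bool = False            # a negative oxidation rate was floored at 0
    nonphysiological_rq: bool = False


@dataclass
class RmrResult:
    """Resting metabolic rate with its substrate breakdown."""

    rmr_kcal_day: float
    rq: float
    substrate: SubstrateResult
    window_s: tuple[float, float]    # [start, end) of the analysed segment
    n_breaths: int


def substrate_oxidation(vo2: float, vco2: float) -> SubstrateResult:
    """Substrate panel from a single (VO2, VCO2) pair in mL·min⁻¹.

    RQ > 1 (exercise-range bicarbonate buffering) yields 100% carbohydrate
    with the clamp flag set, so percentages always stay inside [0, 100].
    """
    if vo2 <= 0 or vco2 <= 0:
        raise DataError("substrate_oxidation requires positive VO2 and VCO2")
    rq = vco2 / vo2
    v_o2, v_co2 = vo2 / 1000.0, vco2 / 1000.0
    fat = FAT_COEF[0] * v_o2 + FAT_COEF[1] * v_co2
    cho = CHO_COEF[0] * v_o2 + CHO_COEF[1] * v_co2
    clamped = fat < 0 or cho < 0
    fat, cho = max(fat, 0.0), max(cho, 0.0)
    fat_kcal = fat * KCAL_PER_G_FAT * 1440.0
    cho_kcal = cho * KCAL_PER_G_CHO * 1440.0
    total = fat_kcal + cho_kcal
    if total <= 0:
        fat_pct = cho_pct = 0.0
    else:
        fat_pct = 100.0 * fat_kcal / total
        cho_pct = 100.0 - fat_pct
    return SubstrateResult(
        fat_g_min=fat, cho_g_min=cho,
        fat_kcal_day=fat_kcal, cho_kcal_day=cho_kcal,
        fat_pct=fat_pct, cho_pct=cho_pct, rq=rq, clamped=clamped,
        nonphysiological_rq=not (RQ_PHYSIOLOGICAL[0] <= rq <= RQ_PHYSIOLOGICAL[1]),
    )


def weir_kcal_day(vo2: float, vco2: float) -> float:
    """Weir energy expenditure, gases in mL·min⁻¹."""
    return (WEIR_O2 * vo2 + WEIR_CO2 * vco2) * WEIR_DAY


def rmr_from_rest(
    series: BreathSeries, discard: float = 300.0, total: float = 2400.0
) -> RmrResult:
    """Resting metabolic rate from a supine recording.

    The first ``discard`` seconds (acclimatization) are dropped and Weir is
    applied to the mean VO2/VCO2 of the remaining segment (35 min of a 40-min
    recording at the defaults).  Substrate kcal/day are the Weir total split
    by the Frayn energy shares, so fat + cho always reproduces the RMR.
    """
    t = series.df["t"].to_numpy(float)
    if len(t) == 0 or t[-1] - t[0] < discard:
        raise DataError("rest recording shorter than the acclimatization discard window")
    start = t[0] + discard
    end = min(t[0] + total, t[-1] + np.finfo(float).eps)
    mask = (t >= start) & (t <= end)
    seg = series.df[mask]
    if seg.empty:
        raise DataError("no breaths in the retained rest window")
    vo2 = float(seg["vo2"].mean())
    vco2 = float(seg["vco2"].mean())
    rmr = weir_kcal_day(vo2, vco2)
    sub = substrate_oxidation(vo2, vco2)
    sub = replace(
        sub,
        fat_kcal_day=rmr * sub.fat_pct / 100.0,
        cho_kcal_day=rmr * sub.cho_pct / 100.0,
    )
    return RmrResult(
        rmr_kcal_day=rmr, rq=vco2 / vo2, substrate=sub,
        window_s=(start, end), n_breaths=len(seg),
    )


def mets(vo2_rel: float) -> float:
    """Metabolic equivalents from relative VO2 (mL·kg⁻¹·min⁻¹)."""
    if vo2_rel < 0:
        raise DataError("relative VO2 must be non-negative")
    return vo2_rel / O2_PER_MET


def oue(ve_vo2: float) -> float:
    """Oxygen uptake efficiency (mL O2 per L ventilation) = 1000 / (VE/VO2)."""
    if ve_vo2 <= 0:
        raise DataError("VE/VO2 must be positive")
    return 1000.0 / ve_vo2
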