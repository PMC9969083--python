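"""Detection of CPET events: COP, ventilatory thresholds, VO2max, and the
variable panel extracted at each event.

The cardiorespiratory optimal point (COP) is the minimum per-minute VE/VO2
over complete exercise minutes.  VT1 is located by the V-slope method — an
exhaustive two-segment least-squares fit of VCO2 against VO2 — and VT2 by
the same fit of VE against VCO2, each confirmed against the behaviour of the
ventilatory equivalents around the estimate.  VO2max is the highest rolling
30-s mean of VO2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import DataError, DetectionError
from .metabolic import mets as _mets, substrate_oxidation
from .prep import MinuteSeries, WindowedSeries

#: minimum relative SSE improvement for declaring a slope break
IMPROVEMENT_THRESHOLD = 0.05
MIN_SEG = 5

COP_LOW_MAX = 22.0     # VE/VO2 below this: "low"
COP_HIGH_MIN = 30.0    # above this: "high"


# --------------------------------------------------------------------------
# two-segment regression

@dataclass
class SegmentFit:
    """Result of an exhaustive two-segment least-squares fit."""

    breakpoint_index: int                    # first index of the right segment
    left_coef: tuple[float, float]           # (slope, intercept)
    right_coef: tuple[float, float]
    intersection: Optional[tuple[float, float]]
    sse_two: float
    sse_one: float
    improvement: float                       # 1 − SSE2/SSE1
    has_breakpoint: bool
    parallel: bool = False


def _line_sse(x: np.ndarray, y: np.ndarray,
              w: np.ndarray | None = None) -> tuple[float, float, float]:
    """(Weighted) least-squares line through (x, y); slope, intercept, SSE."""
    if w is None:
        w = np.ones_like(x)
    wsum = float(w.sum())
    xm = float((w * x).sum()) / wsum
    ym = float((w * y).sum()) / wsum
    sxx = float((w * (x - xm) ** 2).sum())
    if sxx == 0.0:
        return 0.0, ym, float((w * (y - ym) ** 2).sum())
    slope = float((w * (x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    return slope, intercept, float((w * resid**2).sum())


def fit_two_segment(x, y, min_seg: int = MIN_SEG,
                    improvement_threshold: float = IMPROVEMENT_THRESHOLD,
                    weights=None) -> SegmentFit:
    """Exhaustive two-segment fit of y on strictly increasing x.

    Every admissible split (each side keeping ``min_seg`` points) gets two
    independent least-squares lines; the split minimising pooled SSE wins,
    earliest on ties.  The threshold location is the intersection of the two
    lines.  A fit whose SSE improvement over a single line falls below
    ``improvement_threshold`` carries ``has_breakpoint=False``.

    Optional ``weights`` switch the objective to weighted SSE (the detectors
    pass 1/y² under multiplicative measurement noise); the default is the
    plain unweighted criterion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    n = len(x)
    if n != len(y):
        raise DataError("x and y lengths differ")
    if n < 2 * min_seg:
        raise DataError(f"need at least {2*min_seg} points for a two-segment fit")
    if not np.all(np.diff(x) > 0):
        raise DataError("x must be strictly increasing")

    _, _, sse_one = _line_sse(x, y, w)

    best = None
    best_sse = np.inf
    for k in range(min_seg, n - min_seg + 1):
        wl = None if w is None else w[:k]
        wr = None if w is None else w[k:]
        ls, li, lsse = _line_sse(x[:k], y[:k], wl)
        rs, ri, rsse = _line_sse(x[k:], y[k:], wr)
        sse = lsse + rsse
        # strict improvement beyond relative tie tolerance keeps the earliest split
        if best is None or sse < best_sse - 1e-12 * max(1.0, best_sse):
            best_sse = sse
            best = (k, (ls, li), (rs, ri))

    k, (ls, li), (rs, ri) = best
    parallel = abs(ls - rs) < 1e-12 * max(1.0, abs(ls), abs(rs))
    if parallel:
        intersection = None
    else:
        xi = (ri - li) / (ls - rs)
        intersection = (xi, ls * xi + li)
    improvement = 0.0 if sse_one <= 0 else max(0.0, 1.0 - best_sse / sse_one)
    has_bp = (not parallel) and improvement >= improvement_threshold
    return SegmentFit(
        breakpoint_index=k, left_coef=(ls, li), right_coef=(rs, ri),
        intersection=intersection, sse_two=best_sse, sse_one=sse_one,
        improvement=improvement, has_breakpoint=has_bp, parallel=parallel,
    )


# --------------------------------------------------------------------------
# result containers

@dataclass
class ThresholdEstimate:
    vo2_at_threshold: float      # mL/min
    time: float                  # s
    percent_of_vo2max: float
    method: str                  # "v-slope" | "ve-vs-vco2"
    confirmed: bool
    fit: SegmentFit


@dataclass
class VO2maxResult:
    vo2max_abs: float            # mL/min
    vo2max_rel: float            # mL/kg/min
    time: float                  # s, end of the best rolling block
    rer_at_max: float
    percent_of_predicted: Optional[float] = None


@dataclass
class CopResult:
    cop: float                   # VE/VO2, dimensionless
    minute: int
    time: float                  # s (minute centre)
    category: str
    vo2_at_cop: float
    before_vt1: Optional[bool] = None
    panel: Optional[dict] = None


# --------------------------------------------------------------------------
# detectors

def detect_vo2max(
    windowed: WindowedSeries, mass: float,
    predicted: Optional[float] = None, rolling_s: float = 30.0,
) -> VO2maxResult:
    """VO2max as the highest rolling 30-s mean of windowed VO2."""
    df = windowed.complete()
    k = int(round(rolling_s / windowed.width))
    if len(df) < k:
        raise DataError("series shorter than the rolling VO2max window")
    vo2 = df["vo2"].to_numpy(float)
    roll = np.convolve(vo2, np.ones(k) / k, mode="valid")
    i = int(np.argmax(roll))
    vo2max_abs = float(roll[i])
    t_end = float(df["window_start"].iloc[i + k - 1]) + windowed.width
    rer = float(df["rer"].iloc[i : i + k].mean())
    rel = vo2max_abs / mass
    pct_pred = None if predicted is None else 100.0 * rel / predicted
    return VO2maxResult(
        vo2max_abs=vo2max_abs, vo2max_rel=rel, time=t_end,
        rer_at_max=rer, percent_of_predicted=pct_pred,
    )


def _smoothed(df, smooth: int):
    """Centred rolling mean over consecutive windows; tempers breath noise
    before the segmented fits while barely rounding a slope break."""
    if smooth <= 1:
        return df
    out = df.copy()
    cols = [c for c in ("vo2", "vco2", "ve") if c in df.columns]
    out[cols] = df[cols].rolling(smooth, center=True, min_periods=1).mean()
    return out


def _ordered_xy(df, xcol: str, ycol: str):
    """Sort windows by x and collapse duplicate x (mean y, mean time)."""
    x = df[xcol].to_numpy(float)
    y = df[ycol].to_numpy(float)
    t = df["t"].to_numpy(float)
    order = np.argsort(x, kind="stable")
    x, y, t = x[order], y[order], t[order]
    ux, inv = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        ut = np.bincount(inv, weights=t) / np.bincount(inv)
        return ux, uy, ut
    return x, y, t


def _local_slope(df, col: str, t0: float, t1: float) -> Optional[float]:
    sel = df[(df["t"] >= t0) & (df["t"] <= t1)]
    if len(sel) < 3:
        return None
    res = sps.linregress(sel["t"], sel[col])
    return float(res.slope)


def _time_at(df, xcol: str, x_star: float) -> float:
    """Time at which the (monotonized) channel reaches the fitted threshold.

    The channel rises along the ramp apart from measurement noise, so its
    running maximum in time order is an invertible proxy; interpolating on
    it is far less jittery than picking the nearest noisy window."""
    x = np.maximum.accumulate(df[xcol].to_numpy(float))
    t = df["t"].to_numpy(float)
    return float(np.interp(x_star, x, t))


def detect_vt1(
    windowed: WindowedSeries, vo2max: VO2maxResult,
    vo2_ceiling: Optional[float] = None,
    min_seg: int = MIN_SEG, improvement_threshold: float = IMPROVEMENT_THRESHOLD,
    slope_eps_per_window: float = 0.01, smooth: int = 5,
) -> ThresholdEstimate:
    """First ventilatory threshold by the V-slope break of VCO2 vs VO2.

    ``vo2_ceiling`` restricts the fit to data below an already-located VT2 so
    the respiratory-compensation break cannot dominate.  Confirmation checks
    the classic equivalents criterion in the 30 s after the estimate: VE/VO2
    rising while VE/VCO2 stays flat or falling.
    """
    df = windowed.complete()
    fit_df = _smoothed(df, smooth)
    if vo2_ceiling is not None:
        fit_df = fit_df[fit_df["vo2"] <= vo2_ceiling]
    x, y, _ = _ordered_xy(fit_df, "vo2", "vco2")
    fit = fit_two_segment(x, y, min_seg=min_seg,
                          improvement_threshold=improvement_threshold)
    if not fit.has_breakpoint:
        raise DetectionError("no V-slope breakpoint found for VT1")
    vo2_star = float(fit.intersection[0])
    if not (x[0] <= vo2_star <= x[-1]):
        vo2_star = float(x[min(fit.breakpoint_index, len(x) - 1)])
    t_star = _time_at(fit_df, "vo2", vo2_star)
    post_eqo2 = _local_slope(df, "ve_vo2", t_star, t_star + 30.0)
    post_eqco2 = _local_slope(df, "ve_vco2", t_star, t_star + 30.0)
    eps = slope_eps_per_window / windowed.width  # units/window -> units/s
    confirmed = (
        post_eqo2 is not None and post_eqco2 is not None
        and post_eqo2 > 0 and post_eqco2 <= eps
    )
    return ThresholdEstimate(
        vo2_at_threshold=vo2_star, time=t_star,
        percent_of_vo2max=100.0 * vo2_star / vo2max.vo2max_abs,
        method="v-slope", confirmed=confirmed, fit=fit,
    )


def detect_vt2(
    windowed: WindowedSeries, vo2max: VO2maxResult,
    vt1: Optional[ThresholdEstimate] = None,
    vo2_floor: Optional[float] = None,
    min_seg: int = MIN_SEG, improvement_threshold: float = IMPROVEMENT_THRESHOLD,
    smooth: int = 5,
) -> ThresholdEstimate:
    """Second ventilatory threshold (respiratory compensation point) by the
    slope break of VE vs VCO2; confirmed when both ventilatory equivalents
    rise after the estimate.  Flags an ordering violation if VT2 ≤ VT1.

    ``vo2_floor`` restricts the fit to data above an already-located VT1,
    keeping the curved sub-threshold part of the VE-VCO2 relation (where the
    ventilatory equivalent is still falling toward its optimum) out of the
    respiratory-compensation fit.  The segmented fit is weighted by 1/VE²
    because breath noise is multiplicative: without the weighting the few
    largest (and noisiest) end-of-test windows dominate the pooled SSE and
    can pull the split onto a short noise-chasing end segment."""
    df = windowed.complete()
    fit_df = _smoothed(df, smooth)
    if vo2_floor is not None:
        restricted = fit_df[fit_df["vo2"] >= vo2_floor]
        if len(restricted) >= 2 * min_seg:
            fit_df = restricted
    x, y, _ = _ordered_xy(fit_df, "vco2", "ve")
    fit = fit_two_segment(x, y, min_seg=min_seg,
                          improvement_threshold=improvement_threshold,
                          weights=1.0 / y**2)
    if not fit.has_breakpoint:
        raise DetectionError("no VE-vs-VCO2 breakpoint found for VT2")
    vco2_star = float(fit.intersection[0])
    # an intersection extrapolated outside the observed range is meaningless;
    # fall back to the data value at the split
    if not (x[0] <= vco2_star <= x[-1]):
        vco2_star = float(x[min(fit.breakpoint_index, len(x) - 1)])
    # map the VCO2 breakpoint back to VO2 by interpolation along the series
    xs, vo2s, _ = _ordered_xy(fit_df, "vco2", "vo2")
    vo2_star = float(np.interp(vco2_star, xs, vo2s))
    t_star = _time_at(fit_df, "vco2", vco2_star)
    post_eqo2 = _local_slope(df, "ve_vo2", t_star, t_star + 30.0)
    post_eqco2 = _local_slope(df, "ve_vco2", t_star, t_star + 30.0)
    confirmed = (
        post_eqo2 is not None and post_eqco2 is not None
        and post_eqo2 > 0 and post_eqco2 > 0
    )
    est = ThresholdEstimate(
        vo2_at_threshold=vo2_star, time=t_star,
        percent_of_vo2max=100.0 * vo2_star / vo2max.vo2max_abs,
        method="ve-vs-vco2", confirmed=confirmed, fit=fit,
    )
    if vt1 is not None and vo2_star <= vt1.vo2_at_threshold:
        raise DetectionError(
            f"VT2 ({vo2_star:.0f} mL/min) does not exceed VT1 "
            f"({vt1.vo2_at_threshold:.0f} mL/min)"
        )
    return est


def classify_cop(cop: float) -> str:
    """COP category: low (<22), moderate (22–30, inclusive), high (>30)."""
    if cop <= 0:
        raise DataError("COP must be positive")
    if cop < COP_LOW_MAX:
        return "low"
    if cop <= COP_HIGH_MIN:
        return "moderate"
    return "high"


def detect_cop(minutes: MinuteSeries,
               vt1: Optional[ThresholdEstimate] = None) -> CopResult:
    """COP = minimum minute-mean VE/VO2 over complete exercise minutes
    (earliest minute on exact ties)."""
    df = minutes.complete()
    if df.empty:
        raise DetectionError("no complete exercise minutes for COP detection")
    vals = df["ve_vo2"].to_numpy(float)
    i = int(np.argmin(vals))          # argmin returns the first minimum
    cop = float(vals[i])
    t = float(df["t"].iloc[i])
    before = None if vt1 is None else bool(t < vt1.time)
    return CopResult(
        cop=cop, minute=int(df["minute"].iloc[i]), time=t,
        category=classify_cop(cop), vo2_at_cop=float(df["vo2"].iloc[i]),
        before_vt1=before,
    )


# --------------------------------------------------------------------------
# event panel

PANEL_FIELDS = [
    "rf", "vt_tidal", "ve", "iv", "vo2", "vco2", "rer", "ve_vo2", "ve_vco2",
    "mets", "hr", "vo2_hr", "peto2", "petco2", "fat_pct", "cho_pct",
    "ti", "te", "ttot", "ti_ttot", "vd_vt", "vt_ti", "hrr", "sv",
    "power", "t_pct",
]


def extract_panel(
    windowed: WindowedSeries, t_event: float,
    mass: float, age: float, test_duration: float,
    hr_max_pred: Optional[float] = None,
) -> dict:
    """Variable panel at the window containing ``t_event``.

    Derived entries: METs from relative VO2; FAT%/CHO% from Frayn substrate
    shares; oxygen pulse VO2/HR; ventilatory drive VT/Ti; heart-rate reserve
    against ``hr_max_pred`` (default 220 − age); t% as elapsed exercise time
    over total exercise duration.
    """
    df = windowed.complete()
    starts = df["window_start"].to_numpy(float)
    if t_event < starts[0] or t_event >= starts[-1] + windowed.width:
        raise DataError(f"event time {t_event:.1f}s outside the recorded exercise range")
    row = df.iloc[int(np.searchsorted(starts, t_event, side="right")) - 1]

    if hr_max_pred is None:
        hr_max_pred = 220.0 - age
    sub = substrate_oxidation(float(row["vo2"]), float(row["vco2"]))
    panel: dict = {}
    for ch in ("rf", "vt_tidal", "ve", "iv", "vo2", "vco2", "rer",
               "ve_vo2", "ve_vco2", "hr", "peto2", "petco2", "ti", "te",
               "vd_vt", "sv", "power"):
        panel[ch] = float(row[ch]) if ch in row.index and np.isfinite(row.get(ch, np.nan)) else None
    panel["mets"] = _mets(panel["vo2"] / mass)
    panel["vo2_hr"] = None if not panel.get("hr") else panel["vo2"] / panel["hr"]
    panel["fat_pct"] = sub.fat_pct
    panel["cho_pct"] = sub.cho_pct
    ti, te = panel.get("ti"), panel.get("te")
    panel["ttot"] = None if ti is None or te is None else ti + te
    panel["ti_ttot"] = None if panel["ttot"] in (None, 0) else ti / panel["ttot"]
    panel["vt_ti"] = None if ti in (None, 0) or panel["vt_tidal"] is None else panel["vt_tidal"] / ti
    panel["hrr"] = None if panel.get("hr") is None else hr_max_pred - panel["hr"]
    elapsed = t_event - windowed.anchor_time
    panel["t_pct"] = 100.0 * elapsed / test_duration if test_duration > 0 else None
    panel["t_event"] = float(t_event)
    return panel
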