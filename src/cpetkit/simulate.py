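"""Synthetic breath-by-breath ramp CPET generator with known ground truth.

Each simulated test follows the ramp protocol used for the cohort analyses
(5 min rest, 5 min warm-up at 25 W, ramp from 50 W at +25 W/min, 70 rpm) and
is built from noiseless construction rules before multiplicative breath noise
is applied:

* mean VO2 follows first-order kinetics toward ``vo2_baseline + vo2_gain ×
  power`` with time constant ``vo2_tau``;
* the ventilatory equivalent VE/VO2 as a function of VO2 is a convex
  quadratic below VT1 — its minimum is the cardiorespiratory optimal point,
  placed at ``cop_location_frac`` of the VT1 VO2 so the COP always precedes
  VT1 — then rises linearly with one slope to VT2 and a steeper slope beyond;
* VCO2 is piecewise linear in VO2 with a single slope break at VT1 (the
  V-slope signature) under a monotone RER ramp from rest toward the maximal
  value, which also breaks the VE-vs-VCO2 slope at VT2;
* respiratory frequency, heart rate and end-tidal pressures interpolate
  between resting and maximal values along the VO2 trajectory, and breath
  timing is deterministic given Rf(t) with Ti/Ttot = 0.45;
* every measurement channel is multiplied by independent lognormal noise
  with coefficient of variation ``noise_cv`` (mean-one, so window averages
  stay unbiased).

The test ends when the rolling 30-s mean VO2 reaches the profile's VO2max.
Ground truth records the noiseless event values and times.

Cohort sampling draws athlete parameters from sex-specific truncated normal
distributions (±3 SD) whose means and spreads reproduce the reference
cohort: 9 female / 24 male highly trained endurance athletes with, e.g.,
VO2max 46.2 ± 5.9 (F) vs 56.1 ± 7.6 (M) mL·kg⁻¹·min⁻¹ and COP 27.2 ± 3.4 (F)
vs 22.6 ± 3.0 (M).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .io import BreathSeries, SeriesMeta

TI_TTOT = 0.45           # inspiratory fraction of the breath cycle
_GRID_DT = 0.25          # s, integration step for the VO2 kinetics
_MAX_TEST_S = 7200.0


@dataclass(frozen=True)
class RampProtocol:
    """Timing and workload of the incremental cycle-ergometer protocol."""

    rest_duration: float = 300.0      # s
    warmup_duration: float = 300.0    # s
    warmup_power: float = 25.0        # W
    start_power: float = 50.0         # W
    increment: float = 25.0           # W per minute, applied continuously
    cadence_target: float = 70.0      # rpm, metadata only

    def __post_init__(self) -> None:
        if self.rest_duration <= 0 or self.warmup_duration <= 0:
            raise DataError("protocol durations must be positive")
        if not (self.start_power > self.warmup_power >= 0):
            raise DataError("start power must exceed warm-up power (≥ 0)")
        if self.increment <= 0:
            raise DataError("ramp increment must be positive")

    @property
    def ramp_onset(self) -> float:
        return self.rest_duration + self.warmup_duration


DEFAULT_PROTOCOL = RampProtocol()


def power_at(t, protocol: RampProtocol = DEFAULT_PROTOCOL):
    """Ergometer workload (W) at time ``t`` seconds from recording start.

    Zero during rest, the warm-up wattage during warm-up, then the ramp
    start power plus the continuous per-minute increment.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DataError("negative time has no workload")
    ramp0 = protocol.ramp_onset
    out = np.where(
        t_arr < protocol.rest_duration,
        0.0,
        np.where(
            t_arr < ramp0,
            protocol.warmup_power,
            protocol.start_power + protocol.increment * (t_arr - ramp0) / 60.0,
        ),
    )
    return float(out) if np.isscalar(t) else out


# --------------------------------------------------------------------------
# athlete profiles

@dataclass
class AthleteProfile:
    """Generator-side physiology of one athlete.

    The fractions place the ventilatory thresholds on the VO2max scale and
    the COP strictly before VT1; the equivalent-curve parameters shape the
    VE/VO2 profile whose minimum is the COP.
    """

    sex: str                       # "female" | "male"
    age: float                     # years
    mass: float                    # kg
    height: float                  # cm
    vo2max_rel: float              # mL/kg/min
    vo2_baseline: float            # mL/min at rest (0 W intercept)
    vo2_gain: float                # mL/min per W
    vo2_tau: float                 # s
    vt1_frac: float                # VT1 VO2 as fraction of VO2max
    vt2_frac: float
    cop_value: float               # VE/VO2 at the optimum
    cop_location_frac: float       # COP VO2 as fraction of VT1 VO2
    eq_start: float                # VE/VO2 at ramp-onset steady state
    eq_slope_post_vt1: float       # VE/VO2 units per L/min VO2
    eq_slope_post_vt2: float
    rer_rest: float
    rer_max: float
    hr_rest: float                 # bpm
    hr_max: float
    rf_rest: float                 # breaths/min
    rf_max: float
    noise_cv: float = 0.05
    athlete_id: str = "A00"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (0 < self.vt1_frac < self.vt2_frac < 1, "need 0 < vt1_frac < vt2_frac < 1"),
            (self.vt2_frac - self.vt1_frac >= 0.08,
             "thresholds closer than 8% of VO2max are not resolvable events"),
            (0 < self.cop_location_frac < 1, "cop_location_frac must lie in (0, 1)"),
            (self.cop_value < self.eq_start, "COP must undercut the onset equivalent"),
            (self.rer_rest < 1 <= self.rer_max, "need rer_rest < 1 ≤ rer_max"),
            (self.hr_rest < self.hr_max, "need hr_rest < hr_max"),
            (self.rf_rest < self.rf_max, "need rf_rest < rf_max"),
            (self.mass > 0 and self.vo2max_rel > 0, "mass and VO2max must be positive"),
            (self.vo2_baseline > 0 and self.vo2_gain > 0, "VO2 kinetics must be positive"),
            (self.vo2_tau > 0, "kinetics time constant must be positive"),
            (self.noise_cv >= 0, "noise CV must be non-negative"),
            (self.eq_slope_post_vt1 > 0 and self.eq_slope_post_vt2 > self.eq_slope_post_vt1,
             "post-VT2 equivalent slope must exceed the post-VT1 slope"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DataError(f"invalid athlete profile: {msg}")

    @property
    def vo2max_abs(self) -> float:
        return self.vo2max_rel * self.mass


@dataclass
class GroundTruth:
    """Noiseless event values encoded by a simulated test."""

    cop_true: float                # VE/VO2
    cop_time: float                # s
    vt1_vo2: float                 # mL/min
    vt2_vo2: float
    vo2max_abs: float
    event_times: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# sex-specific (mean, SD) parameter distributions reproducing the reference
# cohort tables; resting/kinetic constants not reported there use standard
# exercise-physiology values (see docs/methods.md)
COHORT_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "female": {
        "age": (17.44, 3.13), "mass": (56.62, 7.14), "height": (160.0, 5.59),
        "vo2max_rel": (46.17, 5.87),
        "vt1_frac": (0.6533, 0.0899), "vt2_frac": (0.8144, 0.0897),
        "cop_value": (27.24, 3.36),
        "rer_max": (1.161, 0.10),
        "hr_max": (186.9, 5.47), "rf_max": (52.46, 9.86),
        "vo2_baseline": (263.0, 55.9),
        "eq_slope_post_vt1": (7.0, 1.5), "eq_slope_post_vt2": (13.5, 2.0),
    },
    "male": {
        "age": (19.71, 4.01), "mass": (69.92, 12.88), "height": (175.4, 9.04),
        "vo2max_rel": (56.05, 7.57),
        "vt1_frac": (0.68, 0.0918), "vt2_frac": (0.8425, 0.0984),
        "cop_value": (22.64, 2.95),
        "rer_max": (1.185, 0.08),
        "hr_max": (189.5, 9.62), "rf_max": (51.18, 7.63),
        "vo2_baseline": (336.0, 51.9),
        "eq_slope_post_vt1": (5.0, 1.2), "eq_slope_post_vt2": (14.0, 2.0),
    },
}

# shared (mean, SD) distributions
_SHARED = {
    "rer_rest": (0.82, 0.03),
    "hr_rest": (60.0, 8.0),
    "rf_rest": (12.0, 2.0),
    "vo2_gain": (10.1, 0.8),
    "vo2_tau": (25.0, 5.0),
    "cop_location_frac": (0.85, 0.05),
    "eq_start_offset": (5.5, 1.0),   # eq_start = cop_value + offset
}

# hard physiological bounds applied on top of the ±3 SD truncation
_BOUNDS = {
    "age": (12.0, 60.0), "mass": (35.0, 130.0), "height": (140.0, 210.0),
    "vo2max_rel": (25.0, 90.0),
    "vt1_frac": (0.45, 0.85), "vt2_frac": (0.62, 0.97),
    "cop_value": (15.0, 40.0),
    "rer_rest": (0.70, 0.95), "rer_max": (1.0, 1.45),
    "hr_rest": (40.0, 90.0), "hr_max": (160.0, 215.0),
    "rf_rest": (8.0, 20.0), "rf_max": (35.0, 75.0),
    "vo2_baseline": (150.0, 550.0), "vo2_gain": (8.0, 12.5),
    "vo2_tau": (12.0, 45.0),
    # upper bound keeps the VE/VO2 minimum at least ~1 ramp-minute below the
    # VT1 break: the COP is defined on a one-minute grid, so a minimum closer
    # than that is not a distinct event
    "cop_location_frac": (0.60, 0.90),
    "eq_start_offset": (2.0, 9.0),
    "eq_slope_post_vt1": (2.0, 11.0), "eq_slope_post_vt2": (8.0, 22.0),
}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  key: str) -> float:
    lo, hi = _BOUNDS.get(key, (-np.inf, np.inf))
    lo = max(lo, mean - 3 * sd)
    hi = min(hi, mean + 3 * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_profile(sex: str, rng: np.random.Generator,
                   noise_cv: float = 0.05, athlete_id: str = "A00") -> AthleteProfile:
    """Draw one athlete from the sex-specific parameter distributions,
    resampling until every profile invariant holds."""
    dists = COHORT_DISTRIBUTIONS[sex]
    for _ in range(200):
        draw = {k: _trunc_normal(rng, m, s, k) for k, (m, s) in dists.items()}
        # thresholds are strongly correlated within an athlete; redraw VT2
        # conditionally on VT1 (bivariate normal, ρ = 0.8) so the marginal
        # spreads stay at the cohort values while the VT1-VT2 gap stays
        # physiological
        rho = 0.8
        (m1, s1), (m2, s2) = dists["vt1_frac"], dists["vt2_frac"]
        z1 = (draw["vt1_frac"] - m1) / s1
        cond_mean = m2 + rho * s2 * z1
        cond_sd = s2 * np.sqrt(1 - rho**2)
        draw["vt2_frac"] = _trunc_normal(rng, cond_mean, cond_sd, "vt2_frac")
        shared = {k: _trunc_normal(rng, m, s, k) for k, (m, s) in _SHARED.items()}
        eq_start = draw["cop_value"] + shared.pop("eq_start_offset")
        try:
            profile = AthleteProfile(
                sex=sex, noise_cv=noise_cv, athlete_id=athlete_id,
                eq_start=eq_start, **draw, **shared,
            )
            _derive_truth(profile, DEFAULT_PROTOCOL)  # rejects kinetically degenerate draws
            return profile
        except DataError:
            continue
    raise DataError(f"could not sample a valid {sex} profile")


def sample_cohort(n_female: int, n_male: int, seed: int,
                  noise_cv: float = 0.05) -> list[AthleteProfile]:
    """Reproducible cohort draw: ``n_female`` athletes then ``n_male``."""
    if n_female < 0 or n_male < 0:
        raise DataError("cohort counts must be non-negative")
    rng = np.random.default_rng(seed)
    cohort = [
        sample_profile("female", rng, noise_cv, athlete_id=f"F{i+1:02d}")
        for i in range(n_female)
    ]
    cohort += [
        sample_profile("male", rng, noise_cv, athlete_id=f"M{i+1:02d}")
        for i in range(n_male)
    ]
    return cohort


# --------------------------------------------------------------------------
# noiseless construction rules

def _curve_params(profile: AthleteProfile, protocol: RampProtocol) -> dict:
    """Anchor points of the noiseless equivalent/VCO2 curves in VO2 space."""
    vo2max = profile.vo2max_abs
    vt1 = profile.vt1_frac * vo2max
    vt2 = profile.vt2_frac * vo2max
    cop_vo2 = profile.cop_location_frac * vt1
    v_onset = profile.vo2_baseline + profile.vo2_gain * protocol.start_power
    if v_onset >= cop_vo2:
        raise DataError(
            "degenerate profile: ramp-onset VO2 reaches the COP location "
            f"({v_onset:.0f} ≥ {cop_vo2:.0f} mL/min)"
        )
    quad_a = (profile.eq_start - profile.cop_value) / (v_onset - cop_vo2) ** 2
    e_vt1 = profile.cop_value + quad_a * (vt1 - cop_vo2) ** 2
    # the equivalent curve must accelerate at VT1: quadratic slope there may
    # not exceed the post-VT1 linear rise, else the construction would put a
    # downward kink where physiology puts an upward one
    if 2.0 * quad_a * (vt1 - cop_vo2) * 1000.0 > profile.eq_slope_post_vt1:
        raise DataError(
            "degenerate profile: equivalent-curve slope would decrease at VT1"
        )
    # RER waypoint at VT1 positioned inside the rest→max rise so the V-slope
    # break is upward (slope above VT1 exceeds slope below)
    rer_vt1 = profile.rer_rest + 0.28 * (profile.rer_max - profile.rer_rest)
    c_onset = profile.rer_rest * v_onset
    c_vt1 = rer_vt1 * vt1
    s1 = (c_vt1 - c_onset) / (vt1 - v_onset)
    s2 = (profile.rer_max * vo2max - c_vt1) / (vo2max - vt1)
    if not (s2 > s1 > 0):
        raise DataError("degenerate profile: VCO2-vs-VO2 slopes not increasing at VT1")
    # post-VT2 VCO2 runs linearly in VE-vs-VCO2 space from the VT2 point to
    # (RERmax·VO2max, VE at VO2max): the respiratory-compensation break is a
    # crisp slope change of the VE-VCO2 relation at VT2, as in real tests
    e_vt2 = e_vt1 + profile.eq_slope_post_vt1 * (vt2 - vt1) / 1000.0
    ve_vt2 = e_vt2 * vt2 / 1000.0
    e_max = e_vt2 + profile.eq_slope_post_vt2 * (vo2max - vt2) / 1000.0
    ve_max = e_max * vo2max / 1000.0
    c_vt2 = c_vt1 + s2 * (vt2 - vt1)
    c_max = profile.rer_max * vo2max
    if c_max <= c_vt2:
        raise DataError("degenerate profile: VCO2 at VO2max below its VT2 value")
    g2 = (ve_max - ve_vt2) / (c_max - c_vt2)
    g1_end = (e_vt2 + vt2 * profile.eq_slope_post_vt1 / 1000.0) / 1000.0 / s2
    if g2 < 1.25 * g1_end:
        raise DataError(
            "degenerate profile: VE-vs-VCO2 slope does not rise appreciably at VT2"
        )
    return {
        "vo2max": vo2max, "vt1": vt1, "vt2": vt2, "cop_vo2": cop_vo2,
        "v_onset": v_onset, "quad_a": quad_a, "e_vt1": e_vt1,
        "c_onset": c_onset, "c_vt1": c_vt1, "s1": s1, "s2": s2,
        "e_vt2": e_vt2, "ve_vt2": ve_vt2, "c_vt2": c_vt2, "g2": g2,
    }


def _derive_truth(profile: AthleteProfile,
                  protocol: RampProtocol) -> dict:
    return _curve_params(profile, protocol)


def _equivalent(v: np.ndarray, profile: AthleteProfile, p: dict) -> np.ndarray:
    """Target VE/VO2 as a function of noiseless VO2 (mL/min)."""
    v = np.asarray(v, dtype=float)
    e = profile.cop_value + p["quad_a"] * (v - p["cop_vo2"]) ** 2
    mid = p["e_vt1"] + profile.eq_slope_post_vt1 * (v - p["vt1"]) / 1000.0
    e_vt2 = p["e_vt1"] + profile.eq_slope_post_vt1 * (p["vt2"] - p["vt1"]) / 1000.0
    top = e_vt2 + profile.eq_slope_post_vt2 * (v - p["vt2"]) / 1000.0
    return np.where(v <= p["vt1"], e, np.where(v <= p["vt2"], mid, top))


def _vco2(v: np.ndarray, profile: AthleteProfile, p: dict) -> np.ndarray:
    """Target VCO2 (mL/min): RER·VO2 below ramp onset, piecewise linear in
    VO2 with the V-slope break at VT1, then (beyond VT2) the inverse of the
    straight post-compensation VE-VCO2 segment."""
    v = np.asarray(v, dtype=float)
    below = profile.rer_rest * v
    lower = p["c_onset"] + p["s1"] * (v - p["v_onset"])
    upper = p["c_vt1"] + p["s2"] * (v - p["vt1"])
    ve = _equivalent(v, profile, p) * v / 1000.0
    top = p["c_vt2"] + (ve - p["ve_vt2"]) / p["g2"]
    return np.where(
        v <= p["v_onset"], below,
        np.where(v <= p["vt1"], lower, np.where(v <= p["vt2"], upper, top)),
    )


def _vo2_trajectory(profile: AthleteProfile, protocol: RampProtocol):
    """Integrate the first-order VO2 kinetics on a fine grid and find the
    termination time (rolling 30-s mean reaching VO2max)."""
    vo2max = profile.vo2max_abs
    n_max = int(_MAX_TEST_S / _GRID_DT)
    t = np.arange(n_max) * _GRID_DT
    target = profile.vo2_baseline + profile.vo2_gain * power_at(t, protocol)
    decay = 1.0 - np.exp(-_GRID_DT / profile.vo2_tau)
    v = np.empty(n_max)
    v[0] = profile.vo2_baseline
    k30 = int(round(30.0 / _GRID_DT))
    rolling_sum = v[0]
    end = None
    for i in range(1, n_max):
        v[i] = v[i - 1] + (target[i - 1] - v[i - 1]) * decay
        rolling_sum += v[i]
        if i >= k30:
            rolling_sum -= v[i - k30]
        if i >= k30 - 1 and rolling_sum / k30 >= vo2max:
            end = i
            break
    if end is None:
        raise DataError("VO2 never reached VO2max within the simulation horizon")
    return t[: end + 1], v[: end + 1]


def _interp_state(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear rest→max interpolation along the VO2 trajectory."""
    return np.asarray(lo + (hi - lo) * v, dtype=float)


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, shape) - sigma**2 / 2.0)


def simulate_test(
    profile: AthleteProfile,
    protocol: RampProtocol = DEFAULT_PROTOCOL,
    seed: int = 0,
) -> tuple[BreathSeries, GroundTruth]:
    """Simulate one ramp CPET; returns the noisy breath series and the
    noiseless ground truth."""
    p = _curve_params(profile, protocol)
    t_grid, v_grid = _vo2_trajectory(profile, protocol)
    t_end = float(t_grid[-1])

    def first_crossing(threshold: float) -> float:
        idx = np.flatnonzero(v_grid >= threshold)
        return float(t_grid[idx[0]]) if len(idx) else t_end

    truth = GroundTruth(
        cop_true=profile.cop_value,
        cop_time=first_crossing(p["cop_vo2"]),
        vt1_vo2=p["vt1"], vt2_vo2=p["vt2"], vo2max_abs=p["vo2max"],
        event_times={
            "cop": first_crossing(p["cop_vo2"]),
            "vt1": first_crossing(p["vt1"]),
            "vt2": first_crossing(p["vt2"]),
            "vo2max": t_end,
        },
    )

    # deterministic breath clock from the noiseless Rf(t)
    frac_grid = np.clip(
        (v_grid - profile.vo2_baseline) / (p["vo2max"] - profile.vo2_baseline), 0, 1
    )
    times = []
    t = 0.0
    while t < t_end:
        times.append(t)
        f = float(np.interp(t, t_grid, frac_grid))
        rf = profile.rf_rest + (profile.rf_max - profile.rf_rest) * f
        t += 60.0 / rf
    tb = np.array(times)

    v = np.interp(tb, t_grid, v_grid)
    f = np.interp(tb, t_grid, frac_grid)
    e = _equivalent(v, profile, p)
    ve = e * v / 1000.0
    vco2 = _vco2(v, profile, p)
    rf = _interp_state(f, profile.rf_rest, profile.rf_max)
    hr = _interp_state(f, profile.hr_rest, profile.hr_max)
    vt_tidal = ve / rf
    peto2 = 95.0 - 6.0 * f + 14.0 * f**2
    petco2 = 38.0 + 14.0 * f - 14.0 * f**2
    ti = TI_TTOT * 60.0 / rf
    te = (1.0 - TI_TTOT) * 60.0 / rf

    rng = np.random.default_rng(seed)
    cv = profile.noise_cv
    noisy = {
        name: arr * _lognormal_factors(rng, cv, arr.shape)
        for name, arr in [
            ("vo2", v), ("vco2", vco2), ("ve", ve), ("hr", hr), ("rf", rf),
            ("vt_tidal", vt_tidal), ("peto2", peto2), ("petco2", petco2),
        ]
    }
    df = pd.DataFrame({
        "t": tb,
        "vo2": noisy["vo2"], "vco2": noisy["vco2"], "ve": noisy["ve"],
        "hr": noisy["hr"], "rf": noisy["rf"], "vt_tidal": noisy["vt_tidal"],
        "iv": noisy["vt_tidal"] * 1000.0,
        "peto2": noisy["peto2"], "petco2": noisy["petco2"],
        "ti": ti, "te": te,
        "power": power_at(tb, protocol),
    })
    meta = SeriesMeta(
        athlete_id=profile.athlete_id, sex=profile.sex, age=profile.age,
        mass_kg=profile.mass, height_cm=profile.height,
        rest_onset_s=0.0, warmup_onset_s=protocol.rest_duration,
        ramp_onset_s=protocol.ramp_onset,
    )
    return BreathSeries(df=df, meta=meta), truth


def simulate_rest(
    profile: AthleteProfile, duration: float = 2400.0, seed: int = 0,
) -> BreathSeries:
    """Simulate a supine resting recording: stationary gas exchange around
    the profile's resting values with RER = ``rer_rest``."""
    if duration <= 0:
        raise DataError("rest duration must be positive")
    interval = 60.0 / profile.rf_rest
    tb = np.arange(0.0, duration, interval)
    n = len(tb)
    vo2 = np.full(n, profile.vo2_baseline)
    vco2 = profile.rer_rest * vo2
    ve = 35.0 * vo2 / 1000.0          # resting ventilatory equivalent ~35
    rng = np.random.default_rng(seed)
    cv = profile.noise_cv
    df = pd.DataFrame({
        "t": tb,
        "vo2": vo2 * _lognormal_factors(rng, cv, n),
        "vco2": vco2 * _lognormal_factors(rng, cv, n),
        "ve": ve * _lognormal_factors(rng, cv, n),
        "hr": profile.hr_rest * _lognormal_factors(rng, cv, n),
        "rf": profile.rf_rest * _lognormal_factors(rng, cv, n),
        "vt_tidal": (ve / profile.rf_rest) * _lognormal_factors(rng, cv, n),
        "iv": (ve / profile.rf_rest) * 1000.0 * _lognormal_factors(rng, cv, n),
        "peto2": 95.0 * _lognormal_factors(rng, cv, n),
        "petco2": 38.0 * _lognormal_factors(rng, cv, n),
        "ti": np.full(n, TI_TTOT * interval),
        "te": np.full(n, (1.0 - TI_TTOT) * interval),
        "power": np.zeros(n),
    })
    meta = SeriesMeta(
        athlete_id=profile.athlete_id, sex=profile.sex, age=profile.age,
        mass_kg=profile.mass, height_cm=profile.height,
    )
    return BreathSeries(df=df, meta=meta)
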