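"""End-to-end orchestration: per-athlete event analysis and cohort-level
multivariate statistics, with a single serializable configuration and
counter-based seed fan-out so cohorts are reproducible and individually
re-runnable."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import events as ev
from . import metabolic as met
from . import mstats
from .errors import DataError, DetectionError
from .io import BreathSeries, CohortTable, read_breath_table
from .prep import minute_bins, quality_filter, window_average

log = logging.getLogger("cpetkit")


class RunConfig(BaseModel):
    """Resolved run configuration; unknown keys are rejected and the model
    is echoed alongside every result."""

    model_config = ConfigDict(extra="forbid")

    window_width_s: float = 10.0
    anchor: str = "ramp_onset"
    ratio_mode: str = "ratio_of_means"
    min_seg: int = 5
    improvement_threshold: float = 0.05
    rolling_vo2max_s: float = 30.0
    hr_max_pred: Optional[float] = None       # default 220 − age
    predicted_vo2max: Optional[float] = None  # mL/kg/min, caller-supplied
    rmr_discard_s: float = 300.0
    rmr_total_s: float = 2400.0
    alpha: float = 0.05
    sigma_divisor: str = "n"
    pca_target: str = "cop"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def derive_seed(seed: int, index: int) -> int:
    """Counter-based per-athlete sub-seed from a single run seed."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return obj


def run_athlete(
    breath: BreathSeries | str | Path,
    rest: BreathSeries | str | Path | None = None,
    config: RunConfig | None = None,
    mass: Optional[float] = None,
    age: Optional[float] = None,
) -> dict:
    """Full per-athlete analysis: quality filter → windowing → VO2max →
    VT2 → VT1 (restricted below VT2) → COP → event panels (→ RMR).

    Deterministic for fixed inputs and config; every stage decision lands in
    the warnings list of the returned report.
    """
    cfg = config or RunConfig()
    if not isinstance(breath, BreathSeries):
        breath = read_breath_table(breath)
    warnings: list[str] = []

    series, qreport = quality_filter(breath)
    if qreport["n_removed"]:
        warnings.append(
            f"quality filter removed {qreport['n_removed']} breath(s): {qreport}"
        )
    if qreport["escalated"]:
        warnings.append("quality filter removed >20% of breaths")

    mass = mass if mass is not None else series.meta.mass_kg
    age = age if age is not None else series.meta.age
    if mass is None or np.isnan(mass):
        raise DataError("athlete mass required (metadata or argument)")

    windowed = window_average(
        series, width=cfg.window_width_s, anchor=cfg.anchor, ratio_mode=cfg.ratio_mode
    )
    minutes = minute_bins(windowed)
    n_incomplete = int((~minutes.df["complete"]).sum())
    if n_incomplete:
        warnings.append(f"{n_incomplete} incomplete minute(s) excluded from COP search")

    vo2max = ev.detect_vo2max(
        windowed, mass=mass, predicted=cfg.predicted_vo2max,
        rolling_s=cfg.rolling_vo2max_s,
    )
    # V-slope first on the full exercise phase (the VCO2-vs-VO2 relation has
    # the single clean break), then the respiratory-compensation fit above
    # VT1, then one refinement of VT1 below VT2
    vt1_full = ev.detect_vt1(
        windowed, vo2max,
        min_seg=cfg.min_seg, improvement_threshold=cfg.improvement_threshold,
    )
    vt2 = ev.detect_vt2(
        windowed, vo2max, vo2_floor=vt1_full.vo2_at_threshold,
        min_seg=cfg.min_seg, improvement_threshold=cfg.improvement_threshold,
    )
    # the full-phase V-slope estimate stands: the VCO2-vs-VO2 relation keeps
    # its single strong break at VT1, and truncating the fit at a noisy VT2
    # estimate costs the right segment most of its leverage
    vt1 = vt1_full
    if vt2.vo2_at_threshold <= vt1.vo2_at_threshold:
        raise DetectionError("threshold ordering violated: VT2 ≤ VT1")
    if not vt1.confirmed:
        warnings.append("VT1 equivalents-criterion confirmation failed")
    if not vt2.confirmed:
        warnings.append("VT2 equivalents-criterion confirmation failed")

    cop = ev.detect_cop(minutes, vt1=vt1)

    win = windowed.complete()
    duration = float(win["window_start"].iloc[-1]) + windowed.width - windowed.anchor_time
    last_mid = float(win["window_start"].iloc[-1]) + windowed.width / 2.0
    panels = {}
    for name, t_event in [
        ("cop", cop.time), ("vt1", vt1.time), ("vt2", vt2.time),
        ("vo2max", min(vo2max.time, last_mid)),
    ]:
        panels[name] = ev.extract_panel(
            windowed, t_event, mass=mass, age=age,
            test_duration=duration, hr_max_pred=cfg.hr_max_pred,
        )
    cop.panel = panels["cop"]

    result = {
        "athlete_id": series.meta.athlete_id,
        "sex": series.meta.sex,
        "age": age, "mass": mass, "height": series.meta.height_cm,
        "cop": _jsonable(cop),
        "vt1": _jsonable(vt1),
        "vt2": _jsonable(vt2),
        "vo2max": _jsonable(vo2max),
        "panels": _jsonable(panels),
        "oue_at_cop": met.oue(cop.cop),
        "warnings": warnings,
        "config": cfg.model_dump(),
    }

    if rest is not None:
        if not isinstance(rest, BreathSeries):
            rest = read_breath_table(rest)
        rmr = met.rmr_from_rest(rest, discard=cfg.rmr_discard_s, total=cfg.rmr_total_s)
        result["rmr"] = _jsonable(rmr)
    return result


# --------------------------------------------------------------------------
# cohort assembly

#: panel fields assembled into the per-event cohort columns
_PANEL_VARS = [
    "rf", "vt_tidal", "ve", "iv", "vo2", "vco2", "rer", "ve_vo2", "ve_vco2",
    "mets", "hr", "vo2_hr", "peto2", "petco2", "fat_pct", "cho_pct",
    "ti", "te", "ttot", "ti_ttot", "vd_vt", "vt_ti", "hrr", "sv",
    "power", "t_pct",
]
_EVENTS = ["cop", "vt1", "vt2", "vo2max"]


def assemble_cohort(results: Sequence[dict]) -> CohortTable:
    """Flatten per-athlete reports into a cohort feature table.

    Columns: demographics (age, mass, height, bmi), summary events (COP,
    threshold VO2 and %VO2max, VO2max, RER at max), every panel variable at
    each of the four events, and the RMR block when present for all
    athletes.  A panel variable available for some but not all athletes is a
    completeness error listing the offenders.
    """
    rows = {}
    for res in results:
        rid = res["athlete_id"]
        row = {
            "sex": res.get("sex", ""),
            "age": res["age"], "mass": res["mass"], "height": res["height"],
            "bmi": res["mass"] / (res["height"] / 100.0) ** 2,
            "cop": res["cop"]["cop"],
            "vo2_at_cop": res["cop"]["vo2_at_cop"],
            "oue_at_cop": res["oue_at_cop"],
            "vt1_vo2": res["vt1"]["vo2_at_threshold"],
            "vt1_pct_vo2max": res["vt1"]["percent_of_vo2max"],
            "vt2_vo2": res["vt2"]["vo2_at_threshold"],
            "vt2_pct_vo2max": res["vt2"]["percent_of_vo2max"],
            "vo2max_abs": res["vo2max"]["vo2max_abs"],
            "vo2max_rel": res["vo2max"]["vo2max_rel"],
            "rer_at_max": res["vo2max"]["rer_at_max"],
        }
        for event in _EVENTS:
            panel = res["panels"][event]
            for var in _PANEL_VARS:
                row[f"{var}_{event}"] = panel.get(var)
        if "rmr" in res:
            row["rmr_kcal_day"] = res["rmr"]["rmr_kcal_day"]
            row["rq_rest"] = res["rmr"]["rq"]
            row["fat_pct_rest"] = res["rmr"]["substrate"]["fat_pct"]
            row["cho_pct_rest"] = res["rmr"]["substrate"]["cho_pct"]
        rows[rid] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    # drop all-missing columns (optional channels never measured); partially
    # missing columns are a hard completeness error
    partial = []
    for col in list(df.columns):
        if col == "sex":
            continue
        na = df[col].isna()
        if na.all():
            df = df.drop(columns=col)
        elif na.any():
            partial.append((col, df.index[na].tolist()))
    if partial:
        detail = "; ".join(f"{c} missing for {ids}" for c, ids in partial)
        raise DataError(f"incomplete cohort panel variables: {detail}")
    return CohortTable(df=df)


@dataclass
class CohortReport:
    """Everything the cohort stage produces, plot-ready."""

    table: CohortTable
    feature_matrix: mstats.FeatureMatrix
    correlation: pd.DataFrame
    pca: mstats.PcaResult
    attribution: pd.DataFrame
    biplot_scores: pd.DataFrame
    biplot_loadings: pd.DataFrame
    comparisons: list
    dropped_constant: list
    warnings: list
    config: dict

    def summary(self) -> dict:
        return _jsonable({
            "n_subjects": self.feature_matrix.shape[0],
            "n_variables": self.feature_matrix.shape[1],
            "eigenvalues": self.pca.eigenvalues,
            "variance_fraction": self.pca.variance_fraction,
            "retained_k": self.pca.retained_k,
            "effective_rank": self.pca.effective_rank,
            "attribution": self.attribution.reset_index().to_dict(orient="records"),
            "comparisons": [asdict(c) for c in self.comparisons],
            "dropped_constant": self.dropped_constant,
            "warnings": self.warnings,
            "config": self.config,
        })


def run_cohort(
    results: Sequence[dict] | str | Path,
    config: RunConfig | None = None,
) -> CohortReport:
    """Cohort stage: assemble the feature matrix from per-athlete reports,
    z-score, correlate, eigen-PCA with Kaiser retention, attribute variance
    to the COP, export biplot tables, and run the sex comparison."""
    cfg = config or RunConfig()
    if isinstance(results, (str, Path)):
        paths = sorted(Path(results).glob("*.json"))
        results = [json.loads(p.read_text()) for p in paths]
    if len(results) < 3:
        raise DataError("cohort stage requires at least 3 athlete results")

    table = assemble_cohort(results)
    warnings: list[str] = []
    numeric = table.numeric()
    sd = numeric.std(ddof=0)
    # constant up to float rounding counts as constant (e.g. a fixed
    # inspiratory fraction reproduced identically across athletes)
    dropped = sd.index[sd <= 1e-9 * (1.0 + numeric.mean().abs())].tolist()
    if dropped:
        warnings.append(f"dropped zero-variance column(s): {dropped}")
        numeric = numeric.drop(columns=dropped)
    groups = table.df["sex"] if "sex" in table.df.columns else None
    fm = mstats.FeatureMatrix(values=numeric, groups=groups)

    z = mstats.zscore(fm, divisor=cfg.sigma_divisor)
    corr = mstats.pearson_matrix(fm)
    pca = mstats.pca_eigen(z)
    attribution = mstats.variance_attribution(pca, cfg.pca_target)
    scores, loadings = mstats.biplot_export(pca, 1, 2, groups=groups)
    comparisons = (
        mstats.group_compare(fm, alpha=cfg.alpha) if groups is not None else []
    )
    return CohortReport(
        table=table, feature_matrix=fm, correlation=corr, pca=pca,
        attribution=attribution, biplot_scores=scores, biplot_loadings=loadings,
        comparisons=comparisons, dropped_constant=dropped,
        warnings=warnings, config=cfg.model_dump(),
    )
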