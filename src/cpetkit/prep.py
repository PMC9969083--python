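"""Windowing and quality filtering of breath series.

The detection stages work on tumbling 10-s window means anchored at ramp
onset, and on per-minute means of six consecutive windows — the averaging
scheme under which the cardiorespiratory optimal point is defined.  Derived
ventilatory equivalents default to ratio-of-means (window-mean VE over
window-mean VO2) because they are ratios of minute quantities; mean-of-ratios
is available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import BreathSeries

#: channels carried through window averaging when present
_AVERAGED = [
    "vo2", "vco2", "ve", "hr", "rf", "vt_tidal", "iv",
    "peto2", "petco2", "ti", "te", "power", "sv", "vd_vt",
]

#: plausible ventilatory-equivalent range for a breath during exercise
VE_VO2_RANGE = (10.0, 80.0)


@dataclass
class WindowedSeries:
    """Tumbling-window means of every channel plus derived equivalents."""

    df: pd.DataFrame            # one row per window
    width: float                # s
    anchor_time: float          # s, window 0 starts here

    def complete(self) -> pd.DataFrame:
        return self.df[self.df["n_breaths"] > 0].reset_index(drop=True)


@dataclass
class MinuteSeries:
    """Per-minute means of six 10-s windows; incomplete minutes flagged."""

    df: pd.DataFrame            # one row per minute
    windows_per_minute: int

    def complete(self) -> pd.DataFrame:
        return self.df[self.df["complete"]].reset_index(drop=True)


def _derived(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ve_vo2"] = df["ve"] * 1000.0 / df["vo2"]
    df["ve_vco2"] = df["ve"] * 1000.0 / df["vco2"]
    df["rer"] = df["vco2"] / df["vo2"]
    return df


def window_average(
    series: BreathSeries,
    width: float = 10.0,
    anchor: str = "ramp_onset",
    ratio_mode: str = "ratio_of_means",
) -> WindowedSeries:
    """Average breaths into half-open tumbling windows ``[t, t+width)``.

    ``anchor`` places window 0 at ramp onset (default — makes "a given
    minute" of the ramp well defined) or at recording start.  Isolated empty
    windows are linearly interpolated from their neighbours; runs of empties
    stay empty (``n_breaths == 0``) and propagate to incomplete minutes.
    """
    if width <= 0:
        raise ConfigError("window width must be positive")
    if ratio_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ConfigError(f"unknown ratio_mode {ratio_mode!r}")
    if anchor == "ramp_onset":
        t0 = series.meta.ramp_onset_s
        if np.isnan(t0):
            raise ConfigError("anchor='ramp_onset' requires ramp_onset_s metadata")
    elif anchor == "recording_start":
        t0 = float(series.df["t"].iloc[0]) if len(series.df) else 0.0
    else:
        raise ConfigError(f"unknown anchor {anchor!r}")

    df = series.df[series.df["t"] >= t0]
    if df.empty:
        raise DataError("no breaths at or after the windowing anchor")

    idx = np.floor((df["t"].to_numpy(float) - t0) / width).astype(int)
    cols = [c for c in _AVERAGED if c in df.columns]
    grouped = df.groupby(idx)[cols].mean()
    counts = df.groupby(idx).size()

    full = pd.RangeIndex(0, int(idx.max()) + 1)
    out = grouped.reindex(full)
    out["n_breaths"] = counts.reindex(full).fillna(0).astype(int)

    if ratio_mode == "ratio_of_means":
        out = _derived(out)
    else:
        per_breath = _derived(df[["vo2", "vco2", "ve"]])
        for col in ("ve_vo2", "ve_vco2", "rer"):
            out[col] = per_breath.groupby(idx)[col].mean().reindex(full)

    # isolated empty windows: fill by linear interpolation, leave runs empty
    empty = out["n_breaths"].to_numpy() == 0
    isolated = empty.copy()
    isolated[1:] &= ~empty[:-1]
    isolated[:-1] &= ~empty[1:]
    if isolated.any():
        interp = out.drop(columns="n_breaths").interpolate(
            method="linear", limit_area="inside"
        )
        fill_rows = isolated & ~interp.isna().any(axis=1).to_numpy()
        out.loc[fill_rows, interp.columns] = interp[fill_rows]

    out.insert(0, "window_start", t0 + out.index.to_numpy() * width)
    out.insert(1, "t", out["window_start"] + width / 2.0)
    return WindowedSeries(df=out.reset_index(drop=True), width=width, anchor_time=t0)


def minute_bins(windowed: WindowedSeries) -> MinuteSeries:
    """Collapse windows into minutes from the anchor; a complete minute needs
    every one of its windows filled (six, at the default 10-s width)."""
    per_min = int(round(60.0 / windowed.width))
    df = windowed.df
    minute = ((df["window_start"] - windowed.anchor_time) / 60.0).astype(int)
    filled = df["n_breaths"] > 0
    cols = [c for c in df.columns if c not in ("window_start", "n_breaths")]
    agg = df[cols].groupby(minute).mean()
    n_windows = filled.groupby(minute).sum()
    total = minute.groupby(minute).size()
    agg["n_windows"] = n_windows
    agg["complete"] = (n_windows == per_min) & (total == per_min)
    agg.insert(0, "minute", agg.index)
    agg["t"] = windowed.anchor_time + agg["minute"] * 60.0 + 30.0
    return MinuteSeries(df=agg.reset_index(drop=True), windows_per_minute=per_min)


def quality_filter(series: BreathSeries) -> tuple[BreathSeries, dict]:
    """Drop physiologically impossible breaths; return the cleaned series and
    a per-rule removal report (``escalated`` set when >20% removed)."""
    df = series.df
    report = {"n_input": len(df)}
    keep = np.ones(len(df), dtype=bool)

    gas = (df["vo2"] <= 0) | (df["vco2"] <= 0) | (df["ve"] <= 0)
    report["nonpositive_gas"] = int(gas.sum())
    keep &= ~gas.to_numpy()

    t0 = series.meta.ramp_onset_s
    in_exercise = (
        np.ones(len(df), dtype=bool) if np.isnan(t0) else (df["t"] >= t0).to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        vevo2 = df["ve"].to_numpy(float) * 1000.0 / df["vo2"].to_numpy(float)
    lo, hi = VE_VO2_RANGE
    out_of_range = in_exercise & keep & ((vevo2 < lo) | (vevo2 > hi))
    report["ve_vo2_out_of_range"] = int(out_of_range.sum())
    keep &= ~out_of_range

    report["n_removed"] = int((~keep).sum())
    report["escalated"] = report["n_removed"] > 0.2 * max(len(df), 1)
    clean = BreathSeries(df=df[keep].reset_index(drop=True), meta=series.meta)
    return clean, report
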