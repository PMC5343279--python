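"""Quantification of store-operated calcium entry (SOCE) from per-cell
fluorescence traces.

The imaging protocol: cells bathe in Ca²⁺-containing Ringer's solution
(baseline), thapsigargin in Ca²⁺-free buffer empties ER stores (first
wave of cytosolic Ca²⁺ rise), and re-addition of extracellular Ca²⁺
triggers SOCE (second wave). Traces are normalized as ΔF/F₀ where F₀ is
the background-subtracted minimum of the record, set to exactly 1.

Per-cell metrics: peak height of each wave above the pre-thapsigargin
baseline, and baseline-subtracted trapezoid areas (total SOCE area, plus
an early-phase/late-phase split at ``early_s`` seconds after Ca²⁺
re-addition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FluorescenceTrace:
    times: np.ndarray  # seconds, uniform grid, strictly increasing
    raw: np.ndarray    # arbitrary fluorescence units
    background: float | np.ndarray
    tg_time_s: float   # thapsigargin addition
    ca_time_s: float   # extracellular Ca2+ re-addition
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.raw):
            raise ValueError("times and raw must be 1-D and equal length")
        dt = np.diff(self.times)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing on a uniform grid")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("intensities must be finite")
        if not self.tg_time_s < self.ca_time_s:
            raise ValueError("tg_time_s must precede ca_time_s")


@dataclass(frozen=True)
class PhaseWindows:
    pre: tuple[float, float]    # [0, tg)
    wave1: tuple[float, float]  # [tg, ca)
    wave2: tuple[float, float]  # [ca, end]


@dataclass(frozen=True)
class SoceMetrics:
    cell_id: str
    condition: str
    baseline_level: float
    wave1_peak: float
    wave2_peak: float
    wave1_auc: float
    wave2_auc_total: float
    wave2_auc_early: float
    wave2_auc_late: float


def normalize_trace(trace: FluorescenceTrace) -> np.ndarray:
    """ΔF/F₀: (raw − background) / min(raw − background); minimum is 1."""
    sub = trace.raw - trace.background
    m = sub.min()
    if m <= 0:
        raise ValueError(
            f"background exceeds signal: min(raw - background) = {m:g} <= 0"
        )
    return sub / m


def segment_phases(trace: FluorescenceTrace) -> PhaseWindows:
    """Split the record into pre / ER-release / SOCE windows."""
    t0, t_end = float(trace.times[0]), float(trace.times[-1])
    if not (t0 <= trace.tg_time_s <= t_end and trace.ca_time_s <= t_end):
        raise ValueError("event times must lie within the recorded range")
    if trace.tg_time_s <= t0:
        warnings.warn("thapsigargin at record start: empty pre-window")
    return PhaseWindows(
        pre=(t0, trace.tg_time_s),
        wave1=(trace.tg_time_s, trace.ca_time_s),
        wave2=(trace.ca_time_s, t_end),
    )


def _window_auc(times: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    """Trapezoid area over [a, b] with linear interpolation at the bounds.

    Splitting [a, b] at any interior point therefore decomposes the area
    exactly (early + late = total).
    """
    if b <= a:
        return 0.0
    inside = (times > a) & (times < b)
    t = np.concatenate([[a], times[inside], [b]])
    v = np.concatenate(
        [[np.interp(a, times, values)], values[inside], [np.interp(b, times, values)]]
    )
    return float(np.trapezoid(v, t))


def wave_metrics(
    trace: FluorescenceTrace,
    normalized: np.ndarray | None = None,
    windows: PhaseWindows | None = None,
    early_s: float = 50.0,
    baseline: str = "pre",
) -> SoceMetrics:
    """Peak heights and baseline-subtracted areas for both waves.

    ``baseline='pre'`` (default) references peaks and areas to the mean
    ΔF/F₀ of the pre-thapsigargin window; ``baseline='floor'`` uses the
    normalization floor of 1. Values below baseline are clipped at 0 so
    areas stay non-negative under noise. The early phase of SOCE covers
    [ca, ca + early_s]; the late phase the remainder of the record.
    """
    if normalized is None:
        normalized = normalize_trace(trace)
    if windows is None:
        windows = segment_phases(trace)
    t = trace.times
    if baseline == "pre":
        pre_mask = (t >= windows.pre[0]) & (t < windows.pre[1])
        base = float(normalized[pre_mask].mean()) if pre_mask.any() else 1.0
        if not pre_mask.any():
            warnings.warn("empty pre-window: baseline falls back to the floor of 1")
    elif baseline == "floor":
        base = 1.0
    else:
        raise ValueError(f"unknown baseline {baseline!r}")

    above = np.clip(normalized - base, 0.0, None)

    def _peak(lo: float, hi: float, closed_end: bool) -> float:
        mask = (t >= lo) & ((t <= hi) if closed_end else (t < hi))
        if not mask.any():
            return float("nan")
        return float(above[mask].max())

    w1_lo, w1_hi = windows.wave1
    w2_lo, w2_hi = windows.wave2
    early_hi = min(w2_lo + early_s, w2_hi)
    return SoceMetrics(
        cell_id=trace.cell_id,
        condition=trace.condition,
        baseline_level=base,
        wave1_peak=_peak(w1_lo, w1_hi, closed_end=False),
        wave2_peak=_peak(w2_lo, w2_hi, closed_end=True),
        wave1_auc=_window_auc(t, above, w1_lo, w1_hi),
        wave2_auc_total=_window_auc(t, above, w2_lo, w2_hi),
        wave2_auc_early=_window_auc(t, above, w2_lo, early_hi),
        wave2_auc_late=_window_auc(t, above, early_hi, w2_hi),
    )


METRIC_COLUMNS = [
    "wave1_peak", "wave2_peak", "wave1_auc",
    "wave2_auc_total", "wave2_auc_early", "wave2_auc_late",
]


def metrics_frame(metrics: list[SoceMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id, "condition": m.condition,
                "baseline_level": m.baseline_level,
                **{c: getattr(m, c) for c in METRIC_COLUMNS},
            }
            for m in metrics
        ]
    )


def cohort_summary(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition median/quartiles/extrema plus pairwise median ratios.

    Returns (summary, ratios). Empty conditions are dropped with a warning.
    The output matches box-plot semantics: the line is the median, the box
    the 25th/75th percentiles, whiskers minima and maxima.
    """
    df = df.copy()
    empty = [c for c, g in df.groupby("condition") if g[METRIC_COLUMNS].dropna().empty]
    if empty:
        warnings.warn(f"excluding empty conditions: {empty}")
        df = df[~df["condition"].isin(empty)]
    rows = []
    for cond, g in df.groupby("condition", sort=True):
        for metric in METRIC_COLUMNS:
            v = g[metric].dropna()
            rows.append(
                {
                    "condition": cond, "metric": metric, "n": len(v),
                    "median": v.median(), "q25": v.quantile(0.25),
                    "q75": v.quantile(0.75), "min": v.min(), "max": v.max(),
                }
            )
    summary = pd.DataFrame(rows)
    ratio_rows = []
    conds = sorted(df["condition"].unique())
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            for metric in METRIC_COLUMNS:
                ma = summary.query("condition == @a and metric == @metric")["median"].iloc[0]
                mb = summary.query("condition == @b and metric == @metric")["median"].iloc[0]
                ratio_rows.append(
                    {
                        "metric": metric, "numerator": b, "denominator": a,
                        "median_ratio": mb / ma if ma != 0 else np.inf if mb > 0 else np.nan,
                    }
                )
    return summary, pd.DataFrame(ratio_rows)


def traces_from_frame(
    df: pd.DataFrame, tg_time_s: float, ca_time_s: float
) -> list[FluorescenceTrace]:
    """Build per-cell traces from a tidy table (io.read_trace_table)."""
    out = []
    for (cond, cell), g in df.groupby(["condition", "cell_id"], sort=True):
        g = g.sort_values("time_s")
        bg = g["background"].to_numpy()
        out.append(
            FluorescenceTrace(
                times=g["time_s"].to_numpy(),
                raw=g["raw"].to_numpy(),
                background=float(bg[0]) if np.allclose(bg, bg[0]) else bg,
                tg_time_s=tg_time_s,
                ca_time_s=ca_time_s,
                cell_id=str(cell),
                condition=str(cond),
            )
        )
    return out
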