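"""Plate-reader growth-curve quantification and strain comparison.

Growth in each well is quantified with a two-point definition: a baseline is
taken during the first 500 min of incubation; Amin is the first reading 10%
above baseline (sustained over a few consecutive reads so noise cannot fire
it), Amax the culture density at the end of the first exponential phase,
located where the smoothed derivative falls to 5% of its in-phase peak.
Then rate = (Amax - Amin)/(Tmax - Tmin) in dA600/h and density =
Amax - Amin; wells that never rise by 0.1 A600 are scored no-growth.
Replicate groups are summarised as mean +/- SD (n-1), compared by two-sided
Student's t tests (pooled variance, p < 0.01 by default), and mutants are
expressed as percent of the wild-type reference density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MINUTES_PER_HOUR = 60.0


@dataclass
class GrowthCurve:
    well_id: str
    time_min: np.ndarray
    a600: np.ndarray
    strain: str = ""
    substrate: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a600 = np.asarray(self.a600, dtype=float)
        if self.time_min.size < 2 or self.time_min.size != self.a600.size:
            raise ValueError(f"well {self.well_id}: need >=2 matched (time, A600) points")
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if np.any(self.time_min < 0) or np.any(self.a600 < 0):
            raise ValueError(f"well {self.well_id}: negative time or absorbance")


@dataclass
class GrowthMetrics:
    well_id: str
    grew: bool
    t_min: float = math.nan
    t_max: float = math.nan
    a_min: float = math.nan
    a_max: float = math.nan
    rate: float = math.nan  # dA600 per hour
    density: float = math.nan
    strain: str = ""
    substrate: str = ""


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def locate_growth_window(
    curve: GrowthCurve,
    baseline_window_min: float = 500.0,
    rise_fraction: float = 0.10,
    min_density: float = 0.1,
    smooth_points: int = 5,
    slope_fraction: float = 0.05,
    confirm_points: int = 3,
) -> GrowthMetrics:
    """Locate (Tmin, Amin) and (Tmax, Amax) for one well, or call no-growth.

    Baseline = mean of readings in the first ``baseline_window_min`` minutes.
    Tmin is the first time the reading and the next ``confirm_points - 1``
    readings all reach baseline*(1 + rise_fraction).  Tmax terminates the
    first exponential phase: the first point after the peak of the smoothed
    derivative where that derivative drops to <= ``slope_fraction`` of its
    peak.  No-growth when the threshold is never reached or the total rise
    Amax - Amin is below ``min_density``.
    """
    t, y = curve.time_min, curve.a600
    base_mask = t <= baseline_window_min
    if not base_mask.any():
        raise ValueError(
            f"well {curve.well_id}: no readings within the {baseline_window_min}-min baseline window"
        )
    baseline = float(y[base_mask].mean())
    threshold = baseline * (1.0 + rise_fraction)

    above = y >= threshold
    i_min = None
    k = max(1, int(confirm_points))
    for i in range(y.size):
        stop = min(y.size, i + k)
        if above[i:stop].all() and (stop - i) == min(k, y.size - i):
            i_min = i
            break
    no_growth = GrowthMetrics(curve.well_id, grew=False, strain=curve.strain, substrate=curve.substrate)
    if i_min is None:
        return no_growth

    smooth = _moving_average(y, smooth_points)
    slope = np.gradient(smooth, t)
    tail = slope[i_min:]
    i_peak = i_min + int(np.argmax(tail))
    peak_slope = slope[i_peak]
    if peak_slope <= 0:
        return no_growth
    # the drop below the slope threshold must be sustained over confirm_points
    # reads so one noisy derivative sample cannot terminate the phase early
    i_max = y.size - 1
    drop = slope[i_peak + 1 :] <= slope_fraction * peak_slope
    for j in range(drop.size):
        stop = min(drop.size, j + k)
        if drop[j:stop].all():
            i_max = i_peak + 1 + j
            break
    a_min, a_max = float(y[i_min]), float(y[i_max])
    t_min, t_max = float(t[i_min]), float(t[i_max])
    if a_max - a_min < min_density or t_max <= t_min:
        return no_growth
    m = GrowthMetrics(
        curve.well_id, grew=True, t_min=t_min, t_max=t_max, a_min=a_min, a_max=a_max,
        strain=curve.strain, substrate=curve.substrate,
    )
    m.rate = growth_rate(m)
    m.density = a_max - a_min
    return m


def growth_rate(m: GrowthMetrics) -> float:
    """Two-point rate (Amax - Amin)/(Tmax - Tmin), converted to dA600/hour."""
    if not m.grew:
        raise ValueError(f"well {m.well_id}: no growth window")
    if m.t_max == m.t_min:
        raise ValueError(f"well {m.well_id}: degenerate window (t_max == t_min)")
    return (m.a_max - m.a_min) / ((m.t_max - m.t_min) / MINUTES_PER_HOUR)


def analyze_plate(
    plate: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    **window_kwargs,
) -> pd.DataFrame:
    """Quantify every well of a plate.

    ``plate``: first column time in minutes, remaining columns well readings.
    ``layout``: optional table with columns well_id, strain, substrate
    (and anything else, carried through).  Returns one row per well.
    """
    tcol = plate.columns[0]
    t = plate[tcol].to_numpy(dtype=float)
    meta = {}
    if layout is not None:
        meta = {str(r.well_id): r for r in layout.itertuples(index=False)}
    rows = []
    for well in plate.columns[1:]:
        info = meta.get(str(well))
        curve = GrowthCurve(
            well_id=str(well), time_min=t, a600=plate[well].to_numpy(dtype=float),
            strain=getattr(info, "strain", ""), substrate=getattr(info, "substrate", ""),
        )
        m = locate_growth_window(curve, **window_kwargs)
        rows.append(vars(m))
    return pd.DataFrame(rows)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_layout_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def aggregate_and_compare(
    metrics: pd.DataFrame,
    group_cols: Sequence[str] = ("strain", "substrate"),
    value_col: str = "density",
    reference_group: tuple | str | None = None,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-group mean +/- SD with pairwise t-tests against a reference group.

    No-growth wells contribute zero to the group values (a well that never
    grew has zero density/rate).  The t-test is the classic pooled-variance
    Student's test by default; single-replicate groups are aggregated but
    skipped for testing.  ``percent_of_reference`` = 100 * group mean /
    reference group mean.
    """
    work = metrics.copy()
    work[value_col] = np.where(work["grew"].astype(bool), work[value_col], 0.0)
    grouped = work.groupby(list(group_cols))[value_col]
    out = grouped.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    ref_values = None
    ref_mean = math.nan
    if reference_group is not None:
        key = reference_group if isinstance(reference_group, tuple) else (reference_group,)
        sel = np.ones(len(work), dtype=bool)
        for col, val in zip(group_cols, key):
            sel &= work[col] == val
        ref_values = work.loc[sel, value_col].to_numpy()
        if ref_values.size:
            ref_mean = float(ref_values.mean())
    pvals, sig, pct = [], [], []
    for row in out.itertuples(index=False):
        if ref_values is None or ref_values.size < 2 or row.n < 2:
            pvals.append(math.nan)
            sig.append(False)
        else:
            sel = np.ones(len(work), dtype=bool)
            for col in group_cols:
                sel &= work[col] == getattr(row, col)
            vals = work.loc[sel, value_col].to_numpy()
            res = stats.ttest_ind(vals, ref_values, equal_var=equal_var)
            pvals.append(float(res.pvalue))
            sig.append(bool(res.pvalue < alpha))
        pct.append(100.0 * row.mean / ref_mean if math.isfinite(ref_mean) and ref_mean else math.nan)
    out["p_value"] = pvals
    out["significant"] = sig
    out["percent_of_reference"] = pct
    return out


# ---------------------------------------------------------------------------
# Closed-form window for a single logistic curve (oracle for planted kinetics)

def logistic_window_truth(
    a0: float,
    amplitude: float,
    rate_per_min: float,
    midpoint_min: float,
    baseline_window_min: float = 500.0,
    rise_fraction: float = 0.10,
    slope_fraction: float = 0.05,
) -> dict:
    """Analytic (Tmin, Tmax, rate, density) for A(t) = a0 + amp/(1+exp(-r(t-tm)))
    under the same window rules, evaluated on the continuous noise-free curve.

    The baseline is the exact mean of A(t) over [0, baseline_window_min]
    (the logistic integrates in closed form); Tmin solves
    A(t) = baseline*(1+rise_fraction); Tmax is where the instantaneous slope
    falls to ``slope_fraction`` of the peak slope amp*r/4, i.e. at logistic
    fraction p_max = (1 + sqrt(1 - slope_fraction))/2.
    """
    r, tm, amp = rate_per_min, midpoint_min, amplitude
    T = baseline_window_min

    def softplus(x: float) -> float:
        return math.log1p(math.exp(-abs(x))) + max(x, 0.0)

    mean_logistic = amp / (r * T) * (softplus(r * (T - tm)) - softplus(-r * tm))
    baseline = a0 + mean_logistic
    threshold = baseline * (1.0 + rise_fraction)
    p_min = (threshold - a0) / amp
    if not (0.0 < p_min < 1.0):
        return {"grew": False}
    t_min = tm + math.log(p_min / (1.0 - p_min)) / r
    p_max = (1.0 + math.sqrt(1.0 - slope_fraction)) / 2.0
    t_max = tm + math.log(p_max / (1.0 - p_max)) / r
    density = amp * (p_max - p_min)
    if density < 0.1 or t_max <= t_min:
        return {"grew": False}
    return {
        "grew": True,
        "t_min": t_min,
        "t_max": t_max,
        "a_min": a0 + amp * p_min,
        "a_max": a0 + amp * p_max,
        "rate": density / ((t_max - t_min) / MINUTES_PER_HOUR),
        "density": density,
        "max_slope_per_min": amp * r / 4.0,
    }
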