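"""Daily average in-stream loads from concentration and discharge.

Load (g/d) = c (ng/L) * Q (m^3/s) * 0.0864, the unit conversion
ng/L * m^3/s = 1e-9 g / 1e-3 m^3 * m^3/s = 1e-6 g/s = 0.0864 g/d.
Concentration samples are linearly interpolated onto the daily grid
(constant extrapolation beyond the first/last sample), multiplied by the
daily discharge, and averaged over the deployment window. Time-weighted
average (POCIS) concentrations enter as a single constant over the window.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DeploymentWindow, InvalidArgument, LoadEstimate

#: ng/L * m^3/s -> g/d
NG_L_M3S_TO_G_D = 0.0864


def daily_load(c_ng_per_l: float, q_m3s: float) -> float:
    """Instantaneous daily load in g/d for one concentration/discharge pair."""
    if c_ng_per_l < 0 or q_m3s < 0:
        raise InvalidArgument("concentration and discharge must be >= 0")
    return c_ng_per_l * q_m3s * NG_L_M3S_TO_G_D


def time_weighted_load(samples: Sequence[tuple[float, float]],
                       discharge: np.ndarray,
                       window: DeploymentWindow,
                       site_id: str = "", compound: str = "",
                       method: str = "grab",
                       c_sd: float = 0.0) -> LoadEstimate:
    """Daily average load over a deployment window.

    Parameters
    ----------
    samples:
        (day, concentration ng/L) pairs; a single pair yields a constant
        concentration (the TWA case).
    discharge:
        Daily discharge series (m^3/s) indexed by day 0..len-1 and covering
        the window.
    c_sd:
        Concentration SD propagated linearly to the load SD (relative SD of
        the mean concentration applied to the load).
    """
    if len(samples) == 0:
        raise InvalidArgument("need at least one concentration sample")
    q = np.asarray(discharge, dtype=float)
    if len(q) == 0:
        raise InvalidArgument("empty discharge series")
    if window.end_day > len(q) - 1 or window.start_day < 0:
        raise InvalidArgument("discharge does not cover the window")
    pts = sorted(samples)
    days = np.array([p[0] for p in pts], dtype=float)
    concs = np.array([p[1] for p in pts], dtype=float)
    if (concs < 0).any():
        raise InvalidArgument("concentrations must be nonnegative")
    grid = np.arange(window.start_day, window.end_day + 1, dtype=float)
    c_grid = np.interp(grid, days, concs)  # constant beyond end samples
    q_grid = q[window.start_day:window.end_day + 1]
    if (q_grid < 0).any():
        raise InvalidArgument("discharge must be nonnegative")
    daily = c_grid * q_grid * NG_L_M3S_TO_G_D
    load = float(daily.mean())
    c_mean = float(c_grid.mean())
    sd = load * (c_sd / c_mean) if (c_sd > 0 and c_mean > 0) else 0.0
    return LoadEstimate(site_id=site_id, compound=compound, method=method,
                        start_day=window.start_day, end_day=window.end_day,
                        load=load, sd=float(sd))


def stratified_load(sub_loads: Sequence[LoadEstimate]) -> LoadEstimate:
    """Combine loads over sub-windows that partition a union period.

    The union load is the duration-weighted mean of the sub-window loads.
    Sub-windows must be contiguous and non-overlapping.
    """
    if not sub_loads:
        raise InvalidArgument("no sub-window loads")
    parts = sorted(sub_loads, key=lambda e: e.start_day)
    for a, b in zip(parts, parts[1:]):
        if a.end_day != b.start_day:
            raise InvalidArgument(
                "sub-windows must partition the union period "
                f"(gap/overlap between day {a.end_day} and {b.start_day})")
    durations = np.array([e.end_day - e.start_day for e in parts], dtype=float)
    loads = np.array([e.load for e in parts])
    sds = np.array([e.sd for e in parts])
    total = durations.sum()
    w = durations / total
    load = float(np.sum(w * loads))
    sd = float(np.sqrt(np.sum((w * sds) ** 2)))
    first = parts[0]
    return LoadEstimate(site_id=first.site_id, compound=first.compound,
                        method=first.method, start_day=first.start_day,
                        end_day=parts[-1].end_day, load=load, sd=sd)


def loads_frame(estimates: Sequence[LoadEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "site_id": e.site_id, "compound": e.compound, "method": e.method,
        "start_day": e.start_day, "end_day": e.end_day,
        "load_g_per_d": e.load, "load_sd_g_per_d": e.sd}
        for e in estimates])


def compare_loads(twa: pd.DataFrame, grab: pd.DataFrame,
                  group_by: Optional[str] = "compound") -> pd.DataFrame:
    """Pairwise L_TWA / L_grab ratios with grouped mean and SD.

    Both inputs are frames from ``loads_frame`` (columns site_id, compound,
    load_g_per_d); pairs are matched on (site_id, compound). Pairs where
    either load is zero or missing are excluded. ``group_by`` is
    "compound", "site_id" or None (one global group).
    """
    merged = twa.merge(grab, on=["site_id", "compound"],
                       suffixes=("_twa", "_grab"))
    merged = merged[(merged["load_g_per_d_twa"] > 0)
                    & (merged["load_g_per_d_grab"] > 0)]
    if merged.empty:
        return pd.DataFrame(
            columns=["group", "n", "mean_ratio", "sd_ratio"])
    merged["ratio"] = (merged["load_g_per_d_twa"]
                       / merged["load_g_per_d_grab"])
    if group_by is None:
        groups = [("all", merged)]
    else:
        groups = list(merged.groupby(group_by, sort=True))
    rows = []
    for key, g in groups:
        rows.append({"group": key, "n": len(g),
                     "mean_ratio": float(g["ratio"].mean()),
                     "sd_ratio": float(g["ratio"].std(ddof=1))
                     if len(g) > 1 else 0.0})
    return pd.DataFrame(rows)
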