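"""Field sampling-rate estimation and time-weighted average concentrations.

For each compound quantified in both POCIS and grab samples at enough
sites, the field sampling rate R_s (L/d) is the slope of the ordinary
least-squares regression of the POCIS daily accumulated mass m_POCIS
(ng/d) on the grab concentration c_grab (ng/L) across sites. Compounds
whose regression explains the cross-site variance well (R^2 above a
cutoff, default 0.90, with a positive slope) are retained, and their R_s
converts m_POCIS into a time-weighted average water concentration
c_TWA = m_POCIS / R_s under linear (integrative) uptake.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    InsufficientData,
    InvalidArgument,
    SamplingRateEstimate,
    SingularFit,
    TwaConcentration,
)


def estimate_rs(c_grab: np.ndarray, m_pocis: np.ndarray, compound: str = "",
                min_pairs: int = 5, intercept: bool = True
                ) -> SamplingRateEstimate:
    """Estimate the field sampling rate of one compound.

    Parameters
    ----------
    c_grab, m_pocis:
        Paired per-site grab concentrations (ng/L) and POCIS daily masses
        (ng/d); pairs with NaN in either member are dropped (nondetects
        must be excluded by the caller, not substituted).
    min_pairs:
        Minimum number of complete pairs (default 5).
    intercept:
        Fit slope + intercept (default) or a through-origin line.

    The slope is R_s in L/d with its standard error; R^2 is the coefficient
    of determination of the fit. A nonpositive slope yields ``valid=False``.
    """
    x = np.asarray(c_grab, dtype=float)
    y = np.asarray(m_pocis, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_pairs:
        raise InsufficientData(
            f"{compound or 'compound'}: {n} pairs < {min_pairs}")
    if np.ptp(x) == 0.0:
        raise SingularFit("zero variance in c_grab")

    if intercept:
        res = stats.linregress(x, y)
        slope, inter = float(res.slope), float(res.intercept)
        se = float(res.stderr)
        ss_res = float(np.sum((y - (slope * x + inter)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y) / sxx)
        inter = 0.0
        resid = y - slope * x
        dof = max(n - 1, 1)
        se = float(np.sqrt(np.sum(resid ** 2) / dof / sxx))
        ss_res = float(np.sum(resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return SamplingRateEstimate(
        compound=compound, r_s=slope, se_r_s=se,
        r_squared=float(np.clip(r2, 0.0, 1.0)), n_pairs=n,
        intercept=inter, with_intercept=intercept, valid=slope > 0.0)


def estimate_rs_table(measurements: pd.DataFrame, min_pairs: int = 5,
                      intercept: bool = True) -> list[SamplingRateEstimate]:
    """Per-compound sampling rates from a long measurement table.

    Expects columns site_id, compound, m_pocis, c_grab with optional
    boolean nondetect columns; nondetect pairs are excluded. Compounds
    with too few co-occurring pairs or degenerate designs are skipped.
    """
    out = []
    for comp, g in measurements.groupby("compound", sort=True):
        x = g["c_grab"].to_numpy(float).copy()
        y = g["m_pocis"].to_numpy(float).copy()
        if "c_grab_nondetect" in g:
            x[g["c_grab_nondetect"].fillna(False).astype(bool).to_numpy()] = np.nan
        if "m_pocis_nondetect" in g:
            y[g["m_pocis_nondetect"].fillna(False).astype(bool).to_numpy()] = np.nan
        try:
            out.append(estimate_rs(x, y, compound=comp, min_pairs=min_pairs,
                                   intercept=intercept))
        except (InsufficientData, SingularFit):
            continue
    return out


def filter_by_fit(estimates: Iterable[SamplingRateEstimate],
                  min_r2: float = 0.90) -> list[SamplingRateEstimate]:
    """Keep estimates with R^2 strictly above ``min_r2`` and positive slope."""
    return [e for e in estimates
            if e.valid and e.r_s > 0.0 and e.r_squared > min_r2]


def compute_twa(m_pocis: float, estimate: SamplingRateEstimate,
                site_id: str = "", m_pocis_sd: float = 0.0
                ) -> TwaConcentration:
    """Time-weighted average concentration c_TWA = m_POCIS / R_s (ng/L).

    The standard deviation combines the sampling-rate standard error and
    the POCIS replicate SD by the first-order delta method:
    (sd/c)^2 = (sd_m/m)^2 + (se_Rs/Rs)^2.
    """
    if estimate.r_s <= 0:
        raise InvalidArgument("sampling rate must be positive for TWA")
    if m_pocis < 0:
        raise InvalidArgument("m_pocis must be nonnegative")
    c = m_pocis / estimate.r_s
    if m_pocis > 0:
        rel2 = (m_pocis_sd / m_pocis) ** 2 + (estimate.se_r_s / estimate.r_s) ** 2
        sd = c * float(np.sqrt(rel2))
    else:
        sd = 0.0
    return TwaConcentration(site_id=site_id, compound=estimate.compound,
                            c_twa=float(c), sd=float(sd))


def twa_table(measurements: pd.DataFrame,
              estimates: Iterable[SamplingRateEstimate]) -> pd.DataFrame:
    """c_TWA for every (site, compound) with an accepted sampling rate.

    POCIS nondetects propagate as nondetect rows with NaN concentration.
    """
    by_comp = {e.compound: e for e in estimates}
    rows = []
    for _, r in measurements.iterrows():
        est = by_comp.get(r["compound"])
        if est is None:
            continue
        nondetect = bool(r.get("m_pocis_nondetect", False))
        if nondetect or not np.isfinite(r["m_pocis"]):
            rows.append({"site_id": r["site_id"], "compound": r["compound"],
                         "c_twa_ng_per_l": np.nan, "c_twa_sd": np.nan,
                         "nondetect": True})
            continue
        t = compute_twa(float(r["m_pocis"]), est, site_id=r["site_id"],
                        m_pocis_sd=float(r.get("m_pocis_sd", 0.0)))
        rows.append({"site_id": t.site_id, "compound": t.compound,
                     "c_twa_ng_per_l": t.c_twa, "c_twa_sd": t.sd,
                     "nondetect": False})
    return pd.DataFrame(rows)


def rates_frame(estimates: Iterable[SamplingRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "compound": e.compound, "r_s_l_per_d": e.r_s, "se_r_s": e.se_r_s,
        "r_squared": e.r_squared, "n_pairs": e.n_pairs,
        "intercept": e.intercept, "with_intercept": e.with_intercept,
        "valid": e.valid} for e in estimates])
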