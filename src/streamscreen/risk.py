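"""Screening-level mixture risk assessment.

Two complementary mixture metrics per site:

* Cumulative exposure-activity ratio under concentration addition:
  EAR_i = c_i / ACC_i for each compound-endpoint pair (ACC = in-vitro
  activity concentration at cutoff); EARs are summed within an endpoint
  and the site score is the maximum endpoint sum (or the grand sum).
  Precautionary effects-screening threshold: 0.001.

* Multi-substance potentially affected fraction under response addition:
  each compound's PAF is the log-normal species sensitivity distribution
  (SSD) evaluated at its concentration, PAF = Phi((log10 c - mu)/sigma),
  and msPAF = 1 - prod(1 - PAF_i). Generally accepted effect threshold: 5%.

Monte-Carlo uncertainty propagation redraws uncertain inputs from
zero-truncated normal distributions and recomputes any metric.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import InvalidArgument, RiskResult

EAR_THRESHOLD = 0.001
MSPAF_THRESHOLD = 0.05


def ear(concentration: float, acc: float) -> float:
    """Exposure-activity ratio c/ACC (both ng/L)."""
    if acc <= 0:
        raise InvalidArgument("ACC must be positive")
    if concentration < 0:
        raise InvalidArgument("concentration must be nonnegative")
    return concentration / acc


def sum_ear(concentrations: Mapping[str, float], acc_table: pd.DataFrame,
            aggregation: str = "max_endpoint"
            ) -> tuple[float, dict[str, float]]:
    """Cumulative EAR for one site's compound mixture.

    ``concentrations``: compound -> ng/L. ``acc_table``: columns compound,
    endpoint, acc_ng_per_l. EARs are summed across compounds within each
    endpoint; the site score is the maximum endpoint sum
    (``aggregation="max_endpoint"``, the screening-framework convention)
    or the sum over all pairs (``"total"``).

    Returns (score, per-compound contribution on the scoring endpoint).
    """
    if aggregation not in ("max_endpoint", "total"):
        raise InvalidArgument(f"unknown aggregation {aggregation!r}")
    t = acc_table[acc_table["compound"].isin(concentrations)]
    if t.empty:
        return 0.0, {}
    ears = {}
    for _, r in t.iterrows():
        e = ear(concentrations[r["compound"]], float(r["acc_ng_per_l"]))
        ears.setdefault(r["endpoint"], {})
        ears[r["endpoint"]][r["compound"]] = (
            ears[r["endpoint"]].get(r["compound"], 0.0) + e)
    endpoint_sums = {ep: sum(d.values()) for ep, d in ears.items()}
    if aggregation == "total":
        contrib: dict[str, float] = {}
        for d in ears.values():
            for comp, e in d.items():
                contrib[comp] = contrib.get(comp, 0.0) + e
        return float(sum(endpoint_sums.values())), contrib
    best = max(sorted(endpoint_sums), key=lambda ep: endpoint_sums[ep])
    return float(endpoint_sums[best]), dict(ears[best])


def paf(concentration: float, mu_log10: float, sigma_log10: float) -> float:
    """Potentially affected fraction from a log-normal SSD.

    PAF = Phi((log10 c - mu)/sigma); zero concentration maps to PAF = 0
    by convention (the limit as c -> 0).
    """
    if sigma_log10 <= 0:
        raise InvalidArgument("SSD sigma must be positive")
    if concentration < 0:
        raise InvalidArgument("concentration must be nonnegative")
    if concentration == 0:
        return 0.0
    z = (np.log10(concentration) - mu_log10) / sigma_log10
    return float(stats.norm.cdf(z))


def mspaf(concentrations: Mapping[str, float], ssd_table: pd.DataFrame
          ) -> tuple[float, dict[str, float]]:
    """Multi-substance PAF under response addition: 1 - prod(1 - PAF_i).

    ``ssd_table``: columns compound, mu_log10, sigma_log10. Returns
    (msPAF, per-compound PAF_i). Compounds without SSD parameters are
    skipped.
    """
    pafs: dict[str, float] = {}
    for _, r in ssd_table.iterrows():
        comp = r["compound"]
        if comp not in concentrations:
            continue
        pafs[comp] = paf(concentrations[comp], float(r["mu_log10"]),
                         float(r["sigma_log10"]))
    if not pafs:
        return 0.0, {}
    log_surv = np.sum(np.log1p(-np.clip(list(pafs.values()), 0.0, 1.0 - 1e-300)))
    total = float(-np.expm1(log_surv))
    return min(max(total, 0.0), 1.0), pafs


def leave_one_out_drops(pafs: Mapping[str, float]) -> dict[str, float]:
    """msPAF reduction when each compound is removed (contribution measure)."""
    vals = dict(pafs)
    log_surv_all = np.sum(np.log1p(-np.clip(list(vals.values()), 0.0,
                                            1.0 - 1e-300)))
    total = -np.expm1(log_surv_all)
    out = {}
    for comp, p in vals.items():
        rest = log_surv_all - np.log1p(-min(p, 1.0 - 1e-300))
        out[comp] = float(total - (-np.expm1(rest)))
    return out


def site_risk(concentrations: Mapping[str, float], acc_table: pd.DataFrame,
              ssd_table: pd.DataFrame, site_id: str = "",
              aggregation: str = "max_endpoint") -> RiskResult:
    """Both mixture metrics with threshold flags for one site."""
    clean = {c: v for c, v in concentrations.items()
             if v is not None and np.isfinite(v)}
    s_ear, ear_contrib = sum_ear(clean, acc_table, aggregation=aggregation)
    ms, pafs = mspaf(clean, ssd_table)
    return RiskResult(
        site_id=site_id, sum_ear=s_ear, mspaf=ms,
        ear_contributions=ear_contrib, paf_contributions=pafs,
        ear_flag=s_ear >= EAR_THRESHOLD, mspaf_flag=ms >= MSPAF_THRESHOLD)


def propagate_uncertainty(metric: Callable[[np.ndarray], float],
                          means: np.ndarray, sds: np.ndarray,
                          n_draws: int = 1000, seed: int = 0,
                          vectorized: bool = False) -> tuple[float, float]:
    """Monte-Carlo mean and SD of a metric of uncertain nonnegative inputs.

    Inputs are drawn independently from normal distributions truncated at
    zero (matching symmetric reported +/- SDs on nonnegative quantities);
    inputs with zero SD stay fixed. Deterministic under a fixed seed.

    ``metric`` maps one input vector to a scalar; with ``vectorized`` it
    receives the whole (n_draws, k) matrix and returns n_draws values.
    """
    if n_draws < 100:
        raise InvalidArgument("n_draws must be at least 100")
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape:
        raise InvalidArgument("means and sds must have the same shape")
    if (sds < 0).any():
        raise InvalidArgument("SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    draws = np.tile(means, (n_draws, 1))
    pos = sds > 0
    if pos.any():
        a = (0.0 - means[pos]) / sds[pos]
        tn = stats.truncnorm.rvs(a, np.inf, loc=means[pos], scale=sds[pos],
                                 size=(n_draws, int(pos.sum())),
                                 random_state=rng)
        draws[:, pos] = tn
    if vectorized:
        vals = np.asarray(metric(draws), dtype=float)
    else:
        vals = np.array([metric(draws[i]) for i in range(n_draws)])
    return float(vals.mean()), float(vals.std(ddof=1))


def risk_table(concentrations: pd.DataFrame, acc_table: pd.DataFrame,
               ssd_table: pd.DataFrame, conc_col: str = "c_twa_ng_per_l",
               sd_col: Optional[str] = "c_twa_sd",
               aggregation: str = "max_endpoint",
               n_draws: int = 500, seed: int = 0) -> pd.DataFrame:
    """Site-level risk table from a long concentration frame.

    ``concentrations``: columns site_id, compound, ``conc_col`` and
    optionally ``sd_col``; nondetect/NaN rows are ignored. Monte-Carlo SDs
    for both metrics are attached when ``sd_col`` is present.
    """
    rows = []
    for site, g in concentrations.groupby("site_id", sort=True):
        g = g[np.isfinite(g[conc_col])]
        conc = dict(zip(g["compound"], g[conc_col].astype(float)))
        res = site_risk(conc, acc_table, ssd_table, site_id=site,
                        aggregation=aggregation)
        if sd_col and sd_col in g and len(g):
            comps = list(g["compound"])
            means = g[conc_col].to_numpy(float)
            sds = np.nan_to_num(g[sd_col].to_numpy(float), nan=0.0)
            # EAR coefficients: endpoints x compounds matrix of summed 1/ACC
            sub = acc_table[acc_table["compound"].isin(comps)]
            coef = sub.pivot_table(index="endpoint", columns="compound",
                                   values="acc_ng_per_l",
                                   aggfunc=lambda s: float(np.sum(1.0 / s)))
            C = coef.reindex(columns=comps).fillna(0.0).to_numpy(float)
            st = ssd_table.drop_duplicates("compound").set_index("compound")
            st = st.reindex(comps)
            mu = st["mu_log10"].to_numpy(float)
            sig = st["sigma_log10"].to_numpy(float)
            has_ssd = np.isfinite(mu) & np.isfinite(sig)

            def ear_metric(D):
                if C.size == 0:
                    return np.zeros(len(D))
                sums = D @ C.T
                return (sums.max(axis=1) if aggregation == "max_endpoint"
                        else sums.sum(axis=1))

            def ms_metric(D):
                if not has_ssd.any():
                    return np.zeros(len(D))
                Dp = D[:, has_ssd]
                with np.errstate(divide="ignore"):
                    z = (np.where(Dp > 0, np.log10(np.maximum(Dp, 1e-300)),
                                  -np.inf) - mu[has_ssd]) / sig[has_ssd]
                p = np.clip(stats.norm.cdf(z), 0.0, 1.0 - 1e-12)
                return -np.expm1(np.log1p(-p).sum(axis=1))

            _, res.sum_ear_sd = propagate_uncertainty(
                ear_metric, means, sds, n_draws=n_draws, seed=seed,
                vectorized=True)
            _, res.mspaf_sd = propagate_uncertainty(
                ms_metric, means, sds, n_draws=n_draws, seed=seed + 1,
                vectorized=True)
        rows.append({
            "site_id": site, "sum_ear": res.sum_ear,
            "sum_ear_sd": res.sum_ear_sd, "mspaf": res.mspaf,
            "mspaf_sd": res.mspaf_sd, "ear_flag": res.ear_flag,
            "mspaf_flag": res.mspaf_flag,
            "top_ear_compound": (max(res.ear_contributions,
                                     key=res.ear_contributions.get)
                                 if res.ear_contributions else ""),
            "top_paf_compound": (max(res.paf_contributions,
                                     key=res.paf_contributions.get)
                                 if res.paf_contributions else "")})
    return pd.DataFrame(rows)
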