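"""Ground-truth recovery experiments on the synthetic cohort.

Each function simulates data under the default study conditions, runs the
corresponding analysis module, and measures how well the known truth is
recovered. These are the quantitative checks behind the package's claims
about parameter recovery, prioritization performance and cluster
identification.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import clustering, kinetics, nontarget, synthetic_data
from .synthetic_data import ScenarioConfig
from .types import DeploymentWindow


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def rs_recovery(n_seeds: int = 100, seed: int = 0, n_sites: int = 20,
                true_r_s: float = 0.07, cv: float = 0.10,
                intercept: bool = True) -> pd.DataFrame:
    """Field sampling-rate recovery under the default study conditions.

    Per replicate: a 20-site cohort, one agricultural-cluster compound,
    a 23-day deployment, true R_s = 0.07 L/d, and ``cv`` multiplicative
    measurement noise on both the POCIS daily mass and the grab
    concentrations. Returns one row per replicate with the relative error
    of the slope and the regression R^2.
    """
    rows = []
    for s in _subseeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        sites = synthetic_data.generate_sites(n_sites, s)
        truth = synthetic_data.make_ground_truth(
            {"A": ["cmp001"]}, s + 1)
        truth.true_r_s["cmp001"] = true_r_s
        c_w = synthetic_data.generate_concentrations(
            sites, ["cmp001"], truth, s + 2, n_days=30)
        m, g = [], []
        for site in sites:
            w = DeploymentWindow(site_id=site.site_id, start_day=3,
                                 end_day=26)
            series = np.asarray(c_w[site.site_id]["cmp001"])
            m_true = synthetic_data.simulate_pocis_uptake(
                series, true_r_s, w)
            m.append(m_true * max(0.0, 1.0 + rng.normal(0.0, cv)))
            grabs = [series[d] * max(0.0, 1.0 + rng.normal(0.0, cv))
                     for d in (w.start_day, w.end_day)]
            g.append(np.mean(grabs))
        est = kinetics.estimate_rs(np.array(g), np.array(m),
                                   compound="cmp001", intercept=intercept)
        rows.append({"seed": s, "r_s_hat": est.r_s,
                     "rel_error": (est.r_s - true_r_s) / true_r_s,
                     "r_squared": est.r_squared})
    return pd.DataFrame(rows)


def nontarget_recovery(n_seeds: int = 20, seed: int = 0,
                       config: Optional[ScenarioConfig] = None
                       ) -> pd.DataFrame:
    """Recall and false-discovery proportion of the nontarget
    prioritization against the planted features, per replicate cohort."""
    rows = []
    for s in _subseeds(seed, n_seeds):
        cohort = synthetic_data.simulate_cohort(config, seed=s)
        res = nontarget.prioritize(cohort.features, cohort.sites_frame,
                                   cohort.suspects)
        selected = set(res.prioritized.index)
        planted = set(cohort.truth.planted_nontarget_ids)
        tp = len(selected & planted)
        rows.append({
            "seed": s,
            "recall": tp / len(planted) if planted else np.nan,
            "fdp": (len(selected) - tp) / len(selected) if selected else 0.0,
            "n_selected": len(selected)})
    return pd.DataFrame(rows)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two label sequences (pair-counting
    form with the expected-index correction)."""
    a = pd.Categorical(list(labels_a)).codes
    b = pd.Categorical(list(labels_b)).codes
    n = len(a)
    if n != len(b):
        raise ValueError("label sequences differ in length")
    table = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def clustering_recovery(seed: int = 0,
                        config: Optional[ScenarioConfig] = None) -> dict:
    """Source-cluster recovery on one default cohort: ARI of the Ward
    partition against the planted clusters and the A/B/C label accuracy."""
    cohort = synthetic_data.simulate_cohort(config, seed=seed)
    meas = cohort.measurements.copy()
    levels = meas.pivot(index="site_id", columns="compound",
                        values="m_pocis")
    nd = meas.pivot(index="site_id", columns="compound",
                    values="m_pocis_nondetect").astype(bool)
    levels = levels.mask(nd)
    _, labels, _ = clustering.cluster_items(levels, cohort.sites_frame, k=3)
    truth = cohort.truth.source_cluster
    common = [c for c in labels if c in truth]
    ari = adjusted_rand_index([truth[c] for c in common],
                              [labels[c] for c in common])
    acc = float(np.mean([truth[c] == labels[c] for c in common]))
    return {"ari": ari, "label_accuracy": acc, "n_items": len(common)}
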