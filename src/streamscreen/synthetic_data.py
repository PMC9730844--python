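"""Synthetic multi-watershed datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: watershed attribute vectors with a correlated developed-land
block, source-driven micropollutant concentration fields (agricultural,
developed/septic, and wastewater clusters), linear-phase POCIS uptake with
replicate disks, noisy LC-HRMS feature intensities with isotope envelopes
and fragment spectra, and storm-pulse discharge series. Every random draw
is a function of the supplied seed, and the full ground truth (source
clusters, true sampling rates, latent water concentrations, planted
nontarget feature ids) is returned for recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import screening
from .featuretable import FeatureTable
from .types import (
    AGRICULTURAL_ATTRIBUTES,
    ATTRIBUTE_COLUMNS,
    DEVELOPED_ATTRIBUTES,
    WASTEWATER_ATTRIBUTES,
    ConfigurationError,
    DeploymentWindow,
    GroundTruth,
    InvalidArgument,
    SuspectCompound,
    WatershedSite,
)

CLUSTER_ATTRIBUTES = {
    "A": AGRICULTURAL_ATTRIBUTES,
    "B": DEVELOPED_ATTRIBUTES,
    "C": WASTEWATER_ATTRIBUTES,
}

#: Gaussian-copula correlation that yields Spearman rank correlation ~0.7
#: between attributes of the same block: r = 2 sin(pi * rho_s / 6).
_BLOCK_RANK_RHO = 0.7
_BLOCK_GAUSS_R = 2.0 * np.sin(np.pi * _BLOCK_RANK_RHO / 6.0)


# ---------------------------------------------------------------------------
# Watershed sites


def generate_sites(n_sites: int, seed: int) -> list[WatershedSite]:
    """Draw a cohort of watershed attribute vectors.

    A Gaussian copula ties the developed-land block (dev_pct, road_density,
    pop_density, septic_density) together and, separately, the agricultural
    block (ag_pct, cafo_count, rpi), each at rank correlation ~0.7; the two
    blocks and wwtp_capacity are mutually independent. Marginals are chosen
    so that ag_pct + dev_pct <= 100 holds by construction.
    """
    if n_sites < 2:
        raise InvalidArgument("need at least 2 sites")
    rng = np.random.default_rng(seed)

    def block(k: int) -> np.ndarray:
        cov = np.full((k, k), _BLOCK_GAUSS_R)
        np.fill_diagonal(cov, 1.0)
        return rng.multivariate_normal(np.zeros(k), cov, size=n_sites,
                                       method="cholesky")

    dev_z = block(4)          # dev_pct, road_density, pop_density, septic
    ag_z = block(3)           # ag_pct, cafo_count, rpi
    wwtp_z = rng.standard_normal(n_sites)

    u = stats.norm.cdf
    sites = []
    for i in range(n_sites):
        dev_pct = 40.0 * u(dev_z[i, 0])
        road = float(np.exp(np.log(1.5) + 0.6 * dev_z[i, 1]))
        pop = float(np.exp(np.log(50.0) + 1.0 * dev_z[i, 2]))
        septic = float(np.exp(np.log(10.0) + 0.8 * dev_z[i, 3]))
        ag_pct = 60.0 * u(ag_z[i, 0])
        cafo = int(stats.poisson.ppf(u(ag_z[i, 1]), mu=3.0))
        rpi = 100.0 * u(ag_z[i, 2])
        wwtp = float(np.exp(np.log(2000.0) + 1.5 * wwtp_z[i]))
        sites.append(WatershedSite(
            site_id=f"site{i + 1:02d}", ag_pct=float(ag_pct),
            dev_pct=float(dev_pct), septic_density=septic, cafo_count=cafo,
            wwtp_capacity=wwtp, road_density=road, rpi=float(rpi),
            pop_density=pop))
    return sites


def sites_frame(sites: Sequence[WatershedSite]) -> pd.DataFrame:
    """Site attribute table indexed by site_id (canonical column order)."""
    df = pd.DataFrame([asdict(s) for s in sites]).set_index("site_id")
    return df[list(ATTRIBUTE_COLUMNS)]


# ---------------------------------------------------------------------------
# Ground truth scaffolding


def _random_formula(rng: np.random.Generator) -> str:
    n_c = int(rng.integers(8, 28))
    n_h = int(rng.integers(max(4, int(0.8 * n_c)), 2 * n_c + 3))
    parts = [f"C{n_c}", f"H{n_h}"]
    n_n = int(rng.integers(0, 5))
    n_o = int(rng.integers(0, 7))
    if n_n:
        parts.append(f"N{n_n}")
    if n_o:
        parts.append(f"O{n_o}")
    if rng.random() < 0.10:
        parts.append("S")
    if rng.random() < 0.20:
        parts.append(f"Cl{int(rng.integers(1, 3))}")
    if rng.random() < 0.15:
        parts.append(f"F{int(rng.integers(1, 4))}")
    return "".join(parts)


def _draw_r_s(n: int, rng: np.random.Generator,
              low: float = 0.02, high: float = 0.22,
              median: float = 0.07) -> np.ndarray:
    """Sampling rates spanning [low, high] with distribution median
    ``median`` — the right-skewed shape of field-derived POCIS rates
    (piecewise-uniform quantile through the three anchors)."""
    u = rng.uniform(0.0, 1.0, size=n)
    r = np.where(u < 0.5,
                 low + (median - low) * 2.0 * u,
                 median + (high - median) * (2.0 * u - 1.0))
    return r


def default_effect_sizes(beta: float = 0.3, beta_wwtp: float = 0.6
                         ) -> dict[str, float]:
    """Per-attribute log10 effect sizes; the single-attribute wastewater
    block gets a larger coefficient so all three sources have comparable
    total signal."""
    out = {a: beta for a in ATTRIBUTE_COLUMNS}
    out["wwtp_capacity"] = beta_wwtp
    return out


def make_ground_truth(compounds_by_cluster: dict[str, Sequence[str]],
                      seed: int,
                      effect_sizes: Optional[dict[str, float]] = None,
                      sigma_log10: float = 0.2,
                      temporal_sigma: float = 0.05,
                      alpha_center: float = 1.0,
                      alpha_spread: float = 0.5) -> GroundTruth:
    """Assemble the latent parameters of a scenario.

    alpha (per-compound log10 baseline, ng/L) ~ N(alpha_center,
    alpha_spread); LOQ ~ 10**U(-0.5, 0.5) ng/L; true sampling rates uniform
    on [0.02, 0.22] L/d with the cohort median pinned at 0.07 L/d.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        effect_sizes=effect_sizes or default_effect_sizes(),
        noise={"sigma_log10": sigma_log10, "temporal_sigma": temporal_sigma},
    )
    all_compounds = [c for cl in sorted(compounds_by_cluster)
                     for c in compounds_by_cluster[cl]]
    r_s = _draw_r_s(len(all_compounds), rng)
    for i, comp in enumerate(all_compounds):
        truth.true_r_s[comp] = float(r_s[i])
        truth.alpha_log10[comp] = float(
            rng.normal(alpha_center, alpha_spread))
        truth.loq_ng_per_l[comp] = float(10.0 ** rng.uniform(-0.5, 0.5))
        truth.compound_formula[comp] = _random_formula(rng)
    for cl, comps in compounds_by_cluster.items():
        if cl not in CLUSTER_ATTRIBUTES:
            raise ConfigurationError(f"unknown source cluster {cl!r}")
        for c in comps:
            truth.source_cluster[c] = cl
    return truth


# ---------------------------------------------------------------------------
# Concentrations


def generate_concentrations(sites: Sequence[WatershedSite],
                            compounds: Sequence[str],
                            truth: GroundTruth, seed: int,
                            n_days: int = 30) -> dict[str, dict[str, np.ndarray]]:
    """Simulate the daily water-concentration field c_w (ng/L).

    log10 c_w(site, compound, day) = alpha_k + sum_a beta_a * z_a(site)
    + eps(site, compound) + eta(site, compound, day), where the attribute
    sum runs over the compound's source-cluster block (z_a = cohort
    z-score of attribute a), eps ~ N(0, sigma_log10) is site scatter and
    eta ~ N(0, temporal_sigma) is day-to-day variability.

    The result (site -> compound -> day series) is also stored on
    ``truth.c_w``.
    """
    missing = [c for c in compounds if c not in truth.source_cluster]
    if missing:
        raise ConfigurationError(f"compounds without cluster: {missing}")
    bad = [a for a, b in truth.effect_sizes.items() if not np.isfinite(b)]
    if bad:
        raise ConfigurationError(f"non-finite effect sizes: {bad}")

    rng = np.random.default_rng(seed)
    attr = sites_frame(sites)
    z = (attr - attr.mean()) / attr.std(ddof=0).replace(0.0, 1.0)
    sigma = truth.noise.get("sigma_log10", 0.0)
    temporal = truth.noise.get("temporal_sigma", 0.0)

    out: dict[str, dict[str, np.ndarray]] = {s.site_id: {} for s in sites}
    for comp in compounds:
        cluster = truth.source_cluster[comp]
        block = CLUSTER_ATTRIBUTES[cluster]
        betas = np.array([truth.effect_sizes.get(a, 0.0) for a in block])
        signal = z[list(block)].to_numpy(float) @ betas
        eps = rng.normal(0.0, sigma, size=len(sites)) if sigma else np.zeros(len(sites))
        for i, s in enumerate(sites):
            base = truth.alpha_log10.get(comp, 1.0) + signal[i] + eps[i]
            eta = (rng.normal(0.0, temporal, size=n_days)
                   if temporal else np.zeros(n_days))
            out[s.site_id][comp] = 10.0 ** (base + eta)
    for site_id, comps in out.items():
        truth.c_w[site_id] = {c: v.tolist() for c, v in comps.items()}
    return out


# ---------------------------------------------------------------------------
# POCIS uptake


def simulate_pocis_uptake(c_w: np.ndarray, true_r_s: float,
                          window: DeploymentWindow,
                          elimination_rate: float = 0.0) -> float:
    """Daily average mass accumulated in a POCIS disk (ng/d).

    Default is the linear (integrative) uptake phase: the accumulated mass
    is M(T) = R_s * integral of c_w over the deployment, so the daily
    average is R_s times the time-average concentration (trapezoidal rule
    on the daily grid; exact for constant c_w).

    With ``elimination_rate`` k_e > 0 the curvilinear first-order solution
    M(T) = R_s * integral c_w(t) exp(-k_e (T - t)) dt is used instead, to
    study the bias of assuming integrative sampling.
    """
    if true_r_s < 0:
        raise InvalidArgument("sampling rate must be nonnegative")
    c = np.asarray(c_w, dtype=float)
    t0, t1 = window.start_day, window.end_day
    if t0 < 0 or t1 > len(c) - 1:
        raise InvalidArgument("window extends beyond the concentration series")
    days = np.arange(t0, t1 + 1)
    seg = c[t0:t1 + 1]
    if elimination_rate > 0.0:
        weights = np.exp(-elimination_rate * (t1 - days))
        m_total = np.trapezoid(seg * weights, days)
    else:
        m_total = np.trapezoid(seg, days)
    return float(true_r_s * m_total / window.duration)


# ---------------------------------------------------------------------------
# Discharge


def generate_discharge(window: DeploymentWindow, baseflow: float,
                       storms: Sequence[tuple[float, float, float]],
                       seed: int, n_days: Optional[int] = None) -> np.ndarray:
    """Daily discharge series (m^3/s) over days 0..n_days-1.

    Q(t) = baseflow + sum of storm pulses; each storm is a tuple
    (start_day, peak_m3s, recession_days) contributing
    peak * exp(-(t - start)/recession) for t >= start. The seed perturbs
    pulse peaks by lognormal noise (sigma 0.2) so repeated scenarios differ;
    Q > 0 everywhere since baseflow > 0 and pulses are nonnegative.
    """
    if baseflow <= 0:
        raise InvalidArgument("baseflow must be positive")
    rng = np.random.default_rng(seed)
    n = n_days if n_days is not None else window.end_day + 1
    t = np.arange(n, dtype=float)
    q = np.full(n, baseflow, dtype=float)
    for start, peak, recession in storms:
        if peak < 0 or recession <= 0:
            raise InvalidArgument("storm peak must be >= 0, recession > 0")
        jitter = float(np.exp(rng.normal(0.0, 0.2)))
        pulse = np.where(t >= start,
                         peak * jitter * np.exp(-(t - start) / recession), 0.0)
        q += pulse
    return q


def random_storms(n_storms: int, window: DeploymentWindow, baseflow: float,
                  seed: int) -> list[tuple[float, float, float]]:
    """Storm tuples with lognormal peaks (median 2x baseflow) and 1-4 day
    recessions, uniformly placed inside the deployment window."""
    rng = np.random.default_rng(seed)
    storms = []
    for _ in range(n_storms):
        start = float(rng.uniform(window.start_day, window.end_day))
        peak = float(baseflow * 2.0 * np.exp(rng.normal(0.0, 0.7)))
        recession = float(rng.uniform(1.0, 4.0))
        storms.append((start, peak, recession))
    return storms


# ---------------------------------------------------------------------------
# Feature table


def _fragment_template(rng: np.random.Generator, precursor_mz: float,
                       n_frag: int = 6) -> list[tuple[float, float]]:
    mzs = np.sort(rng.uniform(50.0, max(60.0, precursor_mz - 10.0), n_frag))
    weights = rng.dirichlet(np.ones(n_frag))
    rel = 100.0 * weights / weights.max()
    return list(zip(mzs.tolist(), rel.tolist()))


def _noisy_envelope(theo: list[tuple[float, float]], sigma: float,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    if sigma <= 0:
        return list(theo)
    out = []
    for dm, ab in theo:
        noisy = ab * max(0.0, 1.0 + rng.normal(0.0, sigma))
        out.append((dm + rng.normal(0.0, 0.001), noisy))
    base = max(ab for _, ab in out)
    return [(dm, 100.0 * ab / base) for dm, ab in out if ab > 0]


def generate_feature_table(sites: Sequence[WatershedSite],
                           m_pocis: pd.DataFrame,
                           truth: GroundTruth,
                           n_background: int, seed: int,
                           gain: float = 1.0e6,
                           feature_noise_sigma: float = 0.10,
                           background_presence_prob: float = 0.85,
                           background_no_formula_frac: float = 0.30,
                           envelope_noise_compound: float = 0.03,
                           envelope_noise_background: float = 0.20,
                           ) -> tuple[FeatureTable, dict[str, str]]:
    """Build the site x feature intensity table.

    Compound-linked features (suspect-database compounds and planted
    nontarget compounds, i.e. every row of ``m_pocis``) get intensity
    gain * m_POCIS * lognormal(feature_noise_sigma) at every site, an
    isotope envelope derived from the assigned formula with small
    multiplicative noise, and a fragment spectrum from the per-compound
    template. Background features are attribute-independent lognormal
    noise peaks, present per site with probability
    ``background_presence_prob``, with poorer envelopes and a fraction
    lacking any candidate formula.

    ``m_pocis``: compounds x sites (ng/d).
    Returns the table and a feature_id -> compound mapping for the
    compound-linked rows.
    """
    if n_background < 0:
        raise InvalidArgument("n_background must be nonnegative")
    rng = np.random.default_rng(seed)
    site_ids = [s.site_id for s in sites]
    meta_rows = []
    intens_rows = []
    envelopes: dict[str, list[tuple[float, float]]] = {}
    fragments: dict[str, list[tuple[float, float]]] = {}
    feature_compound: dict[str, str] = {}

    fid = 0
    for comp in m_pocis.index:
        fid += 1
        feature_id = f"F{fid:04d}"
        formula = truth.compound_formula[comp]
        mono = screening.monoisotopic_mass(formula)
        mz = mono + screening.PROTON_MASS
        theo = screening.isotope_pattern(formula)
        envelopes[feature_id] = _noisy_envelope(
            theo, envelope_noise_compound, rng)
        fragments[feature_id] = _fragment_template(rng, mz)
        noise = np.exp(rng.normal(0.0, np.log(10.0) * feature_noise_sigma,
                                  size=len(site_ids)))
        vals = gain * m_pocis.loc[comp, site_ids].to_numpy(float) * noise
        meta_rows.append({"feature_id": feature_id, "mz": mz,
                          "rt": float(rng.uniform(1.0, 25.0)),
                          "formula": formula,
                          "blank_intensity": float(
                              np.exp(rng.normal(np.log(100.0), 0.3)))})
        intens_rows.append(vals)
        feature_compound[feature_id] = comp

    for _ in range(n_background):
        fid += 1
        feature_id = f"F{fid:04d}"
        has_formula = rng.random() >= background_no_formula_frac
        if has_formula:
            formula = _random_formula(rng)
            mz = screening.monoisotopic_mass(formula) + screening.PROTON_MASS
            theo = screening.isotope_pattern(formula)
            envelopes[feature_id] = _noisy_envelope(
                theo, envelope_noise_background, rng)
        else:
            formula = ""
            mz = float(rng.uniform(100.0, 900.0))
        if rng.random() < 0.5:
            fragments[feature_id] = _fragment_template(
                rng, mz, n_frag=int(rng.integers(3, 8)))
        level = float(rng.normal(np.log10(3.0e5), 0.8))
        vals = 10.0 ** rng.normal(level, 0.5, size=len(site_ids))
        present = rng.random(len(site_ids)) < background_presence_prob
        vals = np.where(present, vals, 0.0)
        meta_rows.append({"feature_id": feature_id, "mz": mz,
                          "rt": float(rng.uniform(1.0, 25.0)),
                          "formula": formula,
                          "blank_intensity": float(
                              np.exp(rng.normal(np.log(100.0), 0.3)))})
        intens_rows.append(vals)

    meta = pd.DataFrame(meta_rows).set_index("feature_id")
    intens = pd.DataFrame(np.vstack(intens_rows), index=meta.index,
                          columns=site_ids)
    table = FeatureTable(meta=meta, intensities=intens,
                         envelopes=envelopes, fragments=fragments)
    return table, feature_compound


# ---------------------------------------------------------------------------
# Scenario driver


@dataclass
class ScenarioConfig:
    """Default study conditions for the synthetic cohort.

    20 sites and 23 +/- 2 day deployments reflect the field campaign the
    generator emulates; compound counts give three source clusters of equal
    size plus planted nontarget compounds and attribute-independent
    background features for the prioritization to reject.
    """

    n_sites: int = 20
    n_days: int = 30
    window_start: int = 3
    window_duration_mean: int = 23
    window_duration_sd: int = 2
    n_suspects_per_cluster: int = 15
    n_nontarget_per_cluster: int = 10
    n_background: int = 300
    n_indicators: int = 14
    beta: float = 0.3
    beta_wwtp: float = 0.6
    sigma_log10: float = 0.2
    temporal_sigma: float = 0.05
    grab_cv: float = 0.10
    disk_cv: float = 0.10
    n_disks: int = 3
    gain: float = 1.0e6
    feature_noise_sigma: float = 0.10
    background_presence_prob: float = 0.85
    background_no_formula_frac: float = 0.30
    envelope_noise_compound: float = 0.03
    envelope_noise_background: float = 0.20
    baseflow_median: float = 2.0
    n_storms: int = 2

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        for name in ("grab_cv", "disk_cv", "sigma_log10", "temporal_sigma",
                     "feature_noise_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not (0.0 < self.background_presence_prob <= 1.0):
            raise ConfigurationError(
                "background_presence_prob must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    """Everything one simulated field campaign produces."""

    config: ScenarioConfig
    sites: list[WatershedSite]
    windows: dict[str, DeploymentWindow]
    truth: GroundTruth
    suspects: list[SuspectCompound]
    measurements: pd.DataFrame        # long: site x suspect compound
    grabs: pd.DataFrame               # per-event grab table
    features: FeatureTable
    feature_compound: dict[str, str]
    discharge: pd.DataFrame           # long: site_id, day, q_m3s
    acc: pd.DataFrame                 # compound, endpoint, acc_ng_per_l
    ssd: pd.DataFrame                 # compound, mu_log10, sigma_log10
    library_spectra: dict[str, list[tuple[float, float]]]

    @property
    def sites_frame(self) -> pd.DataFrame:
        return sites_frame(self.sites)


def simulate_cohort(config: Optional[ScenarioConfig] = None,
                    seed: int = 0) -> SyntheticCohort:
    """Run the full generator under one seed.

    Suspect-database compounds are named cmpNNN, planted nontarget
    compounds ntcNNN; both are split evenly over source clusters A
    (agricultural), B (developed/septic) and C (wastewater). The indicator
    mixture is the ``n_indicators`` suspects with the highest detection
    frequency (ties by cumulative POCIS mass).
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2 ** 31 - 1))  # noqa: E731
    seeds = {k: sub() for k in
             ("sites", "truth", "conc", "disk", "grab", "features",
              "discharge", "tox")}

    sites = generate_sites(cfg.n_sites, seeds["sites"])
    clusters = ["A", "B", "C"]
    suspects_by_cluster = {
        cl: [f"cmp{i + 1 + j * cfg.n_suspects_per_cluster:03d}"
             for i in range(cfg.n_suspects_per_cluster)]
        for j, cl in enumerate(clusters)}
    nontarget_by_cluster = {
        cl: [f"ntc{i + 1 + j * cfg.n_nontarget_per_cluster:03d}"
             for i in range(cfg.n_nontarget_per_cluster)]
        for j, cl in enumerate(clusters)}
    by_cluster = {cl: list(suspects_by_cluster[cl]) + list(nontarget_by_cluster[cl])
                  for cl in clusters}
    truth = make_ground_truth(
        by_cluster, seeds["truth"],
        effect_sizes=default_effect_sizes(cfg.beta, cfg.beta_wwtp),
        sigma_log10=cfg.sigma_log10, temporal_sigma=cfg.temporal_sigma)

    all_compounds = sorted(truth.source_cluster)
    suspect_names = sorted(c for cl in clusters for c in suspects_by_cluster[cl])
    # suspect compounds (whose field R_s the analysis estimates) get
    # stratified quantiles of the rate distribution, randomly assigned:
    # the cohort median is exactly 0.07 L/d and the range spans the
    # field-reported decade
    n_s = len(suspect_names)
    pos = (np.arange(n_s) + 0.5) / n_s
    vals = np.where(pos < 0.5, 0.02 + (0.07 - 0.02) * 2.0 * pos,
                    0.07 + (0.22 - 0.07) * (2.0 * pos - 1.0))
    rng.shuffle(vals)
    for name, v in zip(suspect_names, vals):
        truth.true_r_s[name] = float(v)
    c_w = generate_concentrations(sites, all_compounds, truth,
                                  seeds["conc"], n_days=cfg.n_days)

    windows = {}
    for s in sites:
        dur = int(np.clip(round(rng.normal(cfg.window_duration_mean,
                                           cfg.window_duration_sd)),
                          cfg.window_duration_mean - 2 * cfg.window_duration_sd,
                          cfg.n_days - cfg.window_start - 1))
        windows[s.site_id] = DeploymentWindow(
            site_id=s.site_id, start_day=cfg.window_start,
            end_day=cfg.window_start + dur)

    # POCIS disks and grab events
    disk_rng = np.random.default_rng(seeds["disk"])
    grab_rng = np.random.default_rng(seeds["grab"])
    meas_rows, grab_rows = [], []
    m_pocis_all = pd.DataFrame(index=all_compounds,
                               columns=[s.site_id for s in sites],
                               dtype=float)
    for s in sites:
        w = windows[s.site_id]
        for comp in all_compounds:
            series = np.asarray(c_w[s.site_id][comp])
            m_true = simulate_pocis_uptake(series, truth.true_r_s[comp], w)
            disks = m_true * np.maximum(
                0.0, 1.0 + disk_rng.normal(0.0, cfg.disk_cv, cfg.n_disks))
            m_mean = float(disks.mean())
            m_sd = float(disks.std(ddof=1))
            m_pocis_all.loc[comp, s.site_id] = m_mean
            loq = truth.loq_ng_per_l[comp]
            events = []
            for ev, day in (("deploy", w.start_day), ("retrieve", w.end_day)):
                cg = float(series[day] * max(
                    0.0, 1.0 + grab_rng.normal(0.0, cfg.grab_cv)))
                events.append(cg)
                if comp in suspect_names:
                    grab_rows.append({
                        "site_id": s.site_id, "compound": comp, "event": ev,
                        "day": day, "c_grab_ng_per_l": cg,
                        "loq_flag": cg < loq})
            if comp in suspect_names:
                cg_mean = float(np.mean(events))
                cg_sd = float(np.std(events, ddof=1))
                m_loq = loq * 0.05    # POCIS-equivalent LOQ at nominal R_s
                meas_rows.append({
                    "site_id": s.site_id, "compound": comp,
                    "m_pocis": m_mean, "m_pocis_sd": m_sd,
                    "m_pocis_nondetect": m_mean < m_loq,
                    "c_grab": cg_mean, "c_grab_sd": cg_sd,
                    "c_grab_nondetect": cg_mean < loq,
                    "loq": loq})
    measurements = pd.DataFrame(meas_rows)
    grabs = pd.DataFrame(grab_rows)

    # indicator mixture: most frequently detected suspects
    det = measurements[~measurements["m_pocis_nondetect"]]
    freq = det.groupby("compound")["site_id"].nunique()
    mass = measurements.groupby("compound")["m_pocis"].sum()
    ranking = pd.DataFrame({"freq": freq, "mass": mass}).fillna(0.0)
    ranking = ranking.sort_values(["freq", "mass"], ascending=False)
    truth.indicator_compounds = sorted(ranking.index[:cfg.n_indicators])

    suspects = [
        SuspectCompound(
            name=c, formula=truth.compound_formula[c],
            monoisotopic_mass=screening.monoisotopic_mass(
                truth.compound_formula[c]),
            compound_class=("PEST" if truth.source_cluster[c] == "A"
                            else "PHAR" if truth.source_cluster[c] == "C"
                            else "PCHI"),
            is_indicator=c in truth.indicator_compounds)
        for c in suspect_names]

    features, feature_compound = generate_feature_table(
        sites, m_pocis_all, truth, cfg.n_background, seeds["features"],
        gain=cfg.gain, feature_noise_sigma=cfg.feature_noise_sigma,
        background_presence_prob=cfg.background_presence_prob,
        background_no_formula_frac=cfg.background_no_formula_frac,
        envelope_noise_compound=cfg.envelope_noise_compound,
        envelope_noise_background=cfg.envelope_noise_background)
    truth.planted_nontarget_ids = sorted(
        f for f, comp in feature_compound.items()
        if comp not in set(suspect_names))

    dis_rng = np.random.default_rng(seeds["discharge"])
    dis_rows = []
    for s in sites:
        w = windows[s.site_id]
        baseflow = float(np.exp(dis_rng.normal(
            np.log(cfg.baseflow_median), 0.7)))
        storms = random_storms(cfg.n_storms, w, baseflow,
                               int(dis_rng.integers(0, 2 ** 31 - 1)))
        q = generate_discharge(w, baseflow, storms,
                               int(dis_rng.integers(0, 2 ** 31 - 1)),
                               n_days=cfg.n_days)
        for day, qv in enumerate(q):
            dis_rows.append({"site_id": s.site_id, "day": day,
                             "q_m3s": float(qv)})
    discharge = pd.DataFrame(dis_rows)

    # bioactivity tables: agricultural compounds are the most potent, so
    # that cluster A dominates mixture risk as in mixed-use stream cohorts
    tox_rng = np.random.default_rng(seeds["tox"])
    acc_rows, ssd_rows = [], []
    for comp in suspect_names:
        potent = truth.source_cluster[comp] == "A"
        acc_med = 5.0e4 if potent else 5.0e5
        for endpoint in ("nuclear_receptor", "oxidoreductase"):
            acc_rows.append({
                "compound": comp, "endpoint": endpoint,
                "acc_ng_per_l": float(
                    acc_med * np.exp(tox_rng.normal(0.0, 1.0)))})
        # log10 acute SSD means around 60-160 ug/L keep site msPAF in the
        # few-percent range typical of mixed-use stream cohorts
        mu = float(tox_rng.normal(4.8 if potent else 5.2, 0.3))
        sig = float(tox_rng.uniform(0.6, 1.0))
        ssd_rows.append({"compound": comp, "mu_log10": mu,
                         "sigma_log10": sig})
    acc = pd.DataFrame(acc_rows)
    ssd = pd.DataFrame(ssd_rows)

    library_spectra = {comp: features.fragments[fid]
                       for fid, comp in feature_compound.items()
                       if fid in features.fragments}

    return SyntheticCohort(
        config=cfg, sites=sites, windows=windows, truth=truth,
        suspects=suspects, measurements=measurements, grabs=grabs,
        features=features, feature_compound=feature_compound,
        discharge=discharge, acc=acc, ssd=ssd,
        library_spectra=library_spectra)


# ---------------------------------------------------------------------------
# Flat-file output


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Write the cohort as the pipeline's canonical CSV set + truth.json."""
    os.makedirs(outdir, exist_ok=True)
    cohort.sites_frame.to_csv(os.path.join(outdir, "sites.csv"))
    conc_rows = []
    for site_id, comps in cohort.truth.c_w.items():
        for comp, series in comps.items():
            for day, v in enumerate(series):
                conc_rows.append((site_id, comp, day, v))
    pd.DataFrame(conc_rows, columns=["site_id", "compound", "day",
                                     "c_w_ng_per_l"]
                 ).to_csv(os.path.join(outdir, "concentrations.csv"),
                          index=False)
    cohort.measurements.to_csv(os.path.join(outdir, "pocis.csv"), index=False)
    cohort.grabs.to_csv(os.path.join(outdir, "grab.csv"), index=False)
    cohort.features.write(outdir)
    cohort.discharge.to_csv(os.path.join(outdir, "discharge.csv"), index=False)
    cohort.acc.to_csv(os.path.join(outdir, "acc.csv"), index=False)
    cohort.ssd.to_csv(os.path.join(outdir, "ssd.csv"), index=False)
    pd.DataFrame(
        [{"name": s.name, "formula": s.formula,
          "monoisotopic_mass": s.monoisotopic_mass,
          "compound_class": s.compound_class,
          "is_indicator": s.is_indicator} for s in cohort.suspects]
    ).to_csv(os.path.join(outdir, "suspects.csv"), index=False)
    lib_rows = [{"compound": comp, "frag_mz": mz, "rel_intensity": ri}
                for comp, spec in sorted(cohort.library_spectra.items())
                for mz, ri in spec]
    pd.DataFrame(lib_rows).to_csv(
        os.path.join(outdir, "library_spectra.csv"), index=False)
    windows = [{"site_id": w.site_id, "start_day": w.start_day,
                "end_day": w.end_day}
               for w in cohort.windows.values()]
    pd.DataFrame(windows).to_csv(os.path.join(outdir, "windows.csv"),
                                 index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({
            "source_cluster": cohort.truth.source_cluster,
            "true_r_s": cohort.truth.true_r_s,
            "planted_nontarget_ids": cohort.truth.planted_nontarget_ids,
            "effect_sizes": cohort.truth.effect_sizes,
            "noise": cohort.truth.noise,
            "indicator_compounds": cohort.truth.indicator_compounds,
            "alpha_log10": cohort.truth.alpha_log10,
            "loq_ng_per_l": cohort.truth.loq_ng_per_l,
            "compound_formula": cohort.truth.compound_formula,
            "feature_compound": cohort.feature_compound,
        }, fh, indent=1, sort_keys=True)
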