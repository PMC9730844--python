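"""Pipeline orchestration: simulate -> screen -> cluster -> prioritize ->
calibrate -> loads -> risk, with a manifest and table validation.

Every stage reads and writes flat CSVs in one run directory, so any stage
can be re-run from its persisted inputs and the whole run is diff-able.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import clustering, kinetics, loads as loads_mod, nontarget, risk as risk_mod
from . import screening, synthetic_data
from .config import RunConfig
from .featuretable import FeatureTable
from .types import DeploymentWindow, InvalidArgument, StreamScreenError

log = logging.getLogger("streamscreen")


@dataclass
class RunManifest:
    config_hash: str
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, rows_in: int, rows_out: int,
               elapsed: float) -> None:
        self.stages[stage] = {"rows_in": rows_in, "rows_out": rows_out,
                              "elapsed_s": round(elapsed, 3)}
        log.info("stage=%s rows_in=%d rows_out=%d elapsed=%.2fs",
                 stage, rows_in, rows_out, elapsed)

    def write(self, outdir: str) -> None:
        path = os.path.join(outdir, "manifest.json")
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump({"config_hash": self.config_hash,
                       "version": self.version,
                       "stages": self.stages}, fh, indent=1, sort_keys=True)
        os.replace(tmp, path)

    def stable_signature(self) -> dict:
        """Manifest content without wall times (determinism checks)."""
        return {"config_hash": self.config_hash,
                "stages": {s: {k: v for k, v in d.items()
                               if k != "elapsed_s"}
                           for s, d in self.stages.items()}}


def _read_windows(outdir: str) -> dict[str, DeploymentWindow]:
    df = pd.read_csv(os.path.join(outdir, "windows.csv"))
    return {r["site_id"]: DeploymentWindow(site_id=r["site_id"],
                                           start_day=int(r["start_day"]),
                                           end_day=int(r["end_day"]))
            for _, r in df.iterrows()}


def _read_suspects(outdir: str):
    df = pd.read_csv(os.path.join(outdir, "suspects.csv"))
    from .types import SuspectCompound
    return [SuspectCompound(name=r["name"], formula=r["formula"],
                            monoisotopic_mass=float(r["monoisotopic_mass"]),
                            compound_class=r["compound_class"],
                            is_indicator=bool(r["is_indicator"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig, outdir: str) -> int:
    cohort = synthetic_data.simulate_cohort(config.simulate, seed=config.seed)
    synthetic_data.write_cohort(cohort, outdir)
    return len(cohort.measurements)


def stage_suspect(config: RunConfig, outdir: str) -> int:
    meas = pd.read_csv(os.path.join(outdir, "pocis.csv"))
    suspects = _read_suspects(outdir)
    indicators = [s.name for s in suspects if s.is_indicator]
    summary = screening.detection_summary(meas, indicator_compounds=indicators)
    summary.to_csv(os.path.join(outdir, "detections.csv"), index=False)
    # suspect matches of the feature table (mass + isotope-fit screen)
    table = FeatureTable.read(outdir)
    adduct = (screening.PROTON_MASS if config.screening.polarity == "positive"
              else -screening.PROTON_MASS)
    hits = screening.match_mass_table(table.meta["mz"].to_numpy(float),
                                      suspects, tol_ppm=config.screening.tol_ppm,
                                      adduct_mass=adduct)
    rows = []
    for fid, cands in zip(table.meta.index, hits):
        env = table.envelopes.get(fid)
        for c in cands:
            fit = np.nan
            if env:
                fit = screening.isotope_fit(
                    env, screening.isotope_pattern(c.formula))
            if not env or fit > config.screening.isofit_min:
                rows.append({"feature_id": fid, "compound": c.name,
                             "isotope_fit": fit})
    pd.DataFrame(rows, columns=["feature_id", "compound", "isotope_fit"]
                 ).to_csv(os.path.join(outdir, "suspect_matches.csv"),
                          index=False)
    return len(summary)


def _levels_matrix(meas: pd.DataFrame) -> pd.DataFrame:
    """Sites x compounds levels for clustering: per compound, whichever of
    m_POCIS / c_grab is quantified at more sites (union convention);
    nondetects become NaN."""
    m = meas.copy()
    for col in ("m_pocis", "c_grab"):
        nd = f"{col}_nondetect"
        if nd in m:
            m.loc[m[nd].fillna(False).astype(bool), col] = np.nan
    pm = m.pivot(index="site_id", columns="compound", values="m_pocis")
    pg = m.pivot(index="site_id", columns="compound", values="c_grab")
    cols = {}
    for comp in pm.columns:
        cols[comp] = pm[comp] if pm[comp].notna().sum() >= pg[comp].notna().sum() \
            else pg[comp]
    return pd.DataFrame(cols)


def stage_cluster(config: RunConfig, outdir: str) -> int:
    meas = pd.read_csv(os.path.join(outdir, "pocis.csv"))
    sites = pd.read_csv(os.path.join(outdir, "sites.csv"), index_col="site_id")
    levels = _levels_matrix(meas)
    matrix, labels, ann = clustering.cluster_items(
        levels, sites, k=config.clustering.k, alpha=config.clustering.alpha)
    matrix.rho.rename_axis("compound").to_csv(os.path.join(outdir, "rho.csv"))
    matrix.pvalue.rename_axis("compound").to_csv(
        os.path.join(outdir, "pvalues.csv"))
    pd.DataFrame(sorted(labels.items()), columns=["compound", "cluster"]
                 ).to_csv(os.path.join(outdir, "clusters.csv"), index=False)
    ann.to_csv(os.path.join(outdir, "correlation_annotations.csv"),
               index=False)
    return len(labels)


def stage_nontarget(config: RunConfig, outdir: str) -> int:
    table = FeatureTable.read(outdir)
    sites = pd.read_csv(os.path.join(outdir, "sites.csv"), index_col="site_id")
    suspects = _read_suspects(outdir)
    ncfg = config.nontarget
    result = nontarget.prioritize(
        table, sites, suspects, min_intensity=ncfg.min_intensity,
        min_similarity=ncfg.isofit_min, alpha=ncfg.alpha,
        tol_ppm=ncfg.tol_ppm)
    pri = result.prioritized
    # co-cluster survivors with the indicator mixture
    meas = pd.read_csv(os.path.join(outdir, "pocis.csv"))
    indicators = [s.name for s in suspects if s.is_indicator]
    ind_levels = meas[meas["compound"].isin(indicators)].pivot(
        index="site_id", columns="compound", values="m_pocis")
    if len(pri) and not ind_levels.isna().any().any():
        labels = nontarget.cocluster_with_indicators(
            table, list(pri.index), ind_levels, sites,
            k=config.clustering.k)
        pri["cluster"] = [labels[f] for f in pri.index]
    else:
        pri["cluster"] = ""
    # spectral match factors against the library
    lib_path = os.path.join(outdir, "library_spectra.csv")
    library: dict[str, list[tuple[float, float]]] = {}
    if os.path.exists(lib_path):
        lib = pd.read_csv(lib_path)
        for comp, g in lib.groupby("compound"):
            library[str(comp)] = list(zip(g["frag_mz"], g["rel_intensity"]))
    matches, factors = [], []
    for fid in pri.index:
        frags = table.fragments.get(fid)
        if frags and library:
            name, score = nontarget.best_library_match(frags, library)
        else:
            name, score = "", np.nan
        matches.append(name)
        factors.append(score)
    pri["library_match"] = matches
    pri["match_factor"] = factors
    pri["confirmed"] = pri["match_factor"] > ncfg.match_min
    out = pri.join(result.flags.loc[pri.index])
    out.rename_axis("feature_id").to_csv(
        os.path.join(outdir, "prioritized.csv"))
    result.flags.to_csv(os.path.join(outdir, "criteria_flags.csv"))
    return len(pri)


def stage_calibrate(config: RunConfig, outdir: str) -> int:
    meas = pd.read_csv(os.path.join(outdir, "pocis.csv"))
    estimates = kinetics.estimate_rs_table(
        meas, min_pairs=config.kinetics.min_pairs,
        intercept=config.kinetics.intercept)
    accepted = kinetics.filter_by_fit(estimates, min_r2=config.kinetics.min_r2)
    kinetics.rates_frame(estimates).to_csv(
        os.path.join(outdir, "sampling_rates.csv"), index=False)
    twa = kinetics.twa_table(meas, accepted)
    twa.to_csv(os.path.join(outdir, "twa.csv"), index=False)
    return len(accepted)


def stage_loads(config: RunConfig, outdir: str) -> int:
    twa = pd.read_csv(os.path.join(outdir, "twa.csv"))
    grabs = pd.read_csv(os.path.join(outdir, "grab.csv"))
    discharge = pd.read_csv(os.path.join(outdir, "discharge.csv"))
    windows = _read_windows(outdir)
    q_by_site = {s: g.sort_values("day")["q_m3s"].to_numpy(float)
                 for s, g in discharge.groupby("site_id")}
    twa_loads, grab_loads = [], []
    for _, r in twa.iterrows():
        if r.get("nondetect", False) or not np.isfinite(r["c_twa_ng_per_l"]):
            continue
        w = windows[r["site_id"]]
        est = loads_mod.time_weighted_load(
            [(w.start_day, float(r["c_twa_ng_per_l"]))],
            q_by_site[r["site_id"]], w, site_id=r["site_id"],
            compound=r["compound"], method="TWA",
            c_sd=float(r.get("c_twa_sd", 0.0) or 0.0))
        twa_loads.append(est)
    accepted = set(twa["compound"].unique())
    for (site, comp), g in grabs.groupby(["site_id", "compound"]):
        if comp not in accepted:
            continue
        w = windows[site]
        quant = g[~g["loq_flag"].astype(bool)]
        if quant.empty:
            continue
        samples = list(zip(quant["day"].astype(float),
                           quant["c_grab_ng_per_l"].astype(float)))
        est = loads_mod.time_weighted_load(
            samples, q_by_site[site], w, site_id=site, compound=comp,
            method="grab")
        grab_loads.append(est)
    lt = loads_mod.loads_frame(twa_loads)
    lg = loads_mod.loads_frame(grab_loads)
    pd.concat([lt, lg], ignore_index=True).to_csv(
        os.path.join(outdir, "loads.csv"), index=False)
    comparison = loads_mod.compare_loads(lt, lg, group_by=None)
    by_comp = loads_mod.compare_loads(lt, lg, group_by="compound")
    by_site = loads_mod.compare_loads(lt, lg, group_by="site_id")
    comparison["grouping"] = "all"
    by_comp["grouping"] = "compound"
    by_site["grouping"] = "site"
    pd.concat([comparison, by_comp, by_site], ignore_index=True).to_csv(
        os.path.join(outdir, "load_ratios.csv"), index=False)
    return len(lt) + len(lg)


def stage_risk(config: RunConfig, outdir: str) -> int:
    twa = pd.read_csv(os.path.join(outdir, "twa.csv"))
    acc = pd.read_csv(os.path.join(outdir, "acc.csv"))
    ssd = pd.read_csv(os.path.join(outdir, "ssd.csv"))
    r_twa = risk_mod.risk_table(
        twa, acc, ssd, conc_col="c_twa_ng_per_l", sd_col="c_twa_sd",
        aggregation=config.risk.aggregation, n_draws=config.risk.n_draws,
        seed=config.seed)
    r_twa["basis"] = "TWA"
    meas = pd.read_csv(os.path.join(outdir, "pocis.csv"))
    grab_conc = meas.loc[~meas["c_grab_nondetect"].astype(bool),
                         ["site_id", "compound", "c_grab", "c_grab_sd"]]
    r_grab = risk_mod.risk_table(
        grab_conc, acc, ssd, conc_col="c_grab", sd_col="c_grab_sd",
        aggregation=config.risk.aggregation, n_draws=config.risk.n_draws,
        seed=config.seed)
    r_grab["basis"] = "grab"
    pd.concat([r_twa, r_grab], ignore_index=True).to_csv(
        os.path.join(outdir, "risk.csv"), index=False)
    return len(r_twa) + len(r_grab)


_STAGES = [
    ("simulate", stage_simulate),
    ("suspect", stage_suspect),
    ("cluster", stage_cluster),
    ("nontarget", stage_nontarget),
    ("calibrate", stage_calibrate),
    ("loads", stage_loads),
    ("risk", stage_risk),
]


def run_all(config: RunConfig, outdir: str) -> RunManifest:
    """Execute all stages in dependency order; any stage failure aborts
    with the stage name and cause."""
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash())
    rows_prev = 0
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            rows_out = fn(config, outdir)
        except Exception as exc:
            raise StreamScreenError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, rows_prev, rows_out, time.perf_counter() - t0)
        rows_prev = rows_out
    manifest.write(outdir)
    return manifest


# ---------------------------------------------------------------------------
# Table validation


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    checked: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def _check(df: pd.DataFrame, mask: pd.Series, message: str,
           report: ValidationReport) -> None:
    bad = df.index[mask]
    for idx in bad[:20]:
        report.issues.append(f"{message} (row {idx})")


def validate_tables(outdir: str) -> ValidationReport:
    """Schema and invariant checks on every known CSV in a run directory.

    Columns are matched by name, not position. Missing files are listed
    but not fatal.
    """
    report = ValidationReport()

    def load(name: str, **kw):
        path = os.path.join(outdir, name)
        if not os.path.exists(path):
            report.missing.append(name)
            return None
        report.checked.append(name)
        return pd.read_csv(path, **kw)

    sites = load("sites.csv")
    if sites is not None:
        need = {"site_id", "ag_pct", "dev_pct"}
        if not need.issubset(sites.columns):
            report.issues.append(f"sites.csv missing columns {need - set(sites.columns)}")
        else:
            _check(sites, sites["ag_pct"] + sites["dev_pct"] > 100 + 1e-9,
                   "sites.csv: ag_pct + dev_pct > 100", report)
            for col in ("septic_density", "wwtp_capacity", "road_density",
                        "rpi", "pop_density", "cafo_count"):
                if col in sites:
                    _check(sites, sites[col] < 0,
                           f"sites.csv: negative {col}", report)
    pocis = load("pocis.csv")
    if pocis is not None:
        _check(pocis, pocis["m_pocis"] < 0,
               "pocis.csv: negative m_pocis", report)
        _check(pocis, pocis["c_grab"] < 0,
               "pocis.csv: negative c_grab", report)
    grab = load("grab.csv")
    if grab is not None:
        _check(grab, grab["c_grab_ng_per_l"] < 0,
               "grab.csv: negative concentration", report)
    rho = load("rho.csv", index_col=0)
    if rho is not None:
        if (rho.abs() > 1 + 1e-9).any().any():
            report.issues.append("rho.csv: |rho| > 1")
    pv = load("pvalues.csv", index_col=0)
    if pv is not None:
        vals = pv.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            report.issues.append("pvalues.csv: p outside [0, 1]")
    disc = load("discharge.csv")
    if disc is not None:
        _check(disc, disc["q_m3s"] <= 0,
               "discharge.csv: nonpositive discharge", report)
    ld = load("loads.csv")
    if ld is not None and len(ld):
        _check(ld, ld["load_g_per_d"] < 0,
               "loads.csv: negative load", report)
    rk = load("risk.csv")
    if rk is not None and len(rk):
        _check(rk, (rk["mspaf"] < 0) | (rk["mspaf"] > 1),
               "risk.csv: msPAF outside [0, 1]", report)
        _check(rk, rk["sum_ear"] < 0,
               "risk.csv: negative cumulative EAR", report)
    feats = load("features.csv", index_col="feature_id")
    if feats is not None:
        num = feats.select_dtypes("number")
        site_cols = [c for c in num.columns if c.startswith("site")]
        if site_cols and (num[site_cols] < 0).any().any():
            report.issues.append("features.csv: negative intensity")
        if "mz" in feats and (feats["mz"] <= 0).any():
            report.issues.append("features.csv: nonpositive m/z")
    twa = load("twa.csv")
    if twa is not None and len(twa):
        quant = twa[~twa["nondetect"].astype(bool)]
        _check(quant, quant["c_twa_ng_per_l"] < 0,
               "twa.csv: negative TWA concentration", report)
    return report
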