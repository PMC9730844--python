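"""Nontarget feature prioritization.

Mass-spectral features from POCIS extracts are retained when they satisfy
four criteria:

(a) maximum cross-site peak intensity above a threshold (default 1e5);
(b) isotope-envelope similarity to the candidate formula's theoretical
    pattern of at least 0.90 (features without an envelope are rejected);
(c) detected at every site (intensity above 3x the field-blank level)
    and absent from the suspect database within the mass tolerance;
(d) z-score standardized intensities positively and significantly
    (two-sided p < alpha on positive rho) rank-correlated with at least
    one anthropogenic watershed attribute.

Survivors are co-clustered with the indicator compounds to inherit a
source label (A/B/C) and scored against library fragment spectra with a
greedy-cosine spectral match factor (0-100, confirmation cutoff 70).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, screening
from .featuretable import FeatureTable
from .types import InvalidArgument, SuspectCompound

#: Default criteria thresholds.
MIN_INTENSITY = 1.0e5
MIN_ISOTOPE_SIMILARITY = 0.90
ALPHA = 0.05
MATCH_FACTOR_MIN = 70.0
BLANK_FACTOR = 3.0


def detected_matrix(table: FeatureTable,
                    blank_factor: float = BLANK_FACTOR) -> pd.DataFrame:
    """Boolean features x sites: intensity above blank_factor x field blank."""
    blank = table.meta["blank_intensity"].to_numpy(float)[:, None]
    return table.intensities.gt(blank_factor * blank)


def filter_intensity(table: FeatureTable,
                     min_intensity: float = MIN_INTENSITY) -> list[str]:
    """Criterion (a): features whose maximum cross-site intensity reaches
    ``min_intensity``."""
    if min_intensity <= 0:
        raise InvalidArgument("min_intensity must be positive")
    keep = table.intensities.max(axis=1) >= min_intensity
    return list(table.meta.index[keep])


def filter_formula_fit(table: FeatureTable,
                       min_similarity: float = MIN_ISOTOPE_SIMILARITY
                       ) -> tuple[list[str], dict[str, str]]:
    """Criterion (b): isotope-envelope similarity >= ``min_similarity``.

    The measured envelope is scored against the theoretical pattern of the
    candidate formula with the L1-based isotope fit (scaled to [0, 1]).
    Features without a candidate formula or measured envelope are rejected.
    Returns (survivor ids, rejection reasons for the rest).
    """
    keep, reasons = [], {}
    for fid, row in table.meta.iterrows():
        formula = row.get("formula", "")
        if not isinstance(formula, str) or not formula:
            reasons[fid] = "no_candidate_formula"
            continue
        env = table.envelopes.get(fid)
        if not env:
            reasons[fid] = "no_measured_envelope"
            continue
        theo = screening.isotope_pattern(formula)
        score = screening.isotope_fit(env, theo) / 100.0
        if score >= min_similarity:
            keep.append(fid)
        else:
            reasons[fid] = f"isotope_fit={score:.3f}"
    return keep, reasons


def filter_ubiquity_and_novelty(table: FeatureTable,
                                site_ids: Sequence[str],
                                suspect_db: Sequence[SuspectCompound],
                                tol_ppm: float = 5.0,
                                adduct_mass: float = screening.PROTON_MASS,
                                blank_factor: float = BLANK_FACTOR
                                ) -> list[str]:
    """Criterion (c): present at every site and not in the suspect database.

    Presence means intensity above ``blank_factor`` times the feature's
    field-blank intensity; novelty means no suspect-database compound
    matches the feature's neutral mass within ``tol_ppm``.
    """
    if not list(site_ids):
        raise InvalidArgument("site list must be nonempty")
    det = detected_matrix(table, blank_factor)[list(site_ids)]
    ubiquitous = det.all(axis=1)
    hits = screening.match_mass_table(
        table.meta["mz"].to_numpy(float), list(suspect_db),
        tol_ppm=tol_ppm, adduct_mass=adduct_mass)
    novel = np.array([len(h) == 0 for h in hits])
    keep = ubiquitous.to_numpy() & novel
    return list(table.meta.index[keep])


def filter_attribute_correlation(table: FeatureTable,
                                 attributes: pd.DataFrame,
                                 alpha: float = ALPHA,
                                 attribute_subset: Optional[Sequence[str]] = None
                                 ) -> pd.DataFrame:
    """Criterion (d): significant positive rank correlation with at least
    one anthropogenic attribute.

    Intensities are z-score standardized across sites before correlation
    (rank correlations are unchanged by this monotone step; it mirrors the
    screening convention). Returns a frame indexed by surviving feature id
    with the best attribute and its rho and p.
    """
    if len(attributes) < 4:
        raise InvalidArgument("need at least 4 sites")
    attrs = attributes[list(attribute_subset)] if attribute_subset else attributes
    levels = table.intensities.T.loc[attrs.index]
    matrix = clustering.spearman_matrix(levels, attrs)
    rho = matrix.rho.to_numpy()
    p = matrix.pvalue.to_numpy()
    sig = (rho > 0) & (p < alpha)
    rows = []
    for i, fid in enumerate(matrix.rho.index):
        if not sig[i].any():
            continue
        best = np.nanargmax(np.where(sig[i], rho[i], -np.inf))
        rows.append({"feature_id": fid,
                     "best_attribute": matrix.rho.columns[best],
                     "rho": float(rho[i, best]),
                     "pvalue": float(p[i, best])})
    return pd.DataFrame(rows).set_index("feature_id") if rows else \
        pd.DataFrame(columns=["best_attribute", "rho", "pvalue"])


def spectral_match(query: Sequence[tuple[float, float]],
                   library: Sequence[tuple[float, float]],
                   mz_tol: float = 0.01) -> float:
    """Greedy-cosine spectral match factor in [0, 100].

    Candidate peak pairs within ``mz_tol`` Da are accepted greedily by
    descending intensity product (mass distance breaks ties); the score is
    the cosine similarity between the aligned intensity vectors (unmatched
    peaks contribute zero overlap), times 100. Symmetric in its arguments.
    """
    if not query or not library:
        raise InvalidArgument("spectra must be nonempty")
    q = np.asarray(query, dtype=float)
    l = np.asarray(library, dtype=float)
    # all in-tolerance pairs, greedily accepted by descending intensity
    # product (mass distance breaks ties) — symmetric by construction
    pairs = [(-q[i, 1] * l[j, 1], abs(q[i, 0] - l[j, 0]), i, j)
             for i in range(len(q)) for j in range(len(l))
             if abs(q[i, 0] - l[j, 0]) <= mz_tol]
    pairs.sort()
    used_q = np.zeros(len(q), dtype=bool)
    used_l = np.zeros(len(l), dtype=bool)
    dot = 0.0
    for neg_prod, _, i, j in pairs:
        if used_q[i] or used_l[j]:
            continue
        used_q[i] = used_l[j] = True
        dot -= neg_prod
    norm = np.linalg.norm(q[:, 1]) * np.linalg.norm(l[:, 1])
    return float(100.0 * dot / norm) if norm > 0 else 0.0


def best_library_match(fragments: Sequence[tuple[float, float]],
                       library: dict[str, Sequence[tuple[float, float]]],
                       mz_tol: float = 0.01) -> tuple[str, float]:
    """Best-scoring library entry for a fragment spectrum."""
    best_name, best_score = "", 0.0
    for name in sorted(library):
        s = spectral_match(fragments, library[name], mz_tol=mz_tol)
        if s > best_score:
            best_name, best_score = name, s
    return best_name, best_score


@dataclass
class PrioritizationResult:
    """Survivor table plus per-criterion flags for every input feature."""

    prioritized: pd.DataFrame     # survivors with rho/p, cluster, match factor
    flags: pd.DataFrame           # all features x criteria a..d (boolean)


def prioritize(table: FeatureTable, attributes: pd.DataFrame,
               suspect_db: Sequence[SuspectCompound],
               min_intensity: float = MIN_INTENSITY,
               min_similarity: float = MIN_ISOTOPE_SIMILARITY,
               alpha: float = ALPHA, tol_ppm: float = 5.0,
               attribute_subset: Optional[Sequence[str]] = None
               ) -> PrioritizationResult:
    """Apply criteria (a)-(d); filters commute, so each is evaluated on the
    full table and survivors are the intersection."""
    ids = list(table.meta.index)
    a = set(filter_intensity(table, min_intensity))
    b = set(filter_formula_fit(table, min_similarity)[0])
    c = set(filter_ubiquity_and_novelty(
        table, list(attributes.index), suspect_db, tol_ppm=tol_ppm))
    dtab = filter_attribute_correlation(
        table, attributes, alpha=alpha, attribute_subset=attribute_subset)
    d = set(dtab.index)
    flags = pd.DataFrame({
        "criterion_a_intensity": [f in a for f in ids],
        "criterion_b_isotope_fit": [f in b for f in ids],
        "criterion_c_ubiquitous_novel": [f in c for f in ids],
        "criterion_d_attribute_correlation": [f in d for f in ids],
    }, index=pd.Index(ids, name="feature_id"))
    survivors = sorted(a & b & c & d)
    pri = table.meta.loc[survivors, ["mz", "rt", "formula"]].copy()
    pri = pri.join(dtab.loc[survivors])
    return PrioritizationResult(prioritized=pri, flags=flags)


def cocluster_with_indicators(table: FeatureTable,
                              prioritized_ids: Sequence[str],
                              indicator_levels: pd.DataFrame,
                              attributes: pd.DataFrame,
                              k: int = 3) -> dict[str, str]:
    """Joint Ward clustering of prioritized features and indicator compounds.

    ``indicator_levels``: sites x indicator-compound levels (must cover all
    sites). Rows of the joint Spearman matrix (features + indicators vs
    attributes) are clustered; with k = 3 each feature inherits the A/B/C
    label of its cluster.
    """
    if indicator_levels.isna().any().any():
        raise InvalidArgument("indicator measurements must cover all sites")
    feat_levels = table.intensities.T.loc[attributes.index, list(prioritized_ids)]
    joint = pd.concat([feat_levels, indicator_levels.loc[attributes.index]],
                      axis=1)
    matrix = clustering.spearman_matrix(joint, attributes)
    assignment = clustering.ward_cluster(matrix, k=k)
    return clustering.label_clusters(assignment, matrix)
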