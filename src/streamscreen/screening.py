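"""Suspect screening: exact-mass matching against a compound database,
theoretical isotope envelopes and isotope-pattern fit scoring,
internal-standard quantification, and detection summaries.

The screening logic mirrors the standard vendor workflow for full-scan
LC-HRMS data: a feature is a candidate for a database compound when its
neutral mass agrees within a ppm tolerance and its measured isotope
envelope resembles the envelope predicted from the molecular formula.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .types import (
    CalibrationCurve,
    InvalidArgument,
    StreamScreenError,
    SuspectCompound,
)

#: Proton mass; adduct offsets for the two adducts handled ([M+H]+, [M-H]-).
PROTON_MASS = 1.00727646688
ADDUCT_MASSES = {"[M+H]+": PROTON_MASS, "[M-H]-": -PROTON_MASS}

#: Elements supported by the isotope-envelope convolution.
SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P", "Cl", "Br", "F")

#: The fourteen most frequently detected compounds across sites; their summed
#: levels serve as an indicator mixture proxying total contamination.
INDICATOR_COMPOUNDS = (
    "2,4-D",
    "atrazine",
    "atrazine-2-hydroxy",
    "atrazine-desethyl",
    "benzothiazole",
    "DEET",
    "galaxolidone",
    "lamotrigine",
    "lidocaine",
    "methyl-1H-benzotriazole",
    "metolachlor",
    "metolachlor ethanesulfonic acid",
    "metolachlor oxanilic acid",
    "sucralose",
)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C8H10N4O2`` into element counts.

    Raises InvalidArgument for elements outside the supported set
    (C, H, N, O, S, P, Cl, Br, F) or malformed input.
    """
    if not formula or not formula.strip():
        raise InvalidArgument("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise InvalidArgument(f"malformed formula: {formula!r}")
        pos = m.end()
        if not m.group(0):
            break
        el = m.group(1)
        if el not in SUPPORTED_ELEMENTS:
            raise InvalidArgument(f"unsupported element {el!r} in {formula!r}")
        n = int(m.group(2) or 1)
        if n <= 0:
            raise InvalidArgument(f"nonpositive count for {el} in {formula!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula.strip()) or not counts:
        raise InvalidArgument(f"malformed formula: {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (lightest-isotope) mass of a formula in Da."""
    parse_formula(formula)  # restrict element set before delegating
    return float(_ptmass.calculate_mass(formula=formula))


def _element_isotopes(element: str) -> list[tuple[float, float]]:
    """(mass, abundance) pairs for the naturally occurring isotopes."""
    table = _ptmass.nist_mass[element]
    return [(m, a) for key, (m, a) in table.items() if key != 0 and a > 0.0]


def isotope_pattern(formula: str, min_rel_abundance: float = 0.1
                    ) -> list[tuple[float, float]]:
    """Theoretical isotope envelope of a molecular formula.

    Convolves the natural isotope distributions of the constituent elements
    and aggregates the fine structure into nominal-mass isotopologue peaks
    (M, M+1, M+2, ...), the resolution at which vendor isotope-fit scores
    operate.

    Parameters
    ----------
    formula:
        Molecular formula restricted to C, H, N, O, S, P, Cl, Br, F.
    min_rel_abundance:
        Truncation threshold in percent of the base peak (default 0.1).

    Returns
    -------
    list of (mass offset from the monoisotopic peak in Da, relative
    abundance normalized to base peak = 100), sorted by offset.
    """
    counts = parse_formula(formula)
    # peaks: dict mass -> probability; start from the trivial distribution
    peaks: dict[float, float] = {0.0: 1.0}
    prune = 1e-8
    for el, n in counts.items():
        isotopes = _element_isotopes(el)
        lightest = min(m for m, _ in isotopes)
        # distribution of mass excess contributed by one atom
        single = [(m - lightest, a) for m, a in isotopes]
        # binary exponentiation of the single-atom distribution
        acc: dict[float, float] = {0.0: 1.0}
        base = {round(dm, 6): a for dm, a in single}
        k = n
        while k:
            if k & 1:
                acc = _convolve(acc, base, prune)
            k >>= 1
            if k:
                base = _convolve(base, base, prune)
        peaks = _convolve(peaks, acc, prune)

    mono = monoisotopic_mass(formula)
    # aggregate fine structure by nominal offset, abundance-weighted mass
    agg: dict[int, list[float]] = {}
    for dm, p in peaks.items():
        key = int(round(dm))
        slot = agg.setdefault(key, [0.0, 0.0])
        slot[0] += p
        slot[1] += p * dm
    out = []
    for key in sorted(agg):
        p, wm = agg[key]
        out.append((wm / p, p))
    base_peak = max(p for _, p in out)
    envelope = [(dm, 100.0 * p / base_peak) for dm, p in out
                if 100.0 * p / base_peak >= min_rel_abundance]
    return envelope


def _convolve(a: dict[float, float], b: dict[float, float],
              prune: float) -> dict[float, float]:
    out: dict[float, float] = {}
    for ma, pa in a.items():
        for mb, pb in b.items():
            p = pa * pb
            if p < prune:
                continue
            key = round(ma + mb, 6)
            out[key] = out.get(key, 0.0) + p
    return out


def isotope_fit(measured: Sequence[tuple[float, float]],
                theoretical: Sequence[tuple[float, float]],
                align_tol: float = 0.010) -> float:
    """Isotope-pattern fit score in [0, 100].

    Both envelopes are (mass offset, relative abundance) lists. Abundances
    are renormalized to sum to 1; peaks are aligned greedily within
    ``align_tol`` Da (10 mDa default); the score is
    ``100 * (1 - L1/2)`` where L1 is the total absolute difference over
    aligned pairs plus the full mass of unmatched peaks on either side.
    Identical envelopes score 100; envelopes with no aligned peaks score 0.
    """
    if not measured or not theoretical:
        raise InvalidArgument("envelopes must be nonempty")
    m = np.asarray(measured, dtype=float)
    t = np.asarray(theoretical, dtype=float)
    pm = m[:, 1] / m[:, 1].sum()
    pt = t[:, 1] / t[:, 1].sum()

    used = np.zeros(len(t), dtype=bool)
    l1 = 0.0
    for i in np.argsort(-pm):  # heavier measured peaks claim partners first
        d = np.abs(t[:, 0] - m[i, 0])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= align_tol:
            used[j] = True
            l1 += abs(pm[i] - pt[j])
        else:
            l1 += pm[i]
    l1 += pt[~used].sum()
    return float(100.0 * max(0.0, 1.0 - 0.5 * l1))


def match_mass(feature_mz: float, db: Sequence[SuspectCompound],
               tol_ppm: float = 5.0, adduct_mass: float = PROTON_MASS
               ) -> list[SuspectCompound]:
    """Candidates whose monoisotopic mass matches the feature's neutral mass.

    The observed neutral mass is ``feature_mz - adduct_mass``; a database
    compound matches when the relative mass error is at most ``tol_ppm``
    parts per million of the candidate mass.
    """
    if tol_ppm <= 0:
        raise InvalidArgument("tol_ppm must be positive")
    neutral = feature_mz - adduct_mass
    out = []
    for c in db:
        if abs(neutral - c.monoisotopic_mass) / c.monoisotopic_mass * 1e6 <= tol_ppm:
            out.append(c)
    return out


def match_mass_table(feature_mz: np.ndarray, db: Sequence[SuspectCompound],
                     tol_ppm: float = 5.0, adduct_mass: float = PROTON_MASS
                     ) -> list[list[SuspectCompound]]:
    """Vectorized ``match_mass`` over an array of feature m/z values."""
    if tol_ppm <= 0:
        raise InvalidArgument("tol_ppm must be positive")
    neutral = np.asarray(feature_mz, dtype=float) - adduct_mass
    masses = np.array([c.monoisotopic_mass for c in db], dtype=float)
    if masses.size == 0:
        return [[] for _ in neutral]
    err = np.abs(neutral[:, None] - masses[None, :]) / masses[None, :] * 1e6
    hit = err <= tol_ppm
    return [[db[j] for j in np.flatnonzero(row)] for row in hit]


def quantify(area: float, is_area: float, curve: CalibrationCurve,
             loq: float = 0.0) -> tuple[Optional[float], bool]:
    """Invert an internal-standard calibration curve.

    Returns ``(concentration, nondetect_flag)`` in the curve's concentration
    units. The flag is True when the back-calculated value falls below the
    limit of quantification; the value itself is retained for transparency.
    """
    if is_area <= 0:
        raise StreamScreenError("internal-standard area must be positive")
    ratio = area / is_area
    conc = (ratio - curve.intercept) / curve.slope
    nondetect = conc < loq
    return conc, nondetect


def detection_summary(measurements: pd.DataFrame,
                      indicator_compounds: Iterable[str] = INDICATOR_COMPOUNDS
                      ) -> pd.DataFrame:
    """Per-site detection summary of a long measurement table.

    ``measurements`` columns: site_id, compound, and any of
    m_pocis (ng/d), c_grab (ng/L), with boolean nondetect columns
    m_pocis_nondetect / c_grab_nondetect (missing columns treated as all
    detected where the value is present).

    Returns one row per site with cumulative daily POCIS mass
    (sum_m_pocis), cumulative grab concentration (sum_c_grab), detection
    frequency over compounds, and the same sums restricted to the indicator
    mixture. Sums cover quantified (non-nondetect, non-missing) values only.
    """
    df = measurements.copy()
    indicator = set(indicator_compounds)
    rows = []
    n_compounds = df["compound"].nunique()
    for site, g in df.groupby("site_id", sort=True):
        row: dict = {"site_id": site, "n_compounds": n_compounds}
        detected = pd.Series(False, index=g.index)
        for col in ("m_pocis", "c_grab"):
            if col not in g:
                row[f"sum_{col}"] = 0.0
                row[f"indicator_sum_{col}"] = 0.0
                continue
            nd_col = f"{col}_nondetect"
            quant = g[col].notna()
            if nd_col in g:
                quant &= ~g[nd_col].fillna(False).astype(bool)
            detected |= quant
            vals = g.loc[quant, col]
            row[f"sum_{col}"] = float(vals.sum())
            ind_mask = quant & g["compound"].isin(indicator)
            row[f"indicator_sum_{col}"] = float(g.loc[ind_mask, col].sum())
        n_det = int(g.loc[detected, "compound"].nunique())
        row["n_detected"] = n_det
        row["detection_frequency_pct"] = (
            100.0 * n_det / n_compounds if n_compounds else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
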