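"""In-memory container and flat-file round-trip for LC-HRMS feature tables.

A feature table couples a site x feature intensity matrix with per-feature
metadata (m/z, retention time, candidate formula, field-blank intensity),
measured isotope envelopes, and fragment spectra. On disk it is a set of
plain CSVs so every stage of the pipeline is diff-able.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import InvalidArgument


@dataclass
class FeatureTable:
    """Mass-spectral feature table.

    meta:
        indexed by feature_id with columns mz (Da), rt (min), formula
        (candidate molecular formula or empty), blank_intensity.
    intensities:
        DataFrame features x sites (arbitrary units, >= 0; 0 = not detected).
    envelopes:
        feature_id -> list of (mass offset Da, relative abundance) pairs.
    fragments:
        feature_id -> list of (fragment m/z, relative intensity) pairs.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    envelopes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    fragments: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise InvalidArgument("meta and intensity rows must align")
        if (self.intensities.to_numpy(float) < 0).any():
            raise InvalidArgument("feature intensities must be nonnegative")
        if (self.meta["mz"] <= 0).any():
            raise InvalidArgument("feature m/z must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def subset(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            meta=self.meta.loc[ids].copy(),
            intensities=self.intensities.loc[ids].copy(),
            envelopes={f: self.envelopes[f] for f in ids if f in self.envelopes},
            fragments={f: self.fragments[f] for f in ids if f in self.fragments},
        )

    # ------------------------------------------------------------------
    # flat-file round trip

    def write(self, outdir: str) -> None:
        main = self.meta.copy()
        main = main.join(self.intensities)
        main.index.name = "feature_id"
        main.to_csv(os.path.join(outdir, "features.csv"))
        env_rows = [
            {"feature_id": f, "mass_offset_da": dm, "rel_abundance": ab}
            for f, env in sorted(self.envelopes.items()) for dm, ab in env
        ]
        pd.DataFrame(env_rows, columns=["feature_id", "mass_offset_da",
                                        "rel_abundance"]
                     ).to_csv(os.path.join(outdir, "feature_envelopes.csv"),
                              index=False)
        frag_rows = [
            {"feature_id": f, "frag_mz": mz, "rel_intensity": ri}
            for f, spec in sorted(self.fragments.items()) for mz, ri in spec
        ]
        pd.DataFrame(frag_rows, columns=["feature_id", "frag_mz",
                                         "rel_intensity"]
                     ).to_csv(os.path.join(outdir, "feature_fragments.csv"),
                              index=False)

    @classmethod
    def read(cls, indir: str) -> "FeatureTable":
        main = pd.read_csv(os.path.join(indir, "features.csv"),
                           index_col="feature_id",
                           keep_default_na=True)
        meta_cols = ["mz", "rt", "formula", "blank_intensity"]
        meta = main[meta_cols].copy()
        meta["formula"] = meta["formula"].fillna("")
        intens = main.drop(columns=meta_cols).astype(float)
        envelopes: dict[str, list[tuple[float, float]]] = {}
        env_path = os.path.join(indir, "feature_envelopes.csv")
        if os.path.exists(env_path):
            for f, g in pd.read_csv(env_path).groupby("feature_id"):
                envelopes[str(f)] = list(
                    zip(g["mass_offset_da"], g["rel_abundance"]))
        fragments: dict[str, list[tuple[float, float]]] = {}
        frag_path = os.path.join(indir, "feature_fragments.csv")
        if os.path.exists(frag_path):
            for f, g in pd.read_csv(frag_path).groupby("feature_id"):
                fragments[str(f)] = list(zip(g["frag_mz"], g["rel_intensity"]))
        return cls(meta=meta, intensities=intens,
                   envelopes=envelopes, fragments=fragments)
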