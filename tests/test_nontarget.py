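"""Nontarget prioritization criteria and spectral matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from streamscreen import nontarget, screening, synthetic_data as sd
from streamscreen.featuretable import FeatureTable
from streamscreen.types import InvalidArgument, SuspectCompound


def _table(intensities: dict, sites, mz=None, formula=None, blank=10.0,
           envelopes=None, fragments=None):
    ids = list(intensities)
    meta = pd.DataFrame({
        "mz": [mz.get(f, 300.0) if mz else 300.0 for f in ids],
        "rt": 5.0,
        "formula": [formula.get(f, "") if formula else "" for f in ids],
        "blank_intensity": blank,
    }, index=pd.Index(ids, name="feature_id"))
    intens = pd.DataFrame(intensities, index=sites).T
    return FeatureTable(meta=meta, intensities=intens,
                        envelopes=envelopes or {},
                        fragments=fragments or {})


SITES = [f"s{i}" for i in range(6)]


class TestFilterIntensity:
    def test_all_below_threshold(self):
        t = _table({"f1": [1e4] * 6, "f2": [5e4] * 6}, SITES)
        assert nontarget.filter_intensity(t, 1e5) == []

    def test_max_rule_single_hot_site(self):
        t = _table({"f1": [1e3, 1e3, 2e5, 1e3, 1e3, 1e3]}, SITES)
        assert nontarget.filter_intensity(t, 1e5) == ["f1"]

    def test_matches_brute_force_scan(self, rng):
        vals = {f"f{i}": rng.uniform(0, 3e5, size=6) for i in range(50)}
        t = _table(vals, SITES)
        fast = set(nontarget.filter_intensity(t, 1e5))
        brute = {f for f, v in vals.items() if max(v) >= 1e5}
        assert fast == brute


class TestFilterFormulaFit:
    def test_exact_envelope_kept(self):
        theo = screening.isotope_pattern("C10H14N2O")
        t = _table({"f1": [1e6] * 6}, SITES,
                   formula={"f1": "C10H14N2O"},
                   envelopes={"f1": theo})
        keep, _ = nontarget.filter_formula_fit(t)
        assert keep == ["f1"]

    def test_halved_m1_matches_hand_score(self):
        theo = screening.isotope_pattern("C10H14N2O")
        distorted = [(dm, ab * (0.5 if round(dm) == 1 else 1.0))
                     for dm, ab in theo]
        t = _table({"f1": [1e6] * 6}, SITES,
                   formula={"f1": "C10H14N2O"},
                   envelopes={"f1": distorted})
        score = screening.isotope_fit(distorted, theo) / 100.0
        keep, reasons = nontarget.filter_formula_fit(t, 0.90)
        assert (keep == ["f1"]) == (score >= 0.90)

    def test_missing_envelope_rejected_with_reason(self):
        t = _table({"f1": [1e6] * 6}, SITES, formula={"f1": "C10H14N2O"})
        keep, reasons = nontarget.filter_formula_fit(t)
        assert keep == []
        assert reasons["f1"] == "no_measured_envelope"

    def test_missing_formula_rejected(self):
        t = _table({"f1": [1e6] * 6}, SITES)
        keep, reasons = nontarget.filter_formula_fit(t)
        assert reasons["f1"] == "no_candidate_formula"


class TestUbiquityNovelty:
    DB = [SuspectCompound(name="known", formula="C10H10",
                          monoisotopic_mass=299.0 - screening.PROTON_MASS
                          + screening.PROTON_MASS)]

    def test_missing_at_one_site_rejected(self):
        vals = [1e6] * 6
        vals[3] = 0.0
        t = _table({"f1": vals}, SITES)
        out = nontarget.filter_ubiquity_and_novelty(t, SITES, [])
        assert out == []

    def test_db_match_rejected(self):
        db = [SuspectCompound(name="known", formula="C10H10",
                              monoisotopic_mass=300.0)]
        t = _table({"f1": [1e6] * 6}, SITES,
                   mz={"f1": 300.0 + screening.PROTON_MASS})
        assert nontarget.filter_ubiquity_and_novelty(t, SITES, db) == []

    def test_novel_ubiquitous_kept(self):
        db = [SuspectCompound(name="known", formula="C10H10",
                              monoisotopic_mass=500.0)]
        t = _table({"f1": [1e6] * 6}, SITES,
                   mz={"f1": 300.0 + screening.PROTON_MASS})
        assert nontarget.filter_ubiquity_and_novelty(t, SITES, db) == ["f1"]

    def test_blank_factor(self):
        t = _table({"f1": [25.0] * 6}, SITES, blank=10.0)
        # 25 < 3 x 10 -> not detected anywhere
        assert nontarget.filter_ubiquity_and_novelty(t, SITES, []) == []


class TestAttributeCorrelation:
    def test_proportional_feature_kept_with_rho_one(self, attribute_frame):
        ag = attribute_frame["ag_pct"]
        t = _table({"f1": (1e4 * ag).tolist()}, list(attribute_frame.index))
        out = nontarget.filter_attribute_correlation(t, attribute_frame)
        assert list(out.index) == ["f1"]
        assert out.loc["f1", "rho"] == pytest.approx(1.0)

    def test_background_rejected_in_most_seeds(self, attribute_frame):
        rejected = 0
        n_seeds = 40
        for s in range(n_seeds):
            r = np.random.default_rng(s)
            t = _table({"f1": r.lognormal(10, 1, size=20).tolist()},
                       list(attribute_frame.index))
            out = nontarget.filter_attribute_correlation(t, attribute_frame)
            rejected += int(len(out) == 0)
        assert rejected / n_seeds >= 0.80

    def test_needs_four_sites(self):
        attrs = pd.DataFrame({"ag_pct": [1, 2, 3]},
                             index=["s0", "s1", "s2"])
        t = _table({"f1": [1, 2, 3]}, ["s0", "s1", "s2"])
        with pytest.raises(InvalidArgument):
            nontarget.filter_attribute_correlation(t, attrs)


class TestSpectralMatch:
    def test_identical_spectra(self):
        spec = [(100.0, 50.0), (150.0, 100.0), (200.0, 25.0)]
        assert nontarget.spectral_match(spec, spec) == pytest.approx(100.0)

    def test_disjoint_spectra(self):
        a = [(100.0, 50.0)]
        b = [(300.0, 50.0)]
        assert nontarget.spectral_match(a, b) == 0.0

    def test_hand_computed_cosine_with_shifted_peak(self):
        a = [(100.0, 60.0), (150.0, 100.0), (200.0, 30.0)]
        b = [(100.0, 60.0), (150.0, 100.0), (200.5, 30.0)]  # peak shifted
        # only the first two align: dot = 60*60 + 100*100
        expected = 100.0 * (60 * 60 + 100 * 100) / (
            np.linalg.norm([60, 100, 30]) ** 2)
        assert nontarget.spectral_match(a, b) == pytest.approx(expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(50, 500), st.floats(1, 100)),
                    min_size=1, max_size=8))
    def test_symmetric_and_bounded(self, spec):
        other = [(mz + 0.005, i) for mz, i in spec][::-1]
        s1 = nontarget.spectral_match(spec, other)
        s2 = nontarget.spectral_match(other, spec)
        assert 0.0 <= s1 <= 100.0 + 1e-9
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_agrees_with_matchms_greedy_cosine(self, rng):
        import matchms
        from matchms.similarity import CosineGreedy
        for _ in range(10):
            n1, n2 = rng.integers(3, 9, size=2)
            a = sorted(zip(rng.uniform(50, 500, n1),
                           rng.uniform(1, 100, n1)))
            b = sorted(zip(rng.uniform(50, 500, n2),
                           rng.uniform(1, 100, n2)))
            sa = matchms.Spectrum(
                mz=np.array([p[0] for p in a]),
                intensities=np.array([p[1] for p in a]),
                metadata_harmonization=False)
            sb = matchms.Spectrum(
                mz=np.array([p[0] for p in b]),
                intensities=np.array([p[1] for p in b]),
                metadata_harmonization=False)
            ref = float(CosineGreedy(tolerance=0.01).pair(sa, sb)["score"])
            mine = nontarget.spectral_match(a, b, mz_tol=0.01) / 100.0
            assert mine == pytest.approx(ref, abs=1e-6)


class TestPrioritize:
    def test_noiseless_planted_table_recovered_exactly(self,
                                                       attribute_frame):
        """Planted attribute-driven features survive; constant background
        and suspect-database features do not."""
        sites = list(attribute_frame.index)
        formula = "C12H16N2O2"
        theo = screening.isotope_pattern(formula)
        mono = screening.monoisotopic_mass(formula)
        ag = attribute_frame["ag_pct"].to_numpy()
        vals = {
            "planted": (1e4 * ag + 1e5).tolist(),
            "background": [2e5] * 20,            # constant -> rho undefined/0
            "suspect_linked": (1e4 * ag + 1e5).tolist(),
        }
        mz = {"planted": mono + screening.PROTON_MASS,
              "background": 401.0, "suspect_linked": 501.0}
        db = [SuspectCompound(name="k", formula="C10H10",
                              monoisotopic_mass=501.0
                              - screening.PROTON_MASS)]
        t = _table(vals, sites, mz=mz,
                   formula={f: formula for f in vals},
                   envelopes={f: theo for f in vals})
        res = nontarget.prioritize(t, attribute_frame, db)
        assert list(res.prioritized.index) == ["planted"]
        assert res.flags.loc["planted"].all()
        assert not res.flags.loc["suspect_linked",
                                 "criterion_c_ubiquitous_novel"]

    def test_filters_commute(self, small_cohort):
        t = small_cohort.features
        attrs = small_cohort.sites_frame
        db = small_cohort.suspects
        res = nontarget.prioritize(t, attrs, db)
        # intersection computed in any order equals the bitwise AND
        survivors = set(res.flags.index[res.flags.all(axis=1)])
        assert survivors == set(res.prioritized.index)

    def test_planted_recovery_default_conditions(self, default_cohort):
        res = nontarget.prioritize(default_cohort.features,
                                   default_cohort.sites_frame,
                                   default_cohort.suspects)
        planted = set(default_cohort.truth.planted_nontarget_ids)
        selected = set(res.prioritized.index)
        tp = len(selected & planted)
        assert tp / len(planted) >= 0.9
        assert (len(selected) - tp) / len(selected) <= 0.2


class TestCocluster:
    def test_duplicate_profile_inherits_indicator_cluster(self,
                                                          attribute_frame):
        sites = list(attribute_frame.index)
        ag = attribute_frame["ag_pct"].to_numpy()
        septic = attribute_frame["septic_density"].to_numpy()
        wwtp = attribute_frame["wwtp_capacity"].to_numpy()
        t = _table({"feat": (10.0 * ag).tolist()}, sites)
        indicators = pd.DataFrame(
            {"ind_a": 5.0 * ag, "ind_b": 4.0 * septic, "ind_c": 3.0 * wwtp},
            index=attribute_frame.index)
        labels = nontarget.cocluster_with_indicators(
            t, ["feat"], indicators, attribute_frame, k=3)
        assert labels["feat"] == labels["ind_a"]

    def test_k1_single_cluster(self, attribute_frame):
        sites = list(attribute_frame.index)
        ag = attribute_frame["ag_pct"].to_numpy()
        t = _table({"feat": (10.0 * ag).tolist()}, sites)
        indicators = pd.DataFrame({"ind": 5.0 * ag},
                                  index=attribute_frame.index)
        labels = nontarget.cocluster_with_indicators(
            t, ["feat"], indicators, attribute_frame, k=1)
        assert len(set(labels.values())) == 1

    def test_agricultural_features_cocluster(self, default_cohort):
        res = nontarget.prioritize(default_cohort.features,
                                   default_cohort.sites_frame,
                                   default_cohort.suspects)
        truth = default_cohort.truth
        meas = default_cohort.measurements
        ind_levels = meas[meas["compound"].isin(
            truth.indicator_compounds)].pivot(
            index="site_id", columns="compound", values="m_pocis")
        labels = nontarget.cocluster_with_indicators(
            default_cohort.features, list(res.prioritized.index),
            ind_levels, default_cohort.sites_frame, k=3)
        fc = default_cohort.feature_compound
        ag_feats = [f for f in res.prioritized.index
                    if f in fc and truth.source_cluster.get(fc[f]) == "A"
                    and f in set(truth.planted_nontarget_ids)]
        assert ag_feats
        correct = np.mean([labels[f] == "A" for f in ag_feats])
        assert correct >= 0.8
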