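"""Generator invariants: determinism, copula structure, uptake exactness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from streamscreen import synthetic_data as sd
from streamscreen.types import (
    ConfigurationError,
    DeploymentWindow,
    GroundTruth,
    InvalidArgument,
)


class TestGenerateSites:
    def test_invariants_hold(self):
        sites = sd.generate_sites(20, seed=1)
        assert len(sites) == 20
        for s in sites:
            assert 0 <= s.ag_pct <= 100 and 0 <= s.dev_pct <= 100
            assert s.ag_pct + s.dev_pct <= 100
            assert s.septic_density >= 0 and s.cafo_count >= 0
            assert s.wwtp_capacity >= 0 and s.rpi >= 0

    def test_seed_determinism(self):
        a = sd.sites_frame(sd.generate_sites(20, seed=1))
        b = sd.sites_frame(sd.generate_sites(20, seed=1))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_sites(self):
        with pytest.raises(InvalidArgument):
            sd.generate_sites(1, seed=0)

    def test_copula_rank_correlation(self):
        # developed block ties dev_pct to road density at rank rho ~ 0.7
        df = sd.sites_frame(sd.generate_sites(200, seed=7))
        rho = spearmanr(df["dev_pct"], df["road_density"]).statistic
        assert rho == pytest.approx(0.7, abs=0.15)
        # agricultural and developed blocks are independent
        cross = spearmanr(df["ag_pct"], df["dev_pct"]).statistic
        assert abs(cross) < 0.25


class TestGenerateConcentrations:
    def _truth(self, **noise):
        t = GroundTruth(
            source_cluster={"x": "A"},
            true_r_s={"x": 0.07},
            effect_sizes={a: 0.0 for a in
                          ("ag_pct", "cafo_count", "rpi")},
            noise={"sigma_log10": 0.0, "temporal_sigma": 0.0},
            alpha_log10={"x": 1.0}, loq_ng_per_l={"x": 0.1})
        t.noise.update(noise)
        return t

    def test_null_effects_give_constant_field(self):
        sites = sd.generate_sites(10, seed=3)
        c = sd.generate_concentrations(sites, ["x"], self._truth(), seed=1,
                                       n_days=5)
        for s in sites:
            assert np.allclose(c[s.site_id]["x"], 10.0)

    def test_monotone_in_loading_attribute(self):
        sites = sd.generate_sites(20, seed=3)
        truth = self._truth()
        truth.effect_sizes["ag_pct"] = 0.5
        c = sd.generate_concentrations(sites, ["x"], truth, seed=1,
                                       n_days=3)
        ag = [s.ag_pct for s in sites]
        conc = [c[s.site_id]["x"][0] for s in sites]
        assert spearmanr(ag, conc).statistic == pytest.approx(1.0)

    def test_default_correlation_matches_large_n_oracle(self):
        # Monte-Carlo oracle: the same model evaluated at large n
        truth_small = sd.make_ground_truth({"A": ["x"]}, seed=5)
        sites = sd.generate_sites(200, seed=9)
        c = sd.generate_concentrations(sites, ["x"], truth_small, seed=2,
                                       n_days=2)
        obs = spearmanr([s.ag_pct for s in sites],
                        [c[s.site_id]["x"][0] for s in sites]).statistic
        big_sites = sd.generate_sites(20000, seed=10)
        truth_big = sd.make_ground_truth({"A": ["x"]}, seed=5)
        cb = sd.generate_concentrations(big_sites, ["x"], truth_big, seed=3,
                                        n_days=1)
        oracle = spearmanr([s.ag_pct for s in big_sites],
                           [cb[s.site_id]["x"][0] for s in big_sites]
                           ).statistic
        assert obs == pytest.approx(oracle, abs=0.1)

    def test_unassigned_compound_rejected(self):
        sites = sd.generate_sites(5, seed=0)
        with pytest.raises(ConfigurationError):
            sd.generate_concentrations(sites, ["ghost"], self._truth(),
                                       seed=0)


class TestPocisUptake:
    WINDOW = DeploymentWindow(site_id="s", start_day=0, end_day=23)

    def test_constant_concentration_exact(self):
        c = np.full(24, 100.0)
        m = sd.simulate_pocis_uptake(c, 0.07, self.WINDOW)
        assert m == 0.07 * 100.0  # exact product, machine precision

    def test_zero_concentration(self):
        assert sd.simulate_pocis_uptake(np.zeros(24), 0.1, self.WINDOW) == 0.0

    def test_triangular_chemograph_matches_trapezoid_oracle(self):
        t = np.arange(24.0)
        c = np.where(t <= 11.5, 200.0 * t / 11.5,
                     200.0 * (23.0 - t) / 11.5)
        m = sd.simulate_pocis_uptake(c, 0.1, self.WINDOW)
        oracle = 0.1 * np.trapezoid(c, t) / 23.0
        assert m == pytest.approx(oracle, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgument):
            sd.simulate_pocis_uptake(np.ones(24), -0.1, self.WINDOW)

    def test_elimination_reduces_accumulation(self):
        c = np.full(24, 100.0)
        linear = sd.simulate_pocis_uptake(c, 0.07, self.WINDOW)
        curvi = sd.simulate_pocis_uptake(c, 0.07, self.WINDOW,
                                         elimination_rate=0.05)
        assert 0 < curvi < linear

    def test_twa_round_trip(self):
        # uptake then division by the true rate returns c_w exactly
        from streamscreen import kinetics
        from streamscreen.types import SamplingRateEstimate
        c = np.full(24, 42.0)
        m = sd.simulate_pocis_uptake(c, 0.07, self.WINDOW)
        est = SamplingRateEstimate(compound="x", r_s=0.07, se_r_s=0.0,
                                   r_squared=1.0, n_pairs=20)
        out = kinetics.compute_twa(m, est)
        assert abs(out.c_twa - 42.0) / 42.0 < 1e-12


class TestDischarge:
    WINDOW = DeploymentWindow(site_id="s", start_day=0, end_day=23)

    def test_no_storms_constant(self):
        q = sd.generate_discharge(self.WINDOW, 2.0, [], seed=0)
        assert np.allclose(q, 2.0)

    def test_single_pulse_shape(self):
        q = sd.generate_discharge(self.WINDOW, 2.0, [(5.0, 10.0, 2.0)],
                                  seed=1)
        assert q.max() > 2.0
        assert q[-1] == pytest.approx(2.0, rel=0.05)  # recession decayed
        assert (q > 0).all()

    def test_determinism(self):
        a = sd.generate_discharge(self.WINDOW, 2.0, [(5, 10, 2)], seed=3)
        b = sd.generate_discharge(self.WINDOW, 2.0, [(5, 10, 2)], seed=3)
        assert (a == b).all()

    def test_nonpositive_baseflow_rejected(self):
        with pytest.raises(InvalidArgument):
            sd.generate_discharge(self.WINDOW, 0.0, [], seed=0)


class TestFeatureTable:
    def test_noiseless_gain_is_exact(self):
        sites = sd.generate_sites(5, seed=2)
        truth = sd.make_ground_truth({"A": ["x"]}, seed=4)
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["x"],
                         columns=[s.site_id for s in sites])
        table, fc = sd.generate_feature_table(
            sites, m, truth, n_background=0, seed=0, gain=1e4,
            feature_noise_sigma=0.0, envelope_noise_compound=0.0)
        fid = next(iter(fc))
        assert np.allclose(table.intensities.loc[fid],
                           1e4 * m.loc["x"])

    def test_background_independent_of_attributes(self):
        # null-distribution check: background features rarely correlate
        sites = sd.generate_sites(200, seed=2)
        truth = sd.make_ground_truth({"A": ["x"]}, seed=4)
        m = pd.DataFrame(np.ones((1, 200)), index=["x"],
                         columns=[s.site_id for s in sites])
        table, fc = sd.generate_feature_table(
            sites, m, truth, n_background=60, seed=1,
            background_presence_prob=1.0)
        ag = np.array([s.ag_pct for s in sites])
        bg = [f for f in table.feature_ids if f not in fc]
        rhos = [abs(spearmanr(table.intensities.loc[f], ag).statistic)
                for f in bg]
        assert np.mean(np.asarray(rhos) < 0.3) >= 0.95

    def test_round_trip_through_csv(self, tmp_path, small_cohort):
        from streamscreen.featuretable import FeatureTable
        small_cohort.features.write(str(tmp_path))
        back = FeatureTable.read(str(tmp_path))
        pd.testing.assert_frame_equal(
            back.intensities, small_cohort.features.intensities)
        assert set(back.envelopes) == set(small_cohort.features.envelopes)


class TestCohort:
    def test_determinism(self):
        cfg = sd.ScenarioConfig(n_sites=6, n_suspects_per_cluster=2,
                                n_nontarget_per_cluster=1, n_background=10)
        a = sd.simulate_cohort(cfg, seed=5)
        b = sd.simulate_cohort(cfg, seed=5)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.features.intensities,
                                      b.features.intensities)
        assert a.truth.true_r_s == b.truth.true_r_s

    def test_suspect_rs_median_pinned(self, default_cohort):
        suspects = [s.name for s in default_cohort.suspects]
        rs = np.array([default_cohort.truth.true_r_s[c] for c in suspects])
        assert np.median(rs) == pytest.approx(0.07)
        assert rs.min() >= 0.02 and rs.max() <= 0.22

    def test_window_durations(self, default_cohort):
        for w in default_cohort.windows.values():
            assert 19 <= w.duration <= 27

    def test_planted_ids_subset_of_features(self, default_cohort):
        ids = set(default_cohort.features.feature_ids)
        assert set(default_cohort.truth.planted_nontarget_ids) <= ids

    def test_written_cohort_validates(self, tmp_path, small_cohort):
        from streamscreen import pipeline
        sd.write_cohort(small_cohort, str(tmp_path))
        report = pipeline.validate_tables(str(tmp_path))
        assert report.ok
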