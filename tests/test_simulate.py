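import numpy as np
import pytest
from scipy import stats

from lirype import climate as climate_mod
from lirype import simulate
from lirype.data_model import filter_observations, read_survey_tables
from lirype.detection import truncated_normalizer


class TestLandscape:
    def test_default_design_sizes_and_survey_floor(self):
        ls = simulate.generate_landscape(seed=4)
        assert ls.n_transects == 150 and ls.n_regions == 10 and ls.n_years == 10
        assert ls.surveyed.sum(axis=1).min() >= 6

    def test_single_transect_design(self):
        ls = simulate.generate_landscape(1, 1, 3, seed=0)
        assert ls.n_transects == 1 and ls.n_regions == 1

    def test_seeded_determinism(self):
        a = simulate.generate_landscape(seed=9)
        b = simulate.generate_landscape(seed=9)
        assert a.transects == b.transects
        assert np.array_equal(a.surveyed, b.surveyed)

    def test_lengths_scale_around_survey_mean(self):
        ls = simulate.generate_landscape(seed=1)
        lengths = np.array([t.length_km for t in ls.transects])
        assert 3.0 < lengths.mean() < 4.4  # log-normal around 3.7 km


class TestCovariates:
    def test_standardized_columns(self, small_study):
        cs = np.array(list(small_study.covariates.cs.values()))
        ct = np.array(list(small_study.covariates.ct.values()))
        assert abs(cs.mean()) < 1e-9 and abs(cs.std(ddof=1) - 1) < 1e-9
        assert abs(ct.mean()) < 1e-9 and abs(ct.std(ddof=1) - 1) < 1e-9

    def test_cs_tracks_regional_harshness(self):
        ls = simulate.generate_landscape(seed=3)
        cov = simulate.generate_covariates(ls, seed=3)
        cs = np.array([cov.cs[t.transect_id] for t in ls.transects])
        rho = stats.spearmanr(cs, ls.harshness[ls.region_of_transect]).statistic
        assert rho > 0.9


class TestClimateGenerator:
    def test_zero_anomaly_zero_noise_gives_flat_anomalies(self):
        ls = simulate.generate_landscape(2, 2, 3, seed=5)
        records, years = simulate.generate_climate(
            ls, seed=5, anomaly_sd_c=0.0, daily_noise_c=0.0
        )
        tables = climate_mod.derive_climate_variables(records, years)
        _, ct_raw = climate_mod.split_spatial_temporal(tables["winter_temp"], years)
        assert np.abs(ct_raw.to_numpy()).max() < 0.05

    def test_colder_regions_clear_later(self):
        ls = simulate.generate_landscape(6, 2, 3, seed=7)
        records, years = simulate.generate_climate(ls, seed=7)
        tables = climate_mod.derive_climate_variables(records, years)
        onset = tables["spring_onset"].mean(axis=1)
        region_mean = {
            r: np.mean([onset[t.transect_id] for t in ls.transects if t.region_id == r])
            for r in ls.region_ids
        }
        vals = [region_mean[r] for r in ls.region_ids]
        rho = stats.spearmanr(vals, ls.harshness).statistic
        assert rho > 0.8

    def test_seeded_determinism(self):
        ls = simulate.generate_landscape(2, 1, 2, seed=8)
        a, _ = simulate.generate_climate(ls, seed=8)
        b, _ = simulate.generate_climate(ls, seed=8)
        assert a == b


class TestRodentGenerator:
    def test_no_gradient_when_peaks_equal(self):
        ls = simulate.generate_landscape(5, 2, 8, seed=1)
        rt = simulate.generate_rodents(ls, seed=1, peak_p_cold=0.5, peak_p_warm=0.5)
        peaks = rt.occurrence.max(axis=1)
        assert np.allclose(peaks, peaks[0])

    def test_period_four_over_ten_years_has_repeated_peaks(self):
        ls = simulate.generate_landscape(4, 2, 10, seed=2)
        rt = simulate.generate_rodents(ls, seed=2)
        for r in range(ls.n_regions):
            peak_level = rt.occurrence[r].max()
            assert (rt.occurrence[r] > 0.9 * peak_level).sum() >= 2

    def test_realized_peak_occurrence_matches_targets_within_3se(self):
        # big regions so the binomial check has power
        ls = simulate.generate_landscape(2, 400, 8, seed=3)
        # region 0 is the most benign, region 1 the harshest
        rt = simulate.generate_rodents(ls, seed=3, missing_rate=0.0)
        for r, target in ((0, 0.38), (1, 0.64)):
            t_peak = int(np.argmax(rt.occurrence[r]))
            rows = ls.region_of_transect == r
            obs = rt.rodent_obs[rows, t_peak]
            obs = obs[~np.isnan(obs)]
            se = np.sqrt(target * (1 - target) / obs.size)
            assert abs(obs.mean() - target) < 3 * se

    def test_parameter_validation(self):
        ls = simulate.generate_landscape(2, 2, 4, seed=0)
        with pytest.raises(ValueError):
            simulate.generate_rodents(ls, peak_p_cold=0.3, peak_p_warm=0.5)


class TestPtarmiganGenerator:
    def test_stationary_truth_reproduces_expected_counts(self):
        """With covariate effects off and b0 = -bA·lnD*, density is stationary
        and total counts match D*·TL·ESW·2 in expectation (moment oracle)."""
        lnD_star = 2.5
        study = simulate.simulate_study(
            n_regions=1, transects_per_region=60, n_years=10, seed=21,
            decoy_rate=0.0,
            bCS=0.0, bCT=0.0, bR=0.0, bRL=0.0, bint_R=0.0, bint_CT=0.0,
            bA=-1.0, b0=lnD_star, mu1=lnD_star,
            sd_line_g=1e-6, sd_region_g=1e-6, sd_year_g=1e-6, sd_eps1=1e-6,
            sd_line_det=1e-6, sd_region_det=1e-6,
            sd_line_gs=1e-6, sd_regionyear_gs=1e-6,
        )
        data = study.data
        lam0 = np.exp(study.truth.params.groupsize.g0)
        sig0 = np.exp(study.truth.params.detection.b0_det)  # mean-size sigma
        esw0 = sig0 * np.sqrt(np.pi / 2)
        expect = (
            np.exp(lnD_star) * data.length_km[:, None] * esw0 * 2 / 1000.0
        ) * data.surveyed
        total_expect = expect.sum()
        disp = study.truth.params.observation.nb_dispersion
        var = (expect + expect**2 / disp).sum()
        total_obs = np.nansum(data.n_obs)
        assert abs(total_obs - total_expect) < 3 * np.sqrt(var)

    def test_count_moments_match_negative_binomial(self):
        """Counts on identical transect-years: var/mean ≈ 1 + mean/dispersion."""
        study = simulate.simulate_study(
            n_regions=1, transects_per_region=100, n_years=10, seed=22,
            decoy_rate=0.0,
            bCS=0.0, bCT=0.0, bR=0.0, bRL=0.0, bint_R=0.0, bint_CT=0.0,
            bA=-1.0, b0=2.5, mu1=2.5,
            sd_line_g=1e-6, sd_region_g=1e-6, sd_year_g=1e-6, sd_eps1=1e-6,
            sd_line_det=1e-6, sd_region_det=1e-6,
            sd_line_gs=1e-6, sd_regionyear_gs=1e-6,
        )
        data = study.data
        # restrict to cells of near-identical expected count (lengths vary)
        lengths = data.length_km
        sel = np.abs(lengths - np.median(lengths)) / np.median(lengths) < 0.10
        counts = data.n_obs[sel][data.surveyed[sel]]
        mean, var = counts.mean(), counts.var(ddof=1)
        disp = study.truth.params.observation.nb_dispersion
        want_ratio = 1 + mean / disp
        assert var / mean == pytest.approx(want_ratio, rel=0.25)

    def test_detected_distances_follow_truncated_halfnormal(self, medium_study):
        """PIT per observation against its own truncated half-normal CDF."""
        data = medium_study.data
        det = medium_study.truth.params.detection
        gs_c, gs_s = medium_study.truth.gs_center, medium_study.truth.gs_scale
        tids = data.transect_ids
        rof = data.region_of_transect
        sig = np.array(
            [
                np.exp(
                    det.b0_det
                    + det.b_gs * (data.obs_size[k] - gs_c) / gs_s
                    + det.line_det[tids[data.obs_transect[k]]]
                    + det.region_det[data.region_ids[rof[data.obs_transect[k]]]]
                )
                for k in range(data.n_groups_total)
            ]
        )
        # PIT: F(d) = normalizer(0..d) / normalizer(0..w), uniform if distances
        # are truncated half-normal with each observation's own sigma
        from scipy.special import erf

        F = erf(data.obs_distance / (sig * np.sqrt(2))) / erf(
            data.trunc_w_m / (sig * np.sqrt(2))
        )
        assert F.size > 500
        assert stats.kstest(F, "uniform").pvalue > 0.01

    def test_zero_density_produces_no_observations(self):
        study = simulate.simulate_study(
            n_regions=1, transects_per_region=5, n_years=4, seed=23,
            decoy_rate=0.0, mu1=-30.0, b0=-30.0, bA=-1.0,
        )
        assert study.data.n_groups_total == 0
        assert np.nansum(study.data.n_obs) == 0

    def test_n_obs_equals_sum_of_retained_group_sizes(self, small_study):
        data = small_study.data
        retained = filter_observations(small_study.observations)
        total_groups = sum(o.group_size for o in retained)
        assert int(np.nansum(data.n_obs)) == total_groups

    def test_decoys_are_removed_by_filters(self):
        study = simulate.simulate_study(
            n_regions=2, transects_per_region=6, n_years=6, seed=24, decoy_rate=0.3
        )
        decoys = [o for o in study.observations if o.detector == "surveyor"]
        assert decoys, "expected decoy records at a high decoy rate"
        kept = filter_observations(study.observations)
        assert all(o.detector == "dog" for o in kept)


class TestFixtureIO:
    def test_write_read_roundtrip_with_clean_validation(self, tmp_path, small_study):
        paths = simulate.write_fixture(tmp_path, small_study)
        transects, observations, tyears, report = read_survey_tables(paths)
        assert len(report) == 0
        assert observations == small_study.observations
        assert tyears == small_study.tyears

    def test_manifest_seed_reproduces_fixture(self, tmp_path):
        a = simulate.simulate_study(2, 3, 5, seed=31)
        paths = simulate.write_fixture(tmp_path, a)
        manifest = simulate.read_truth_manifest(paths["truth"])
        b = simulate.simulate_study(2, 3, 5, seed=31)
        assert a.observations == b.observations
        assert manifest["fixed_effects"]["bA"] == pytest.approx(
            b.truth.params.growth.bA
        )
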