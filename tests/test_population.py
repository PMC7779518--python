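import copy
import math

import numpy as np
import pytest
from scipy import special, stats

from lirype import simulate
from lirype._fastmodel import GaussianMeanToy, JointModel
from lirype.population import (
    GrowthParameters,
    LatentState,
    ModelConfig,
    ModelParameters,
    ObservationParameters,
    PriorConfig,
    RodentParameters,
    advance_density,
    count_loglik,
    expected_count,
    growth_rate,
    joint_log_posterior,
    log_prior,
    random_effects_density_surface,
    rodent_logit,
    rodent_loglik,
)


class _Cov:
    def __init__(self, cs, ct):
        self.cs, self.ct = cs, ct


def _state(lnD, rodent):
    return LatentState(log_density=dict(lnD), rodent_p=dict(rodent))


class TestGrowthRate:
    def test_all_zero_inputs(self):
        st = _state({("A", 1): 0.0}, {("R", 1): 0.5, ("R", 2): 0.5})
        g = GrowthParameters(b0=0.0, bA=-0.5)
        cov = _Cov({"A": 0.0}, {("A", 2): 0.0})
        # centred rodent covariate is 0 at p = 0.5
        assert growth_rate("A", "R", 2, st, cov, g) == pytest.approx(0.5 * 0.0)

    def test_equilibrium_is_minus_b0_over_bA(self):
        g = GrowthParameters(b0=0.2, bA=-0.5)
        st = _state({("A", 1): 0.4}, {("R", 1): 0.5, ("R", 2): 0.5})
        cov = _Cov({"A": 0.0}, {("A", 2): 0.0})
        assert growth_rate("A", "R", 2, st, cov, g) == pytest.approx(0.0)

    def test_year_one_rejected(self):
        st = _state({}, {})
        with pytest.raises(ValueError):
            growth_rate("A", "R", 1, st, None, GrowthParameters())

    def test_matches_term_by_term_oracle(self, rng):
        g = GrowthParameters(
            b0=rng.normal(), bA=-0.8, bCS=rng.normal(), bCT=rng.normal(),
            bR=rng.normal(), bRL=rng.normal(), bH=rng.normal(),
            bint_CT=rng.normal(), bint_R=rng.normal(),
            line_g={"A": 0.1}, region_g={"R": -0.2}, year_g={3: 0.05},
        )
        lnD_prev, csv, ctv, rp_now, rp_prev, h = rng.normal(size=6)
        rp_now, rp_prev = special.expit(rp_now), special.expit(rp_prev)
        st = _state({("A", 2): lnD_prev}, {("R", 2): rp_prev, ("R", 3): rp_now})
        cov = _Cov({"A": csv}, {("A", 3): ctv})
        want = (
            g.b0 + g.bA * lnD_prev + 0.1 - 0.2 + 0.05
            + g.bCS * csv + g.bCT * ctv
            + g.bR * (rp_now - 0.5) + g.bRL * (rp_prev - 0.5) + g.bH * h
            + g.bint_CT * csv * ctv + g.bint_R * csv * (rp_now - 0.5)
        )
        got = growth_rate("A", "R", 3, st, cov, g, harvest_prev=h)
        assert got == pytest.approx(want)

    def test_invariant_to_querying_transect_within_region(self):
        # rodent probabilities are region-year constants by construction
        p = RodentParameters(c0=0.4, region_r={"R": 0.3}, year_r={2: -0.1})
        assert rodent_logit("R", 2, p) == rodent_logit("R", 2, p)


class TestDensityRecursion:
    def test_zero_growth_keeps_density_constant(self):
        st = _state({("A", 1): 1.3}, {})
        for t in range(2, 6):
            advance_density(st, "A", t, 0.0)
        assert st.log_density[("A", 5)] == pytest.approx(1.3)

    @pytest.mark.parametrize("bA", [-0.2, -1.0, -1.8])
    def test_converges_to_closed_form_equilibrium(self, bA):
        """The Gompertz recursion is AR(1) on the log scale: with fixed
        covariates it converges to ln D* = -(linear predictor)/bA."""
        b0 = 0.3
        g = GrowthParameters(b0=b0, bA=bA)
        cov = _Cov({"A": 0.0}, {("A", t): 0.0 for t in range(2, 300)})
        st = _state({("A", 1): 2.0}, {("R", t): 0.5 for t in range(1, 300)})
        for t in range(2, 202):
            r = growth_rate("A", "R", t, st, cov, g)
            advance_density(st, "A", t, r)
        assert st.log_density[("A", 201)] == pytest.approx(-b0 / bA, abs=1e-8)

    def test_geometric_convergence_rate(self):
        # AR(1) with coefficient 1 + bA: error shrinks by |1 + bA| per step
        bA, b0 = -0.5, 0.2
        g = GrowthParameters(b0=b0, bA=bA)
        cov = _Cov({"A": 0.0}, {("A", t): 0.0 for t in range(2, 20)})
        st = _state({("A", 1): 2.0}, {("R", t): 0.5 for t in range(1, 20)})
        eq = -b0 / bA
        errs = [2.0 - eq]
        for t in range(2, 12):
            advance_density(st, "A", t, growth_rate("A", "R", t, st, cov, g))
            errs.append(st.log_density[("A", t)] - eq)
        ratios = [errs[k + 1] / errs[k] for k in range(len(errs) - 1)]
        assert np.allclose(ratios, 1 + bA, atol=1e-10)


class TestExpectedCount:
    def test_survey_scale_arithmetic(self):
        # density 10 birds/km², the survey's mean transect and mean ESW
        assert expected_count(10.0, 3.7, 107.0) == pytest.approx(7.918)

    def test_zero_density(self):
        assert expected_count(0.0, 3.7, 107.0) == 0.0

    def test_linear_in_esw(self):
        assert expected_count(5.0, 2.0, 200.0) == pytest.approx(
            2 * expected_count(5.0, 2.0, 100.0)
        )


class TestCountLoglik:
    def test_poisson_limit_at_large_dispersion(self):
        p = ObservationParameters(nb_dispersion=1e6)
        ks = np.arange(0, 40)
        nb = np.array([count_loglik(k, 5.0, p) for k in ks])
        po = stats.poisson.logpmf(ks, 5.0)
        assert np.max(np.abs(np.exp(nb) - np.exp(po))) < 1e-6

    def test_pmf_sums_to_one(self):
        p = ObservationParameters(nb_dispersion=0.8)
        total = sum(np.exp(count_loglik(k, 7.0, p)) for k in range(3000))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_mean_zero_count_limit(self):
        p = ObservationParameters(nb_dispersion=2.0)
        assert count_loglik(0, 0.0, p) == pytest.approx(0.0)
        assert count_loglik(3, 0.0, p) == -np.inf

    def test_matches_scipy_nbinom(self, rng):
        r, m = 2.5, 6.0
        p = ObservationParameters(nb_dispersion=r)
        ks = rng.integers(0, 30, size=20)
        want = stats.nbinom.logpmf(ks, r, r / (r + m)).sum()
        assert count_loglik(ks, m, p) == pytest.approx(want)


class TestRodentSubmodel:
    def test_all_terms_zero_gives_half(self):
        assert rodent_logit("R", 1, RodentParameters()) == pytest.approx(0.5)

    def test_inverse_logit_recovers_peak_occurrence_scale(self):
        # logit(0.64): the harsh-region peak occurrence magnitude
        p = RodentParameters(c0=float(special.logit(0.64)))
        assert rodent_logit("R", 1, p) == pytest.approx(0.64)

    def test_loglik_trivial_cases(self):
        rp = {("R", 1): 0.5}
        assert rodent_loglik([("R", 1, 1)], rp) == pytest.approx(math.log(0.5))
        assert rodent_loglik([("R", 1, None)], rp) == 0.0

    def test_loglik_matches_per_row_bernoulli_oracle(self, rng):
        rp = {("R", t): float(special.expit(rng.normal())) for t in range(1, 6)}
        obs = [("R", t, v) for t in range(1, 6)
               for v in (0, 1, None) if rng.random() < 0.8]
        want = sum(
            stats.bernoulli.logpmf(v, rp[("R", t)])
            for (_, t, v) in obs if v is not None
        )
        assert rodent_loglik(obs, rp) == pytest.approx(want)

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            rodent_loglik([("R", 1, 2)], {("R", 1): 0.5})


class TestLogPrior:
    def test_density_dependence_support(self):
        params = ModelParameters()
        params.growth.bA = -1.0
        assert np.isfinite(log_prior(params))
        object.__setattr__(params.growth, "bA", 0.5) if False else None
        bad = copy.deepcopy(params)
        bad.growth.bA = 0.5
        assert log_prior(bad) == -np.inf

    def test_nonpositive_sd_rejected_by_type(self):
        with pytest.raises(ValueError):
            GrowthParameters(sd_line_g=0.0)

    def test_prior_mode_value_is_hand_summed(self):
        pr = PriorConfig()
        params = ModelParameters()
        params.growth.bA = -1.0
        # 13 fixed effects at 0, 11 SDs at 1, two uniforms
        want = (
            13 * stats.norm.logpdf(0.0, scale=pr.fixed_sd)
            + 11 * stats.halfnorm.logpdf(1.0, scale=pr.sd_scale)
            - math.log(pr.bA_hi - pr.bA_lo)
            - math.log(pr.disp_hi - pr.disp_lo)
        )
        assert log_prior(params, pr) == pytest.approx(want)


def _tiny_fixture():
    return simulate.simulate_study(
        n_regions=2, transects_per_region=2, n_years=3, seed=42
    )


def _full_params(study, seed=9):
    params = copy.deepcopy(study.truth.params)
    rng = np.random.default_rng(seed)
    params.rodent = RodentParameters(
        c0=0.2,
        year_r={y: float(rng.normal(0, 0.2)) for y in study.data.years},
        region_r={r: float(rng.normal(0, 0.2)) for r in study.data.region_ids},
        regionyear_r={
            (r, y): float(rng.normal(0, 0.2))
            for r in study.data.region_ids for y in study.data.years
        },
    )
    return params


class TestJointLogPosterior:
    def test_equals_sum_of_independently_computed_components(self):
        """Component-sum oracle computed with scipy only, on a tiny fixture."""
        study = _tiny_fixture()
        data = study.data
        params = _full_params(study)
        got = joint_log_posterior(data, params)

        g, init, obsp = params.growth, params.initial, params.observation
        rod, det, gsp = params.rodent, params.detection, params.groupsize
        rof = data.region_of_transect

        want = log_prior(params)
        for vals, sd in (
            (g.line_g, g.sd_line_g), (g.region_g, g.sd_region_g),
            (g.year_g, g.sd_year_g), (init.eps1, init.sd_eps1),
            (det.line_det, det.sd_line_det), (det.region_det, det.sd_region_det),
            (gsp.line_gs, gsp.sd_line_gs), (gsp.regionyear_gs, gsp.sd_regionyear_gs),
            (rod.year_r, rod.sd_year_r), (rod.region_r, rod.sd_region_r),
            (rod.regionyear_r, rod.sd_regionyear_r),
        ):
            want += stats.norm.logpdf(list(vals.values()), scale=sd).sum()

        # latent surfaces recomputed independently
        rp = {}
        for r_i, rid in enumerate(data.region_ids):
            for t in range(1, data.n_years + 1):
                eta = (rod.c0 + rod.year_r[t] + rod.region_r[rid]
                       + rod.regionyear_r[(rid, t)])
                rp[(rid, t)] = special.expit(eta)
        lnD = {}
        for i, tid in enumerate(data.transect_ids):
            rid = data.region_ids[rof[i]]
            lnD[(tid, 1)] = init.mu1 + init.eps1[tid]
            for t in range(2, data.n_years + 1):
                r_it = (
                    g.b0 + g.bA * lnD[(tid, t - 1)] + g.line_g[tid]
                    + g.region_g[rid] + g.year_g.get(t, 0.0)
                    + g.bCS * data.cs[i] + g.bCT * data.ct[i, t - 1]
                    + g.bR * (rp[(rid, t)] - 0.5) + g.bRL * (rp[(rid, t - 1)] - 0.5)
                    + g.bH * data.harvest[i, t - 1]
                    + g.bint_CT * data.cs[i] * data.ct[i, t - 1]
                    + g.bint_R * data.cs[i] * (rp[(rid, t)] - 0.5)
                )
                lnD[(tid, t)] = lnD[(tid, t - 1)] + r_it

        w = data.trunc_w_m
        for k in range(data.n_groups_total):
            i = data.obs_transect[k]
            tid, rid = data.transect_ids[i], data.region_ids[rof[i]]
            year = int(data.obs_year[k]) + 1
            z = (data.obs_size[k] - data.gs_center) / data.gs_scale
            sig = math.exp(det.b0_det + det.b_gs * z + det.line_det[tid]
                           + det.region_det[rid])
            norm = sig * math.sqrt(math.pi / 2) * special.erf(w / (sig * math.sqrt(2)))
            want += -data.obs_distance[k] ** 2 / (2 * sig**2) - math.log(norm)
            lam = math.exp(gsp.g0 + gsp.line_gs[tid] + gsp.regionyear_gs[(rid, year)])
            want += stats.poisson.logpmf(data.obs_size[k] - 1, lam)

        r_disp = obsp.nb_dispersion
        for i, tid in enumerate(data.transect_ids):
            rid = data.region_ids[rof[i]]
            for t in range(1, data.n_years + 1):
                if not data.surveyed[i, t - 1]:
                    continue
                lam = math.exp(gsp.g0 + gsp.line_gs[tid]
                               + gsp.regionyear_gs[(rid, t)])
                z = (lam + 1.0 - data.gs_center) / data.gs_scale
                sig = math.exp(det.b0_det + det.b_gs * z + det.line_det[tid]
                               + det.region_det[rid])
                mean = (math.exp(lnD[(tid, t)]) * data.length_km[i]
                        * sig * math.sqrt(math.pi / 2) / 1000.0 * 2.0)
                want += stats.nbinom.logpmf(
                    int(data.n_obs[i, t - 1]), r_disp, r_disp / (r_disp + mean)
                )
                v = data.rodent_obs[i, t - 1]
                if not np.isnan(v):
                    want += stats.bernoulli.logpmf(int(v), rp[(rid, t)])

        assert got == pytest.approx(want, abs=1e-8)

    def test_fast_model_agrees_with_reference(self):
        study = _tiny_fixture()
        params = _full_params(study)
        model = JointModel(study.data)
        theta = model.theta_from_params(params)
        assert model.log_posterior(theta) == pytest.approx(
            joint_log_posterior(study.data, params), abs=1e-8
        )

    def test_removing_one_observation_changes_by_its_loglik(self):
        study = _tiny_fixture()
        params = _full_params(study)
        data = study.data
        full = joint_log_posterior(data, params)
        # drop the last detected cluster
        import lirype.population as pop

        reduced = pop.StudyData(
            data.transect_ids, data.region_ids, data.region_of_transect,
            data.length_km, data.years, data.n_obs, data.rodent_obs,
            data.cs, data.ct, data.harvest,
            data.obs_transect[:-1], data.obs_year[:-1],
            data.obs_distance[:-1], data.obs_size[:-1], data.trunc_w_m,
        )
        # keep identical standardization so the dropped term is well-defined
        reduced.gs_center, reduced.gs_scale = data.gs_center, data.gs_scale
        reduced.obs_size_std = (reduced.obs_size - data.gs_center) / data.gs_scale
        part = joint_log_posterior(reduced, params)
        k = data.n_groups_total - 1
        i = data.obs_transect[k]
        tid = data.transect_ids[i]
        rid = data.region_ids[data.region_of_transect[i]]
        det, gsp = params.detection, params.groupsize
        z = (data.obs_size[k] - data.gs_center) / data.gs_scale
        sig = math.exp(det.b0_det + det.b_gs * z + det.line_det[tid]
                       + det.region_det[rid])
        norm = sig * math.sqrt(math.pi / 2) * special.erf(
            data.trunc_w_m / (sig * math.sqrt(2)))
        dist_ll = -data.obs_distance[k] ** 2 / (2 * sig**2) - math.log(norm)
        lam = math.exp(gsp.g0 + gsp.line_gs[tid]
                       + gsp.regionyear_gs[(rid, int(data.obs_year[k]) + 1)])
        gs_ll = float(stats.poisson.logpmf(data.obs_size[k] - 1, lam))
        assert full - part == pytest.approx(dist_ll + gs_ll, abs=1e-8)

    def test_nan_covariates_rejected(self):
        study = _tiny_fixture()
        params = _full_params(study)
        study.data.cs[0] = np.nan
        with pytest.raises(ValueError):
            joint_log_posterior(study.data, params)


class TestRandomEffectsStateModel:
    def test_flat_surface_at_intercept(self, small_study):
        data = small_study.data
        surface = random_effects_density_surface(data, 1.7, {}, {}, {}, {})
        assert np.allclose(surface, 1.7)

    def test_shares_observation_layer_with_covariate_model(self, small_study):
        """Given identical ln D, both state models produce identical counts."""
        data = small_study.data
        m_re = JointModel(data, ModelConfig(state="random_effects"))
        m_g = JointModel(data)
        rng = np.random.default_rng(0)
        th_re = m_re.init_theta(rng)
        th_g = m_g.init_theta(np.random.default_rng(0))
        cache_re = m_re.make_cache(th_re)
        cache_g = m_g.make_cache(th_g)
        # impose the same lnD and detection scale on both models
        th_g[m_g.layout["det_fixed"]] = th_re[m_re.layout["det_fixed"]]
        cache_g = m_g.make_cache(th_g)
        lam = cache_g["lam"]
        sig = cache_g["sigma_ty"]
        nm_re = np.exp(cache_g["lnD"]) * m_re.TLfac[:, None] * sig * np.sqrt(np.pi / 2)
        assert np.allclose(nm_re, cache_g["nmean"])


class TestRandomEffectsRecovery:
    def test_posterior_mean_surface_tracks_true_density(self):
        """The descriptive random-effects state model reproduces the realized
        density surface without knowing any covariates.

        The scenario has pronounced rodent-driven density cycles (strong
        same-year effect, no lag), the regime this visualization model exists
        for; with a near-stationary surface the representable signal is small
        relative to count noise and any surface estimate flattens.
        """
        from lirype.inference import McmcSettings, run_mcmc

        study = simulate.simulate_study(seed=202, bR=1.0, bRL=0.0)
        model = JointModel(study.data, ModelConfig(state="random_effects"))
        samples = run_mcmc(
            model, McmcSettings(chains=2, iterations=1200, burn_in=600, seed=31)
        )
        theta_mean = samples.theta.reshape(-1, samples.theta.shape[-1]).mean(axis=0)
        lnD_hat = model.make_cache(theta_mean)["lnD"]
        truth = study.truth.ln_density
        mask = study.data.surveyed
        r = np.corrcoef(lnD_hat[mask], truth[mask])[0, 1]
        assert r > 0.7, f"surface correlation {r:.3f}"


class TestToyTarget:
    def test_closed_form_moments(self):
        toy = GaussianMeanToy(np.array([1.0, 2.0, 3.0]), sigma=1.0, m0=0.0, s0=10.0)
        mean, sd = toy.posterior_moments()
        prec = 3 / 1.0 + 1 / 100.0
        assert mean == pytest.approx((6.0 / 1.0) / prec)
        assert sd == pytest.approx(math.sqrt(1 / prec))
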