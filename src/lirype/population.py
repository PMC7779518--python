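"""The joint state–observation model for ptarmigan dynamics.

The latent variable is ptarmigan density D (birds per km²) on each transect in
each year.  Year-1 log-density has transect-level random effects; later years
follow a Gompertz growth model on the log scale,

    ln D_{i,t} = ln D_{i,t−1} + r_{i,t}
    r_{i,t}  = b0 + bA·ln D_{i,t−1} + L_i + SR_i + Year_t
             + bCS·CS_i + bCT·CT_{i,t} + bR·R_{i,t} + bRL·R_{i,t−1}
             + bH·H_{i,t−1} + bint_CT·CS_i·CT_{i,t} + bint_R·CS_i·R_{i,t}

with bA ∈ (−2, 0) giving Gompertz density dependence.  The observed total
count on a transect follows a negative binomial around the expected count
N = D·TL·ESW·2 (ESW in km), linking density to the distance-sampling
observation model.  Rodent occurrence R is a latent region-year probability
with a saturated logit decomposition, fitted jointly so that missing rodent
records are imputed; it enters the growth model centred at 0.5 by default.

This module holds the readable, record-keyed reference implementation used by
the simulator and the tests; the array-vectorized equivalent used for MCMC
lives in :mod:`lirype._fastmodel` and is cross-checked against this one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import detection
from .detection import DetectionParameters, GroupSizeParameters

__all__ = [
    "GrowthParameters",
    "InitialDensityParameters",
    "ObservationParameters",
    "RodentParameters",
    "LatentState",
    "ModelParameters",
    "PriorConfig",
    "ModelConfig",
    "StudyData",
    "growth_rate",
    "advance_density",
    "expected_count",
    "count_loglik",
    "rodent_logit",
    "rodent_loglik",
    "rodent_covariate",
    "log_prior",
    "joint_log_posterior",
    "random_effects_density_surface",
]


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class GrowthParameters:
    """Fixed and random effects of the growth-rate decomposition."""

    b0: float = 0.0
    bA: float = -0.5
    bCS: float = 0.0
    bCT: float = 0.0
    bR: float = 0.0
    bRL: float = 0.0
    bH: float = 0.0
    bint_CT: float = 0.0
    bint_R: float = 0.0
    line_g: Mapping[str, float] = field(default_factory=dict)
    region_g: Mapping[str, float] = field(default_factory=dict)
    year_g: Mapping[int, float] = field(default_factory=dict)
    sd_line_g: float = 1.0
    sd_region_g: float = 1.0
    sd_year_g: float = 1.0

    def __post_init__(self) -> None:
        if not (-2.0 < self.bA < 0.0):
            raise ValueError(f"bA must lie in (-2, 0), got {self.bA}")
        if min(self.sd_line_g, self.sd_region_g, self.sd_year_g) <= 0:
            raise ValueError("random-effect SDs must be > 0")


@dataclass
class InitialDensityParameters:
    """Year-1 log-density: grand mean plus transect-level random effects."""

    mu1: float = 0.0
    eps1: Mapping[str, float] = field(default_factory=dict)
    sd_eps1: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_eps1 <= 0:
            raise ValueError("sd_eps1 must be > 0")


@dataclass
class ObservationParameters:
    """Negative-binomial dispersion of the count layer.

    Distinct from the growth rate r_{i,t}: variance = mean + mean²/dispersion,
    so large values approach the Poisson.
    """

    nb_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class RodentParameters:
    """Saturated logit decomposition of region-year rodent occurrence."""

    c0: float = 0.0
    year_r: Mapping[int, float] = field(default_factory=dict)
    region_r: Mapping[str, float] = field(default_factory=dict)
    regionyear_r: Mapping[tuple, float] = field(default_factory=dict)
    sd_year_r: float = 1.0
    sd_region_r: float = 1.0
    sd_regionyear_r: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sd_year_r, self.sd_region_r, self.sd_regionyear_r) <= 0:
            raise ValueError("random-effect SDs must be > 0")


@dataclass
class LatentState:
    """ln D per (transect, year) and rodent probability per (region, year)."""

    log_density: Mapping[tuple, float] = field(default_factory=dict)
    rodent_p: Mapping[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.rodent_p.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"rodent_p[{key}] must lie in (0, 1)")


@dataclass
class ModelParameters:
    """Every parameter block of the joint model in one bundle."""

    growth: GrowthParameters = field(default_factory=GrowthParameters)
    initial: InitialDensityParameters = field(default_factory=InitialDensityParameters)
    observation: ObservationParameters = field(default_factory=ObservationParameters)
    rodent: RodentParameters = field(default_factory=RodentParameters)
    detection: DetectionParameters = field(default_factory=DetectionParameters)
    groupsize: GroupSizeParameters = field(default_factory=GroupSizeParameters)


@dataclass(frozen=True)
class PriorConfig:
    """Weak priors in the JAGS idiom; the density-dependence prior is stated.

    Fixed effects ~ Normal(0, fixed_sd); random-effect SDs ~ half-Normal(0,
    sd_scale); NB dispersion ~ Uniform(disp_lo, disp_hi); bA ~ Uniform(bA_lo,
    bA_hi).
    """

    fixed_sd: float = 10.0
    sd_scale: float = 2.0
    disp_lo: float = 0.01
    disp_hi: float = 50.0
    bA_lo: float = -2.0
    bA_hi: float = 0.0


@dataclass(frozen=True)
class ModelConfig:
    """Structural switches of the joint model.

    ``state``: 'gompertz' (covariate growth model) or 'random_effects' (the
    purely descriptive density surface used for visualization).
    ``rodent_terms``: include bR/bRL/bint_R in the growth rate.
    ``climate_terms``: include bCS/bCT/bint_CT.
    ``rodent_scale``: how the latent probability enters the growth model —
    'centred' subtracts 0.5 (default; a latent cannot be pre-standardized),
    'raw' uses the probability as is.
    """

    state: str = "gompertz"
    rodent_terms: bool = True
    climate_terms: bool = True
    rodent_scale: str = "centred"

    def __post_init__(self) -> None:
        if self.state not in ("gompertz", "random_effects"):
            raise ValueError("state must be 'gompertz' or 'random_effects'")
        if self.rodent_scale not in ("centred", "raw"):
            raise ValueError("rodent_scale must be 'centred' or 'raw'")


# ---------------------------------------------------------------------------
# data container


class StudyData:
    """Array view of one study: design, counts, covariates and observations.

    Years are re-indexed 1..Y from the first analysis year.  ``n_obs`` is NaN
    for unsurveyed transect-years, ``rodent_obs`` NaN where missing, and the
    harvest covariate defaults to 0 (its mean) where unavailable.
    """

    def __init__(
        self,
        transect_ids: Sequence[str],
        region_ids: Sequence[str],
        region_of_transect: Sequence[int],
        length_km: Sequence[float],
        years: Sequence[int],
        n_obs: np.ndarray,
        rodent_obs: np.ndarray,
        cs: np.ndarray,
        ct: np.ndarray,
        harvest: Optional[np.ndarray],
        obs_transect: np.ndarray,
        obs_year: np.ndarray,
        obs_distance: np.ndarray,
        obs_size: np.ndarray,
        trunc_w_m: float = 200.0,
    ) -> None:
        self.transect_ids = list(transect_ids)
        self.region_ids = list(region_ids)
        self.region_of_transect = np.asarray(region_of_transect, dtype=int)
        self.length_km = np.asarray(length_km, dtype=float)
        self.years = list(years)
        self.n_transects = len(self.transect_ids)
        self.n_regions = len(self.region_ids)
        self.n_years = len(self.years)
        self.n_obs = np.asarray(n_obs, dtype=float)
        self.rodent_obs = np.asarray(rodent_obs, dtype=float)
        self.cs = np.asarray(cs, dtype=float)
        self.ct = np.asarray(ct, dtype=float)
        self.harvest = (
            np.zeros((self.n_transects, self.n_years))
            if harvest is None
            else np.nan_to_num(np.asarray(harvest, dtype=float))
        )
        self.obs_transect = np.asarray(obs_transect, dtype=int)
        self.obs_year = np.asarray(obs_year, dtype=int)  # 0-based year index
        self.obs_distance = np.asarray(obs_distance, dtype=float)
        self.obs_size = np.asarray(obs_size, dtype=int)
        self.trunc_w_m = float(trunc_w_m)

        if np.isnan(self.cs).any() or np.isnan(self.ct).any():
            raise ValueError("covariates contain NaN")
        self.surveyed = ~np.isnan(self.n_obs)
        # group-size standardization constants over retained observations
        if self.obs_size.size >= 2:
            self.gs_center = float(self.obs_size.mean())
            self.gs_scale = float(self.obs_size.std(ddof=1))
            if self.gs_scale == 0.0:
                self.gs_scale = 1.0
        else:
            self.gs_center, self.gs_scale = 0.0, 1.0
        self.obs_size_std = (self.obs_size - self.gs_center) / self.gs_scale
        # region-year tallies of rodent records
        self.rodent_k1 = np.zeros((self.n_regions, self.n_years))
        self.rodent_k0 = np.zeros((self.n_regions, self.n_years))
        for r in range(self.n_regions):
            rows = self.region_of_transect == r
            sub = self.rodent_obs[rows]
            self.rodent_k1[r] = np.nansum(sub == 1, axis=0)
            self.rodent_k0[r] = np.nansum(sub == 0, axis=0)

    @property
    def n_groups_total(self) -> int:
        return int(self.obs_transect.size)

    @classmethod
    def from_records(
        cls,
        transects,
        observations,
        tyears,
        cov: "object" = None,
        years: Optional[Sequence[int]] = None,
        trunc_w_m: float = 200.0,
    ) -> "StudyData":
        """Assemble arrays from typed records and a covariate table.

        ``cov`` must expose ``cs`` (indexed by transect) and ``ct`` (indexed by
        (transect, year)); ``harvest`` likewise or None.  Covariates are taken
        as already standardized.
        """
        transects = list(transects)
        tids = [t.transect_id for t in transects]
        tpos = {tid: k for k, tid in enumerate(tids)}
        rids = sorted({t.region_id for t in transects})
        rpos = {rid: k for k, rid in enumerate(rids)}
        rof = [rpos[t.region_id] for t in transects]
        if years is None:
            years = sorted({ty.year for ty in tyears})
        years = list(years)
        ypos = {y: k for k, y in enumerate(years)}
        T, Y = len(tids), len(years)

        n_obs = np.full((T, Y), np.nan)
        rodent = np.full((T, Y), np.nan)
        harvest = np.full((T, Y), np.nan)
        for ty in tyears:
            if ty.transect_id not in tpos or ty.year not in ypos:
                continue
            i, t = tpos[ty.transect_id], ypos[ty.year]
            if ty.n_obs is not None:
                n_obs[i, t] = ty.n_obs
            if ty.rodent_obs is not None:
                rodent[i, t] = ty.rodent_obs
            if ty.harvest_prev is not None:
                harvest[i, t] = ty.harvest_prev

        obs = [o for o in observations if o.transect_id in tpos and o.year in ypos]
        obs_t = np.array([tpos[o.transect_id] for o in obs], dtype=int)
        obs_y = np.array([ypos[o.year] for o in obs], dtype=int)
        obs_d = np.array([o.distance_m for o in obs], dtype=float)
        obs_s = np.array([o.group_size for o in obs], dtype=int)

        cs = np.zeros(T)
        ct = np.zeros((T, Y))
        harv = harvest if np.isfinite(harvest).any() else None
        if cov is not None:
            cs = np.array([float(cov.cs[tid]) for tid in tids])
            for i, tid in enumerate(tids):
                for t, y in enumerate(years):
                    ct[i, t] = float(cov.ct[(tid, y)])
            if getattr(cov, "harvest", None) is not None:
                harv = np.zeros((T, Y))
                for i, tid in enumerate(tids):
                    for t, y in enumerate(years):
                        harv[i, t] = float(cov.harvest.get((tid, y), 0.0))
        return cls(
            tids, rids, rof, [t.length_km for t in transects], years,
            n_obs, rodent, cs, ct, harv, obs_t, obs_y, obs_d, obs_s, trunc_w_m,
        )


# ---------------------------------------------------------------------------
# state-model operations


def rodent_covariate(p: float, mode: str = "centred") -> float:
    """The rodent probability as it enters the growth model."""
    return p - 0.5 if mode == "centred" else p


def growth_rate(
    i: str,
    region: str,
    t: int,
    state: LatentState,
    cov,
    p: GrowthParameters,
    harvest_prev: float = 0.0,
    rodent_scale: str = "centred",
) -> float:
    """The growth-rate linear predictor r_{i,t} for year index t ≥ 2."""
    if t < 2:
        raise ValueError("growth is defined from year 2 onward")
    lnD_prev = state.log_density[(i, t - 1)]
    R_now = rodent_covariate(state.rodent_p[(region, t)], rodent_scale)
    R_prev = rodent_covariate(state.rodent_p[(region, t - 1)], rodent_scale)
    cs_i = float(cov.cs[i]) if cov is not None else 0.0
    ct_it = float(cov.ct[(i, t)]) if cov is not None else 0.0
    return (
        p.b0
        + p.bA * lnD_prev
        + p.line_g.get(i, 0.0)
        + p.region_g.get(region, 0.0)
        + p.year_g.get(t, 0.0)
        + p.bCS * cs_i
        + p.bCT * ct_it
        + p.bR * R_now
        + p.bRL * R_prev
        + p.bH * harvest_prev
        + p.bint_CT * cs_i * ct_it
        + p.bint_R * cs_i * R_now
    )


def advance_density(state: LatentState, i: str, t: int, r_it: float) -> float:
    """ln D_{i,t} = ln D_{i,t−1} + r_{i,t}; stores and returns the new value."""
    if t < 2:
        raise ValueError("growth is defined from year 2 onward")
    new = state.log_density[(i, t - 1)] + r_it
    state.log_density[(i, t)] = new
    return new


def expected_count(D: float, TL_km: float, esw_m: float) -> float:
    """Expected birds counted: density × length × strip width (both sides)."""
    return D * TL_km * (esw_m / 1000.0) * 2.0


def count_loglik(n_obs, mean, p: ObservationParameters) -> float:
    """NB log-pmf with mean/dispersion parameterization (summed)."""
    n = np.asarray(n_obs, dtype=float)
    m = np.asarray(mean, dtype=float)
    r = p.nb_dispersion
    if np.any(m <= 0):
        # mean -> 0 limit: point mass at zero
        out = np.where(n == 0, 0.0, -np.inf)
        m = np.where(m <= 0, 1.0, m)
        ll = (
            special.gammaln(n + r) - special.gammaln(r) - special.gammaln(n + 1)
            + r * np.log(r / (r + m)) + n * np.log(m / (r + m))
        )
        return float(np.sum(np.where(np.asarray(mean) <= 0, out, ll)))
    ll = (
        special.gammaln(n + r) - special.gammaln(r) - special.gammaln(n + 1)
        + r * np.log(r / (r + m)) + n * np.log(m / (r + m))
    )
    return float(np.sum(ll))


def rodent_logit(region: str, t: int, p: RodentParameters) -> float:
    """Region-year occurrence probability (identical for all member transects)."""
    eta = (
        p.c0
        + p.year_r.get(t, 0.0)
        + p.region_r.get(region, 0.0)
        + p.regionyear_r.get((region, t), 0.0)
    )
    return float(special.expit(eta))


def rodent_loglik(obs: Iterable[tuple], rodent_p: Mapping[tuple, float]) -> float:
    """Bernoulli log-likelihood of transect-level rodent records.

    ``obs`` yields ``(region, year, value)`` with value in {0, 1, None};
    missing records contribute nothing (they are imputed through the latent
    probability, not scored).
    """
    total = 0.0
    for region, t, v in obs:
        if v is None:
            continue
        if v not in (0, 1):
            raise ValueError(f"rodent observation must be 0, 1 or None, got {v!r}")
        pr = rodent_p[(region, t)]
        total += math.log(pr) if v == 1 else math.log(1.0 - pr)
    return total


# ---------------------------------------------------------------------------
# priors and the joint posterior


def _norm_logpdf(x, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * (x / sd) ** 2))


def _halfnorm_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(0.5 * np.log(2 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2)


def log_prior(params: ModelParameters, priors: PriorConfig = PriorConfig()) -> float:
    """Sum of log prior densities over every parameter block; −inf off-support."""
    g, init, obs, rod, det, gs = (
        params.growth, params.initial, params.observation,
        params.rodent, params.detection, params.groupsize,
    )
    if not (priors.bA_lo < g.bA < priors.bA_hi):
        return -np.inf
    if not (priors.disp_lo < obs.nb_dispersion < priors.disp_hi):
        return -np.inf
    total = -math.log(priors.bA_hi - priors.bA_lo)
    total += -math.log(priors.disp_hi - priors.disp_lo)
    fixed = [
        g.b0, g.bCS, g.bCT, g.bR, g.bRL, g.bH, g.bint_CT, g.bint_R,
        init.mu1, det.b0_det, det.b_gs, gs.g0, rod.c0,
    ]
    total += _norm_logpdf(np.array(fixed), priors.fixed_sd)
    for sd in (
        g.sd_line_g, g.sd_region_g, g.sd_year_g, init.sd_eps1,
        det.sd_line_det, det.sd_region_det, gs.sd_line_gs, gs.sd_regionyear_gs,
        rod.sd_year_r, rod.sd_region_r, rod.sd_regionyear_r,
    ):
        lp = _halfnorm_logpdf(sd, priors.sd_scale)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def _latent_from_params(
    data: StudyData, params: ModelParameters, config: ModelConfig
) -> LatentState:
    """Deterministic latent surfaces implied by the parameters."""
    state = LatentState()
    years = range(1, data.n_years + 1)
    for r_idx, rid in enumerate(data.region_ids):
        for t in years:
            state.rodent_p[(rid, t)] = rodent_logit(rid, t, params.rodent)

    class _Cov:
        cs = {tid: data.cs[i] for i, tid in enumerate(data.transect_ids)}
        ct = {
            (tid, t): data.ct[i, t - 1]
            for i, tid in enumerate(data.transect_ids)
            for t in years
        }

    cov = _Cov() if config.climate_terms else None
    g = params.growth
    if not config.rodent_terms:
        g = GrowthParameters(
            **{
                **{k: getattr(g, k) for k in (
                    "b0", "bA", "bCS", "bCT", "bH", "bint_CT",
                    "line_g", "region_g", "year_g",
                    "sd_line_g", "sd_region_g", "sd_year_g",
                )},
                "bR": 0.0, "bRL": 0.0, "bint_R": 0.0,
            }
        )
    for i, tid in enumerate(data.transect_ids):
        rid = data.region_ids[data.region_of_transect[i]]
        state.log_density[(tid, 1)] = params.initial.mu1 + params.initial.eps1.get(tid, 0.0)
        for t in range(2, data.n_years + 1):
            # harvest is stored already lagged (harvest_prev of year t)
            r_it = growth_rate(
                tid, rid, t, state, cov, g,
                harvest_prev=data.harvest[i, t - 1],
                rodent_scale=config.rodent_scale,
            )
            advance_density(state, tid, t, r_it)
    return state


def joint_log_posterior(
    data: StudyData,
    params: ModelParameters,
    config: ModelConfig = ModelConfig(),
    priors: PriorConfig = PriorConfig(),
    latent: Optional[LatentState] = None,
) -> float:
    """Distance + group-size + count + rodent likelihoods, random-effect
    densities and priors, summed.

    The latent state is deterministic given the parameters (the stochastic
    structure lives in the random effects), so it is recomputed unless given.
    """
    if np.isnan(data.cs).any() or np.isnan(data.ct).any():
        raise ValueError("covariates contain NaN")
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    if latent is None:
        latent = _latent_from_params(data, params, config)

    det, gsp = params.detection, params.groupsize
    # random-effect densities
    g, init, rod = params.growth, params.initial, params.rodent
    lp += _norm_logpdf(list(g.line_g.values()), g.sd_line_g)
    lp += _norm_logpdf(list(g.region_g.values()), g.sd_region_g)
    lp += _norm_logpdf(list(g.year_g.values()), g.sd_year_g)
    lp += _norm_logpdf(list(init.eps1.values()), init.sd_eps1)
    lp += _norm_logpdf(list(det.line_det.values()), det.sd_line_det)
    lp += _norm_logpdf(list(det.region_det.values()), det.sd_region_det)
    lp += _norm_logpdf(list(gsp.line_gs.values()), gsp.sd_line_gs)
    lp += _norm_logpdf(list(gsp.regionyear_gs.values()), gsp.sd_regionyear_gs)
    lp += _norm_logpdf(list(rod.year_r.values()), rod.sd_year_r)
    lp += _norm_logpdf(list(rod.region_r.values()), rod.sd_region_r)
    lp += _norm_logpdf(list(rod.regionyear_r.values()), rod.sd_regionyear_r)

    # distance + group-size likelihood per detected cluster
    for k in range(data.n_groups_total):
        i = data.obs_transect[k]
        tid = data.transect_ids[i]
        rid = data.region_ids[data.region_of_transect[i]]
        year = int(data.obs_year[k]) + 1
        sig = detection.sigma(tid, rid, data.obs_size_std[k], det)
        lp += detection.halfnormal_loglik([data.obs_distance[k]], sig, data.trunc_w_m)
        mgs = detection.mean_group_size(tid, rid, year, gsp)
        lp += detection.groupsize_loglik([data.obs_size[k]], mgs, shifted=gsp.shifted)

    # count likelihood per surveyed transect-year
    for i, tid in enumerate(data.transect_ids):
        rid = data.region_ids[data.region_of_transect[i]]
        for t in range(1, data.n_years + 1):
            if not data.surveyed[i, t - 1]:
                continue
            mgs = detection.mean_group_size(tid, rid, t, gsp)
            gs_std = (mgs - data.gs_center) / data.gs_scale
            sig = detection.sigma(tid, rid, gs_std, det)
            mean = expected_count(
                math.exp(latent.log_density[(tid, t)]), data.length_km[i],
                detection.esw(sig),
            )
            lp += count_loglik(data.n_obs[i, t - 1], mean, params.observation)

    # rodent likelihood over non-missing transect-level records
    rodent_obs = []
    for i, tid in enumerate(data.transect_ids):
        rid = data.region_ids[data.region_of_transect[i]]
        for t in range(1, data.n_years + 1):
            v = data.rodent_obs[i, t - 1]
            rodent_obs.append((rid, t, None if np.isnan(v) else int(v)))
    lp += rodent_loglik(rodent_obs, latent.rodent_p)
    return float(lp)


def random_effects_density_surface(
    data: StudyData,
    intercept: float,
    year_d: Mapping[int, float],
    line_d: Mapping[str, float],
    region_d: Mapping[str, float],
    regionyear_d: Mapping[tuple, float],
) -> np.ndarray:
    """ln D surface of the descriptive random-effects state model.

    Additive year + line + region + region-year effects around a grand mean;
    no covariates and no recursion.  Shares the observation layer with the
    Gompertz model.
    """
    out = np.empty((data.n_transects, data.n_years))
    for i, tid in enumerate(data.transect_ids):
        rid = data.region_ids[data.region_of_transect[i]]
        for t in range(1, data.n_years + 1):
            out[i, t - 1] = (
                intercept
                + year_d.get(t, 0.0)
                + line_d.get(tid, 0.0)
                + region_d.get(rid, 0.0)
                + regionyear_d.get((rid, t), 0.0)
            )
    return out
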