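"""Synthetic ptarmigan surveys with known ground truth.

Generates complete studies — landscape of survey regions and line-transects,
a climatic harshness gradient with interannual anomalies, cyclic rodent
occurrence whose peak amplitude grows with harshness, latent Gompertz density
dynamics, and raw distance-sampling observations — so the full fitting
pipeline can be verified by parameter recovery without the original survey
data.

Conventions mirror the survey the model targets: transect lengths log-normal
around 3.7 km, each transect surveyed in at least 6 of ~10 years, regions of
~15 transects, rodent cycles of period ~4 years whose peak occurrence rises
from ~0.38 in the most benign to ~0.64 in the harshest regions, and counts
that are negative-binomial around D·TL·ESW·2.  In the simulator's direct
covariate mode the spatial climate variable CS is a *harshness score* (larger
= colder/later spring), so a positive rodent × CS interaction means a
stronger rodent effect in harsher regions.

All ground-truth defaults live in :data:`DEFAULT_TRUTH`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import special

from . import climate as climate_mod
from .data_model import (
    DailyClimateRecord,
    GroupObservation,
    Transect,
    TransectYear,
    filter_observations,
    write_survey_tables,
)
from .detection import HALF_NORMAL_ESW_FACTOR
from .population import (
    DetectionParameters,
    GroupSizeParameters,
    GrowthParameters,
    InitialDensityParameters,
    ModelParameters,
    ObservationParameters,
    RodentParameters,
    StudyData,
)

__all__ = [
    "DEFAULT_TRUTH",
    "Landscape",
    "SimpleCovariates",
    "RodentTruth",
    "SimulationTruth",
    "SimulatedStudy",
    "generate_landscape",
    "generate_covariates",
    "generate_climate",
    "generate_rodents",
    "generate_ptarmigan",
    "simulate_study",
    "write_fixture",
    "read_truth_manifest",
]

#: Ground-truth parameter values used by default (single source; never scattered).
DEFAULT_TRUTH: dict[str, float] = {
    # growth model: equilibrium ln D* = -b0/bA = 2.5 (~12 birds/km²)
    "b0": 1.75,
    "bA": -0.7,
    "bCS": 0.2,
    "bCT": 0.1,
    "bR": 0.3,
    "bRL": -0.15,
    "bH": 0.0,
    "bint_CT": 0.0,
    "bint_R": 0.2,
    "mu1": 2.5,
    "sd_line_g": 0.05,
    "sd_region_g": 0.05,
    "sd_year_g": 0.10,
    "sd_eps1": 0.40,
    # detection: sigma 68 m at the mean group size -> ESW ~85 m, rising to
    # ~126 m for the largest groups
    "b0_det": math.log(68.0),
    "b_gs": 0.09,
    "sd_line_det": 0.08,
    "sd_region_det": 0.08,
    # shifted-Poisson group sizes, mean ~4.3 birds
    "g0": math.log(3.3),
    "sd_line_gs": 0.10,
    "sd_regionyear_gs": 0.15,
    "nb_dispersion": 3.0,
}


@dataclass
class Landscape:
    """Survey design: transects, regions, years and the surveyed-year mask."""

    transects: list[Transect]
    years: list[int]
    surveyed: np.ndarray  # (T, Y) bool
    region_ids: list[str]
    region_of_transect: np.ndarray
    harshness: np.ndarray  # (R,), 0 = most benign, 1 = harshest
    seed: int

    @property
    def n_transects(self) -> int:
        return len(self.transects)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass
class SimpleCovariates:
    """Standardized CS/CT in the dict interface the model data layer expects."""

    cs: dict
    ct: dict
    harvest: Optional[dict] = None


@dataclass
class RodentTruth:
    """True cyclic region-year occurrence and the noisy transect records."""

    occurrence: np.ndarray  # (R, Y) probabilities
    rodent_obs: np.ndarray  # (T, Y) float with NaN for missing
    period: float
    phases: np.ndarray


@dataclass
class SimulationTruth:
    """Everything the recovery tests need: parameters, surfaces, seed.

    ``rodent_sigma`` is the SD of the centred rodent surface: multiplying the
    probability-scale rodent slopes by it gives standardized effects
    comparable with the standardized climate covariates.
    """

    params: ModelParameters
    ln_density: np.ndarray  # (T, Y)
    rodent: RodentTruth
    gs_center: float
    gs_scale: float
    seed: int
    rodent_sigma: float = 1.0


@dataclass
class SimulatedStudy:
    landscape: Landscape
    covariates: SimpleCovariates
    truth: SimulationTruth
    observations: list[GroupObservation]
    tyears: list[TransectYear]
    data: StudyData


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def generate_landscape(
    n_regions: int = 10,
    transects_per_region: int = 15,
    n_years: int = 10,
    seed: int = 0,
    mean_length_km: float = 3.7,
    length_sd_log: float = 0.3,
    survey_p: float = 0.92,
    min_years: int = 6,
) -> Landscape:
    """Regions on a harshness gradient, log-normal transect lengths, gappy
    surveyed-year masks with every transect surveyed in ≥ ``min_years`` years."""
    if min(n_regions, transects_per_region, n_years) < 1:
        raise ValueError("design sizes must be positive")
    rng = _rng(seed)
    region_ids = [f"R{r:02d}" for r in range(n_regions)]
    harshness = (
        np.linspace(0.0, 1.0, n_regions) if n_regions > 1 else np.array([0.5])
    )
    transects, rof = [], []
    for r, rid in enumerate(region_ids):
        for k in range(transects_per_region):
            length = mean_length_km * math.exp(
                rng.normal(-0.5 * length_sd_log**2, length_sd_log)
            )
            transects.append(Transect(f"{rid}T{k:03d}", rid, length))
            rof.append(r)
    T = len(transects)
    surveyed = rng.random((T, n_years)) < survey_p
    need = min(min_years, n_years)
    for i in range(T):
        short = need - int(surveyed[i].sum())
        if short > 0:
            off = np.flatnonzero(~surveyed[i])
            surveyed[i, rng.choice(off, size=short, replace=False)] = True
    return Landscape(
        transects, list(range(1, n_years + 1)), surveyed, region_ids,
        np.array(rof), harshness, seed,
    )


def generate_covariates(
    landscape: Landscape,
    seed: int = 0,
    transect_cs_sd: float = 0.15,
    region_anomaly_sd: float = 0.8,
    transect_anomaly_sd: float = 0.3,
) -> SimpleCovariates:
    """Direct (daily-series-free) standardized covariates.

    CS is the per-transect harshness score (region gradient plus local
    variation); CT are interannual anomalies shared within region-years plus
    transect-level noise.  Both standardized to mean 0, SD 1.
    """
    rng = _rng(seed)
    rof = landscape.region_of_transect
    T, Y = landscape.n_transects, landscape.n_years
    cs_raw = landscape.harshness[rof] + rng.normal(0, transect_cs_sd, T)
    a_ry = rng.normal(0, region_anomaly_sd, (landscape.n_regions, Y))
    ct_raw = a_ry[rof, :] + rng.normal(0, transect_anomaly_sd, (T, Y))
    tids = [t.transect_id for t in landscape.transects]
    cs_std, _ = climate_mod.standardize(dict(zip(tids, cs_raw)))
    ct_flat = {
        (tid, y): ct_raw[i, t]
        for i, tid in enumerate(tids)
        for t, y in enumerate(landscape.years)
    }
    ct_std, _ = climate_mod.standardize(ct_flat)
    return SimpleCovariates(cs=dict(cs_std), ct=dict(ct_std))


def generate_climate(
    landscape: Landscape,
    seed: int = 0,
    gradient_range_c: float = 8.0,
    anomaly_sd_c: float = 1.0,
    daily_noise_c: float = 1.5,
    start_year: int = 2007,
) -> tuple[list[DailyClimateRecord], list[int]]:
    """Daily temperature and snow series per transect.

    Temperature is a regional mean (linear in harshness), a seasonal sinusoid,
    a region-year anomaly and daily noise; snow follows a simple
    accumulation/melt rule driven by temperature, so spring clears later and
    winter sets in earlier on harsher transects.  Returns the records and the
    calendar analysis years.
    """
    rng = _rng(seed)
    years_cal = [start_year + t for t in landscape.years]
    dates = np.arange(
        np.datetime64(f"{start_year}-07-01"),
        np.datetime64(f"{years_cal[-1]}-07-01"),
    )
    doy = ((dates - dates[0]).astype(int) + 182) % 365  # ~calendar day of year
    date_year = dates.astype("datetime64[Y]").astype(int) + 1970
    seasonal = -11.0 * np.cos(2 * np.pi * (doy - 15) / 365.0)
    anomalies = rng.normal(0.0, anomaly_sd_c, (landscape.n_regions, len(years_cal) + 1))
    records: list[DailyClimateRecord] = []
    for i, tr in enumerate(landscape.transects):
        r = landscape.region_of_transect[i]
        annual_mean = 6.0 - gradient_range_c * landscape.harshness[r] + rng.normal(0, 0.4)
        year_idx = np.clip(date_year - start_year, 0, len(years_cal))
        temp = (
            annual_mean + seasonal + anomalies[r, year_idx]
            + rng.normal(0, daily_noise_c, dates.size)
        )
        snow = np.empty(dates.size)
        s = 0.0
        for k in range(dates.size):
            s = max(0.0, s + (0.5 if temp[k] < 0 else -0.4 * temp[k]))
            snow[k] = s
        day_list = dates.astype("datetime64[D]").astype(object)
        records.extend(
            DailyClimateRecord(tr.transect_id, day_list[k], float(temp[k]), float(snow[k]))
            for k in range(dates.size)
        )
    return records, years_cal


def generate_rodents(
    landscape: Landscape,
    seed: int = 0,
    period: float = 4.0,
    peak_p_cold: float = 0.64,
    peak_p_warm: float = 0.38,
    trough_p: float = 0.05,
    missing_rate: float = 0.10,
    phases=None,
) -> RodentTruth:
    """Cyclic region-year rodent occurrence with harshness-scaled amplitude.

    Occurrence follows a clipped-cosine cycle of the given period, phase drawn
    per region unless ``phases`` gives one per region explicitly (cycles are
    synchronized within, not necessarily across, regions), peaking
    at a level interpolated between the benign-region and harsh-region peak
    probabilities.  Transect-level Bernoulli records are then drawn, with a
    fraction missing.
    """
    if not (0.0 < peak_p_warm <= peak_p_cold < 1.0):
        raise ValueError("need 0 < peak_p_warm <= peak_p_cold < 1")
    if not (0.0 < trough_p <= peak_p_warm):
        raise ValueError("trough_p must lie in (0, peak_p_warm]")
    rng = _rng(seed)
    R_, Y = landscape.n_regions, landscape.n_years
    if phases is None:
        phases = rng.integers(0, int(round(period)), size=R_)
    else:
        phases = np.asarray(phases)
        if phases.size != R_:
            raise ValueError("need one cycle phase per region")
    t_grid = np.arange(Y)
    occ = np.empty((R_, Y))
    for r in range(R_):
        peak = peak_p_warm + landscape.harshness[r] * (peak_p_cold - peak_p_warm)
        c = np.cos(2 * np.pi * (t_grid - phases[r]) / period)
        shape = np.clip(c, 0.0, None) ** 1.5
        occ[r] = trough_p + (peak - trough_p) * shape
    rof = landscape.region_of_transect
    T = landscape.n_transects
    obs = (rng.random((T, Y)) < occ[rof, :]).astype(float)
    obs[~landscape.surveyed] = np.nan
    miss = rng.random((T, Y)) < missing_rate
    obs[miss] = np.nan
    return RodentTruth(occ, obs, period, phases)


def make_truth_params(
    landscape: Landscape, seed: int = 0, **overrides: float
) -> ModelParameters:
    """Draw realized random effects around the default (or overridden) truth."""
    vals = dict(DEFAULT_TRUTH)
    unknown = set(overrides) - set(vals)
    if unknown:
        raise ValueError(f"unknown truth parameters: {sorted(unknown)}")
    vals.update(overrides)
    rng = _rng(seed)
    tids = [t.transect_id for t in landscape.transects]
    rids = landscape.region_ids
    years = landscape.years

    def draw(keys, sd):
        return dict(zip(keys, rng.normal(0.0, sd, len(keys))))

    growth = GrowthParameters(
        b0=vals["b0"], bA=vals["bA"], bCS=vals["bCS"], bCT=vals["bCT"],
        bR=vals["bR"], bRL=vals["bRL"], bH=vals["bH"],
        bint_CT=vals["bint_CT"], bint_R=vals["bint_R"],
        line_g=draw(tids, vals["sd_line_g"]),
        region_g=draw(rids, vals["sd_region_g"]),
        year_g=draw(years[1:], vals["sd_year_g"]),
        sd_line_g=vals["sd_line_g"], sd_region_g=vals["sd_region_g"],
        sd_year_g=vals["sd_year_g"],
    )
    initial = InitialDensityParameters(
        mu1=vals["mu1"], eps1=draw(tids, vals["sd_eps1"]), sd_eps1=vals["sd_eps1"]
    )
    det = DetectionParameters(
        b0_det=vals["b0_det"], b_gs=vals["b_gs"],
        line_det=draw(tids, vals["sd_line_det"]),
        region_det=draw(rids, vals["sd_region_det"]),
        sd_line_det=vals["sd_line_det"], sd_region_det=vals["sd_region_det"],
    )
    gsp = GroupSizeParameters(
        g0=vals["g0"],
        line_gs=draw(tids, vals["sd_line_gs"]),
        regionyear_gs=draw(
            [(rid, y) for rid in rids for y in years], vals["sd_regionyear_gs"]
        ),
        sd_line_gs=vals["sd_line_gs"], sd_regionyear_gs=vals["sd_regionyear_gs"],
    )
    return ModelParameters(
        growth=growth,
        initial=initial,
        observation=ObservationParameters(nb_dispersion=vals["nb_dispersion"]),
        rodent=RodentParameters(),
        detection=det,
        groupsize=gsp,
    )


def _truncated_halfnormal(rng, sigma: np.ndarray, w: float) -> np.ndarray:
    """Detected distances: uniform candidates on [0, w] thinned by the
    half-normal detection function (kept until every slot is filled)."""
    n = sigma.size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cand = rng.uniform(0.0, w, todo.size)
        keep = rng.random(todo.size) < np.exp(-(cand**2) / (2.0 * sigma[todo] ** 2))
        out[todo[keep]] = cand[keep]
        todo = todo[~keep]
    return out


def generate_ptarmigan(
    landscape: Landscape,
    covariates: SimpleCovariates,
    rodents: RodentTruth,
    params: ModelParameters,
    seed: int = 0,
    rodent_scale: str = "centred",
    decoy_rate: float = 0.02,
    trunc_w_m: float = 200.0,
) -> tuple[list[GroupObservation], list[TransectYear], SimulationTruth]:
    """Forward-simulate the full generative model.

    ln D follows the Gompertz recursion under the true parameters.  The total
    count on a surveyed transect-year is Poisson(N·ω) with ω ~ Gamma(r, r) —
    i.e. exactly the negative binomial with mean N and dispersion r that the
    observation model assumes — and is then partitioned into detected clusters
    with shifted-Poisson sizes (the last cluster trimmed so sizes sum to the
    count).  Detected distances are uniform candidates thinned by
    exp(−d²/2σ²), i.e. truncated half-normal.  A small fraction of decoy
    surveyor-flush records beyond the 10 m surveyor limit is appended (they
    are removed by the standard filters and never counted in ``n_obs``).
    """
    rng = _rng(seed)
    T, Y, R_ = landscape.n_transects, landscape.n_years, landscape.n_regions
    rof = landscape.region_of_transect
    tids = [t.transect_id for t in landscape.transects]
    rids = landscape.region_ids
    g, init = params.growth, params.initial
    det, gsp = params.detection, params.groupsize
    disp = params.observation.nb_dispersion

    cs = np.array([covariates.cs[tid] for tid in tids])
    ct = np.array([[covariates.ct[(tid, y)] for y in landscape.years] for tid in tids])
    harvest = rng.standard_normal((T, Y))  # pre-standardized white-noise index
    Rc = rodents.occurrence - 0.5 if rodent_scale == "centred" else rodents.occurrence
    Rct = Rc[rof, :]
    # SD of the centred rodent surface: the factor that converts the fitted
    # probability-scale slopes to standardized effects for reporting
    rodent_sigma = float(np.std(Rc)) or 1.0

    line_g = np.array([g.line_g[tid] for tid in tids])
    region_g = np.array([g.region_g[rid] for rid in rids])[rof]
    year_g = np.array([g.year_g[y] for y in landscape.years[1:]])
    eps1 = np.array([init.eps1[tid] for tid in tids])

    lnD = np.empty((T, Y))
    lnD[:, 0] = init.mu1 + eps1
    for t in range(1, Y):
        r_t = (
            g.b0 + g.bA * lnD[:, t - 1] + line_g + region_g + year_g[t - 1]
            + g.bCS * cs + g.bCT * ct[:, t]
            + g.bR * Rct[:, t] + g.bRL * Rct[:, t - 1]
            + g.bH * harvest[:, t]
            + g.bint_CT * cs * ct[:, t] + g.bint_R * cs * Rct[:, t]
        )
        lnD[:, t] = lnD[:, t - 1] + r_t

    # reference group-size standardization implied by the truth
    lam0 = math.exp(gsp.g0)
    gs_center, gs_scale = lam0 + 1.0, math.sqrt(lam0)

    line_det = np.array([det.line_det[tid] for tid in tids])
    region_det = np.array([det.region_det[rid] for rid in rids])[rof]
    lam_ty = np.exp(
        gsp.g0
        + np.array([gsp.line_gs[tid] for tid in tids])[:, None]
        + np.array(
            [[gsp.regionyear_gs[(rids[rof[i]], y)] for y in landscape.years]
             for i in range(T)]
        )
    )
    mean_gs = lam_ty + 1.0
    sigma_ty = np.exp(
        det.b0_det + det.b_gs * (mean_gs - gs_center) / gs_scale
        + line_det[:, None] + region_det[:, None]
    )
    TL = np.array([t.length_km for t in landscape.transects])
    nmean = np.exp(lnD) * TL[:, None] * sigma_ty * HALF_NORMAL_ESW_FACTOR * 2.0 / 1000.0

    # surveyed cells: total counts are negative binomial around N (realized as
    # the Poisson-Gamma mixture at the transect-year level), then partitioned
    # into detected clusters with shifted-Poisson sizes (the last cluster is
    # trimmed to make the sizes sum exactly to the count)
    cell_i, cell_t = np.nonzero(landscape.surveyed)
    mean_cell = nmean[cell_i, cell_t]
    omega = rng.gamma(shape=disp, scale=1.0 / disp, size=cell_i.size)
    n_birds = rng.poisson(mean_cell * omega)
    gi_list, gt_list, size_list = [], [], []
    for k in range(cell_i.size):
        remaining = int(n_birds[k])
        lam_cell = lam_ty[cell_i[k], cell_t[k]]
        while remaining > 0:
            s = min(1 + int(rng.poisson(lam_cell)), remaining)
            gi_list.append(cell_i[k])
            gt_list.append(cell_t[k])
            size_list.append(s)
            remaining -= s
    gi = np.array(gi_list, dtype=int)
    gt = np.array(gt_list, dtype=int)
    sizes = np.array(size_list, dtype=int)
    sig_g = np.exp(
        det.b0_det + det.b_gs * (sizes - gs_center) / gs_scale
        + line_det[gi] + region_det[gi]
    )
    dists = _truncated_halfnormal(rng, sig_g, trunc_w_m)

    observations = [
        GroupObservation(tids[gi[k]], int(gt[k]) + 1, float(dists[k]),
                         int(sizes[k]), "dog")
        for k in range(gi.size)
    ]
    # decoy surveyor-flush records, removed by the standard filters
    n_decoy = rng.poisson(decoy_rate * max(gi.size, 1))
    if n_decoy:
        pick = rng.integers(0, cell_i.size, n_decoy)
        observations.extend(
            GroupObservation(
                tids[cell_i[p]], int(cell_t[p]) + 1,
                float(rng.uniform(10.5, trunc_w_m)), int(rng.poisson(lam0) + 1),
                "surveyor",
            )
            for p in pick
        )

    n_obs = np.zeros((T, Y), dtype=int)
    np.add.at(n_obs, (gi, gt), sizes)
    tyears = []
    for i, t in zip(cell_i, cell_t):
        rod = rodents.rodent_obs[i, t]
        tyears.append(
            TransectYear(
                tids[i], int(t) + 1, n_obs=int(n_obs[i, t]),
                rodent_obs=None if np.isnan(rod) else int(rod),
                harvest_prev=float(harvest[i, t]),
            )
        )
    truth = SimulationTruth(params, lnD, rodents, gs_center, gs_scale, seed,
                            rodent_sigma=rodent_sigma)
    return observations, tyears, truth


def simulate_study(
    n_regions: int = 10,
    transects_per_region: int = 15,
    n_years: int = 10,
    seed: int = 0,
    rodent_scale: str = "centred",
    decoy_rate: float = 0.02,
    **truth_overrides: float,
) -> SimulatedStudy:
    """One call from design to fit-ready :class:`StudyData`, with truth attached.

    Sub-seeds for the landscape, covariates, rodents, parameters and the
    observation process are derived deterministically from ``seed``.
    """
    sub = [int(s) for s in np.random.SeedSequence(seed).generate_state(5) & 0x7FFFFFFF]
    landscape = generate_landscape(n_regions, transects_per_region, n_years, seed=sub[0])
    cov = generate_covariates(landscape, seed=sub[1])
    rodents = generate_rodents(landscape, seed=sub[2])
    params = make_truth_params(landscape, seed=sub[3], **truth_overrides)
    observations, tyears, truth = generate_ptarmigan(
        landscape, cov, rodents, params, seed=sub[4],
        rodent_scale=rodent_scale, decoy_rate=decoy_rate,
    )
    retained = filter_observations(observations)
    data = StudyData.from_records(
        landscape.transects, retained, tyears, cov, years=landscape.years
    )
    return SimulatedStudy(landscape, cov, truth, observations, tyears, data)


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(directory, study: SimulatedStudy) -> dict[str, Path]:
    """Write the study as CSVs in the standard dialect plus a truth manifest."""
    directory = Path(directory)
    paths = write_survey_tables(
        directory, study.landscape.transects, study.observations, study.tyears
    )
    import pandas as pd

    tids = [t.transect_id for t in study.landscape.transects]
    cov_rows = [
        {"transect_id": tid, "year": y, "cs": study.covariates.cs[tid],
         "ct": study.covariates.ct[(tid, y)]}
        for tid in tids
        for y in study.landscape.years
    ]
    paths["covariates"] = directory / "covariates.csv"
    pd.DataFrame(cov_rows).to_csv(paths["covariates"], index=False)

    truth = study.truth
    manifest = {
        "seed": truth.seed,
        "design": {
            "n_regions": study.landscape.n_regions,
            "n_transects": study.landscape.n_transects,
            "n_years": study.landscape.n_years,
        },
        "fixed_effects": {
            k: getattr(truth.params.growth, k)
            for k in ("b0", "bA", "bCS", "bCT", "bR", "bRL", "bH", "bint_CT", "bint_R")
        },
        "mu1": truth.params.initial.mu1,
        "rodent_sigma": truth.rodent_sigma,
        "nb_dispersion": truth.params.observation.nb_dispersion,
        "b0_det": truth.params.detection.b0_det,
        "b_gs": truth.params.detection.b_gs,
        "g0": truth.params.groupsize.g0,
        "rodent_occurrence": truth.rodent.occurrence.tolist(),
    }
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(manifest, indent=2))
    return paths


def read_truth_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
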