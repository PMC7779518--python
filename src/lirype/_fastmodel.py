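"""Array-vectorized joint model used by the MCMC sampler.

This is the computational twin of :mod:`lirype.population`: the same posterior
written over flat parameter vectors with cached likelihood components, so that
the blocked adaptive Metropolis-within-Gibbs sampler can update large
random-effect families in single vectorized passes.  Families whose members
are conditionally independent given the rest (transect effects, region
effects, region-year effects) are proposed jointly and accepted element-wise;
correlated fixed-effect blocks use adaptive multivariate random walks.

Consistency with the readable reference implementation is asserted by tests
(the two must agree to near machine precision on fixtures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .detection import HALF_NORMAL_ESW_FACTOR
from .population import ModelConfig, PriorConfig, StudyData

__all__ = ["JointModel", "Layout", "MvRW", "GaussianMeanToy"]

_SQRT2 = math.sqrt(2.0)
_NEG = -1.0e300

try:  # optional JIT for the growth-side hot loop; numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _growth_side_py(gf, yg, cs, ct, harv, Rct, addg, lnD1, TLfacK, sigma_ty,
                    n_obs0, surveyed, ccon, rdisp):
    """Gompertz recursion + expected counts + NB log-likelihood in one pass."""
    T, Y = ct.shape
    lnD = np.empty((T, Y))
    nmean = np.empty((T, Y))
    cll = np.zeros((T, Y))
    b0, bA, bCS, bCT, bR, bRL, bH, bint_CT, bint_R, mu1 = gf
    for i in range(T):
        prev = lnD1[i]
        for t in range(Y):
            if t > 0:
                r_it = (
                    b0 + bA * prev + addg[i] + yg[t - 1]
                    + bCS * cs[i] + bCT * ct[i, t] + bH * harv[i, t]
                    + bR * Rct[i, t] + bRL * Rct[i, t - 1]
                    + bint_CT * cs[i] * ct[i, t] + bint_R * cs[i] * Rct[i, t]
                )
                prev = prev + r_it
            lnD[i, t] = prev
            nm = math.exp(min(prev, 700.0)) * TLfacK[i] * sigma_ty[i, t]
            nmean[i, t] = nm
            if surveyed[i, t]:
                n = n_obs0[i, t]
                nm_safe = nm if nm > 1e-300 else 1e-300
                ll = (ccon[i, t] + n * math.log(nm_safe)
                      - (n + rdisp) * math.log(rdisp + nm_safe))
                cll[i, t] = ll if math.isfinite(ll) else -1.0e300
    return lnD, nmean, cll


def _dist_ll_py(sig_obs, od2, w):
    """Truncated half-normal log-density per detected distance."""
    out = np.empty(sig_obs.size)
    k_esw = math.sqrt(math.pi / 2.0)
    sqrt2 = math.sqrt(2.0)
    for k in range(sig_obs.size):
        sig = sig_obs[k]
        if sig <= 1e-6 or not math.isfinite(sig):
            out[k] = -1.0e300
            continue
        norm = sig * k_esw * math.erf(w / (sig * sqrt2))
        ll = -od2[k] / (2.0 * sig * sig) - math.log(norm)
        out[k] = ll if math.isfinite(ll) else -1.0e300
    return out


if _HAVE_NUMBA:
    _growth_side_jit = _njit(cache=False)(_growth_side_py)
    _dist_ll_jit = _njit(cache=False)(_dist_ll_py)
else:  # pragma: no cover
    _growth_side_jit = _growth_side_py
    _dist_ll_jit = _dist_ll_py

GROWTH_FIXED = ("b0", "bA", "bCS", "bCT", "bR", "bRL", "bH", "bint_CT", "bint_R", "mu1")


class Layout:
    """Maps named parameter blocks to slices of the flat vector."""

    def __init__(self) -> None:
        self.slices: dict[str, slice] = {}
        self.size = 0

    def add(self, name: str, n: int) -> slice:
        s = slice(self.size, self.size + n)
        self.slices[name] = s
        self.size += n
        return s

    def __getitem__(self, name: str) -> slice:
        return self.slices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.slices

    def names_flat(self) -> list[str]:
        out = []
        for name, s in self.slices.items():
            n = s.stop - s.start
            if n == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{k}]" for k in range(n))
        return out


class MvRW:
    """Adaptive multivariate random-walk proposal (Haario-style).

    Keeps a running mean/covariance of the chain for this block and scales a
    Gaussian proposal by 2.38²/d, with a global log-scale tuned toward 23.4%
    acceptance (diminishing adaptation).
    """

    def __init__(self, d: int, init_scale: float = 0.1, learn_cov: bool = True) -> None:
        self.d = d
        self.log_scale = 0.0
        self.init_scale = init_scale
        self.learn_cov = learn_cov
        self.n = 0
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self._chol: np.ndarray | None = None

    def propose(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        z = rng.standard_normal(self.d)
        if self.n < 10 * self.d or self._chol is None:
            step = self.init_scale * math.exp(self.log_scale) * z
        else:
            step = (2.38 / math.sqrt(self.d)) * math.exp(self.log_scale) * (self._chol @ z)
        return x + step

    def update(self, accepted: bool, x: np.ndarray, it: int) -> None:
        gamma = min(0.25, 2.0 / math.sqrt(it + 10.0))
        self.log_scale += gamma * ((1.0 if accepted else 0.0) - 0.234)
        if not self.learn_cov or self.d == 1:
            return
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, x - self.mean)
        if self.n >= 10 * self.d and self.n % 25 == 0:
            cov = self.m2 / max(self.n - 1, 1) + 1e-9 * np.eye(self.d)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                self._chol = None


@dataclass
class VecRW:
    """Per-coordinate adaptive scales for element-wise vector updates."""

    log_scale: np.ndarray

    @classmethod
    def make(cls, n: int, init: float = 0.2) -> "VecRW":
        return cls(np.full(n, math.log(init)))

    def step(self, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.log_scale) * rng.standard_normal(self.log_scale.size)

    def update(self, accepted: np.ndarray, it: int) -> None:
        gamma = min(0.25, 2.0 / math.sqrt(it + 10.0))
        self.log_scale += gamma * (accepted.astype(float) - 0.44)
        np.clip(self.log_scale, -10.0, 3.0, out=self.log_scale)


def _norm_lpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * x.size * math.log(2 * math.pi) - x.size * math.log(sd)
                 - 0.5 * float(np.sum(x * x)) / (sd * sd))


class JointModel:
    """The joint posterior over a flat parameter vector, with block updates."""

    def __init__(
        self,
        data: StudyData,
        config: ModelConfig = ModelConfig(),
        priors: PriorConfig = PriorConfig(),
        growth_block_repeats: int = 3,
    ) -> None:
        self.data = data
        self.config = config
        self.priors = priors
        # how often per sweep to update the correlated growth fixed-effect
        # block (it mixes slowest; more repeats buy ESS per iteration)
        self.growth_block_repeats = growth_block_repeats
        d = data
        self.T, self.R, self.Y = d.n_transects, d.n_regions, d.n_years
        self.rof = d.region_of_transect
        self.w = d.trunc_w_m
        self.TLfac = d.length_km * 2.0 / 1000.0  # ESW in m -> expected count
        self.surveyed = d.surveyed
        self.n_obs0 = np.nan_to_num(d.n_obs)
        self.cs = d.cs
        self.ct = d.ct
        self.harv = d.harvest  # stored already lagged: column t holds H_prev of year t
        self.k1, self.k0 = d.rodent_k1, d.rodent_k0
        self._csct = self.cs[:, None] * self.ct
        self._TLfacK = self.TLfac * HALF_NORMAL_ESW_FACTOR
        self._kernel = _growth_side_jit

        # per-cell tallies of the detected clusters
        self.S1 = np.zeros((self.T, self.Y))
        self.n_g = np.zeros((self.T, self.Y))
        self.Cgs = np.zeros((self.T, self.Y))
        np.add.at(self.S1, (d.obs_transect, d.obs_year), d.obs_size - 1.0)
        np.add.at(self.n_g, (d.obs_transect, d.obs_year), 1.0)
        np.add.at(self.Cgs, (d.obs_transect, d.obs_year), special.gammaln(d.obs_size))
        self.ot, self.oy = d.obs_transect, d.obs_year
        self.od = d.obs_distance
        self.od2 = self.od**2
        self.oz = d.obs_size_std
        self.gs_center, self.gs_scale = d.gs_center, d.gs_scale

        self._build_layout()

    # ------------------------------------------------------------------ layout

    def _build_layout(self) -> None:
        L = Layout()
        cfg = self.config
        if cfg.state == "gompertz":
            L.add("growth_fixed", len(GROWTH_FIXED))
            self.active_growth = [
                k for k, name in enumerate(GROWTH_FIXED)
                if not (
                    (name in ("bR", "bRL", "bint_R") and not cfg.rodent_terms)
                    or (name in ("bCS", "bCT", "bint_CT") and not cfg.climate_terms)
                )
            ]
            L.add("line_g", self.T)
            L.add("region_g", self.R)
            L.add("year_g", self.Y - 1)
            L.add("eps1", self.T)
            for s in ("sd_line_g", "sd_region_g", "sd_year_g", "sd_eps1"):
                L.add(s, 1)
        else:
            L.add("mu_d", 1)
            L.add("year_d", self.Y)
            L.add("line_d", self.T)
            L.add("region_d", self.R)
            L.add("regionyear_d", self.R * self.Y)
            for s in ("sd_year_d", "sd_line_d", "sd_region_d", "sd_regionyear_d"):
                L.add(s, 1)
        L.add("nb_dispersion", 1)
        L.add("det_fixed", 2)  # b0_det, b_gs
        L.add("line_det", self.T)
        L.add("region_det", self.R)
        L.add("sd_line_det", 1)
        L.add("sd_region_det", 1)
        L.add("g0", 1)
        L.add("line_gs", self.T)
        L.add("regionyear_gs", self.R * self.Y)
        L.add("sd_line_gs", 1)
        L.add("sd_regionyear_gs", 1)
        L.add("c0", 1)
        L.add("year_r", self.Y)
        L.add("region_r", self.R)
        L.add("regionyear_r", self.R * self.Y)
        for s in ("sd_year_r", "sd_region_r", "sd_regionyear_r"):
            L.add(s, 1)
        self.layout = L
        self.n_params = L.size

        if cfg.state == "gompertz":
            self.monitor = [
                "growth_fixed", "nb_dispersion", "det_fixed", "g0", "c0",
                "sd_line_g", "sd_year_g", "sd_eps1",
            ]
            # pretty names for the flattened monitored scalars
            self.monitor_names = list(GROWTH_FIXED) + [
                "nb_dispersion", "b0_det", "b_gs", "g0", "c0",
                "sd_line_g", "sd_year_g", "sd_eps1",
            ]
        else:
            self.monitor = ["mu_d", "nb_dispersion", "det_fixed", "g0", "c0"]
            self.monitor_names = ["mu_d", "nb_dispersion", "b0_det", "b_gs", "g0", "c0"]

    def monitor_values(self, theta: np.ndarray) -> np.ndarray:
        return np.concatenate([np.atleast_1d(theta[self.layout[b]]) for b in self.monitor])

    # ----------------------------------------------------------------- getters

    def _g(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.layout[name]]

    def _s(self, theta: np.ndarray, name: str) -> float:
        return float(theta[self.layout[name].start])

    def _growth_coefs(self, theta: np.ndarray) -> dict[str, float]:
        vals = self._g(theta, "growth_fixed")
        return dict(zip(GROWTH_FIXED, vals))

    # ------------------------------------------------------------- model parts

    def _rodent_surface(self, theta: np.ndarray):
        ry = self._g(theta, "regionyear_r").reshape(self.R, self.Y)
        eta = (
            self._s(theta, "c0")
            + self._g(theta, "year_r")[None, :]
            + self._g(theta, "region_r")[:, None]
            + ry
        )
        Rp = special.expit(eta)
        Rc = Rp - 0.5 if self.config.rodent_scale == "centred" else Rp
        with np.errstate(divide="ignore", invalid="ignore"):
            rll = self.k1 * np.log(Rp) + self.k0 * np.log1p(-Rp)
        rll = np.where(np.isfinite(rll), rll, _NEG)
        return Rp, Rc, rll

    def _base(self, theta: np.ndarray, Rc: np.ndarray) -> np.ndarray:
        """Exogenous part of the growth increment for columns 1..Y-1."""
        b0, bA, bCS, bCT, bR, bRL, bH, bint_CT, bint_R, mu1 = self._g(theta, "growth_fixed")
        yg = self._g(theta, "year_g")
        Rct = Rc[self.rof, :]
        base = np.zeros((self.T, self.Y))
        base[:, 1:] = (
            b0 + yg[None, :]
            + bCS * self.cs[:, None] + bCT * self.ct[:, 1:]
            + bH * self.harv[:, 1:]
            + bR * Rct[:, 1:] + bRL * Rct[:, :-1]
            + bint_CT * self._csct[:, 1:]
            + bint_R * self.cs[:, None] * Rct[:, 1:]
        )
        return base

    def _recur(self, base: np.ndarray, addg: np.ndarray, bA: float,
               lnD1: np.ndarray) -> np.ndarray:
        lnD = np.empty((self.T, self.Y))
        lnD[:, 0] = lnD1
        fac = 1.0 + bA
        for t in range(1, self.Y):
            lnD[:, t] = lnD[:, t - 1] * fac + base[:, t] + addg
        return lnD

    def _lnD(self, theta: np.ndarray, Rc: np.ndarray) -> np.ndarray:
        if self.config.state == "random_effects":
            ry = self._g(theta, "regionyear_d").reshape(self.R, self.Y)
            return (
                self._s(theta, "mu_d")
                + self._g(theta, "year_d")[None, :]
                + self._g(theta, "line_d")[:, None]
                + self._g(theta, "region_d")[self.rof, None]
                + ry[self.rof, :]
            )
        g = self._growth_coefs(theta)
        addg = self._g(theta, "line_g") + self._g(theta, "region_g")[self.rof]
        base = self._base(theta, Rc)
        lnD1 = g["mu1"] + self._g(theta, "eps1")
        return self._recur(base, addg, g["bA"], lnD1)

    def _lam(self, theta: np.ndarray) -> np.ndarray:
        ry = self._g(theta, "regionyear_gs").reshape(self.R, self.Y)
        eta = self._s(theta, "g0") + self._g(theta, "line_gs")[:, None] + ry[self.rof, :]
        with np.errstate(over="ignore"):
            return np.exp(eta)

    def _gs_ll(self, lam: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = self.S1 * np.log(lam) - self.n_g * lam - self.Cgs
        return np.where(np.isfinite(ll), ll, _NEG)

    def _sigma_ty(self, theta: np.ndarray, lam: np.ndarray) -> np.ndarray:
        b0d, bgs = self._g(theta, "det_fixed")
        gs_std = (lam + 1.0 - self.gs_center) / self.gs_scale
        eta = (
            b0d + bgs * gs_std
            + self._g(theta, "line_det")[:, None]
            + self._g(theta, "region_det")[self.rof, None]
        )
        with np.errstate(over="ignore"):
            return np.exp(eta)

    def _nmean(self, lnD: np.ndarray, sigma_ty: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(lnD) * self.TLfac[:, None] * sigma_ty * HALF_NORMAL_ESW_FACTOR

    def _count_const(self, r: float) -> np.ndarray:
        n = self.n_obs0
        return (
            special.gammaln(n + r) - special.gammaln(r) - special.gammaln(n + 1)
            + r * math.log(r)
        )

    def _count_ll(self, nmean: np.ndarray, ccon: np.ndarray, r: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = ccon + self.n_obs0 * np.log(nmean) - (self.n_obs0 + r) * np.log(r + nmean)
        ll = np.where(np.isfinite(ll), ll, _NEG)
        return np.where(self.surveyed, ll, 0.0)

    def _sig_obs(self, theta: np.ndarray) -> np.ndarray:
        b0d, bgs = self._g(theta, "det_fixed")
        eta = (
            b0d + bgs * self.oz
            + self._g(theta, "line_det")[self.ot]
            + self._g(theta, "region_det")[self.rof[self.ot]]
        )
        with np.errstate(over="ignore"):
            return np.exp(eta)

    def _dist_ll(self, sig_obs: np.ndarray) -> np.ndarray:
        return _dist_ll_jit(np.ascontiguousarray(sig_obs), self.od2, self.w)

    # -------------------------------------------------------------- full target

    def make_cache(self, theta: np.ndarray, base: dict | None = None,
                   parts: set | None = None) -> dict:
        """Likelihood component cache; with ``base``/``parts``, only the named
        parts ('rodent', 'growth', 'gs', 'det', 'disp') are recomputed."""
        if base is None or parts is None:
            parts = {"rodent", "growth", "gs", "det", "disp"}
            out = {}
        else:
            out = dict(base)
        if "rodent" in parts:
            out["Rp"], out["Rc"], out["rll"] = self._rodent_surface(theta)
        if "gs" in parts:
            out["lam"] = self._lam(theta)
            out["gs_ll"] = self._gs_ll(out["lam"])
        if "gs" in parts or "det" in parts:
            out["sigma_ty"] = self._sigma_ty(theta, out["lam"])
        if "det" in parts:
            out["sig_obs"] = self._sig_obs(theta)
            out["dist_ll"] = self._dist_ll(out["sig_obs"])
        r = self._s(theta, "nb_dispersion")
        if "disp" in parts:
            out["ccon"] = self._count_const(r)
        if self.config.state == "gompertz":
            out["lnD"], out["nmean"], out["count_ll"] = self._growth_eval(
                theta, out["Rc"], out["sigma_ty"], out["ccon"], r
            )
        else:
            if "growth" in parts or "rodent" in parts:
                out["lnD"] = self._lnD(theta, out["Rc"])
            out["nmean"] = self._nmean(out["lnD"], out["sigma_ty"])
            out["count_ll"] = self._count_ll(out["nmean"], out["ccon"], r)
        return out

    def _growth_eval(self, theta, Rc, sigma_ty, ccon, rdisp,
                     addg=None, lnD1=None):
        gf = self._g(theta, "growth_fixed")
        yg = self._g(theta, "year_g")
        if addg is None:
            addg = self._g(theta, "line_g") + self._g(theta, "region_g")[self.rof]
        if lnD1 is None:
            lnD1 = gf[GROWTH_FIXED.index("mu1")] + self._g(theta, "eps1")
        return self._kernel(
            gf, yg, self.cs, self.ct, self.harv, Rc[self.rof, :],
            np.ascontiguousarray(addg), np.ascontiguousarray(lnD1),
            self._TLfacK, sigma_ty, self.n_obs0, self.surveyed, ccon, rdisp,
        )

    def _re_families(self):
        if self.config.state == "gompertz":
            fams = [("line_g", "sd_line_g"), ("region_g", "sd_region_g"),
                    ("year_g", "sd_year_g"), ("eps1", "sd_eps1")]
        else:
            fams = [("year_d", "sd_year_d"), ("line_d", "sd_line_d"),
                    ("region_d", "sd_region_d"), ("regionyear_d", "sd_regionyear_d")]
        fams += [
            ("line_det", "sd_line_det"), ("region_det", "sd_region_det"),
            ("line_gs", "sd_line_gs"), ("regionyear_gs", "sd_regionyear_gs"),
            ("year_r", "sd_year_r"), ("region_r", "sd_region_r"),
            ("regionyear_r", "sd_regionyear_r"),
        ]
        return fams

    def log_prior_fixed(self, theta: np.ndarray) -> float:
        """Priors on fixed effects, dispersion and SD terms (not REs)."""
        pr = self.priors
        total = 0.0
        if self.config.state == "gompertz":
            g = self._growth_coefs(theta)
            if not (pr.bA_lo < g["bA"] < pr.bA_hi):
                return -np.inf
            total += -math.log(pr.bA_hi - pr.bA_lo)
            fixed = [g[n] for n in GROWTH_FIXED if n != "bA"]
        else:
            fixed = [self._s(theta, "mu_d")]
        disp = self._s(theta, "nb_dispersion")
        if not (pr.disp_lo < disp < pr.disp_hi):
            return -np.inf
        total += -math.log(pr.disp_hi - pr.disp_lo)
        fixed += list(self._g(theta, "det_fixed"))
        fixed += [self._s(theta, "g0"), self._s(theta, "c0")]
        total += _norm_lpdf_sum(np.array(fixed), pr.fixed_sd)
        for _, sd_name in self._re_families():
            sd = self._s(theta, sd_name)
            if sd <= 0:
                return -np.inf
            total += 0.5 * math.log(2 / math.pi) - math.log(pr.sd_scale) \
                - 0.5 * (sd / pr.sd_scale) ** 2
        return total

    def log_re_density(self, theta: np.ndarray) -> float:
        total = 0.0
        for fam, sd_name in self._re_families():
            total += _norm_lpdf_sum(self._g(theta, fam), self._s(theta, sd_name))
        return total

    def log_posterior(self, theta: np.ndarray, cache: dict | None = None) -> float:
        lp = self.log_prior_fixed(theta)
        if not np.isfinite(lp):
            return -np.inf
        if cache is None:
            cache = self.make_cache(theta)
        lp += self.log_re_density(theta)
        lp += float(np.sum(cache["rll"]))
        lp += float(np.sum(cache["count_ll"]))
        lp += float(np.sum(cache["gs_ll"]))
        lp += float(np.sum(cache["dist_ll"]))
        return lp

    # -------------------------------------------------------------------- init

    def init_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Data-informed starting point, jittered deterministically from rng."""
        theta = np.zeros(self.n_params)
        L = self.layout
        d = self.data
        sig_hat = math.sqrt(max(float(np.mean(self.od2)), 1.0)) if self.od.size else 50.0
        theta[L["det_fixed"].start] = math.log(sig_hat)
        mean_size = float(d.obs_size.mean()) if d.obs_size.size else 2.0
        theta[L["g0"].start] = math.log(max(mean_size - 1.0, 0.2))
        esw0 = sig_hat * HALF_NORMAL_ESW_FACTOR
        with np.errstate(invalid="ignore"):
            dens = self.n_obs0[self.surveyed] / (
                np.broadcast_to(self.TLfac[:, None], self.n_obs0.shape)[self.surveyed] * esw0
            )
        d_hat = max(float(np.mean(dens)), 0.05) if dens.size else 1.0
        if self.config.state == "gompertz":
            gf = theta[L["growth_fixed"]]
            gf[GROWTH_FIXED.index("bA")] = -0.5
            gf[GROWTH_FIXED.index("mu1")] = math.log(d_hat)
            gf[GROWTH_FIXED.index("b0")] = 0.5 * math.log(d_hat)
        else:
            theta[L["mu_d"].start] = math.log(d_hat)
        ktot1, ktot0 = float(self.k1.sum()), float(self.k0.sum())
        p_hat = (ktot1 + 1.0) / (ktot1 + ktot0 + 2.0)
        theta[L["c0"].start] = math.log(p_hat / (1 - p_hat))
        theta[L["nb_dispersion"].start] = 2.0
        for _, sd_name in self._re_families():
            theta[L[sd_name].start] = 0.3
        # deterministic jitter from the chain's rng
        jit = 0.05 * rng.standard_normal(self.n_params)
        theta = theta + jit
        # keep constrained scalars inside support
        if self.config.state == "gompertz":
            i_bA = L["growth_fixed"].start + GROWTH_FIXED.index("bA")
            theta[i_bA] = float(np.clip(theta[i_bA], -1.9, -0.05))
            for k in range(len(GROWTH_FIXED)):
                if k not in self.active_growth:
                    theta[L["growth_fixed"].start + k] = 0.0
        i_d = L["nb_dispersion"].start
        theta[i_d] = float(np.clip(theta[i_d], 0.1, 40.0))
        for _, sd_name in self._re_families():
            i = L[sd_name].start
            theta[i] = float(np.clip(abs(theta[i]), 0.05, 5.0))
        lp = self.log_posterior(theta)
        if not np.isfinite(lp):
            raise RuntimeError("non-finite posterior at initialization")
        return theta

    # ------------------------------------------------------------------ blocks

    def new_adapt(self) -> dict:
        L = self.layout
        ad: dict[str, object] = {}
        if self.config.state == "gompertz":
            ad["growth_fixed"] = MvRW(len(self.active_growth), init_scale=0.05)
            ad["year_g"] = MvRW(self.Y - 1, init_scale=0.05)
            for fam in ("line_g", "region_g", "eps1"):
                ad[fam] = VecRW.make(L[fam].stop - L[fam].start, 0.1)
        else:
            ad["mu_d"] = MvRW(1, init_scale=0.1)
            for fam in ("year_d", "line_d", "region_d", "regionyear_d"):
                ad[fam] = VecRW.make(L[fam].stop - L[fam].start, 0.2)
        if self.config.state == "gompertz":
            ad["growth_ridge"] = MvRW(1, init_scale=0.15)
        ad["det_fixed"] = MvRW(2, init_scale=0.02)
        ad["g0"] = MvRW(1, init_scale=0.05)
        ad["c0"] = MvRW(1, init_scale=0.1)
        ad["year_r"] = MvRW(self.Y, init_scale=0.1)
        ad["nb_dispersion"] = MvRW(1, init_scale=0.1)
        for fam in ("line_det", "region_det", "line_gs"):
            ad[fam] = VecRW.make(L[fam].stop - L[fam].start, 0.1)
        ad["regionyear_gs"] = VecRW.make(self.R * self.Y, 0.2)
        ad["region_r"] = VecRW.make(self.R, 0.3)
        ad["regionyear_r"] = VecRW.make(self.R * self.Y, 0.5)
        for _, sd_name in self._re_families():
            ad[sd_name] = MvRW(1, init_scale=0.2)
            ad["rescale_" + sd_name] = MvRW(1, init_scale=0.3, learn_cov=False)
        for fam, _, _ in self._recenter_pairs():
            ad["recenter_" + fam] = MvRW(1, init_scale=0.1, learn_cov=False)
        return ad

    # helper: elementwise accept, returns boolean mask
    @staticmethod
    def _accept_mask(rng, delta: np.ndarray) -> np.ndarray:
        return np.log(rng.random(delta.shape)) < delta

    def _prior_delta_normal(self, new: np.ndarray, old: np.ndarray, sd: float) -> np.ndarray:
        return (old * old - new * new) / (2.0 * sd * sd)

    # -- fixed-effect style blocks (single accept, full recompute) -----------

    #: cache parts each correlated block touches, and the component sums that change
    _BLOCK_PARTS = {
        "growth_fixed": ({"growth"}, ("count_ll",)),
        "year_g": ({"growth"}, ("count_ll",)),
        "mu_d": ({"growth"}, ("count_ll",)),
        "c0": ({"rodent"}, ("rll", "count_ll")),
        "year_r": ({"rodent"}, ("rll", "count_ll")),
        "det_fixed": ({"det"}, ("dist_ll", "count_ll")),
        "g0": ({"gs"}, ("gs_ll", "count_ll")),
    }

    def _block_prior_delta(self, name: str, new: np.ndarray, old: np.ndarray) -> float:
        pr = self.priors
        if name == "growth_fixed":
            i_bA = GROWTH_FIXED.index("bA")
            if not (pr.bA_lo < new[i_bA] < pr.bA_hi):
                return -np.inf
            keep = [k for k in range(len(GROWTH_FIXED)) if k != i_bA]
            return float(np.sum(old[keep] ** 2 - new[keep] ** 2)) / (2 * pr.fixed_sd**2)
        if name == "year_g":
            sd = self._sd_cache["sd_year_g"]
        elif name == "year_r":
            sd = self._sd_cache["sd_year_r"]
        else:  # c0, g0, det_fixed, mu_d
            sd = pr.fixed_sd
        return float(np.sum(old**2 - new**2)) / (2 * sd * sd)

    def _update_full_block(self, name: str, idx: np.ndarray | None, theta, cache,
                           rng, adapt, it) -> None:
        """Joint RW update of a block, re-evaluating the affected components."""
        s = self.layout[name]
        cur = theta[s].copy()
        mv: MvRW = adapt[name]
        if idx is None:
            sub = cur
        else:
            sub = cur[idx]
        prop_sub = mv.propose(rng, sub)
        prop_theta = theta.copy()
        if idx is None:
            prop_theta[s] = prop_sub
        else:
            tmp = cur.copy()
            tmp[idx] = prop_sub
            prop_theta[s] = tmp
        self._sd_cache = {
            "sd_year_g": self._s(theta, "sd_year_g") if "sd_year_g" in self.layout else 1.0,
            "sd_year_r": self._s(theta, "sd_year_r"),
        }
        delta = self._block_prior_delta(name, prop_theta[s], cur)
        accept = False
        if np.isfinite(delta):
            parts, comps = self._BLOCK_PARTS[name]
            prop_cache = self.make_cache(prop_theta, base=cache, parts=parts)
            for comp in comps:
                delta += float(np.sum(prop_cache[comp]) - np.sum(cache[comp]))
            accept = np.isfinite(delta) and (math.log(rng.random()) < delta)
        if accept:
            theta[:] = prop_theta
            cache.update(prop_cache)
        mv.update(bool(accept), theta[s][idx] if idx is not None else theta[s].copy(), it)

    # -- vectorized family updates ------------------------------------------

    def _update_growth_vec(self, fam: str, theta, cache, rng, adapt, it) -> None:
        """line_g / region_g / eps1: element-wise accept via the recursion."""
        L = self.layout
        vr: VecRW = adapt[fam]
        cur = theta[L[fam]]
        step = vr.step(rng)
        prop = cur + step
        g = self._growth_coefs(theta)
        line_g = self._g(theta, "line_g")
        region_g = self._g(theta, "region_g")
        eps1 = self._g(theta, "eps1")
        lnD1 = g["mu1"] + eps1
        if fam == "line_g":
            addg = prop + region_g[self.rof]
        elif fam == "region_g":
            addg = line_g + prop[self.rof]
        else:  # eps1
            addg = line_g + region_g[self.rof]
            lnD1 = g["mu1"] + prop
        lnD_p, nmean_p, count_p = self._growth_eval(
            theta, cache["Rc"], cache["sigma_ty"], cache["ccon"],
            self._s(theta, "nb_dispersion"), addg=addg, lnD1=lnD1,
        )
        row_delta = np.sum(count_p - cache["count_ll"], axis=1)
        sd = self._s(theta, {"line_g": "sd_line_g", "region_g": "sd_region_g",
                             "eps1": "sd_eps1"}[fam])
        if fam == "region_g":
            delta = np.bincount(self.rof, weights=row_delta, minlength=self.R)
        else:
            delta = row_delta
        delta = delta + self._prior_delta_normal(prop, cur, sd)
        acc = self._accept_mask(rng, delta)
        if acc.any():
            new = np.where(acc, prop, cur)
            theta[L[fam]] = new
            rows = acc[self.rof] if fam == "region_g" else acc
            cache["lnD"][rows] = lnD_p[rows]
            cache["nmean"][rows] = nmean_p[rows]
            cache["count_ll"][rows] = count_p[rows]
        vr.update(acc, it)

    def _update_re_surface_vec(self, fam: str, theta, cache, rng, adapt, it) -> None:
        """Random-effects state model families (conditionally independent)."""
        L = self.layout
        vr: VecRW = adapt[fam]
        cur = theta[L[fam]].copy()
        prop = cur + vr.step(rng)
        tmp = theta.copy()
        tmp[L[fam]] = prop
        lnD_p = self._lnD(tmp, cache["Rc"])
        nmean_p = self._nmean(lnD_p, cache["sigma_ty"])
        count_p = self._count_ll(nmean_p, cache["ccon"], self._s(theta, "nb_dispersion"))
        cell_delta = count_p - cache["count_ll"]
        sd = self._s(theta, "sd_" + fam)
        if fam == "year_d":
            delta = cell_delta.sum(axis=0)
        elif fam == "line_d":
            delta = cell_delta.sum(axis=1)
        elif fam == "region_d":
            delta = np.bincount(self.rof, weights=cell_delta.sum(axis=1), minlength=self.R)
        else:  # regionyear_d
            agg = np.zeros((self.R, self.Y))
            np.add.at(agg, self.rof, cell_delta)
            delta = agg.ravel()
        delta = delta + self._prior_delta_normal(prop, cur, sd)
        acc = self._accept_mask(rng, delta)
        if acc.any():
            theta[L[fam]] = np.where(acc, prop, cur)
            if fam == "year_d":
                mask = np.broadcast_to(acc[None, :], cell_delta.shape)
            elif fam == "line_d":
                mask = np.broadcast_to(acc[:, None], cell_delta.shape)
            elif fam == "region_d":
                mask = np.broadcast_to(acc[self.rof][:, None], cell_delta.shape)
            else:
                mask = acc.reshape(self.R, self.Y)[self.rof, :]
            cache["lnD"] = np.where(mask, lnD_p, cache["lnD"])
            cache["nmean"] = np.where(mask, nmean_p, cache["nmean"])
            cache["count_ll"] = np.where(mask, count_p, cache["count_ll"])
        vr.update(acc, it)

    def _rodent_recompute(self, theta, cache, Rp_p, Rc_p):
        """Growth-side quantities after a rodent-surface change."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rll_p = self.k1 * np.log(Rp_p) + self.k0 * np.log1p(-Rp_p)
        rll_p = np.where(np.isfinite(rll_p), rll_p, _NEG)
        if self.config.state == "gompertz" and self.config.rodent_terms:
            lnD_p, nmean_p, count_p = self._growth_eval(
                theta, Rc_p, cache["sigma_ty"], cache["ccon"],
                self._s(theta, "nb_dispersion"),
            )
        else:
            lnD_p, nmean_p, count_p = cache["lnD"], cache["nmean"], cache["count_ll"]
        return rll_p, lnD_p, nmean_p, count_p

    def _update_rodent_vec(self, fam: str, theta, cache, rng, adapt, it) -> None:
        """region_r and regionyear_r: per-region block proposals.

        Regions are conditionally independent given everything else, so each
        region's proposal (one value for region_r; the region's whole year-row
        for regionyear_r) is accepted or rejected on its own.
        """
        L = self.layout
        vr: VecRW = adapt[fam]
        cur = theta[L[fam]].copy()
        prop = cur + vr.step(rng)
        tmp = theta.copy()
        tmp[L[fam]] = prop
        Rp_p, Rc_p, _ = self._rodent_surface(tmp)
        rll_p, lnD_p, nmean_p, count_p = self._rodent_recompute(
            theta, cache, Rp_p, Rc_p
        )
        delta = np.sum(rll_p - cache["rll"], axis=1)
        if count_p is not cache["count_ll"]:
            row_delta = np.sum(count_p - cache["count_ll"], axis=1)
            delta = delta + np.bincount(self.rof, weights=row_delta, minlength=self.R)
        sd = self._s(theta, "sd_region_r" if fam == "region_r" else "sd_regionyear_r")
        if fam == "region_r":
            pr_delta = self._prior_delta_normal(prop, cur, sd)
        else:
            pr_delta = self._prior_delta_normal(
                prop.reshape(self.R, self.Y), cur.reshape(self.R, self.Y), sd
            ).sum(axis=1)
        delta = delta + pr_delta
        acc = self._accept_mask(rng, delta)
        if acc.any():
            if fam == "region_r":
                theta[L[fam]] = np.where(acc, prop, cur)
            else:
                mask_ry = np.repeat(acc, self.Y)
                theta[L[fam]] = np.where(mask_ry, prop, cur)
            rows = acc[self.rof]
            cache["Rp"][acc] = Rp_p[acc]
            cache["Rc"][acc] = Rc_p[acc]
            cache["rll"][acc] = rll_p[acc]
            if count_p is not cache["count_ll"]:
                cache["lnD"][rows] = lnD_p[rows]
                cache["nmean"][rows] = nmean_p[rows]
                cache["count_ll"][rows] = count_p[rows]
        # per-region acceptance drives the (shared) scales of that region's block
        if fam == "region_r":
            vr.update(acc, it)
        else:
            vr.update(np.repeat(acc, self.Y), it)

    def _update_det_vec(self, fam: str, theta, cache, rng, adapt, it) -> None:
        """line_det / region_det: distance + count likelihoods, element-wise."""
        L = self.layout
        vr: VecRW = adapt[fam]
        cur = theta[L[fam]].copy()
        step = vr.step(rng)
        prop = cur + step
        if fam == "line_det":
            dz_t = step  # per transect
            sd = self._s(theta, "sd_line_det")
        else:
            dz_t = step[self.rof]
            sd = self._s(theta, "sd_region_det")
        sigma_p = cache["sigma_ty"] * np.exp(dz_t[:, None])
        nmean_p = cache["nmean"] * np.exp(dz_t[:, None])
        count_p = self._count_ll(nmean_p, cache["ccon"], self._s(theta, "nb_dispersion"))
        sig_obs_p = cache["sig_obs"] * np.exp(dz_t[self.ot])
        dist_p = self._dist_ll(sig_obs_p)
        row_delta = np.sum(count_p - cache["count_ll"], axis=1)
        row_delta = row_delta + np.bincount(
            self.ot, weights=dist_p - cache["dist_ll"], minlength=self.T
        )
        if fam == "region_det":
            delta = np.bincount(self.rof, weights=row_delta, minlength=self.R)
        else:
            delta = row_delta
        delta = delta + self._prior_delta_normal(prop, cur, sd)
        acc = self._accept_mask(rng, delta)
        if acc.any():
            theta[L[fam]] = np.where(acc, prop, cur)
            rows = acc[self.rof] if fam == "region_det" else acc
            cache["sigma_ty"][rows] = sigma_p[rows]
            cache["nmean"][rows] = nmean_p[rows]
            cache["count_ll"][rows] = count_p[rows]
            omask = rows[self.ot]
            cache["sig_obs"][omask] = sig_obs_p[omask]
            cache["dist_ll"][omask] = dist_p[omask]
        vr.update(acc, it)

    def _update_gs_vec(self, fam: str, theta, cache, rng, adapt, it) -> None:
        """line_gs (per transect) / regionyear_gs (per cell) updates."""
        L = self.layout
        vr: VecRW = adapt[fam]
        cur = theta[L[fam]].copy()
        step = vr.step(rng)
        prop = cur + step
        if fam == "line_gs":
            dz = step[:, None]
            sd = self._s(theta, "sd_line_gs")
        else:
            dz = step.reshape(self.R, self.Y)[self.rof, :]
            sd = self._s(theta, "sd_regionyear_gs")
        lam_p = cache["lam"] * np.exp(dz)
        gs_p = self._gs_ll(lam_p)
        b0d, bgs = self._g(theta, "det_fixed")
        gs_std_p = (lam_p + 1.0 - self.gs_center) / self.gs_scale
        gs_std_c = (cache["lam"] + 1.0 - self.gs_center) / self.gs_scale
        sigma_p = cache["sigma_ty"] * np.exp(bgs * (gs_std_p - gs_std_c))
        nmean_p = cache["nmean"] * (sigma_p / cache["sigma_ty"])
        count_p = self._count_ll(nmean_p, cache["ccon"], self._s(theta, "nb_dispersion"))
        cell_delta = (gs_p - cache["gs_ll"]) + (count_p - cache["count_ll"])
        if fam == "line_gs":
            delta = cell_delta.sum(axis=1) + self._prior_delta_normal(prop, cur, sd)
            acc = self._accept_mask(rng, delta)
            mask = np.broadcast_to(acc[:, None], cell_delta.shape)
        else:
            agg = np.zeros((self.R, self.Y))
            np.add.at(agg, self.rof, cell_delta)
            delta = agg.ravel() + self._prior_delta_normal(prop, cur, sd)
            acc = self._accept_mask(rng, delta)
            mask = acc.reshape(self.R, self.Y)[self.rof, :]
        if acc.any():
            theta[L[fam]] = np.where(acc, prop, cur)
            for key, new in (("lam", lam_p), ("gs_ll", gs_p), ("sigma_ty", sigma_p),
                             ("nmean", nmean_p), ("count_ll", count_p)):
                cache[key] = np.where(mask, new, cache[key])
        vr.update(acc, it)

    def _update_sd(self, fam: str, sd_name: str, theta, rng, adapt, it) -> None:
        """Scalar MH on log(sd); conditional involves only that family."""
        L = self.layout
        mv: MvRW = adapt[sd_name]
        cur = self._s(theta, sd_name)
        x = self._g(theta, fam)
        n = x.size
        ss = float(np.sum(x * x))
        log_cur = math.log(cur)
        log_prop = float(mv.propose(rng, np.array([log_cur]))[0])
        prop = math.exp(log_prop)
        scale = self.priors.sd_scale

        def cond(sd, logsd):
            # half-normal prior + normal RE density + log-scale Jacobian
            return (
                -0.5 * (sd / scale) ** 2
                - n * logsd - ss / (2.0 * sd * sd)
                + logsd
            )

        delta = cond(prop, log_prop) - cond(cur, log_cur)
        accept = math.log(rng.random()) < delta
        if accept:
            theta[L[sd_name].start] = prop
        mv.update(accept, np.array([math.log(self._s(theta, sd_name))]), it)

    def _update_growth_ridge(self, theta, cache, rng, adapt, it) -> None:
        """Move density dependence along the equilibrium ridge.

        b0 and bA are strongly negatively correlated because the data pin the
        equilibrium log-density q = −b0/bA; this move perturbs bA holding q
        fixed (b0' = −bA'·q), which is a random walk in (q, bA) coordinates
        and therefore carries a |bA'|/|bA| Jacobian factor.
        """
        mv: MvRW = adapt["growth_ridge"]
        s = self.layout["growth_fixed"]
        i_b0 = s.start + GROWTH_FIXED.index("b0")
        i_bA = s.start + GROWTH_FIXED.index("bA")
        b0, bA = theta[i_b0], theta[i_bA]
        q = -b0 / bA
        bA_p = float(mv.propose(rng, np.array([bA]))[0])
        pr = self.priors
        if not (pr.bA_lo < bA_p < pr.bA_hi):
            mv.update(False, np.array([bA]), it)
            return
        b0_p = -bA_p * q
        prop_theta = theta.copy()
        prop_theta[i_b0] = b0_p
        prop_theta[i_bA] = bA_p
        prop_cache = self.make_cache(prop_theta, base=cache, parts={"growth"})
        delta = float(np.sum(prop_cache["count_ll"]) - np.sum(cache["count_ll"]))
        delta += (b0**2 - b0_p**2) / (2 * pr.fixed_sd**2)
        delta += math.log(abs(bA_p)) - math.log(abs(bA))
        accept = np.isfinite(delta) and (math.log(rng.random()) < delta)
        if accept:
            theta[:] = prop_theta
            cache.update(prop_cache)
        mv.update(bool(accept), np.array([theta[i_bA]]), it)

    def _recenter_pairs(self):
        """(family, intercept) pairs whose sum enters the likelihood jointly."""
        if self.config.state == "gompertz":
            i_b0 = self.layout["growth_fixed"].start + GROWTH_FIXED.index("b0")
            i_mu1 = self.layout["growth_fixed"].start + GROWTH_FIXED.index("mu1")
            pairs = [("year_g", i_b0, "sd_year_g"), ("line_g", i_b0, "sd_line_g"),
                     ("region_g", i_b0, "sd_region_g"), ("eps1", i_mu1, "sd_eps1")]
        else:
            i_mu = self.layout["mu_d"].start
            pairs = [(f, i_mu, "sd_" + f)
                     for f in ("year_d", "line_d", "region_d", "regionyear_d")]
        i_b0d = self.layout["det_fixed"].start
        i_g0 = self.layout["g0"].start
        i_c0 = self.layout["c0"].start
        pairs += [
            ("line_det", i_b0d, "sd_line_det"), ("region_det", i_b0d, "sd_region_det"),
            ("line_gs", i_g0, "sd_line_gs"), ("regionyear_gs", i_g0, "sd_regionyear_gs"),
            ("year_r", i_c0, "sd_year_r"), ("region_r", i_c0, "sd_region_r"),
            ("regionyear_r", i_c0, "sd_regionyear_r"),
        ]
        return pairs

    def _update_recenter(self, fam: str, i_scalar: int, sd_name: str,
                         theta, rng, adapt, it) -> None:
        """Shift mass between an intercept and its random-effect family.

        The likelihood depends on intercept + effect only through their sum,
        so the move is judged on the priors alone (exact likelihood
        invariance); it decorrelates intercepts from family means.
        """
        mv: MvRW = adapt["recenter_" + fam]
        d = float(mv.propose(rng, np.array([0.0]))[0])
        s = self.layout[fam]
        vec = theta[s]
        sd = self._s(theta, sd_name)
        scalar = theta[i_scalar]
        # family prior: sum (v^2 - (v-d)^2) / (2 sd^2); intercept prior N(0, fixed_sd)
        n = vec.size
        delta = (2.0 * d * float(vec.sum()) - n * d * d) / (2.0 * sd * sd)
        delta += (scalar**2 - (scalar + d) ** 2) / (2.0 * self.priors.fixed_sd**2)
        accept = math.log(rng.random()) < delta
        if accept:
            theta[s] = vec - d
            theta[i_scalar] = scalar + d
        mv.update(bool(accept), np.array([0.0]), it)

    #: cache parts touched by each random-effect family
    _FAMILY_PARTS = {
        "line_g": ({"growth"}, ("count_ll",)),
        "region_g": ({"growth"}, ("count_ll",)),
        "year_g": ({"growth"}, ("count_ll",)),
        "eps1": ({"growth"}, ("count_ll",)),
        "year_d": ({"growth"}, ("count_ll",)),
        "line_d": ({"growth"}, ("count_ll",)),
        "region_d": ({"growth"}, ("count_ll",)),
        "regionyear_d": ({"growth"}, ("count_ll",)),
        "line_det": ({"det"}, ("dist_ll", "count_ll")),
        "region_det": ({"det"}, ("dist_ll", "count_ll")),
        "line_gs": ({"gs"}, ("gs_ll", "count_ll")),
        "regionyear_gs": ({"gs"}, ("gs_ll", "count_ll")),
        "year_r": ({"rodent"}, ("rll", "count_ll")),
        "region_r": ({"rodent"}, ("rll", "count_ll")),
        "regionyear_r": ({"rodent"}, ("rll", "count_ll")),
    }

    def _update_family_rescale(self, fam: str, sd_name: str, theta, cache,
                               rng, adapt, it) -> None:
        """Joint multiplicative move along the hierarchical funnel.

        Proposes effects' = c·effects together with sd' = c·sd, which leaves
        the standardized effects unchanged and lets the family SD mix even
        when the individual effects are weakly informed.
        """
        key = "rescale_" + sd_name
        mv: MvRW = adapt[key]
        logc = float(mv.propose(rng, np.array([0.0]))[0])
        c = math.exp(logc)
        L = self.layout
        sd_cur = self._s(theta, sd_name)
        sd_prop = c * sd_cur
        prop_theta = theta.copy()
        prop_theta[L[fam]] = c * theta[L[fam]]
        prop_theta[L[sd_name].start] = sd_prop
        parts, comps = self._FAMILY_PARTS[fam]
        prop_cache = self.make_cache(prop_theta, base=cache, parts=parts)
        scale = self.priors.sd_scale
        delta = (sd_cur**2 - sd_prop**2) / (2 * scale**2)  # half-normal prior
        delta += logc  # RE density change (-n log c) + Jacobian ((n+1) log c)
        for comp in comps:
            delta += float(np.sum(prop_cache[comp]) - np.sum(cache[comp]))
        accept = np.isfinite(delta) and (math.log(rng.random()) < delta)
        if accept:
            theta[:] = prop_theta
            cache.update(prop_cache)
        mv.update(bool(accept), np.array([0.0]), it)

    def _update_dispersion(self, theta, cache, rng, adapt, it) -> None:
        L = self.layout
        mv: MvRW = adapt["nb_dispersion"]
        cur = self._s(theta, "nb_dispersion")
        log_prop = float(mv.propose(rng, np.array([math.log(cur)]))[0])
        prop = math.exp(log_prop)
        pr = self.priors
        if pr.disp_lo < prop < pr.disp_hi:
            ccon_p = self._count_const(prop)
            count_p = self._count_ll(cache["nmean"], ccon_p, prop)
            delta = float(np.sum(count_p - cache["count_ll"]))
            delta += log_prop - math.log(cur)  # log-scale Jacobian, uniform prior
            if math.log(rng.random()) < delta:
                theta[L["nb_dispersion"].start] = prop
                cache["ccon"] = ccon_p
                cache["count_ll"] = count_p
                mv.update(True, np.array([log_prop]), it)
                return
        mv.update(False, np.array([math.log(cur)]), it)

    # -------------------------------------------------------- parameter bridge

    def theta_from_params(self, params) -> np.ndarray:
        """Flatten a :class:`~lirype.population.ModelParameters` bundle."""
        if self.config.state != "gompertz":
            raise ValueError("parameter bridge exists for the Gompertz model only")
        d = self.data
        L = self.layout
        theta = np.zeros(self.n_params)
        g, init, obsp = params.growth, params.initial, params.observation
        rod, det, gsp = params.rodent, params.detection, params.groupsize
        gf = [getattr(g, n) if n != "mu1" else init.mu1 for n in GROWTH_FIXED]
        theta[L["growth_fixed"]] = gf
        theta[L["line_g"]] = [g.line_g.get(t, 0.0) for t in d.transect_ids]
        theta[L["region_g"]] = [g.region_g.get(r, 0.0) for r in d.region_ids]
        theta[L["year_g"]] = [g.year_g.get(y, 0.0) for y in d.years[1:]]
        theta[L["eps1"]] = [init.eps1.get(t, 0.0) for t in d.transect_ids]
        for sd_name, val in (
            ("sd_line_g", g.sd_line_g), ("sd_region_g", g.sd_region_g),
            ("sd_year_g", g.sd_year_g), ("sd_eps1", init.sd_eps1),
            ("nb_dispersion", obsp.nb_dispersion),
            ("sd_line_det", det.sd_line_det), ("sd_region_det", det.sd_region_det),
            ("g0", gsp.g0), ("sd_line_gs", gsp.sd_line_gs),
            ("sd_regionyear_gs", gsp.sd_regionyear_gs),
            ("c0", rod.c0), ("sd_year_r", rod.sd_year_r),
            ("sd_region_r", rod.sd_region_r), ("sd_regionyear_r", rod.sd_regionyear_r),
        ):
            theta[L[sd_name].start] = val
        theta[L["det_fixed"]] = [det.b0_det, det.b_gs]
        theta[L["line_det"]] = [det.line_det.get(t, 0.0) for t in d.transect_ids]
        theta[L["region_det"]] = [det.region_det.get(r, 0.0) for r in d.region_ids]
        theta[L["line_gs"]] = [gsp.line_gs.get(t, 0.0) for t in d.transect_ids]
        theta[L["regionyear_gs"]] = [
            gsp.regionyear_gs.get((r, y), 0.0)
            for r in d.region_ids for y in d.years
        ]
        theta[L["year_r"]] = [rod.year_r.get(y, 0.0) for y in d.years]
        theta[L["region_r"]] = [rod.region_r.get(r, 0.0) for r in d.region_ids]
        theta[L["regionyear_r"]] = [
            rod.regionyear_r.get((r, y), 0.0)
            for r in d.region_ids for y in d.years
        ]
        return theta

    # ------------------------------------------------------------------- sweep

    def sweep(self, theta: np.ndarray, cache: dict, rng: np.random.Generator,
              adapt: dict, it: int) -> None:
        """One full pass over every block (in place)."""
        if self.config.state == "gompertz":
            # the correlated fixed-effect block mixes slowest; update it more often
            for _ in range(self.growth_block_repeats):
                self._update_full_block("growth_fixed", np.array(self.active_growth),
                                        theta, cache, rng, adapt, it)
                self._update_growth_ridge(theta, cache, rng, adapt, it)
            self._update_full_block("year_g", None, theta, cache, rng, adapt, it)
            self._update_growth_vec("eps1", theta, cache, rng, adapt, it)
            self._update_growth_vec("line_g", theta, cache, rng, adapt, it)
            self._update_growth_vec("region_g", theta, cache, rng, adapt, it)
        else:
            self._update_full_block("mu_d", None, theta, cache, rng, adapt, it)
            for fam in ("year_d", "line_d", "region_d", "regionyear_d"):
                self._update_re_surface_vec(fam, theta, cache, rng, adapt, it)
        # the rodent surface couples to bR/bRL/bint_R; refresh it twice a sweep
        for _ in range(2):
            self._update_full_block("c0", None, theta, cache, rng, adapt, it)
            self._update_full_block("year_r", None, theta, cache, rng, adapt, it)
            self._update_rodent_vec("region_r", theta, cache, rng, adapt, it)
            self._update_rodent_vec("regionyear_r", theta, cache, rng, adapt, it)
        self._update_full_block("det_fixed", None, theta, cache, rng, adapt, it)
        self._update_det_vec("line_det", theta, cache, rng, adapt, it)
        self._update_det_vec("region_det", theta, cache, rng, adapt, it)
        self._update_full_block("g0", None, theta, cache, rng, adapt, it)
        self._update_gs_vec("line_gs", theta, cache, rng, adapt, it)
        self._update_gs_vec("regionyear_gs", theta, cache, rng, adapt, it)
        self._update_dispersion(theta, cache, rng, adapt, it)
        for k, (fam, sd_name) in enumerate(self._re_families()):
            self._update_sd(fam, sd_name, theta, rng, adapt, it)
            # funnel moves alternate across sweeps (they cost a part recompute)
            if (it + k) % 2 == 0:
                self._update_family_rescale(fam, sd_name, theta, cache, rng, adapt, it)
        for fam, i_scalar, sd_name in self._recenter_pairs():
            self._update_recenter(fam, i_scalar, sd_name, theta, rng, adapt, it)


class GaussianMeanToy:
    """Conjugate normal-mean toy target run through the same sampler machinery.

    y_i ~ Normal(mu, sigma² known), mu ~ Normal(m0, s0²); the posterior for mu
    is available in closed form, which makes this the validity oracle for the
    MCMC driver.
    """

    def __init__(self, y, sigma: float = 1.0, m0: float = 0.0, s0: float = 10.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma, self.m0, self.s0 = float(sigma), float(m0), float(s0)
        self.n_params = 1
        self.layout = Layout()
        self.layout.add("mu", 1)
        self.monitor = ["mu"]
        self.monitor_names = ["mu"]

    def posterior_moments(self) -> tuple[float, float]:
        n = self.y.size
        prec = n / self.sigma**2 + 1.0 / self.s0**2
        mean = (self.y.sum() / self.sigma**2 + self.m0 / self.s0**2) / prec
        return mean, math.sqrt(1.0 / prec)

    def log_posterior(self, theta, cache=None) -> float:
        mu = float(theta[0])
        ll = -0.5 * np.sum((self.y - mu) ** 2) / self.sigma**2
        lp = -0.5 * ((mu - self.m0) / self.s0) ** 2
        return float(ll + lp)

    def init_theta(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([float(self.y.mean()) + 0.5 * rng.standard_normal()])

    def make_cache(self, theta) -> dict:
        return {}

    def new_adapt(self) -> dict:
        return {"mu": MvRW(1, init_scale=0.5)}

    def monitor_values(self, theta) -> np.ndarray:
        return theta.copy()

    def sweep(self, theta, cache, rng, adapt, it) -> None:
        mv: MvRW = adapt["mu"]
        prop = mv.propose(rng, theta)
        delta = self.log_posterior(prop) - self.log_posterior(theta)
        accept = math.log(rng.random()) < delta
        if accept:
            theta[:] = prop
        mv.update(accept, theta.copy(), it)
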