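"""Posterior-predictive simulation and randomized-quantile (PIT) residuals.

Model fit is checked the way DHARMa-style workflows do it: simulate replicate
count datasets from the posterior, place each observed count within its
simulated distribution (randomizing ties, as required for discrete data), and
check the resulting scaled residuals against the Uniform(0, 1) law they follow
under a correctly specified model — via a quantile–quantile table and a
one-sample Kolmogorov–Smirnov statistic — plus a residual-versus-prediction
trend inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorSamples

__all__ = [
    "ResidualSet",
    "posterior_predictive",
    "scaled_residuals",
    "uniformity_check",
    "residual_trend",
]


@dataclass
class ResidualSet:
    """Scaled residuals in [0, 1], one per surveyed transect-year."""

    scaled: np.ndarray
    n_sim: int
    cell_transect: np.ndarray
    cell_year: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.scaled < 0) | (self.scaled > 1)):
            raise ValueError("scaled residuals must lie in [0, 1]")


def posterior_predictive(
    model,
    samples: PosteriorSamples,
    n_sim: int = 250,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate replicate counts at every surveyed transect-year.

    Each replicate takes one posterior draw of the full parameter vector,
    rebuilds the latent density surface, and draws new negative-binomial
    counts.  Returns ``(replicates, cell_transect, cell_year)`` with
    ``replicates`` of shape (n_sim × n_cells); fully seeded.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    theta = samples.theta.reshape(-1, samples.theta.shape[-1])
    pick = rng.integers(0, theta.shape[0], size=n_sim)
    ci, ct = np.nonzero(model.surveyed)
    reps = np.empty((n_sim, ci.size))
    for s, k in enumerate(pick):
        cache = model.make_cache(theta[k])
        mean = cache["nmean"][ci, ct]
        r = float(theta[k][model.layout["nb_dispersion"].start])
        reps[s] = rng.negative_binomial(r, r / (r + mean))
    return reps, ci, ct


def scaled_residuals(
    observed: np.ndarray,
    replicates: np.ndarray,
    seed: int = 0,
    cell_transect: np.ndarray | None = None,
    cell_year: np.ndarray | None = None,
) -> ResidualSet:
    """Randomized probability-integral-transform residuals for counts.

    residual = Pr(sim < obs) + U · Pr(sim = obs) with U ~ Uniform(0, 1): the
    tie randomization makes the residuals exactly uniform under the model
    despite the discreteness of the counts.
    """
    obs = np.asarray(observed, dtype=float)
    reps = np.asarray(replicates, dtype=float)
    if reps.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.Generator(np.random.PCG64(seed))
    below = np.mean(reps < obs[None, :], axis=0)
    ties = np.mean(reps == obs[None, :], axis=0)
    u = rng.random(obs.size)
    res = below + u * ties
    n = obs.size
    if cell_transect is None:
        cell_transect = np.arange(n)
    if cell_year is None:
        cell_year = np.zeros(n, dtype=int)
    return ResidualSet(res, reps.shape[0], np.asarray(cell_transect), np.asarray(cell_year))


def uniformity_check(
    res: ResidualSet,
    predictions: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """KS statistic against Uniform(0, 1) plus a QQ table for plotting.

    The QQ table pairs sorted empirical residuals with uniform plotting
    positions; if ``predictions`` is given, a residual-vs-prediction column is
    included so systematic trends can be inspected.
    """
    x = np.asarray(res.scaled, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 residuals")
    ks = float(stats.kstest(x, "uniform").statistic)
    order = np.argsort(x)
    qq = pd.DataFrame(
        {
            "theoretical": (np.arange(1, x.size + 1) - 0.5) / x.size,
            "empirical": x[order],
        }
    )
    if predictions is not None:
        qq["prediction"] = np.asarray(predictions, dtype=float)[order]
    return ks, qq


def residual_trend(res: ResidualSet, covariate: np.ndarray) -> float:
    """Spearman rank correlation between residuals and a per-cell covariate."""
    rho = stats.spearmanr(np.asarray(covariate, dtype=float), res.scaled).statistic
    return float(rho)
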