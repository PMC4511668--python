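"""Population-level abundance distributions and parametric fits.

Long runs with strong parental transmission leave skewed population-wide
taxon-abundance distributions even though the simulation starts from (and the
fixed environment retains) a uniform pool.  Two standard descriptions of such
distributions are provided:

* a **log-normal** fitted to the nonzero relative abundances (closed-form
  maximum likelihood on the logs), and
* a **Dirichlet-multinomial (DM)** fitted to a sample x taxon count matrix by
  maximum likelihood (Minka's fixed-point iteration on the concentration
  vector, method-of-moments initialization).

The DM has the extra virtue that alpha-, beta- and gamma-diversities can be
re-simulated from the fitted concentrations and compared with the diversities
of the data the fit came from (`reconstruct_diversities_from_dm`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, psi

from .diversity import alpha_diversity, beta_diversity, gamma_diversity
from .simulation import PopulationState

__all__ = [
    "LogNormalFit",
    "DirichletMultinomialFit",
    "population_abundance_distribution",
    "fit_lognormal",
    "fit_dirichlet_multinomial",
    "dm_log_likelihood",
    "dm_moment_estimate",
    "reconstruct_diversities_from_dm",
    "abundance_histogram",
]


@dataclass(frozen=True)
class LogNormalFit:
    """MLE of a log-normal: mu/sigma are the mean and sd of log-abundance."""

    mu: float
    sigma: float
    n_obs: int
    log_likelihood: float


@dataclass(frozen=True)
class DirichletMultinomialFit:
    """MLE concentration vector of a Dirichlet-multinomial.

    ``overdispersion_theta = 1 / (1 + sum(concentration))`` is the usual
    overdispersion parameter (0 = multinomial limit, 1 = maximal clumping).
    ``floored_taxa`` lists taxa absent from every sample, whose concentrations
    were pinned at a small floor rather than driven to zero.
    """

    concentration: np.ndarray
    overdispersion_theta: float
    log_likelihood: float
    converged: bool
    n_iter: int
    degenerate: bool = False
    floored_taxa: tuple[int, ...] = ()


def population_abundance_distribution(population: PopulationState) -> np.ndarray:
    """Per-taxon population-wide relative abundance (normalized column sums)."""
    pooled = population.counts.sum(axis=0).astype(float)
    return pooled / pooled.sum()


def fit_lognormal(abundances: np.ndarray) -> LogNormalFit:
    """Closed-form ML fit of a log-normal to strictly positive abundances."""
    values = np.asarray(abundances, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D array of at least two abundances")
    if (values <= 0).any():
        raise ValueError(
            "log-normal fitting requires strictly positive abundances; "
            "exclude zero entries upstream"
        )
    logs = np.log(values)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma < 1e-12:  # all values (numerically) identical
        raise ValueError(
            "degenerate sample: all abundances identical (sigma would be 0)"
        )
    n = values.size
    # log-normal log-likelihood at the MLE
    ll = float(
        -n / 2 * np.log(2 * np.pi) - n * np.log(sigma) - logs.sum() - n / 2
    )
    return LogNormalFit(mu=mu, sigma=sigma, n_obs=n, log_likelihood=ll)


def dm_log_likelihood(counts: np.ndarray, concentration: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood of a sample x taxon count matrix."""
    x = np.asarray(counts, dtype=float)
    alpha = np.asarray(concentration, dtype=float)
    totals = x.sum(axis=1)
    a0 = alpha.sum()
    ll = (
        gammaln(totals + 1).sum()
        - gammaln(x + 1).sum()
        + x.shape[0] * gammaln(a0)
        - gammaln(totals + a0).sum()
        + gammaln(x + alpha).sum()
        - x.shape[0] * gammaln(alpha).sum()
    )
    return float(ll)


def dm_moment_estimate(counts: np.ndarray) -> np.ndarray:
    """Method-of-moments concentrations used to initialize the MLE.

    The common precision is estimated from the across-sample variance of the
    per-taxon proportions (Dirichlet variance identity); degenerate tables
    with no between-sample variance get a large finite precision.
    """
    x = np.asarray(counts, dtype=float)
    props = x / x.sum(axis=1, keepdims=True)
    mean_p = props.mean(axis=0)
    var_p = props.var(axis=0, ddof=1)
    mask = (var_p > 0) & (mean_p > 0) & (mean_p < 1)
    if mask.any():
        precisions = mean_p[mask] * (1 - mean_p[mask]) / var_p[mask] - 1.0
        precisions = precisions[precisions > 0]
    else:
        precisions = np.array([])
    precision = float(np.exp(np.mean(np.log(precisions)))) if precisions.size else 1e6
    return np.maximum(precision * mean_p, 1e-10)


def fit_dirichlet_multinomial(
    count_samples: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    floor: float = 1e-10,
) -> DirichletMultinomialFit:
    """Maximum-likelihood Dirichlet-multinomial fit via fixed-point iteration.

    Uses Minka's update
    ``alpha_k <- alpha_k * sum_i[psi(x_ik + alpha_k) - psi(alpha_k)] /
    sum_i[psi(n_i + A) - psi(A)]`` which increases the likelihood at every
    step.  Convergence is declared when the largest concentration change
    falls below ``tol``; non-convergence is reported on the result (and
    warned), never silent.
    """
    x = np.asarray(count_samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D count matrix with at least two samples")
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    totals = x.sum(axis=1)
    if (totals < 1).any():
        raise ValueError("every sample must contain at least one count")

    props = x / totals[:, None]
    degenerate = bool(
        np.count_nonzero(x.sum(axis=0)) <= 1 or np.allclose(props, props[0])
    )
    absent = np.flatnonzero(x.sum(axis=0) == 0)
    alpha = dm_moment_estimate(x)
    if degenerate:
        warnings.warn(
            "degenerate count table (no between-sample variation or a single "
            "taxon); Dirichlet-multinomial concentrations are not identifiable",
            RuntimeWarning,
            stacklevel=2,
        )
        return DirichletMultinomialFit(
            concentration=alpha,
            overdispersion_theta=1.0 / (1.0 + float(alpha.sum())),
            log_likelihood=dm_log_likelihood(x, alpha),
            converged=False,
            n_iter=0,
            degenerate=True,
            floored_taxa=tuple(int(i) for i in absent),
        )

    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        a0 = alpha.sum()
        numerator = (psi(x + alpha) - psi(alpha)).sum(axis=0)
        denominator = (psi(totals + a0) - psi(a0)).sum()
        new_alpha = np.maximum(alpha * numerator / denominator, floor)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    if not converged:
        warnings.warn(
            f"Dirichlet-multinomial fit did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return DirichletMultinomialFit(
        concentration=alpha,
        overdispersion_theta=1.0 / (1.0 + float(alpha.sum())),
        log_likelihood=dm_log_likelihood(x, alpha),
        converged=converged,
        n_iter=iteration,
        degenerate=False,
        floored_taxa=tuple(int(i) for i in absent),
    )


def reconstruct_diversities_from_dm(
    fit: DirichletMultinomialFit,
    num_samples: int,
    depth: int,
    rng: np.random.Generator,
    replicates: int = 10,
    richness_mode: str = "global",
) -> tuple[float, float, float]:
    """Re-simulate (alpha_mean, beta, gamma) from a fitted DM.

    Each replicate draws ``num_samples`` communities (a Dirichlet draw per
    community, then a multinomial of size ``depth``), computes the three
    diversity indices, and the replicate means are returned.
    """
    if num_samples < 1 or depth < 1 or replicates < 1:
        raise ValueError("num_samples, depth and replicates must be >= 1")
    m = fit.concentration.size
    global_richness = m if richness_mode == "global" else None
    alphas, betas, gammas = [], [], []
    for _ in range(replicates):
        probs = rng.dirichlet(fit.concentration, size=num_samples)
        counts = rng.multinomial(depth, probs)
        a_mean, _ = alpha_diversity(counts, richness_mode, global_richness)
        alphas.append(a_mean)
        betas.append(beta_diversity(counts))  # raises for num_samples < 2
        gammas.append(gamma_diversity(counts, richness_mode, global_richness))
    return float(np.mean(alphas)), float(np.mean(betas)), float(np.mean(gammas))


def abundance_histogram(
    abundances: np.ndarray, bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Relative-frequency histogram of an abundance vector (plot-ready)."""
    values = np.asarray(abundances, dtype=float)
    density, edges = np.histogram(values, bins=bins)
    return density / values.size, edges
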