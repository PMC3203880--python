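"""Tajima's D and Fu's F_S with simulation-based significance.

Both statistics ask whether a sample is consistent with mutation–drift
equilibrium in a constant-size population.  Tajima's D contrasts the
mean-pairwise-difference estimator of theta with the segregating-sites
estimator; Fu's F_S asks how improbable the observed number of distinct
haplotypes is under the Ewens sampling distribution.  Strongly negative
values of either indicate an excess of rare variants / young haplotypes, the
footprint of a recent demographic expansion.

Significance is empirical: p-values come from neutral coalescent samples
conditioned on the observed sample size and on theta-hat = mean pairwise
differences (the convention of the standard analysis software this module
mirrors).  D is tested two-tailed, F_S one-tailed low — expansion detection
being the intended use.  Note the field convention that F_S is called
significant at p < 0.02 rather than 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import log, nan, sqrt

import numpy as np
from scipy.special import gammaln, logsumexp

from . import coalescent as coal
from .errors import DegenerateInputError
from .seqio import Alignment, SampleTable
from .sumstats import (
    analyzed_sites,
    pairwise_difference_matrix,
    _population_alignment,
)

__all__ = [
    "NeutralityResult",
    "tajimas_d",
    "fus_fs",
    "tajima_d_value",
    "fs_value",
    "log_stirling_first",
    "ewens_log_pmf",
    "neutral_null",
    "neutrality_result",
]


@dataclass(frozen=True)
class NeutralityResult:
    """Both neutrality statistics for one population.

    ``D``/``Fs`` are NaN with the corresponding flag set when undefined
    (no segregating sites, or a single haplotype).
    """

    population: str
    n: int
    S: int
    k: int
    theta_pi: float  # mean pairwise differences per locus
    D: float
    D_p: float
    D_defined: bool
    Fs: float
    Fs_p: float
    Fs_defined: bool


def tajima_d_value(n: int, S: int, theta_pi: float) -> float:
    """Tajima's D from (n, segregating sites, mean pairwise differences)."""
    if n < 4:
        raise DegenerateInputError(f"Tajima's D needs n >= 4, got {n}")
    if S < 1:
        return nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return nan
    return (theta_pi - S / a1) / sqrt(var)


@lru_cache(maxsize=64)
def log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind).

    Computed in log space through the recurrence
    |s(n+1, k)| = n |s(n, k)| + |s(n, k-1)|, which stays finite well past
    the integer-overflow point of exact arithmetic.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    prev = np.full(2, -np.inf)
    prev[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        cur = np.full(m + 2, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        cur[1 : m + 1] = np.logaddexp(log(m) + prev[1 : m + 1],
                                      prev[0:m])
        cur[m + 1] = prev[m]
        prev = cur
    return prev


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 0..n under the Ewens distribution.

    Pr(K=k) = |s(n,k)| theta^k / theta^(n), theta^(n) the rising factorial.
    """
    if theta <= 0:
        raise DegenerateInputError("theta must be positive for Ewens pmf")
    ls = log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = gammaln(theta + n) - gammaln(theta)
    return ls + k * log(theta) - log_rising


def fs_value(n: int, k_obs: int, theta_pi: float) -> float:
    """Fu's F_S = ln(S'/(1-S')), S' = Pr(K >= k_obs | theta_pi, n).

    Returns +/-inf when S' underflows to 0 or 1 within double precision.
    """
    if k_obs < 2:
        return nan
    if theta_pi <= 0:
        return nan
    lp = ewens_log_pmf(n, theta_pi)
    log_sp = float(min(logsumexp(lp[k_obs:]), 0.0))
    sp = np.exp(log_sp)
    if sp >= 1.0:
        return np.inf  # S' indistinguishable from 1 in double precision
    # when S' underflows, F_S -> log S' which stays finite in log space
    return float(log_sp - np.log1p(-sp))


def _observed(aln, samples, population, exclude_transplanted):
    sub = _population_alignment(aln, samples, population, exclude_transplanted)
    arr = sub.to_array()[:, analyzed_sites(sub)]
    n = arr.shape[0]
    S = int((~(arr == arr[0]).all(axis=0)).sum())
    d = pairwise_difference_matrix(sub)
    theta_pi = float(d[np.triu_indices(n, k=1)].mean()) if n > 1 else 0.0
    keys = {row.tobytes() for row in arr}
    k = len(keys)
    return n, S, k, theta_pi


def neutral_null(
    rng: np.random.Generator, n: int, theta: float, reps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral constant-size null samples of (D, F_S).

    Simulates ``reps`` coalescent genealogies for ``n`` lineages in a single
    population and drops infinite-sites mutations at per-locus rate theta/2
    (time in coalescent units), mirroring how the observed statistics
    condition on theta-hat = mean pairwise differences.
    """
    Ds = np.empty(reps)
    Fs = np.empty(reps)
    for r in range(reps):
        g = coal.simulate_genealogy(rng, [n], [1.0])
        muts = coal.drop_mutation_counts(rng, g, theta / 2.0)
        S, pi, K = coal.infinite_sites_summaries(g, muts)
        Ds[r] = tajima_d_value(n, S, pi) if S >= 1 else nan
        Fs[r] = fs_value(n, K, pi) if (K >= 2 and pi > 0) else nan
    return Ds, Fs


def tajimas_d(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    n_reps: int = 1000,
    seed: int = 0,
    exclude_transplanted: bool = False,
) -> tuple[float, float]:
    """Tajima's D and its two-tailed empirical p-value."""
    n, S, k, theta_pi = _observed(aln, samples, population, exclude_transplanted)
    D = tajima_d_value(n, S, theta_pi)
    if not np.isfinite(D):
        return nan, nan
    rng = np.random.default_rng(seed)
    null_D, _ = neutral_null(rng, n, theta_pi, n_reps)
    null_D = null_D[np.isfinite(null_D)]
    if null_D.size == 0:
        return D, nan
    lo = (np.sum(null_D <= D) + 1) / (null_D.size + 1)
    hi = (np.sum(null_D >= D) + 1) / (null_D.size + 1)
    return D, float(min(1.0, 2.0 * min(lo, hi)))


def fus_fs(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    n_reps: int = 1000,
    seed: int = 0,
    exclude_transplanted: bool = False,
) -> tuple[float, float]:
    """Fu's F_S and its one-tailed (low) empirical p-value."""
    n, S, k, theta_pi = _observed(aln, samples, population, exclude_transplanted)
    if k < 2 or theta_pi <= 0:
        return nan, nan
    F = fs_value(n, k, theta_pi)
    rng = np.random.default_rng(seed)
    _, null_F = neutral_null(rng, n, theta_pi, n_reps)
    null_F = null_F[np.isfinite(null_F)]
    if null_F.size == 0:
        return F, nan
    p = (np.sum(null_F <= F) + 1) / (null_F.size + 1)
    return F, float(p)


def neutrality_result(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    n_reps: int = 1000,
    seed: int = 0,
    exclude_transplanted: bool = False,
) -> NeutralityResult:
    """Both tests sharing one null-simulation stream."""
    n, S, k, theta_pi = _observed(aln, samples, population, exclude_transplanted)
    D = tajima_d_value(n, S, theta_pi) if S >= 1 else nan
    F = fs_value(n, k, theta_pi) if (k >= 2 and theta_pi > 0) else nan
    D_p = Fs_p = nan
    if np.isfinite(D) or np.isfinite(F):
        rng = np.random.default_rng(seed)
        null_D, null_F = neutral_null(rng, n, max(theta_pi, 1e-9), n_reps)
        nd = null_D[np.isfinite(null_D)]
        nf = null_F[np.isfinite(null_F)]
        if np.isfinite(D) and nd.size:
            lo = (np.sum(nd <= D) + 1) / (nd.size + 1)
            hi = (np.sum(nd >= D) + 1) / (nd.size + 1)
            D_p = float(min(1.0, 2.0 * min(lo, hi)))
        if np.isfinite(F) and nf.size:
            Fs_p = float((np.sum(nf <= F) + 1) / (nf.size + 1))
    return NeutralityResult(
        population=population, n=n, S=S, k=k, theta_pi=theta_pi,
        D=D, D_p=D_p, D_defined=bool(np.isfinite(D)),
        Fs=F, Fs_p=Fs_p, Fs_defined=bool(np.isfinite(F)),
    )
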