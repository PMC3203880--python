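"""Sudden-expansion mismatch model: fit tau, theta0, theta1 and date it.

Under a sudden demographic expansion from scaled size theta0 to theta1,
tau = 2ut generations ago, the distribution of pairwise nucleotide
differences follows the closed form

    F_i(tau, theta0, theta1)
      = Fhat_i(theta1)
        + exp(-tau / theta1) * sum_j Pois(j; tau) [Fhat_{i-j}(theta0)
                                                   - Fhat_{i-j}(theta1)]

with Fhat_i(theta) = theta^i / (1+theta)^{i+1} the equilibrium geometric
distribution.  tau = 0 recovers the theta0 equilibrium; theta0 = 0 with
large theta1 approaches a Poisson(tau) "wave", the star-genealogy limit.

The fit minimizes the sum of squared deviations between observed and
expected mismatch frequencies over (tau, theta0, theta1) — deterministic
coarse grid then Nelder–Mead — and the 95% CI on tau comes from a
parametric bootstrap: coalescent datasets simulated under the fitted
two-epoch model, refitted, percentiles taken.  tau converts to time via
t = tau / (2u) with u the per-locus per-generation mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import poisson

from . import coalescent as coal
from .errors import ConfigError, DegenerateInputError
from .sumstats import MismatchDistribution

__all__ = [
    "MismatchFit",
    "ExpansionTiming",
    "expected_mismatch",
    "fit_sudden_expansion",
    "expansion_time",
    "simulate_mismatch",
]


def expected_mismatch(
    tau: float, theta0: float, theta1: float, i_max: int
) -> tuple[np.ndarray, float]:
    """Expected mismatch probabilities F_0..F_imax plus truncation mass.

    The returned vector is the raw truncation of the infinite distribution:
    it sums to 1 minus the reported truncation mass.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ConfigError("mismatch parameters must be non-negative")
    i = np.arange(i_max + 1)

    def fhat(theta: float) -> np.ndarray:
        if theta == 0:
            out = np.zeros(i_max + 1)
            out[0] = 1.0
            return out
        return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))

    f1 = fhat(theta1)
    f0 = fhat(theta0)
    if tau == 0:
        F = f0.copy()
    else:
        w = poisson.pmf(i, tau)
        damp = np.exp(-tau / theta1) if theta1 > 0 else 0.0
        F = f1 + damp * np.convolve(w, f0 - f1)[: i_max + 1]
    F = np.clip(F, 0.0, None)
    return F, float(max(0.0, 1.0 - F.sum()))


@dataclass(frozen=True)
class MismatchFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    tau_ci: tuple[float, float] | None
    degenerate: bool = False


_TAU_GRID = np.arange(0.0, 20.0 + 1e-9, 0.25)
_THETA0_GRID = np.concatenate([[0.0], np.logspace(-2, 1.5, 8)])
_THETA1_GRID = np.logspace(-1, 3, 9)
#: Upper bound on theta1: beyond this the model is in its star-genealogy
#: limit and the objective is flat, so larger values carry no information.
_THETA1_CAP = 1e5


def _ssd(obs: np.ndarray, tau: float, t0: float, t1: float) -> float:
    F, _ = expected_mismatch(tau, t0, t1, len(obs) - 1)
    s = F.sum()
    if s > 0:
        F = F / s
    return float(((obs - F) ** 2).sum())


def _fit_point(md: MismatchDistribution) -> tuple[float, float, float, float]:
    obs_counts = np.asarray(md.counts, dtype=float)
    i_max = len(obs_counts) - 1 + 10
    obs = np.zeros(i_max + 1)
    obs[: len(obs_counts)] = obs_counts / md.n_pairs

    # vectorized coarse grid: cache the equilibrium vectors per theta and
    # the Poisson weights per tau
    i = np.arange(i_max + 1)

    def fhat(theta):
        if theta == 0:
            out = np.zeros(i_max + 1)
            out[0] = 1.0
            return out
        return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))

    f_cache = {t: fhat(t) for t in np.union1d(_THETA0_GRID, _THETA1_GRID)}
    best = (np.inf, 0.0, 0.0, 1.0)
    for tau in _TAU_GRID:
        w = poisson.pmf(i, tau) if tau > 0 else None
        for t1 in _THETA1_GRID:
            f1 = f_cache[t1]
            damp = np.exp(-tau / t1)
            for t0 in _THETA0_GRID:
                if t1 < t0:
                    continue
                if tau == 0:
                    F = f_cache[t0]
                else:
                    F = f1 + damp * np.convolve(w, f_cache[t0] - f1)[: i_max + 1]
                    np.clip(F, 0.0, None, out=F)
                s = F.sum()
                val = float(((obs - F / s) ** 2).sum()) if s > 0 else np.inf
                if val < best[0]:
                    best = (val, tau, t0, t1)
    _, tau, t0, t1 = best

    # unconstrained reparameterization keeps tau, theta0 >= 0 and
    # theta0 <= theta1 <= theta0 + cap
    def unpack(z):
        return z[0] ** 2, z[1] ** 2, z[1] ** 2 + min(z[2] ** 2, _THETA1_CAP)

    def obj(z):
        a, b, c = unpack(z)
        return _ssd(obs, a, b, c)

    z0 = np.sqrt([max(tau, 1e-6), max(t0, 1e-6),
                  max(t1 - t0, 1e-6)])
    res = minimize(obj, z0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-12, "maxiter": 2000})
    if res.fun <= best[0]:
        tau, t0, t1 = unpack(res.x)
        ssd = float(res.fun)
    else:  # pragma: no cover - simplex should never lose to its own start
        ssd = best[0]
    return float(tau), float(t0), float(t1), ssd


def simulate_mismatch(
    rng: np.random.Generator, n: int, tau: float, theta0: float, theta1: float
) -> MismatchDistribution:
    """One coalescent dataset under the two-epoch model, as a mismatch
    histogram.

    Time is measured in pairwise-mutational units (a pair accumulates one
    expected difference per unit), so the deme "size" equals theta and the
    per-locus mutation rate per lineage is 1/2.
    """
    events = []
    if tau > 0:
        events.append(coal.Event(time=tau, kind="resize", a=0,
                                 value=max(theta0, 1e-6)))
    g = coal.simulate_genealogy(rng, [n], [max(theta1, 1e-6)], events)
    muts = coal.drop_mutation_counts(rng, g, 0.5)
    d = coal.pairwise_differences_from_counts(g, muts)
    return MismatchDistribution.from_pairwise(d)


def fit_sudden_expansion(
    md: MismatchDistribution,
    n_bootstrap: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MismatchFit:
    """Least-squares sudden-expansion fit with parametric-bootstrap CI.

    Monomorphic input short-circuits to (tau=0, theta0=0) with the
    degenerate flag set.  Set ``n_bootstrap=0`` to skip the CI.
    """
    if md.n_pairs < 6:
        raise DegenerateInputError("need at least 6 pairs to fit a mismatch")
    counts = np.asarray(md.counts)
    if counts[1:].sum() == 0:
        return MismatchFit(tau=0.0, theta0=0.0, theta1=0.0, ssd=0.0,
                           tau_ci=(0.0, 0.0), degenerate=True)
    tau, t0, t1, ssd = _fit_point(md)
    tau_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        taus = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            sim = simulate_mismatch(rng, md.n, tau, t0, t1)
            if np.asarray(sim.counts)[1:].sum() == 0:
                taus[b] = 0.0
            else:
                taus[b] = _fit_point(sim)[0]
        alpha = (1.0 - ci_level) / 2.0
        tau_ci = (
            float(np.quantile(taus, alpha)),
            float(np.quantile(taus, 1.0 - alpha)),
        )
    return MismatchFit(tau=tau, theta0=t0, theta1=t1, ssd=ssd, tau_ci=tau_ci)


@dataclass(frozen=True)
class ExpansionTiming:
    """tau converted to generations and calendar years."""

    tau: float
    u: float  # per-locus per-generation mutation rate
    g: float  # generation time, years
    t_generations: float
    T_years: float


def expansion_time(
    tau: float, mu_site: float, L: int, g: float
) -> ExpansionTiming:
    """Date an expansion: t = tau / (2u), u = mu_site * L * g.

    ``mu_site`` is the per-site per-*year* rate (the scale on which
    fossil-calibrated rates are quoted); multiplying by the generation time
    ``g`` makes u per-locus per-generation, so t comes out in generations
    and t * g in years.
    """
    if tau < 0:
        raise ConfigError("tau must be >= 0")
    if mu_site <= 0 or L <= 0 or g <= 0:
        raise ConfigError("mutation rate, length and generation time must be > 0")
    u = mu_site * L * g
    t_gen = tau / (2.0 * u)
    return ExpansionTiming(tau=tau, u=u, g=g, t_generations=t_gen,
                           T_years=t_gen * g)
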