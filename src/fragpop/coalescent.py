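"""A small Hudson-style discrete-deme coalescent engine.

The engine is deliberately unit-agnostic: deme "sizes" are whatever makes
``k(k-1)/2 / size`` the within-deme coalescence rate per unit time, and
mutation rates are per lineage per unit time.  Callers pick the time scale:

* generations with haploid effective sizes (the synthetic-data generator),
* coalescent units (size 1) with per-locus rate ``theta/2`` (neutrality
  nulls),
* pairwise-mutational units with size ``theta`` (mismatch bootstrap),
* per-lineage substitutions/site with size ``theta/2`` (ABC divergence).

Demography is piecewise constant with two event kinds processed backwards in
time: ``merge`` (all lineages of a source deme move into a destination deme,
modelling a population split) and ``resize`` (a deme's size changes,
modelling e.g. a demographic expansion).  There is no migration and no
recombination: the target locus is mitochondrial.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "Event",
    "Genealogy",
    "simulate_genealogy",
    "branch_lengths",
    "subtree_tips",
    "drop_mutation_counts",
    "infinite_sites_summaries",
    "pairwise_differences_from_counts",
    "jc_mutate_sequences",
    "pairwise_tmrca",
]


@dataclass(frozen=True)
class Event:
    """A demographic event at a (backwards) time.

    kind 'merge': lineages of deme ``a`` join deme ``b`` (split, viewed
    forwards in time).  kind 'resize': deme ``a`` takes size ``value``.
    """

    time: float
    kind: str  # 'merge' | 'resize'
    a: int
    b: int = -1
    value: float = float("nan")


@dataclass
class Genealogy:
    """A rooted binary coalescent tree over ``n`` tips.

    Nodes ``0..n-1`` are tips (sampling time 0), ``n..2n-2`` internal
    coalescence nodes; ``parent[root] == -1``.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch


def simulate_genealogy(
    rng: np.random.Generator,
    sample_sizes: Sequence[int],
    deme_sizes: Sequence[float],
    events: Sequence[Event] = (),
) -> Genealogy:
    """Sample one genealogy under the specified multi-deme demography.

    ``sample_sizes[d]`` tips start in deme ``d`` at time 0.  Events must be
    sorted by time and must merge every sampled deme into a single surviving
    deme; otherwise lineages trapped in separate demes could never coalesce
    and a :class:`ConfigError` is raised up front.
    """
    sizes = [float(s) for s in deme_sizes]
    if any(s <= 0 for s in sizes):
        raise ConfigError("deme sizes must be positive")
    evs = sorted(events, key=lambda e: e.time)
    if [e.time for e in evs] != [e.time for e in events]:
        # accept unsorted input but keep validation honest about ordering
        events = evs
    # check ultimate connectivity: merges must leave one deme
    alive = set(range(len(sizes)))
    for e in events:
        if e.kind == "merge":
            if e.a not in alive:
                raise ConfigError(f"merge source deme {e.a} already merged")
            if e.b not in alive:
                raise ConfigError(f"merge destination deme {e.b} not alive")
            alive.discard(e.a)
    sampled = {d for d, k in enumerate(sample_sizes) if k > 0}
    if len(sampled) > 1 and len(alive & _reachable_union(sample_sizes, events)) > 1:
        raise ConfigError("events never merge all sampled demes into one")

    n = int(sum(sample_sizes))
    if n < 2:
        raise ConfigError("need at least 2 sampled lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)

    active: list[list[int]] = []
    node = 0
    for k in sample_sizes:
        active.append(list(range(node, node + k)))
        node += k
    next_node = n
    t = 0.0
    ev_i = 0
    n_demes = len(sizes)
    total = n
    while total > 1:
        rates = [
            len(active[d]) * (len(active[d]) - 1) / 2.0 / sizes[d]
            for d in range(n_demes)
        ]
        total_rate = sum(rates)
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = np.inf
        if ev_i < len(events) and t + wait >= events[ev_i].time:
            e = events[ev_i]
            ev_i += 1
            t = e.time
            if e.kind == "merge":
                active[e.b].extend(active[e.a])
                active[e.a] = []
            elif e.kind == "resize":
                if e.value <= 0:
                    raise ConfigError("resize to non-positive size")
                sizes[e.a] = float(e.value)
            else:  # pragma: no cover - guarded by Event construction
                raise ConfigError(f"unknown event kind {e.kind!r}")
            continue
        if not np.isfinite(wait):  # pragma: no cover - blocked by validation
            raise ConfigError("lineages stranded in unmergeable demes")
        t += wait
        # choose deme proportional to its coalescence rate
        u = rng.random() * total_rate
        acc = 0.0
        for d in range(n_demes):
            acc += rates[d]
            if u <= acc:
                break
        lin = active[d]
        i = int(rng.integers(len(lin)))
        j = int(rng.integers(len(lin) - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        parent[a] = next_node
        parent[b] = next_node
        time[next_node] = t
        # replace the two children with their parent
        if i < j:
            i, j = j, i
        lin.pop(i)
        lin.pop(j)
        lin.append(next_node)
        next_node += 1
        total -= 1
    return Genealogy(n=n, parent=parent, time=time)


def _reachable_union(sample_sizes: Sequence[int], events: Sequence[Event]) -> set[int]:
    """Demes that still hold (ancestors of) sampled lineages after all merges."""
    where = {d for d, k in enumerate(sample_sizes) if k > 0}
    for e in events:
        if e.kind == "merge" and e.a in where:
            where.discard(e.a)
            where.add(e.b)
    return where


def branch_lengths(g: Genealogy) -> np.ndarray:
    """Length of the branch above each node (0 for the root)."""
    lens = np.zeros(g.n_nodes)
    has_parent = g.parent >= 0
    lens[has_parent] = g.time[g.parent[has_parent]] - g.time[np.flatnonzero(has_parent)]
    return lens


def subtree_tips(g: Genealogy) -> np.ndarray:
    """Boolean (n_nodes, n) matrix: tips descending from each node."""
    out = np.zeros((g.n_nodes, g.n), dtype=bool)
    out[np.arange(g.n), np.arange(g.n)] = True
    # internal nodes are numbered in coalescence (time) order, so a single
    # ascending pass accumulates children before parents
    for i in range(g.n_nodes):
        p = g.parent[i]
        if p >= 0:
            out[p] |= out[i]
    return out


def drop_mutation_counts(
    rng: np.random.Generator, g: Genealogy, locus_rate: float
) -> np.ndarray:
    """Poisson mutation counts per branch at ``locus_rate`` per unit time."""
    return rng.poisson(branch_lengths(g) * locus_rate)


def infinite_sites_summaries(
    g: Genealogy, muts: np.ndarray
) -> tuple[int, float, int]:
    """(S, pi, K) under infinite sites given per-branch mutation counts.

    ``pi`` is the mean number of pairwise differences per locus; ``K`` the
    number of distinct haplotypes (mutation-free tips share one haplotype).
    """
    n = g.n
    tips = subtree_tips(g)
    sizes = tips.sum(axis=1)
    S = int(muts.sum())
    npairs = comb(n, 2)
    pi = float((muts * sizes * (n - sizes)).sum() / npairs)
    carrier = tips[muts > 0][:, :n]
    if carrier.shape[0] == 0:
        K = 1
    else:
        # a haplotype is the set of mutated branches above a tip; weight by
        # multiplicity so two hits on one branch still give one haplotype
        K = len(np.unique(carrier.T, axis=0))
    return S, pi, K


def pairwise_differences_from_counts(g: Genealogy, muts: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts under infinite sites."""
    sel = muts > 0
    if not sel.any():
        return np.zeros((g.n, g.n))
    A = subtree_tips(g)[sel][:, : g.n].astype(float)
    w = muts[sel].astype(float)
    r = w @ A
    cross = (A * w[:, None]).T @ A
    d = r[:, None] + r[None, :] - 2 * cross
    np.fill_diagonal(d, 0.0)
    return d


_N_BASES = 4


def jc_mutate_sequences(
    rng: np.random.Generator,
    g: Genealogy,
    mu_site: float,
    L: int,
    ancestral: np.ndarray | None = None,
) -> np.ndarray:
    """Finite-sites Jukes–Cantor overlay; returns (n, L) uint8 states 0..3.

    Mutations are a Poisson process at ``mu_site * L`` per lineage per unit
    time; each hit picks a uniform site and replaces its state with one of
    the three other bases, so multiple hits (homoplasy) can and do occur.
    """
    if ancestral is None:
        ancestral = rng.integers(0, _N_BASES, size=L, dtype=np.uint8)
    lens = branch_lengths(g)
    n_mut = rng.poisson(lens * mu_site * L)
    total = int(n_mut.sum())
    all_sites = rng.integers(0, L, size=total)
    all_steps = rng.integers(1, _N_BASES, size=total).astype(np.uint8)
    offsets = np.concatenate([[0], np.cumsum(n_mut)])
    # copy-on-write down the tree: mutation-free branches share the parent row
    rows: list[np.ndarray] = [ancestral] * g.n_nodes
    order = np.argsort(-g.time, kind="stable")  # root first, tips last
    for node in order:
        p = g.parent[node]
        if p < 0:
            continue
        k = n_mut[node]
        if k == 0:
            rows[node] = rows[p]
            continue
        row = rows[p].copy()
        lo = offsets[node]
        for s, st in zip(all_sites[lo : lo + k], all_steps[lo : lo + k]):
            row[s] = (row[s] + st) % _N_BASES
        rows[node] = row
    return np.stack(rows[: g.n])


def pairwise_tmrca(g: Genealogy) -> np.ndarray:
    """(n, n) matrix of pairwise coalescence times (diagonal 0)."""
    tips = subtree_tips(g)
    children = g.children()
    T = np.zeros((g.n, g.n))
    for u in range(g.n, g.n_nodes):
        c1, c2 = children[u]
        a = np.flatnonzero(tips[c1])
        b = np.flatnonzero(tips[c2])
        T[np.ix_(a, b)] = g.time[u]
        T[np.ix_(b, a)] = g.time[u]
    return T
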