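"""Hierarchical AMOVA, pairwise Phi_ST, SAMOVA clustering, and Mantel tests.

AMOVA partitions the total molecular variance — computed from the matrix of
pairwise nucleotide differences, used directly as squared distances — into
among-group, among-site-within-group and within-site components via the
standard unbalanced nested ANOVA expectations.  The derived Phi-statistics
are

* F_CT: fraction of total variance among groups,
* F_SC: fraction of the within-group variance among sites,
* F_ST: fraction of total variance among sites overall.

SAMOVA searches for the spatial partition of sampling sites into K
geographically contiguous groups that maximizes F_CT, using simulated
annealing over single-site moves on a Delaunay neighbourhood graph with
random contiguous restarts.  The Mantel test correlates two labelled
distance matrices with permutation-based significance (one-tailed positive:
isolation by distance predicts a positive correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, ValidationError
from .seqio import Alignment, PairwiseMatrix, SampleTable
from .sumstats import pairwise_difference_matrix

__all__ = [
    "AmovaResult",
    "PartitionResult",
    "MantelResult",
    "amova",
    "pairwise_phist",
    "site_adjacency",
    "samova",
    "samova_scan",
    "mantel_test",
    "enumerate_contiguous_partitions",
]


@dataclass(frozen=True)
class AmovaResult:
    """Variance components and Phi-statistics of a nested AMOVA."""

    K: int
    n_sites: int
    n: int
    sigma_a: float  # among groups
    sigma_b: float  # among sites within groups
    sigma_c: float  # within sites
    F_CT: float
    F_SC: float
    F_ST: float


class _AmovaEngine:
    """Site-level sufficient statistics for fast repeated F_CT evaluation.

    ``C[s, t]`` holds the sum of pairwise distances between samples of sites
    s and t (diagonal: twice the within-site pair sum), so the SSD of any
    grouping is a cheap aggregation — the annealer evaluates thousands of
    partitions against the same matrix.
    """

    def __init__(self, aln: Alignment, samples: SampleTable,
                 exclude_transplanted: bool = False):
        samples.validate_against(aln)
        df = samples.df
        if exclude_transplanted:
            df = df[~df["transplanted"]]
        ids = list(df["sample_id"])
        if len(ids) < 2:
            raise DegenerateInputError("fewer than 2 samples for AMOVA")
        sub = aln.subset(ids)
        d = pairwise_difference_matrix(sub).astype(float)
        site_of = dict(zip(df["sample_id"], df["site_id"]))
        self.sites = tuple(dict.fromkeys(df["site_id"]))
        s_index = {s: i for i, s in enumerate(self.sites)}
        lab = np.array([s_index[site_of[i]] for i in ids])
        S = len(self.sites)
        M = np.zeros((len(ids), S))
        M[np.arange(len(ids)), lab] = 1.0
        self.C = M.T @ d @ M  # ordered pair sums
        self.n_s = M.sum(axis=0)
        self.N = int(self.n_s.sum())
        small = self.n_s < 2
        if small.any():
            warnings.warn(
                f"sites with n<2: {[self.sites[i] for i in np.flatnonzero(small)]}",
                stacklevel=3,
            )

    def components(self, group_of: np.ndarray) -> AmovaResult:
        """Variance components for a site->group assignment array."""
        groups = np.unique(group_of)
        G = len(groups)
        S = len(self.sites)
        N = self.N
        # sums of squared deviations at the three levels
        ssd_total = self.C.sum() / 2.0 / N
        ssd_within_site = sum(
            self.C[s, s] / 2.0 / self.n_s[s] for s in range(S)
        )
        ssd_within_group = 0.0
        n_g = np.zeros(G)
        B = 0.0  # sum_g sum_{s in g} n_s^2 / n_g
        Cg = 0.0  # sum_g n_g^2 / N
        for gi, g in enumerate(groups):
            sel = np.flatnonzero(group_of == g)
            n_g[gi] = self.n_s[sel].sum()
            if n_g[gi] == 0:
                raise ValidationError("empty group in partition")
            ssd_within_group += self.C[np.ix_(sel, sel)].sum() / 2.0 / n_g[gi]
            B += (self.n_s[sel] ** 2).sum() / n_g[gi]
            Cg += n_g[gi] ** 2 / N
        ssd_among_groups = ssd_total - ssd_within_group
        ssd_among_sites = ssd_within_group - ssd_within_site

        A = float((self.n_s**2).sum())
        df_c = N - S
        df_b = S - G
        df_a = G - 1
        sigma_c = ssd_within_site / df_c if df_c > 0 else 0.0
        if df_b > 0:
            n1 = (N - B) / df_b
            ms_b = ssd_among_sites / df_b
            sigma_b = (ms_b - sigma_c) / n1 if n1 > 0 else 0.0
        else:
            sigma_b = 0.0
        if df_a > 0:
            n2 = (B - A / N) / df_a
            n3 = (N - Cg) / df_a
            ms_a = ssd_among_groups / df_a
            sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        else:
            sigma_a = float("nan")
        tot = sigma_a + sigma_b + sigma_c
        if G > 1 and tot > 0:
            f_ct = sigma_a / tot
            f_st = (sigma_a + sigma_b) / tot
        else:
            f_ct = f_st = float("nan")
        f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
        return AmovaResult(
            K=G, n_sites=S, n=N, sigma_a=sigma_a, sigma_b=sigma_b,
            sigma_c=sigma_c, F_CT=f_ct, F_SC=f_sc, F_ST=f_st,
        )

    def f_ct(self, group_of: np.ndarray) -> float:
        r = self.components(group_of)
        return r.F_CT if np.isfinite(r.F_CT) else 0.0


def amova(
    aln: Alignment,
    samples: SampleTable,
    grouping: dict[str, object],
    exclude_transplanted: bool = False,
) -> AmovaResult:
    """Nested AMOVA for an explicit site -> group mapping."""
    eng = _AmovaEngine(aln, samples, exclude_transplanted)
    missing = [s for s in eng.sites if s not in grouping]
    if missing:
        raise ValidationError(f"grouping missing sites: {missing}")
    labels = sorted({grouping[s] for s in eng.sites}, key=str)
    if len(labels) < 2:
        raise ValidationError("need >=2 groups for AMOVA")
    lab_idx = {g: i for i, g in enumerate(labels)}
    assign = np.array([lab_idx[grouping[s]] for s in eng.sites])
    return eng.components(assign)


def pairwise_phist(
    aln: Alignment,
    samples: SampleTable,
    exclude_transplanted: bool = False,
) -> PairwiseMatrix:
    """Pairwise Phi_ST between populations (two-level AMOVA per pair).

    Populations with n < 2 are dropped with a warning.  Small negative
    estimates are retained and flagged on the returned matrix.
    """
    samples.validate_against(aln)
    df = samples.df
    if exclude_transplanted:
        df = df[~df["transplanted"]]
    pops = [
        p for p in dict.fromkeys(df["population"])
        if (df["population"] == p).sum() >= 2
    ]
    dropped = set(dict.fromkeys(df["population"])) - set(pops)
    if dropped:
        warnings.warn(f"populations with n<2 excluded: {sorted(dropped)}")
    if len(pops) < 2:
        raise DegenerateInputError("need >=2 populations with n>=2")
    ids = list(df.loc[df["population"].isin(pops), "sample_id"])
    sub = aln.subset(ids)
    d = pairwise_difference_matrix(sub).astype(float)
    lab = df.set_index("sample_id").loc[ids, "population"].to_numpy()
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _phist_pair(d, lab, pops[i], pops[j])
    return PairwiseMatrix(tuple(pops), out, allow_negative=True)


def _phist_pair(d: np.ndarray, lab: np.ndarray, a: str, b: str) -> float:
    sel = np.flatnonzero((lab == a) | (lab == b))
    dd = d[np.ix_(sel, sel)]
    la = lab[sel] == a
    n1, n2 = int(la.sum()), int((~la).sum())
    N = n1 + n2
    ssd_t = dd.sum() / 2.0 / N
    ssd_w = (
        dd[np.ix_(la, la)].sum() / 2.0 / n1
        + dd[np.ix_(~la, ~la)].sum() / 2.0 / n2
    )
    ssd_a = ssd_t - ssd_w
    ms_w = ssd_w / (N - 2)
    n_c = (N - (n1**2 + n2**2) / N)  # df_a = 1
    sigma_a = (ssd_a - ms_w) / n_c
    tot = sigma_a + ms_w
    if tot <= 0:
        return 0.0
    return float(sigma_a / tot)


def site_adjacency(samples: SampleTable) -> nx.Graph:
    """Neighbourhood graph of sampling sites.

    Delaunay triangulation of the site coordinates; degenerate layouts
    (collinear sites, < 4 sites) fall back to a symmetrized 2-nearest-
    neighbour graph.  A disconnected graph is an error.
    """
    coords = samples.site_coords()
    labels = list(coords.index)
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if len(labels) < 2:
        raise DegenerateInputError("need >=2 sites for an adjacency graph")
    built = False
    if len(labels) >= 4:
        try:
            tri = Delaunay(xy)
            for simplex in tri.simplices:
                for u, v in ((0, 1), (1, 2), (0, 2)):
                    g.add_edge(labels[simplex[u]], labels[simplex[v]])
            built = True
        except QhullError:
            built = False
    if not built:
        dist = cdist(xy, xy)
        np.fill_diagonal(dist, np.inf)
        kk = min(2, len(labels) - 1)
        for i in range(len(labels)):
            for j in np.argsort(dist[i])[:kk]:
                g.add_edge(labels[i], labels[int(j)])
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValidationError(f"site adjacency graph disconnected: {comps}")
    return g


@dataclass
class PartitionResult:
    """Best spatial partition found for one K."""

    K: int
    assignment: dict[str, int]
    F_CT: float
    amova: AmovaResult
    n_restarts: int
    trace: dict


def _random_contiguous_partition(
    rng: np.random.Generator, adj: nx.Graph, sites: tuple[str, ...], K: int
) -> np.ndarray:
    idx = {s: i for i, s in enumerate(sites)}
    assign = np.full(len(sites), -1)
    seeds = rng.choice(len(sites), size=K, replace=False)
    for gi, s in enumerate(seeds):
        assign[s] = gi
    frontier = [s for s in sites if assign[idx[s]] < 0]
    while frontier:
        progressed = False
        order = rng.permutation(len(frontier))
        for oi in order:
            s = frontier[oi]
            nbr_groups = [
                assign[idx[t]] for t in adj.neighbors(s) if assign[idx[t]] >= 0
            ]
            if nbr_groups:
                assign[idx[s]] = nbr_groups[int(rng.integers(len(nbr_groups)))]
                progressed = True
        frontier = [s for s in sites if assign[idx[s]] < 0]
        if not progressed and frontier:  # pragma: no cover - connected graph
            raise ValidationError("could not grow contiguous partition")
    return assign


def _is_contiguous(adj: nx.Graph, sites: tuple[str, ...],
                   assign: np.ndarray, group: int) -> bool:
    members = [s for s, a in zip(sites, assign) if a == group]
    if not members:
        return False
    sub = adj.subgraph(members)
    return nx.is_connected(sub)


def samova(
    aln: Alignment,
    samples: SampleTable,
    K: int,
    n_restarts: int = 100,
    seed: int = 0,
    exclude_transplanted: bool = False,
    cooling: float = 0.95,
    moveless_sweeps: int = 50,
) -> PartitionResult:
    """Simulated-annealing search for the K-group partition maximizing F_CT.

    Moves reassign one boundary site to an adjacent group, rejected outright
    if they would empty a group or break the donor group's contiguity.
    Geometric cooling with T0 set from the typical move magnitude so that
    initial acceptance is ~0.8; best state over ``n_restarts`` random
    contiguous starts is returned.  Deterministic for a fixed seed.
    """
    eng = _AmovaEngine(aln, samples, exclude_transplanted)
    sites = eng.sites
    if K > len(sites):
        raise ValidationError(f"K={K} exceeds {len(sites)} sites")
    if K < 2:
        raise ValidationError("K must be >= 2")
    adj = site_adjacency(samples)
    idx = {s: i for i, s in enumerate(sites)}
    rng = np.random.default_rng(seed)

    best_assign = None
    best_f = -np.inf
    restart_scores = []
    accepted_total = 0
    for _ in range(n_restarts):
        assign = _random_contiguous_partition(rng, adj, sites, K)
        f = eng.f_ct(assign)
        # calibrate T0 from sampled move magnitudes
        deltas = []
        for _ in range(16):
            mv = _propose(rng, adj, sites, idx, assign)
            if mv is None:
                continue
            s, new_g, old_g = mv
            assign[s] = new_g
            deltas.append(abs(eng.f_ct(assign) - f))
            assign[s] = old_g
        t0 = np.median(deltas) / np.log(1 / 0.8) if deltas else 0.01
        T = max(float(t0), 1e-6)
        cur_f = f
        stale = 0
        while stale < moveless_sweeps and T > 1e-9:
            moved = False
            for _ in range(max(4, len(sites))):
                mv = _propose(rng, adj, sites, idx, assign)
                if mv is None:
                    continue
                s, new_g, old_g = mv
                assign[s] = new_g
                new_f = eng.f_ct(assign)
                delta = new_f - cur_f
                if delta > 0 or rng.random() < np.exp(delta / T):
                    cur_f = new_f
                    moved = True
                    accepted_total += 1
                else:
                    assign[s] = old_g
            stale = 0 if moved else stale + 1
            T *= cooling
        restart_scores.append(cur_f)
        if cur_f > best_f:
            best_f = cur_f
            best_assign = assign.copy()
    res = eng.components(best_assign)
    return PartitionResult(
        K=K,
        assignment={s: int(a) for s, a in zip(sites, best_assign)},
        F_CT=best_f,
        amova=res,
        n_restarts=n_restarts,
        trace={
            "restart_best_F_CT": [float(x) for x in restart_scores],
            "accepted_moves": accepted_total,
        },
    )


def _propose(rng, adj, sites, idx, assign):
    """One candidate move: a boundary site into an adjacent foreign group."""
    order = rng.permutation(len(sites))
    for oi in order:
        s = sites[oi]
        g = assign[oi]
        if (assign == g).sum() < 2:
            continue
        foreign = sorted({
            int(assign[idx[t]]) for t in adj.neighbors(s) if assign[idx[t]] != g
        })
        if not foreign:
            continue
        old = assign[oi]
        assign[oi] = -1
        donor_ok = _is_contiguous(adj, sites, assign, old) if (assign == old).any() else False
        assign[oi] = old
        if not donor_ok:
            continue
        return oi, foreign[int(rng.integers(len(foreign)))], int(old)
    return None


def samova_scan(
    aln: Alignment,
    samples: SampleTable,
    K_range=range(2, 9),
    n_restarts: int = 100,
    seed: int = 0,
    exclude_transplanted: bool = False,
) -> tuple[list[PartitionResult], int]:
    """Run SAMOVA over a K range; return the profile and argmax-F_CT K.

    Ties in the profile maximum break toward the smaller K (parsimony).
    """
    results = []
    seeds = np.random.SeedSequence(seed).spawn(len(list(K_range)))
    ks = list(K_range)
    for K, ss in zip(ks, seeds):
        results.append(
            samova(
                aln, samples, K, n_restarts=n_restarts,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                exclude_transplanted=exclude_transplanted,
            )
        )
    fcts = np.array([r.F_CT for r in results])
    selected = ks[int(np.argmax(fcts))]  # argmax returns first (smallest K) tie
    return results, selected


def enumerate_contiguous_partitions(adj: nx.Graph, K: int):
    """Yield all site->group assignments with K non-empty contiguous groups.

    Exhaustive (label-symmetry-reduced) enumeration; intended for small
    instances (<= ~9 sites) as ground truth for the annealer.
    """
    sites = sorted(adj.nodes)
    S = len(sites)
    for assign in product(range(K), repeat=S):
        if assign[0] != 0:
            continue
        # canonical label order removes group-relabelling duplicates
        seen: list[int] = []
        ok = True
        for a in assign:
            if a not in seen:
                if a != len(seen):
                    ok = False
                    break
                seen.append(a)
        if not ok or len(set(assign)) != K:
            continue
        arr = np.array(assign)
        if all(
            nx.is_connected(adj.subgraph([s for s, g in zip(sites, arr) if g == k]))
            for k in range(K)
        ):
            yield dict(zip(sites, (int(a) for a in arr)))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel_test(
    m1: PairwiseMatrix,
    m2: PairwiseMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; p is the
    one-tailed (positive) permutation p-value with +1 smoothing, permuting
    rows and columns of ``m2`` jointly.  Ties count as extreme.
    """
    if set(m1.labels) != set(m2.labels):
        raise ValidationError("Mantel matrices have different label sets")
    if len(m1.labels) < 4:
        raise DegenerateInputError("Mantel test needs >= 4 labels")
    m2 = m2.reorder(m1.labels)
    k = len(m1.labels)
    iu = np.triu_indices(k, 1)
    x = m1.values[iu]
    y0 = m2.values[iu]
    if np.std(x) == 0 or np.std(y0) == 0:
        raise DegenerateInputError("constant matrix: Mantel r undefined")

    def corr(y):
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(y0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = m2.values[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)
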