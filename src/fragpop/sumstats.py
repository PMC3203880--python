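"""Haplotype collapsing, diversity statistics, mismatch distributions,
haplotype networks, and secondary-contact screening.

Missing-data policy: statistics are computed on *analyzed sites* only —
alignment columns containing nothing but A/C/G/T across the sequences under
consideration (complete deletion).  The deletion is applied to the subset
being analyzed, so a gap confined to one population does not shrink the
site set of another.

Estimators follow the standard forms:

* haplotype diversity  h = n/(n-1) * (1 - sum p_i^2), with Nei's
  large-sample sampling variance;
* nucleotide diversity pi = mean pairwise differences / L_analyzed, with
  the total (stochastic + sampling) variance of Tajima's estimator;
* uncorrected p-distance = mean between-group proportion of differing
  analyzed sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
import networkx as nx

from .errors import DegenerateInputError, ValidationError
from .seqio import Alignment, PairwiseMatrix, SampleTable

__all__ = [
    "HaplotypeTable",
    "DiversityStats",
    "MismatchDistribution",
    "analyzed_sites",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "diversity_stats",
    "diversity_report",
    "p_distance_matrix",
    "mismatch_distribution",
    "minimum_spanning_network",
    "detect_secondary_contact",
    "pairwise_difference_matrix",
]

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


def analyzed_sites(aln: Alignment) -> np.ndarray:
    """Indices of columns containing only A/C/G/T in every sequence."""
    arr = aln.to_array()
    ok = np.isin(arr, _ACGT).all(axis=0)
    sites = np.flatnonzero(ok)
    if sites.size == 0:
        raise DegenerateInputError("no fully resolved columns left after deletion")
    return sites


def _analyzed_array(aln: Alignment) -> np.ndarray:
    return aln.to_array()[:, analyzed_sites(aln)]


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """(n, n) counts of nucleotide differences on analyzed sites."""
    arr = _analyzed_array(aln)
    # one boolean comparison per site keeps memory at n^2 per step
    n = arr.shape[0]
    d = np.zeros((n, n), dtype=np.int64)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        d += col[:, None] != col[None, :]
    return d


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population multiplicities.

    ``haplotypes`` are sequences restricted to the analyzed sites;
    ``counts`` is a (haplotype x population) integer table;
    ``assignment`` maps sample_id -> haplotype index.
    """

    haplotypes: tuple[str, ...]
    counts: pd.DataFrame
    assignment: dict[str, int]
    n_analyzed_sites: int

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def multiplicities(self, population: str) -> np.ndarray:
        """Nonzero haplotype counts within one population, descending."""
        if population not in self.counts.columns:
            raise ValidationError(f"unknown population {population!r}")
        m = self.counts[population].to_numpy()
        m = m[m > 0]
        return np.sort(m)[::-1]

    def distance_matrix(self) -> np.ndarray:
        """(k, k) nucleotide differences between haplotypes."""
        arr = np.frombuffer("".join(self.haplotypes).encode(), dtype="S1").reshape(
            self.k, -1
        )
        d = np.zeros((self.k, self.k), dtype=np.int64)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            d += col[:, None] != col[None, :]
        return d


def collapse_haplotypes(
    aln: Alignment,
    samples: SampleTable,
    exclude_transplanted: bool = False,
) -> HaplotypeTable:
    """Group identical sequences (on analyzed sites) into haplotypes.

    Haplotypes are numbered in order of first appearance in the alignment.
    """
    samples.validate_against(aln)
    keep = list(aln.ids)
    if exclude_transplanted:
        flagged = set(samples.df.loc[samples.df["transplanted"], "sample_id"])
        keep = [s for s in keep if s not in flagged]
        if len(keep) < 1:
            raise DegenerateInputError("all samples excluded as transplanted")
    sub = aln.subset(keep)
    sites = analyzed_sites(sub)
    arr = sub.to_array()[:, sites]
    keys = ["".join(x.decode() for x in row) for row in arr]
    hap_index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for sid, key in zip(sub.ids, keys):
        if key not in hap_index:
            hap_index[key] = len(hap_index)
        assignment[sid] = hap_index[key]
    haplotypes = tuple(hap_index.keys())
    pop_of = samples.population_of()
    pops = list(dict.fromkeys(samples.df["population"]))
    counts = pd.DataFrame(
        0, index=range(len(haplotypes)), columns=pops, dtype=np.int64
    )
    for sid, h in assignment.items():
        counts.loc[h, pop_of[sid]] += 1
    ht = HaplotypeTable(
        haplotypes=haplotypes,
        counts=counts,
        assignment=assignment,
        n_analyzed_sites=len(sites),
    )
    ht._sample_pop = {sid: pop_of[sid] for sid in assignment}
    return ht


def haplotype_diversity(ht: HaplotypeTable, population: str) -> tuple[float, float]:
    """Unbiased haplotype (gene) diversity and its standard deviation.

    h = n/(n-1) (1 - sum p_i^2); the variance is Nei's (1987) large-sample
    form used by the standard population-genetics packages.
    """
    m = ht.multiplicities(population)
    n = int(m.sum())
    if n < 2:
        raise DegenerateInputError(f"n={n} < 2 in population {population!r}")
    p = m / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    h = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return h, sqrt(max(var, 0.0))


def _population_alignment(
    aln: Alignment, samples: SampleTable, population: str,
    exclude_transplanted: bool,
) -> Alignment:
    samples.validate_against(aln)
    ids = samples.ids_in(population, exclude_transplanted=exclude_transplanted)
    if len(ids) < 2:
        raise DegenerateInputError(
            f"population {population!r} has n={len(ids)} < 2"
        )
    return aln.subset(ids)


def nucleotide_diversity(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    exclude_transplanted: bool = False,
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard deviation.

    The variance is Tajima's total variance of the mean-pairwise-difference
    estimator (stochastic plus sampling components):
    V = (n+1)/(3(n-1)) * pi/L + 2(n^2+n+3)/(9n(n-1)) * pi^2.
    """
    sub = _population_alignment(aln, samples, population, exclude_transplanted)
    arr = _analyzed_array(sub)
    n, L = arr.shape
    d = pairwise_difference_matrix(sub)
    mean_pairs = d[np.triu_indices(n, k=1)].mean()
    pi = float(mean_pairs) / L
    var = (n + 1) / (3.0 * (n - 1)) * pi / L + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, sqrt(max(var, 0.0))


@dataclass(frozen=True)
class DiversityStats:
    """Per-population diversity summary (one Table row in reports)."""

    population: str
    n: int
    k: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    S: int


def diversity_stats(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    exclude_transplanted: bool = False,
) -> DiversityStats:
    sub = _population_alignment(aln, samples, population, exclude_transplanted)
    ht = collapse_haplotypes(
        sub,
        SampleTable(samples.df[samples.df["sample_id"].isin(sub.ids)]),
        exclude_transplanted=False,
    )
    h, h_sd = haplotype_diversity(ht, population)
    pi, pi_sd = nucleotide_diversity(aln, samples, population,
                                     exclude_transplanted)
    arr = _analyzed_array(sub)
    S = int((~(arr == arr[0]).all(axis=0)).sum())
    return DiversityStats(
        population=population, n=sub.n, k=ht.k, h=h, h_sd=h_sd,
        pi=pi, pi_sd=pi_sd, S=S,
    )


def diversity_report(
    aln: Alignment, samples: SampleTable, exclude_transplanted: bool = True
) -> pd.DataFrame:
    """Per-population diversity table.

    When transplanted (secondary-contact) samples exist and
    ``exclude_transplanted`` is set, their residence population is reported
    twice — excluding ("no sc", the analytical baseline) and including
    ("sc") the flagged individuals.
    """
    rows = []
    flagged_pops = set(
        samples.df.loc[samples.df["transplanted"], "population"]
    )
    for pop in samples.populations:
        variants: list[tuple[str, bool]] = [(pop, False)]
        if exclude_transplanted and pop in flagged_pops:
            variants = [(f"{pop} (no sc)", True), (f"{pop} (sc)", False)]
        for label, excl in variants:
            st = diversity_stats(aln, samples, pop, exclude_transplanted=excl)
            rows.append(
                {
                    "population": label, "n": st.n, "haplotypes": st.k,
                    "h": st.h, "h_sd": st.h_sd, "pi": st.pi,
                    "pi_sd": st.pi_sd, "S": st.S,
                }
            )
    return pd.DataFrame(rows)


def p_distance_matrix(aln: Alignment, samples: SampleTable) -> PairwiseMatrix:
    """Mean between-population uncorrected p-distance on analyzed sites."""
    samples.validate_against(aln)
    pops = samples.populations
    if len(pops) < 2:
        raise DegenerateInputError("need >=2 populations for p-distances")
    order = [samples.population_of()[s] for s in aln.ids]
    arr = _analyzed_array(aln)
    L = arr.shape[1]
    d = pairwise_difference_matrix(aln) / L
    labels = np.array(order)
    k = len(pops)
    out = np.zeros((k, k))
    for i, a in enumerate(pops):
        ia = labels == a
        if not ia.any():
            raise DegenerateInputError(f"population {a!r} empty")
        for j in range(i + 1, k):
            ib = labels == pops[j]
            out[i, j] = out[j, i] = d[np.ix_(ia, ib)].mean()
    return PairwiseMatrix(tuple(pops), out)


@dataclass(frozen=True)
class MismatchDistribution:
    """Histogram of pairwise nucleotide-difference counts."""

    counts: tuple[int, ...]
    n: int  # samples

    @property
    def n_pairs(self) -> int:
        return comb(self.n, 2)

    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pairs

    def mean(self) -> float:
        i = np.arange(len(self.counts))
        return float((i * np.asarray(self.counts)).sum() / self.n_pairs)

    @classmethod
    def from_pairwise(cls, d: np.ndarray) -> "MismatchDistribution":
        n = d.shape[0]
        vals = d[np.triu_indices(n, k=1)].astype(int)
        counts = np.bincount(vals)
        return cls(counts=tuple(int(c) for c in counts), n=n)


def mismatch_distribution(
    aln: Alignment,
    samples: SampleTable,
    population: str,
    exclude_transplanted: bool = False,
) -> MismatchDistribution:
    sub = _population_alignment(aln, samples, population, exclude_transplanted)
    return MismatchDistribution.from_pairwise(pairwise_difference_matrix(sub))


def minimum_spanning_network(ht: HaplotypeTable) -> list[tuple[int, int, int]]:
    """Minimum-spanning haplotype network: all edges lying in *some* MST.

    A weighted edge (i, j, w) belongs to some minimum spanning tree iff i
    and j are disconnected in the subgraph of strictly lighter edges; the
    union of such edges is the classic tied-edge network generalization of
    an MST.  Edge weights are nucleotide steps between haplotypes.
    """
    if ht.k < 2:
        raise DegenerateInputError("need >=2 haplotypes for a network")
    d = ht.distance_matrix()
    edges = [
        (int(d[i, j]), i, j) for i, j in combinations(range(ht.k), 2)
    ]
    edges.sort()
    uf = list(range(ht.k))

    def find(x: int) -> int:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    network: list[tuple[int, int, int]] = []
    i = 0
    while i < len(edges):
        j = i
        w = edges[i][0]
        batch = []
        while j < len(edges) and edges[j][0] == w:
            _, a, b = edges[j]
            if find(a) != find(b):
                batch.append((a, b, w))
            j += 1
        for a, b, w_ in batch:
            network.append((a, b, w_))
            ra, rb = find(a), find(b)
            if ra != rb:
                uf[ra] = rb
        i = j
        if len({find(x) for x in range(ht.k)}) == 1 and all(
            e[0] > w for e in edges[j:]
        ):
            break
    return network


def mst_total_weight(ht: HaplotypeTable) -> int:
    """Weight of a minimum spanning tree over the haplotype distances."""
    g = nx.Graph()
    d = ht.distance_matrix()
    for i, j in combinations(range(ht.k), 2):
        g.add_edge(i, j, weight=int(d[i, j]))
    t = nx.minimum_spanning_tree(g)
    return int(sum(w for _, _, w in t.edges.data("weight")))


def detect_secondary_contact(
    ht: HaplotypeTable, min_steps: int
) -> list[str]:
    """Flag likely transplanted individuals.

    A sample is flagged when its haplotype (a) also occurs in another
    population and (b) lies at least ``min_steps`` mutational steps from
    every non-shared haplotype of the sample's own population.  Carriers in
    the haplotype's presumptive home population are *not* flagged because
    their own deme holds close relatives of it.
    """
    pops = list(ht.counts.columns)
    if len(pops) < 2:
        raise DegenerateInputError("need >=2 populations to screen")
    d = ht.distance_matrix()
    counts = ht.counts.to_numpy()
    shared = (counts > 0).sum(axis=1) > 1
    flagged: list[str] = []
    for h in np.flatnonzero(shared):
        for pi, pop in enumerate(pops):
            if counts[h, pi] == 0:
                continue
            own = [
                g
                for g in range(ht.k)
                if g != h and counts[g, pi] > 0 and not shared[g]
            ]
            # an empty comparison set is no evidence of divergence — do not
            # flag then, except at the min_steps=0 limit (flag everything
            # shared by definition)
            if (own or min_steps == 0) and all(d[h, g] >= min_steps for g in own):
                flagged.extend(
                    sid
                    for sid, hap in ht.assignment.items()
                    if hap == h and _pop_of_sample(ht, sid) == pop
                )
    return sorted(set(flagged))


def _pop_of_sample(ht: HaplotypeTable, sample_id: str) -> str:
    # assignment order parallels construction; recover population from counts
    # is not possible per-sample, so HaplotypeTable callers attach it
    if not hasattr(ht, "_sample_pop"):
        raise ValidationError(
            "HaplotypeTable lacks sample->population map; build via "
            "collapse_haplotypes"
        )
    return ht._sample_pop[sample_id]
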