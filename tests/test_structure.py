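"""AMOVA components, SAMOVA search optimality, and the Mantel test."""

import numpy as np
import pytest

from fragpop.errors import DegenerateInputError, ValidationError
from fragpop.seqio import PairwiseMatrix
from fragpop.structure import (
    _AmovaEngine,
    amova,
    enumerate_contiguous_partitions,
    mantel_test,
    pairwise_phist,
    samova,
    samova_scan,
    site_adjacency,
)
from fragpop.sumstats import pairwise_difference_matrix
from fragpop.simulate import SimConfig, simulate_history

from conftest import make_alignment, make_table, monomorphic_plus_variants


def textbook_amova(d, site_of, group_of_site):
    """Independent nested-AMOVA implementation with explicit loops.

    Straight from the unbalanced nested ANOVA expectations on squared
    distances; written without reference to the package internals.
    """
    n = d.shape[0]
    sites = sorted(set(site_of))
    groups = sorted({group_of_site[s] for s in sites})
    in_site = {s: [i for i in range(n) if site_of[i] == s] for s in sites}
    in_group = {
        g: [i for i in range(n) if group_of_site[site_of[i]] == g]
        for g in groups
    }

    def ssd(members):
        return sum(
            d[i, j] for ii, i in enumerate(members) for j in members[ii + 1:]
        ) / len(members)

    ssd_t = ssd(list(range(n)))
    ssd_ws = sum(ssd(in_site[s]) for s in sites)
    ssd_wg = sum(ssd(in_group[g]) for g in groups)
    ssd_ag = ssd_t - ssd_wg
    ssd_as = ssd_wg - ssd_ws
    S, G = len(sites), len(groups)
    n_s = {s: len(in_site[s]) for s in sites}
    n_g = {g: len(in_group[g]) for g in groups}
    A = sum(v**2 for v in n_s.values())
    B = sum(
        sum(n_s[s] ** 2 for s in sites if group_of_site[s] == g) / n_g[g]
        for g in groups
    )
    C = sum(v**2 for v in n_g.values()) / n
    sigma_c = ssd_ws / (n - S)
    n1 = (n - B) / (S - G)
    sigma_b = (ssd_as / (S - G) - sigma_c) / n1
    n2 = (B - A / n) / (G - 1)
    n3 = (n - C) / (G - 1)
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def _random_dataset(rng, n_sites=4, per_site=3, L=40):
    seqs, rows = [], []
    for s in range(n_sites):
        block = [
            "".join(rng.choice(list("ACGT"), size=L)) for _ in range(per_site)
        ]
        # make sites internally similar: copies of one local sequence + noise
        base = block[0]
        for b in range(per_site):
            t = list(base)
            for _ in range(int(rng.integers(0, 3))):
                j = int(rng.integers(L))
                t[j] = "ACGT"[int(rng.integers(4))]
            sid = f"i{s}_{b}"
            seqs.append((sid, "".join(t)))
            rows.append((sid, f"site{s}", f"pop{s}", float(s % 3),
                         float(s // 3) + 0.1 * s))
    aln = make_alignment([q for _, q in seqs], ids=[i for i, _ in seqs])
    return aln, make_table(rows)


class TestAmova:
    def test_two_monomorphic_groups_fct_one(self):
        a = monomorphic_plus_variants(4, 50, [], np.random.default_rng(0))
        b = [s.translate(str.maketrans("ACGT", "CAGT")) for s in a]
        aln = make_alignment(a + b)
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(4)]
            + [(f"s{i}", "sB", "B", 1, 1) for i in range(4, 8)]
        )
        r = amova(aln, table, {"sA": 0, "sB": 1})
        assert r.F_CT == pytest.approx(1.0)
        assert r.sigma_b == 0.0 and r.sigma_c == 0.0

    def test_random_split_of_panmixia_fct_near_zero(self):
        vals = []
        rng = np.random.default_rng(8)
        for rep in range(100):
            cfg = SimConfig(
                n_per_deme=(6, 6, 6, 6),
                deme_sizes=(20_000.0,) * 4,
                split_times=(0.0, 0.0, 0.0),
                expansion=None,
                seed=1000 + rep,
            )
            out = simulate_history(cfg)
            sites = list(out.samples.sites)
            perm = rng.permutation(4)
            grouping = {sites[perm[0]]: 0, sites[perm[1]]: 0,
                        sites[perm[2]]: 1, sites[perm[3]]: 1}
            vals.append(amova(out.alignment, out.samples, grouping).F_CT)
        vals = [v for v in vals if np.isfinite(v)]  # monomorphic: undefined
        assert len(vals) > 60
        assert abs(float(np.mean(vals))) < 0.05

    def test_components_match_independent_implementation(self):
        rng = np.random.default_rng(4)
        aln, table = _random_dataset(rng, n_sites=4, per_site=3)
        grouping = {"site0": 0, "site1": 0, "site2": 1, "site3": 1}
        r = amova(aln, table, grouping)
        d = pairwise_difference_matrix(aln).astype(float)
        site_of = [f"site{int(i.split('_')[0][1:])}" for i in aln.ids]
        sa, sb, sc = textbook_amova(d, site_of, grouping)
        assert r.sigma_a == pytest.approx(sa, abs=1e-10)
        assert r.sigma_b == pytest.approx(sb, abs=1e-10)
        assert r.sigma_c == pytest.approx(sc, abs=1e-10)

    def test_variance_decomposition_conserved(self):
        """SSD additivity: the three components reconstruct the total SSD
        computed directly from the distance matrix."""
        rng = np.random.default_rng(9)
        aln, table = _random_dataset(rng, n_sites=6, per_site=3)
        eng = _AmovaEngine(aln, table)
        d = pairwise_difference_matrix(aln).astype(float)
        n = d.shape[0]
        ssd_total = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
        assert eng.C.sum() / 2.0 / eng.N == pytest.approx(ssd_total, abs=1e-10)


class TestPairwisePhist:
    def test_identical_populations_zero(self):
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(3)]
            + [(f"s{i}", "sB", "B", 1, 1) for i in range(3, 6)]
        )
        # monomorphic and identical across populations: no variance at all
        aln = make_alignment(["ACGTACGT"] * 6, ids=[f"s{i}" for i in range(6)])
        m = pairwise_phist(aln, table)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        # same polymorphic composition duplicated: estimate must not be
        # positive (small negatives are retained and flagged)
        s = monomorphic_plus_variants(6, 60, [(2, 1)],
                                      np.random.default_rng(1))
        aln2 = make_alignment(s[:3] + s[:3], ids=[f"s{i}" for i in range(6)])
        assert pairwise_phist(aln2, table).values[0, 1] <= 0.0

    def test_fixed_difference_gives_one(self):
        a = monomorphic_plus_variants(3, 50, [], np.random.default_rng(0))
        b = [s.translate(str.maketrans("AC", "CA")) for s in a]
        aln = make_alignment(a + b)
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(3)]
            + [(f"s{i}", "sB", "B", 1, 1) for i in range(3, 6)]
        )
        assert pairwise_phist(aln, table).values[0, 1] == pytest.approx(1.0)

    def test_rank_order_tracks_split_times(self):
        """Deeper splits give larger Phi_ST in expectation.

        A single mitochondrial locus leaves the per-replicate ranking noisy
        (within-deme diversity is one genealogical draw), so the ordering is
        asserted on the replicate means, with only a weak per-replicate
        majority requirement.
        """
        trips = []
        for seed in range(40):
            out = simulate_history(SimConfig(seed=3000 + seed))
            df = pairwise_phist(out.alignment, out.samples).to_dataframe()
            trips.append(
                (df.loc["Dawida", "Sagalla"], df.loc["Dawida", "Kasigau"],
                 df.loc["Dawida", "Mbololo"])
            )
        means = np.mean(trips, axis=0)
        assert means[0] > means[2]  # oldest split > youngest split
        hits = sum(t[0] >= t[2] for t in trips)
        assert hits >= 24  # correct orientation in a clear majority


class TestSamova:
    def _fixture(self, rng, n_sites, per_site=2, L=30, n_groups=2):
        return _random_dataset(rng, n_sites=n_sites, per_site=per_site, L=L)

    def test_recovers_two_fixed_demes(self):
        rng = np.random.default_rng(1)
        a = monomorphic_plus_variants(8, 60, [], rng)
        b = [s.translate(str.maketrans("ACGT", "GTAC")) for s in a]
        rows, seqs, ids = [], [], []
        for s in range(4):  # 4 sites of deme A at x<10
            for j in range(2):
                sid = f"a{s}_{j}"
                ids.append(sid)
                seqs.append(a[0])
                rows.append((sid, f"sA{s}", "A", float(s), float(s % 2)))
        for s in range(4):  # 4 sites of deme B at x>100
            for j in range(2):
                sid = f"b{s}_{j}"
                ids.append(sid)
                seqs.append(b[0])
                rows.append((sid, f"sB{s}", "B", 100.0 + s, float(s % 2)))
        aln = make_alignment(seqs, ids=ids)
        table = make_table(rows)
        res = samova(aln, table, K=2, n_restarts=10, seed=0)
        groups = {}
        for site, g in res.assignment.items():
            groups.setdefault(g, set()).add(site[:2])
        assert all(len(v) == 1 for v in groups.values())  # pure A / pure B
        direct = amova(aln, table,
                       {s: (0 if s.startswith("sA") else 1)
                        for s in table.sites})
        assert res.F_CT == pytest.approx(direct.F_CT, abs=1e-12)

    def test_k_equals_sites_singletons(self):
        rng = np.random.default_rng(2)
        aln, table = self._fixture(rng, n_sites=5, per_site=3)
        res = samova(aln, table, K=5, n_restarts=3, seed=1)
        assert sorted(res.assignment.values()) == list(range(5))
        direct = amova(aln, table, {s: i for i, s in enumerate(table.sites)})
        assert res.F_CT == pytest.approx(direct.F_CT, abs=1e-12)

    @pytest.mark.parametrize("n_sites,K", [(6, 2), (7, 3)])
    def test_matches_exhaustive_enumeration(self, n_sites, K):
        rng = np.random.default_rng(10 * n_sites + K)
        aln, table = self._fixture(rng, n_sites=n_sites, per_site=2)
        res = samova(aln, table, K=K, n_restarts=20, seed=3)
        eng = _AmovaEngine(aln, table)
        adj = site_adjacency(table)
        sites = eng.sites
        best = max(
            eng.f_ct(np.array([p[s] for s in sites]))
            for p in enumerate_contiguous_partitions(adj, K)
        )
        assert res.F_CT == pytest.approx(best, abs=1e-9)

    def test_k_exceeding_sites_rejected(self):
        rng = np.random.default_rng(3)
        aln, table = self._fixture(rng, n_sites=4)
        with pytest.raises(ValidationError):
            samova(aln, table, K=5, n_restarts=2, seed=0)

    def test_scan_selects_four_demes(self, small_sim):
        res, K = samova_scan(small_sim.alignment, small_sim.samples,
                             range(2, 5), n_restarts=8, seed=2)
        assert K == 4
        best = next(r for r in res if r.K == 4)
        pops = small_sim.samples.site_population_map()
        group_pops = {}
        for site, g in best.assignment.items():
            group_pops.setdefault(g, set()).add(pops[site])
        assert all(len(v) == 1 for v in group_pops.values())


class TestMantel:
    def _mat(self, v, labels=("a", "b", "c", "d", "e", "f")):
        return PairwiseMatrix(labels, v, allow_negative=True)

    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, size=(6, 6))
        v = np.triu(x, 1) + np.triu(x, 1).T
        r = mantel_test(self._mat(v), self._mat(2 * v), n_perm=499, seed=1)
        assert r.r == pytest.approx(1.0)
        assert r.p == pytest.approx(1 / 500)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, size=(6, 6))
        v = np.triu(x, 1) + np.triu(x, 1).T
        w = -v + 10
        np.fill_diagonal(w, 0)
        r = mantel_test(self._mat(v), self._mat(w), n_perm=199, seed=1)
        assert r.r == pytest.approx(-1.0)
        assert r.p > 0.5

    def test_constant_matrix_error(self):
        v = np.ones((6, 6)) - np.eye(6)
        with pytest.raises(DegenerateInputError):
            mantel_test(self._mat(v), self._mat(v), n_perm=99, seed=0)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(5)
        a = rng.uniform(1, 9, size=(7, 7))
        b = rng.uniform(1, 9, size=(7, 7))
        va = np.triu(a, 1) + np.triu(a, 1).T
        vb = np.triu(b, 1) + np.triu(b, 1).T
        labels = tuple("abcdefg")
        ours = mantel_test(
            PairwiseMatrix(labels, va), PairwiseMatrix(labels, vb),
            n_perm=999, seed=2,
        )
        r_sk, p_sk, _ = sk_mantel(
            DistanceMatrix(va, labels), DistanceMatrix(vb, labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(ours.p - float(p_sk)) < 0.1
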