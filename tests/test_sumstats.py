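"""Diversity estimators, mismatch distributions, haplotype networks."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from fragpop.errors import DegenerateInputError
from fragpop.sumstats import (
    analyzed_sites,
    collapse_haplotypes,
    detect_secondary_contact,
    diversity_stats,
    haplotype_diversity,
    minimum_spanning_network,
    mismatch_distribution,
    nucleotide_diversity,
    p_distance_matrix,
)

from conftest import make_alignment, make_table, monomorphic_plus_variants


def _simple_pop(seqs, pop="P"):
    aln = make_alignment(seqs)
    table = make_table([(i, "s1", pop, 0, 0) for i in aln.ids])
    return aln, table


class TestAnalyzedSites:
    def test_column_with_n_excluded(self):
        aln = make_alignment(["ACGT", "ANGT"])
        assert list(analyzed_sites(aln)) == [0, 2, 3]

    def test_gap_free_all_retained(self):
        aln = make_alignment(["ACGT", "ACGA"])
        assert len(analyzed_sites(aln)) == 4

    def test_count_with_ambiguous_columns(self):
        rng = np.random.default_rng(1)
        seqs = monomorphic_plus_variants(4, 783, [(1, 2)], rng)
        # poke gaps/ambiguities into 3 distinct invariant columns
        s0 = list(seqs[0])
        s0[100] = "-"
        s0[200] = "N"
        s0[300] = "R"
        seqs[0] = "".join(s0)
        aln = make_alignment(seqs)
        assert len(analyzed_sites(aln)) == 780


class TestHaplotypes:
    def test_identical_collapse_to_one(self):
        aln, table = _simple_pop(["ACGT"] * 4)
        assert collapse_haplotypes(aln, table).k == 1

    def test_mbololo_like_multiplicities(self):
        """17 samples in (10, 6, 1) haplotype classes: the 6-copy haplotype
        is 35% of the sample, and h comes out at the published 0.5588."""
        seqs = monomorphic_plus_variants(17, 783, [(6, 1), (1, 2)])
        aln, table = _simple_pop(seqs)
        ht = collapse_haplotypes(aln, table)
        assert sorted(ht.multiplicities("P"), reverse=True) == [10, 6, 1]
        h, _ = haplotype_diversity(ht, "P")
        assert round(h, 4) == 0.5588
        assert round(6 / 17, 2) == 0.35

    def test_multiplicity_conservation(self, default_sim):
        ht = collapse_haplotypes(default_sim.alignment, default_sim.samples)
        assert int(ht.counts.to_numpy().sum()) == default_sim.alignment.n


class TestHaplotypeDiversity:
    def test_single_haplotype_zero(self):
        aln, table = _simple_pop(["ACGT"] * 15)
        ht = collapse_haplotypes(aln, table)
        h, sd = haplotype_diversity(ht, "P")
        assert h == 0.0 and sd == 0.0

    def test_three_one_split(self):
        seqs = monomorphic_plus_variants(4, 783, [(1, 1)])
        aln, table = _simple_pop(seqs)
        h, sd = haplotype_diversity(collapse_haplotypes(aln, table), "P")
        assert h == pytest.approx(0.5)
        assert sd == pytest.approx(0.2652, abs=5e-5)  # Nei variance

    def test_pair_differs_gives_one(self):
        aln, table = _simple_pop(["ACGT", "ACGA"])
        h, _ = haplotype_diversity(collapse_haplotypes(aln, table), "P")
        assert h == pytest.approx(1.0)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        seqs = monomorphic_plus_variants(10, 50, [(3, 1), (2, 2)], rng)
        aln, table = _simple_pop(seqs)
        h1, _ = haplotype_diversity(collapse_haplotypes(aln, table), "P")
        order = list(rng.permutation(10))
        aln2 = make_alignment([seqs[i] for i in order],
                              ids=[f"s{i}" for i in order])
        table2 = make_table([(f"s{i}", "s1", "P", 0, 0) for i in order])
        h2, _ = haplotype_diversity(collapse_haplotypes(aln2, table2), "P")
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_n_below_two_rejected(self):
        aln, table = _simple_pop(["ACGT", "ACGA"])
        ht = collapse_haplotypes(aln, table)
        with pytest.raises(Exception):
            # population with 0 samples
            haplotype_diversity(ht, "QQ")


class TestNucleotideDiversity:
    def test_kasigau_cell(self):
        seqs = monomorphic_plus_variants(4, 783, [(1, 1)])
        aln, table = _simple_pop(seqs)
        pi, sd = nucleotide_diversity(aln, table, "P")
        assert pi == pytest.approx((3 / 6) / 783)
        assert round(pi, 4) == 0.0006
        assert sd == pytest.approx(0.0008, abs=2e-4)

    def test_identical_zero(self):
        aln, table = _simple_pop(["ACGT"] * 5)
        pi, _ = nucleotide_diversity(aln, table, "P")
        assert pi == 0.0

    def test_single_pair(self):
        seqs = ["AAAAAAAAAA", "AAAAAAAAAC"]
        aln, table = _simple_pop(seqs)
        pi, _ = nucleotide_diversity(aln, table, "P")
        assert pi == pytest.approx(0.1)

    def test_pi_equals_mismatch_mean_over_L(self, default_sim):
        pi, _ = nucleotide_diversity(default_sim.alignment,
                                     default_sim.samples, "Dawida")
        md = mismatch_distribution(default_sim.alignment,
                                   default_sim.samples, "Dawida")
        assert pi == pytest.approx(md.mean() / 783, abs=1e-12)


class TestPDistance:
    def test_two_monomorphic_groups(self):
        a = monomorphic_plus_variants(3, 783, [], np.random.default_rng(0))
        b = monomorphic_plus_variants(2, 783, [(2, 14)],
                                      np.random.default_rng(0))[:2]
        aln = make_alignment(a + b)
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(3)]
            + [(f"s{i}", "sB", "B", 1, 1) for i in range(3, 5)]
        )
        m = p_distance_matrix(aln, table)
        assert m.values[0, 1] == pytest.approx(14 / 783)
        assert round(100 * m.values[0, 1], 2) == 1.79
        assert m.values[0, 0] == 0.0

    def test_rank_order_follows_split_times(self, small_sim):
        m = p_distance_matrix(small_sim.alignment, small_sim.samples)
        df = m.to_dataframe()
        # deepest split (Sagalla) should exceed the shallow Dawida-Mbololo one
        assert df.loc["Dawida", "Sagalla"] > df.loc["Dawida", "Mbololo"]


class TestMismatchDistribution:
    def test_monomorphic_all_mass_at_zero(self):
        aln, table = _simple_pop(["ACGT"] * 5)
        md = mismatch_distribution(aln, table, "P")
        assert md.counts == (10,)

    def test_kasigau_one_step(self):
        seqs = monomorphic_plus_variants(4, 783, [(1, 1)])
        aln, table = _simple_pop(seqs)
        md = mismatch_distribution(aln, table, "P")
        assert md.counts == (3, 3)

    def test_counts_conserved(self, default_sim):
        md = mismatch_distribution(default_sim.alignment,
                                   default_sim.samples, "Dawida")
        assert sum(md.counts) == comb(99, 2)


class TestMinimumSpanningNetwork:
    def test_two_close_one_far(self):
        # haplotypes at mutual distances 1, 1, 2: the two 1-step links win
        aln, table = _simple_pop(["AAAA", "AAAC", "CAAA"])
        ht = collapse_haplotypes(aln, table)
        net = minimum_spanning_network(ht)
        assert sorted((min(a, b), max(a, b)) for a, b, _ in net) == [(0, 1), (0, 2)]

    def test_chain(self):
        aln, table = _simple_pop(["AAAA", "AAAC", "AACC"])
        net = minimum_spanning_network(collapse_haplotypes(aln, table))
        assert sorted((min(a, b), max(a, b)) for a, b, _ in net) == [(0, 1), (1, 2)]

    def test_total_weight_matches_exhaustive_minimum(self):
        """Random 8-haplotype instance against brute force over all spanning
        trees (edge subsets of size k-1 that connect the graph)."""
        rng = np.random.default_rng(5)
        seqs = []
        while len(set(seqs)) < 8:
            seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(8)]
        aln, table = _simple_pop(list(dict.fromkeys(seqs))[:8])
        ht = collapse_haplotypes(aln, table)
        d = ht.distance_matrix()
        k = ht.k
        edges = list(combinations(range(k), 2))

        def is_spanning(tree):
            seen = {0}
            pool = list(tree)
            grew = True
            while grew:
                grew = False
                for a, b in pool:
                    if (a in seen) != (b in seen):
                        seen.update((a, b))
                        grew = True
            return len(seen) == k

        best = min(
            sum(d[a, b] for a, b in t)
            for t in combinations(edges, k - 1)
            if is_spanning(t)
        )
        # every MST-edge set of the network must realize the optimum weight
        net = minimum_spanning_network(ht)
        import networkx as nx

        g = nx.Graph()
        g.add_weighted_edges_from(net)
        mst = nx.minimum_spanning_tree(g)
        total = sum(w for _, _, w in mst.edges.data("weight"))
        assert total == best

    def test_single_haplotype_degenerate(self):
        aln, table = _simple_pop(["ACGT"] * 3)
        with pytest.raises(DegenerateInputError):
            minimum_spanning_network(collapse_haplotypes(aln, table))


class TestDetectSecondaryContact:
    def _two_pop_shared(self):
        rng = np.random.default_rng(2)
        base = monomorphic_plus_variants(5, 100, [(2, 1)], rng)  # pop A
        farseqs = monomorphic_plus_variants(4, 100, [(1, 1)],
                                            np.random.default_rng(9))
        # make pop B distant: flip 10 fixed sites relative to A
        far = []
        for s in farseqs:
            t = list(s)
            for j in range(10):
                t[50 + j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[50 + j]]
            far.append("".join(t))
        # one B individual carries an A haplotype (the shared one)
        seqs = base + far[:3] + [base[0]]
        aln = make_alignment(seqs)
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(5)]
            + [(f"s{i}", "sB", "B", 5, 5) for i in range(5, 9)]
        )
        return aln, table

    def test_no_shared_haplotypes_empty(self):
        a = monomorphic_plus_variants(3, 50, [], np.random.default_rng(0))
        b = ["".join("C" if c == "A" else c for c in s) for s in a[:2]]
        aln = make_alignment(a + b)
        table = make_table(
            [(f"s{i}", "sA", "A", 0, 0) for i in range(3)]
            + [(f"s{i}", "sB", "B", 1, 1) for i in range(3, 5)]
        )
        ht = collapse_haplotypes(aln, table)
        assert detect_secondary_contact(ht, min_steps=1) == []

    def test_threshold_behaviour(self):
        aln, table = self._two_pop_shared()
        ht = collapse_haplotypes(aln, table)
        # with a threshold below the 10-step gulf only the B carrier flags
        flagged = detect_secondary_contact(ht, min_steps=5)
        assert flagged == ["s8"]
        # min_steps=0 flags every carrier of a shared haplotype
        all_flagged = detect_secondary_contact(ht, min_steps=0)
        assert "s8" in all_flagged and len(all_flagged) > 1


class TestDiversityStats:
    def test_table_row_consistency(self, default_sim):
        st = diversity_stats(default_sim.alignment, default_sim.samples,
                             "Dawida")
        assert st.n == 99
        assert 0 <= st.h <= 1
        assert st.k >= 1 and st.S >= 0
        if st.k == 1:
            assert st.h == 0.0 and st.pi == 0.0
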