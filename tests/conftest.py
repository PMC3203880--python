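"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fragpop.seqio import Alignment, SampleTable
from fragpop.simulate import SimConfig, simulate_history


def make_alignment(seqs, ids=None, locus="ND2"):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return Alignment(locus_name=locus, ids=tuple(ids), seqs=tuple(seqs))


def make_table(rows):
    """rows: (sample_id, site_id, population, x, y[, transplanted])."""
    cols = ["sample_id", "site_id", "population", "x", "y", "transplanted"]
    rows = [tuple(r) + (False,) * (6 - len(r)) for r in rows]
    return SampleTable(pd.DataFrame(rows, columns=cols))


def monomorphic_plus_variants(n, L, variant_counts, rng=None, base="A"):
    """n sequences of length L: a common haplotype plus variants.

    ``variant_counts`` maps a number of copies to a number of differing
    sites, e.g. {1: 1} adds one haplotype (1 copy) one step away.
    """
    rng = rng or np.random.default_rng(0)
    ref = "".join(rng.choice(list("ACGT"), size=L))
    seqs = []
    used_sites = set()
    for copies, steps in variant_counts:
        s = list(ref)
        for _ in range(steps):
            while True:
                j = int(rng.integers(L))
                if j not in used_sites:
                    used_sites.add(j)
                    break
            s[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[j]]
        seqs.extend(["".join(s)] * copies)
    seqs.extend([ref] * (n - len(seqs)))
    return seqs[:n]


@pytest.fixture(scope="session")
def default_sim():
    """One draw under the default four-deme study conditions."""
    return simulate_history(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A fast four-deme dataset with two sites per deme (for SAMOVA etc.)."""
    cfg = SimConfig(
        n_per_deme=(16, 10, 8, 6),
        deme_sizes=(30_000.0, 20_000.0, 2_000.0, 15_000.0),
        split_times=(400_000.0, 300_000.0, 200_000.0),
        expansion=None,
        sites_per_deme=2,
        seed=5,
    )
    return simulate_history(cfg)
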