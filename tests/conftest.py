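import numpy as np
import pytest

from rnamod.model_space import (
    KmerTable,
    ModificationSite,
    assign_mod_chars,
    build_branch_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sites(contig, seq, positions, mod_code="Y"):
    """1-based positions; canonical taken from the sequence."""
    sites = [
        ModificationSite(
            contig=contig, position=p, canonical=seq[p - 1].replace("T", "U"),
            mod_code=mod_code, callable=True,
        )
        for p in positions
    ]
    sites, _ = assign_mod_chars(sites)
    return sites


def make_table_for(branch_map, rng, center=100.0, spread=8.0, sd=1.0, mod_shift=3.0):
    """A table covering exactly the branch map's variant kmers; modified
    variants offset from their canonical counterpart by mod_shift."""
    table = KmerTable(k=branch_map.k)
    for j, variants in enumerate(branch_map.slot_variants):
        canonical = branch_map.canonical_kmer(j)
        if canonical not in table:
            table.set(canonical, float(rng.normal(center, spread)), sd)
        base_mean = table[canonical][0]
        for kmer, choices in variants:
            if kmer not in table:
                table.set(kmer, base_mean + mod_shift, sd)
    return table


@pytest.fixture
def tiny_branch_map(rng):
    seq = "ACGUAGCUAGGUACGU"
    sites = make_sites("c", seq, [7])
    return build_branch_map("c", seq, sites, k=5)
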