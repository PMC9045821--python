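"""Annotation loading, modification alphabet, branch map and kmer tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnamod import fixtures
from rnamod.model_space import (
    AnnotationError,
    KmerTable,
    ModificationSite,
    assign_mod_chars,
    branch_kmer_sets,
    build_branch_map,
    derive_branch_kmers,
    load_annotation,
    load_kmer_table,
    write_kmer_table,
)
from tests.conftest import make_sites


class TestLoadAnnotation:
    def test_bundled_yeast_fixture_counts(self):
        """The bundled annotation carries 110 sites: 37 on 18S, 73 on 25S."""
        sites, reference = fixtures.yeast_annotation()
        assert len(sites) == 110
        assert sum(s.contig == "18S" for s in sites) == 37
        assert sum(s.contig == "25S" for s in sites) == 73
        for s in sites:
            assert reference[s.contig][s.pos0] == s.canonical
            assert s.callable  # no yeast rRNA modification sits in the dead zone

    def test_known_clusters_present(self):
        sites, _ = fixtures.yeast_annotation()
        by_key = {(s.contig, s.position): s for s in sites}
        assert by_key[("25S", 2922)].mod_code == "Gm"
        assert by_key[("25S", 2923)].mod_code == "Y"
        assert {by_key[("25S", p)].guide for p in (1437, 1449, 1450)} == {"U24"}

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("contig\tposition\tcanonical\tmod_code\tguide\n")
        assert load_annotation(p, {"c": "ACGU" * 10}) == []

    def test_dead_zone_site_not_callable(self, tmp_path):
        p = tmp_path / "ann.tsv"
        seq = "ACGU" * 10
        p.write_text(
            "contig\tposition\tcanonical\tmod_code\tguide\n"
            f"c\t10\t{seq[9]}\tY\t\n"
            f"c\t20\t{seq[19]}\tY\t\n"
        )
        sites = load_annotation(p, {"c": seq})
        assert [s.callable for s in sites] == [False, True]

    @pytest.mark.parametrize(
        "row",
        [
            "c\t100\tA\tY\t",           # out of bounds
            "c\t3\tU\tY\t",             # canonical mismatch (ref has G)
            "c\t4\tU\tY\t\nc\t4\tU\tY\t",  # duplicate
            "other\t4\tU\tY\t",         # unknown contig
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, row):
        p = tmp_path / "bad.tsv"
        p.write_text("contig\tposition\tcanonical\tmod_code\tguide\n" + row + "\n")
        with pytest.raises(AnnotationError):
            load_annotation(p, {"c": "ACGU" * 10})

    def test_t_normalized_to_u(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("contig\tposition\tcanonical\tmod_code\tguide\nc\t20\tT\tY\t\n")
        sites = load_annotation(p, {"c": "ACGU" * 10})
        assert sites[0].canonical == "U"


class TestAssignModChars:
    def test_single_site(self):
        sites = [ModificationSite("c", 30, "U", "Y")]
        out, alphabet = assign_mod_chars(sites)
        assert out[0].mod_char is not None
        assert alphabet.by_contig["c"] == {out[0].mod_char: 30}

    def test_distant_sites_have_disjoint_kmer_sets(self):
        seq = "AUGC" * 60
        sites = make_sites("c", seq, [50, 150])
        bm = build_branch_map("c", seq, sites, k=5)
        covering = {p: set() for p in bm.site_pos0}
        for j, variants in enumerate(bm.slot_variants):
            for kmer, choices in variants:
                for pos, is_mod in choices:
                    if is_mod:
                        covering[pos].add(kmer)
        a, b = bm.site_pos0
        assert covering[a] and covering[b]
        assert covering[a].isdisjoint(covering[b])

    def test_close_sites_enumerate_four_variants(self):
        """Two sites 2 nt apart inside one 5-mer window: the covering slot
        lists exactly the 2^2 variants of the brute-force enumeration."""
        seq = "ACGUACGUACGUACGU"
        sites = make_sites("c", seq, [7, 9])
        bm = build_branch_map("c", seq, sites, k=5)
        c7, c9 = sites[0].mod_char, sites[1].mod_char
        assert c7 != c9
        j = 5  # covers positions 6..10 (1-based), i.e. both sites
        kmers = {k for k, _ in bm.slot_variants[j]}
        base = list(seq[j : j + 5])
        expected = set()
        for m7, m9 in itertools.product([False, True], repeat=2):
            w = base[:]
            if m7:
                w[1] = c7
            if m9:
                w[3] = c9
            expected.add("".join(w))
        assert kmers == expected

    def test_idempotent_and_order_stable(self):
        seq = "AUGC" * 30
        sites = make_sites("c", seq, [20, 40, 60])
        chars = [s.mod_char for s in sites]
        again, _ = assign_mod_chars(sites)
        assert [s.mod_char for s in again] == chars
        shuffled, _ = assign_mod_chars(list(reversed(sites)))
        assert [s.mod_char for s in shuffled] == chars

    def test_pool_exhaustion(self):
        sites = [ModificationSite("c", p, "U", "Y") for p in range(20, 26)]
        with pytest.raises(ValueError, match="pool exhausted"):
            assign_mod_chars(sites, pool="xy")


class TestBranchMap:
    def test_single_slot_contig(self):
        seq = "ACGUA"
        sites = make_sites("c", seq, [3])
        bm = build_branch_map("c", seq, sites, k=5)
        assert bm.n_slots == 1
        assert len(bm.allowed[2]) == 2
        assert len(bm.slot_variants[0]) == 2

    def test_lone_interior_site_covered_by_k_slots(self):
        seq = "AUGC" * 10
        sites = make_sites("c", seq, [20])
        bm = build_branch_map("c", seq, sites, k=5)
        n_branching = sum(len(v) == 2 for v in bm.slot_variants)
        assert n_branching == 5
        assert all(len(v) in (1, 2) for v in bm.slot_variants)
        assert bm.n_slots == len(seq) - 5 + 1

    def test_site_without_mod_char_rejected(self):
        site = ModificationSite("c", 7, "U", "Y")
        with pytest.raises(ValueError, match="mod_char"):
            build_branch_map("c", "ACGUACGUACGU", [site], k=5)

    def test_k_below_one_rejected(self, tiny_branch_map):
        with pytest.raises(ValueError):
            build_branch_map("c", "ACGUACGU", [], k=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        length=st.integers(min_value=6, max_value=30),
        k=st.integers(min_value=2, max_value=5),
    )
    def test_variant_count_identity(self, data, length, k):
        """Sum of per-slot variant counts equals (L-k+1) plus the extra
        2^b - 1 branches, verified against direct enumeration."""
        seq = "".join(
            data.draw(st.lists(st.sampled_from("ACGU"), min_size=length, max_size=length))
        )
        n_sites = data.draw(st.integers(min_value=0, max_value=3))
        positions = sorted(
            data.draw(
                st.sets(st.integers(min_value=1, max_value=length),
                        min_size=n_sites, max_size=n_sites)
            )
        )
        sites = make_sites("c", seq, positions)
        bm = build_branch_map("c", seq, sites, k=k)
        total = sum(len(v) for v in bm.slot_variants)
        expected = 0
        for j in range(length - k + 1):
            b = sum(1 for p in positions if j < p <= j + k)
            expected += 2**b
        assert total == expected

    def test_forced_maps_have_single_variants(self, tiny_branch_map):
        for state in ("modified", "canonical"):
            forced = tiny_branch_map.forced(state)
            assert all(len(v) == 1 for v in forced.slot_variants)
        mod = tiny_branch_map.forced("modified")
        pos = tiny_branch_map.site_pos0[0]
        char = tiny_branch_map.mod_char_at[pos]
        assert mod.slot_variants[pos][0][0][0] == char  # slot starting at the site


class TestKmerTable:
    def test_toy_k1_roundtrip_and_lookup(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text("kmer\tlevel_mean\tlevel_sd\nA\t100.0\t1.5\nC\t90\t2\nG\t110\t1\nU\t95\t1\n")
        table = load_kmer_table(p)
        assert table.k == 1
        assert table["A"] == (100.0, 1.5)
        out = tmp_path / "out.tsv"
        write_kmer_table(table, out)
        assert load_kmer_table(out).entries == table.entries
        out2 = tmp_path / "out2.tsv"
        write_kmer_table(load_kmer_table(out), out2)
        assert out.read_text() == out2.read_text()

    def test_non_positive_sd_rejected(self, tmp_path):
        p = tmp_path / "model.tsv"
        p.write_text("A\t100.0\t0.0\n")
        with pytest.raises(ValueError, match="sd"):
            load_kmer_table(p)

    def test_derive_adds_k_entries_for_lone_site(self, rng):
        seq = "AUGC" * 10
        sites = make_sites("c", seq, [20])
        bm = build_branch_map("c", seq, sites, k=5)
        table = KmerTable(k=5)
        for j in range(bm.n_slots):
            km = bm.canonical_kmer(j)
            if km not in table:
                table.set(km, float(rng.normal(100, 8)), 1.0)
        n_before = len(table.entries)
        derived = derive_branch_kmers(table, bm)
        assert len(derived.entries) == n_before + 5

    def test_derived_entry_equals_canonical_counterpart(self, tiny_branch_map, rng):
        bm = tiny_branch_map
        table = KmerTable(k=5)
        for j in range(bm.n_slots):
            km = bm.canonical_kmer(j)
            if km not in table:
                table.set(km, float(rng.normal(100, 8)), 1.0)
        derived = derive_branch_kmers(table, bm)
        _, mod_kmers = branch_kmer_sets(bm)
        for kmer in mod_kmers:
            j = next(
                j for j, vs in enumerate(bm.slot_variants) for k2, _ in vs if k2 == kmer
            )
            assert derived[kmer] == derived[bm.canonical_kmer(j)]

    def test_missing_canonical_kmer_rejected(self, tiny_branch_map):
        with pytest.raises(KeyError):
            derive_branch_kmers(KmerTable(k=5), tiny_branch_map)
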