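"""Normalization, forward/backward vs exhaustive enumeration, decode, MEA."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from rnamod._enumerate import enumerate_best_path, enumerate_loglik
from rnamod.model_space import KmerTable, build_branch_map
from rnamod.signal_hmm import (
    AlignmentFailure,
    AlignmentModel,
    EventSequence,
    HmmParams,
    decode_site_probabilities,
    forward_backward,
    load_events_tsv,
    mea_path,
    normalize_events,
    write_events_tsv,
)
from tests.conftest import make_sites, make_table_for


def random_tiny_instance(rng):
    """A random small model (<=3 slots, <=2 variants/slot) + <=4 events."""
    k = int(rng.integers(1, 3))
    n_slots = int(rng.integers(1, 4))
    L = n_slots + k - 1
    seq = "".join(rng.choice(list("ACGU"), size=L))
    sites = []
    if rng.random() < 0.7:
        p = int(rng.integers(1, L + 1))
        sites = make_sites("c", seq, [p])
    bm = build_branch_map("c", seq, sites, k=k)
    table = KmerTable(k=k)
    for variants in bm.slot_variants:
        for kmer, _ in variants:
            if kmer not in table:
                table.set(kmer, float(rng.normal(100, 5)), float(rng.uniform(0.5, 2)))
    model = AlignmentModel.build(bm, table)
    T = int(rng.integers(1, 5))
    events = rng.normal(100, 6, size=T)
    read = EventSequence("r", "c", 1, L, events, normalized=True)
    return model, read


class TestNormalizeEvents:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.seq = "".join(rng.choice(list("ACGU"), size=60))
        self.bm = build_branch_map("c", self.seq, [], k=5)
        self.table = make_table_for(self.bm, rng)

    def test_events_at_model_levels_recover_identity(self):
        levels = [self.table[self.bm.canonical_kmer(j)][0] for j in range(self.bm.n_slots)]
        read = EventSequence("r", "c", 1, 60, np.array(levels))
        shift, scale, _ = normalize_events(read, self.table, self.bm)
        assert abs(shift) < 1e-9
        assert abs(scale - 1.0) < 0.05

    def test_affine_distortion_recovered(self):
        levels = np.array(
            [self.table[self.bm.canonical_kmer(j)][0] for j in range(self.bm.n_slots)]
        )
        read = EventSequence("r", "c", 1, 60, 2.0 * levels + 10.0)
        shift, scale, normalized = normalize_events(read, self.table, self.bm)
        assert abs(shift - 10.0) < 0.5
        assert abs(scale - 2.0) < 0.1
        assert np.allclose(normalized.events, levels)

    def test_constant_events_rejected(self):
        read = EventSequence("r", "c", 1, 60, np.full(20, 100.0))
        with pytest.raises(ValueError, match="zero MAD"):
            normalize_events(read, self.table, self.bm)

    def test_too_few_events_rejected(self):
        read = EventSequence("r", "c", 1, 60, np.arange(5, dtype=float))
        with pytest.raises(ValueError, match=">= 8 events"):
            normalize_events(read, self.table, self.bm)


class TestForwardBackward:
    def test_single_path_k1(self):
        table = KmerTable(k=1)
        table.set("A", 100.0, 1.0)
        bm = build_branch_map("c", "A", [], k=1)
        model = AlignmentModel.build(bm, table)
        read = EventSequence("r", "c", 1, 1, [100.5], normalized=True)
        post = forward_backward(read, model)
        # single event: all mass on slot 0 (match or insert of the only variant)
        assert post.gamma[0].sum() == pytest.approx(1.0)
        assert post.gamma[0, 0] > 0.9  # match state dominates

    def test_likelihood_matches_enumeration(self, rng):
        """Forward likelihood equals exhaustive path enumeration (<=1e-9 log
        units) on random tiny instances with branch variants."""
        worst = 0.0
        for _ in range(60):
            model, read = random_tiny_instance(rng)
            post = forward_backward(read, model)
            ll_ref = enumerate_loglik(model, read.events)
            worst = max(worst, abs(post.loglik - ll_ref))
        assert worst < 1e-9

    def test_gamma_rows_sum_to_one(self, rng):
        for _ in range(10):
            model, read = random_tiny_instance(rng)
            post = forward_backward(read, model)
            assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_far_outlier_event_lowers_loglik(self, rng):
        model, read = random_tiny_instance(rng)
        post = forward_backward(read, model)
        worse = dataclasses.replace(
            read, events=np.append(read.events, 150.0)  # 50 pA beyond every level
        )
        post2 = forward_backward(worse, model)
        assert post2.loglik < post.loglik

    def test_no_admissible_path_is_alignment_failure(self):
        """An event compatible only with a slot strictly behind the current
        position has no admissible (monotone) path: reported as alignment
        failure, not a crash."""
        table = KmerTable(k=1)
        for b, level in (("A", 0.0), ("C", 1000.0), ("G", 2000.0)):
            table.set(b, level, 1e-3)
        bm = build_branch_map("c", "ACG", [], k=1)
        model = AlignmentModel.build(
            bm, table, HmmParams(bg_mean=5000.0, bg_sd=1e-3)
        )
        read = EventSequence("r", "c", 1, 3, [2000.0, 0.0], normalized=True)
        with pytest.raises(AlignmentFailure):
            forward_backward(read, model)


class TestDecode:
    def make_k1_site_model(self, mu_c, sd_c, mu_m, sd_m):
        table = KmerTable(k=1)
        table.set("A", mu_c, sd_c)
        sites = make_sites("c", "A", [1])
        bm = build_branch_map("c", "A", sites, k=1)
        table.set(sites[0].mod_char, mu_m, sd_m)
        return AlignmentModel.build(bm, table)

    @pytest.mark.parametrize("x", [97.0, 100.0, 101.5, 104.0, 110.0])
    def test_single_event_matches_bayes_closed_form(self, x):
        """k=1, one slot, one event: P(mod) equals the two-hypothesis Bayes
        ratio of Gaussian densities to 1e-12."""
        model = self.make_k1_site_model(100.0, 1.0, 103.0, 2.0)
        read = EventSequence("r", "c", 1, 1, [x], normalized=True)
        p = decode_site_probabilities(forward_backward(read, model))[0]
        num = norm.pdf(x, 103.0, 2.0)
        den = num + norm.pdf(x, 100.0, 1.0)
        assert p == pytest.approx(num / den, abs=1e-12)

    def test_identical_gaussians_give_half(self):
        model = self.make_k1_site_model(100.0, 1.0, 100.0, 1.0)
        read = EventSequence("r", "c", 1, 1, [99.2], normalized=True)
        p = decode_site_probabilities(forward_backward(read, model))[0]
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_survives_identical_rescaling(self):
        """Scaling both branch Gaussians identically preserves P(mod) = 0.5."""
        model = self.make_k1_site_model(100.0, 2.5, 100.0, 2.5)
        read = EventSequence("r", "c", 1, 1, [104.0], normalized=True)
        p = decode_site_probabilities(forward_backward(read, model))[0]
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_canonical_read_decodes_low(self, rng):
        """A fully canonical simulated read at 3 pA separation scores
        P(mod) < 0.1 at every site."""
        from rnamod.simulate import SampleSpec, SimConfig, simulate_dataset

        cfg = SimConfig(
            contig_length=140, n_sites=5,
            samples=[SampleSpec("ivt", 8, [np.zeros(5)])],
        )
        ds = simulate_dataset(cfg, 11)
        model_cache = {}
        from rnamod.profiles import call_reads

        matrix = call_reads(
            ds.reads["ivt"], ds.table, ds.branch_map, model_cache=model_cache
        )
        vals = matrix.df.to_numpy()
        vals = vals[~np.isnan(vals)]
        assert (vals < 0.1).mean() > 0.9
        assert vals.max() < 0.5

    def test_decode_invariant_to_affine_transform(self, rng):
        """An affine signal distortion followed by normalization leaves the
        decoded probabilities unchanged (median/MAD are affine-equivariant)."""
        seq = "".join(rng.choice(list("ACGU"), size=40))
        sites = make_sites("c", seq, [20])
        bm = build_branch_map("c", seq, sites, k=5)
        table = make_table_for(bm, rng)
        events = rng.normal(100, 8, size=50)
        read_a = EventSequence("a", "c", 1, 40, events)
        read_b = EventSequence("b", "c", 1, 40, 1.7 * events - 23.0)
        out = []
        for read in (read_a, read_b):
            _, _, nread = normalize_events(read, table, bm)
            model = AlignmentModel.build(bm, table)
            out.append(decode_site_probabilities(forward_backward(nread, model))[19])
        assert out[0] == pytest.approx(out[1], abs=1e-9)


class TestMeaPath:
    def test_one_event_one_slot(self):
        table = KmerTable(k=1)
        table.set("A", 100.0, 1.0)
        bm = build_branch_map("c", "A", [], k=1)
        model = AlignmentModel.build(bm, table)
        read = EventSequence("r", "c", 1, 1, [100.0], normalized=True)
        path = mea_path(forward_backward(read, model))
        assert len(path) == 1
        assert path[0].slot == 0 and not path[0].is_insert

    def test_score_matches_enumeration(self, rng):
        """MEA score equals the brute-force maximum over admissible paths."""
        for _ in range(40):
            model, read = random_tiny_instance(rng)
            post = forward_backward(read, model)
            steps = mea_path(post)
            # recover the state sequence score
            score = 0.0
            for t, step in enumerate(steps):
                s = next(
                    s for s in range(model.n_states)
                    if model.state_slot[s] == step.slot - model.slot0
                    and model.state_kmer[s] == step.kmer
                    and bool(model.is_insert[s]) == step.is_insert
                )
                score += post.gamma[t, s]
            ref_score, _ = enumerate_best_path(model, post.gamma)
            assert score == pytest.approx(ref_score, abs=1e-9)

    def test_monotone_in_events_and_slots(self, rng):
        for _ in range(10):
            model, read = random_tiny_instance(rng)
            steps = mea_path(forward_backward(read, model))
            slots = [s.slot for s in steps]
            assert slots == sorted(slots)

    def test_exact_tie_prefers_leftmost_slot(self):
        """Two identical slots and a uniform posterior: the path stays on the
        leftmost slot, reproducibly."""
        table = KmerTable(k=1)
        for b in "AC":
            table.set(b, 100.0, 1.0)
        bm = build_branch_map("c", "AC", [], k=1)
        model = AlignmentModel.build(bm, table)
        read = EventSequence("r", "c", 1, 2, [100.0], normalized=True)
        for _ in range(3):
            path = mea_path(forward_backward(read, model))
            assert path[0].slot == 0


class TestEventsRoundTrip:
    def test_tsv_roundtrip_preserves_orientation(self, tmp_path, rng):
        reads = [
            EventSequence("r1", "c", 1, 40, rng.normal(100, 5, 30), sequenced_3p5p=True),
            EventSequence("r2", "c", 5, 40, rng.normal(100, 5, 20), sequenced_3p5p=False),
        ]
        path = tmp_path / "events.tsv"
        write_events_tsv(reads, path)
        back = load_events_tsv(path)
        assert [r.read_id for r in back] == ["r1", "r2"]
        for orig, rt in zip(reads, back):
            assert np.allclose(orig.events, rt.events)
            assert (orig.start, orig.end) == (rt.start, rt.end)
            assert orig.sequenced_3p5p == rt.sequenced_3p5p
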