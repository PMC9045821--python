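"""Ward clustering of profiles, cluster fractions, event-mean validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rnamod.clustering import (
    cluster_fractions,
    cluster_profiles,
    event_mean_matrix,
    events_per_kmer,
)
from rnamod.profiles import ModProfileMatrix
from rnamod.simulate import SampleSpec, SimConfig, simulate_profile_matrix


def matrix_of(arr, samples="s"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    idx = pd.Index([f"r{i}" for i in range(arr.shape[0])], name="read_id")
    cols = [f"c:{20 + 5 * j}" for j in range(arr.shape[1])]
    if isinstance(samples, str):
        samples = [samples] * arr.shape[0]
    return ModProfileMatrix(
        df=pd.DataFrame(arr, index=idx, columns=cols),
        samples=pd.Series(samples, index=idx),
    )


def brute_force_ward(X):
    """O(n^3) Lance-Williams agglomeration with Ward's update, as an
    independent oracle for linkage heights."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    d2 = {}  # squared cluster distances
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), best = min(
            ((k, v) for k, v in d2.items() if k[0] in active and k[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        merges.append(np.sqrt(best))
        na, nb = sizes[a], sizes[b]
        for c in list(active - {a, b}):
            nc = sizes[c]
            dac = d2[tuple(sorted((a, c)))]
            dbc = d2[tuple(sorted((b, c)))]
            dab = d2[(a, b)]
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / (na + nb + nc)
            d2[tuple(sorted((next_id, c)))] = new
        sizes[next_id] = na + nb
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return np.array(merges)


@pytest.fixture
def planted_two_pop(rng):
    """200 reads, 10 sites, two templates flipped at every site, noise 0.1."""
    t1 = np.concatenate([np.ones(5), np.zeros(5)])
    t2 = 1 - t1
    reads = []
    labels = []
    for i in range(200):
        t = t1 if i < 100 else t2
        reads.append(np.clip(t + rng.normal(0, 0.1, 10), 0, 1))
        labels.append(i < 100)
    return matrix_of(reads), np.array(labels)


class TestClusterProfiles:
    def test_planted_two_populations_recovered(self, planted_two_pop):
        matrix, labels = planted_two_pop
        dendro = cluster_profiles(matrix)
        members = dendro.cut(2)
        assert adjusted_rand_score(labels, members.to_numpy()) >= 0.95

    def test_identical_reads_merge_at_height_zero(self):
        matrix = matrix_of(np.tile([0.2, 0.8, 0.5], (6, 1)))
        dendro = cluster_profiles(matrix)
        assert np.allclose(dendro.linkage[:, 2], 0.0)

    def test_row_shuffle_gives_identical_partitions(self, planted_two_pop, rng):
        matrix, _ = planted_two_pop
        dendro = cluster_profiles(matrix)
        perm = rng.permutation(matrix.df.index)
        shuffled = matrix.subset(pd.Index(perm, name="read_id"))
        dendro2 = cluster_profiles(shuffled)
        for n in (2, 3, 5):
            a = dendro.cut(n)
            b = dendro2.cut(n).reindex(a.index)
            assert adjusted_rand_score(a.to_numpy(), b.to_numpy()) == 1.0

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(matrix_of([[0.5, 0.5]]))

    def test_ward_heights_match_brute_force_oracle(self, rng):
        X = rng.random((12, 4))
        dendro = cluster_profiles(matrix_of(X))
        oracle = brute_force_ward(X)
        assert np.allclose(np.sort(dendro.linkage[:, 2]), np.sort(oracle), atol=1e-8)


class TestClusterFractions:
    def test_forty_sixty_split(self, rng):
        arr = np.vstack([
            np.tile([0.0, 0.0], (40, 1)) + rng.normal(0, 0.01, (40, 2)),
            np.tile([1.0, 1.0], (60, 1)) + rng.normal(0, 0.01, (60, 2)),
        ])
        matrix = matrix_of(arr)
        dendro = cluster_profiles(matrix)
        fr = cluster_fractions(dendro, 2, matrix.samples)
        assert sorted(fr.loc["s"].tolist()) == pytest.approx([0.4, 0.6])

    def test_singletons_at_n_equals_leaves(self, rng):
        matrix = matrix_of(rng.random((8, 3)))
        dendro = cluster_profiles(matrix)
        fr = cluster_fractions(dendro, 8, matrix.samples)
        assert np.allclose(fr.to_numpy(), 1 / 8)

    def test_fractions_sum_to_one_for_every_n(self, rng):
        matrix = matrix_of(rng.random((20, 3)),
                           samples=["a"] * 10 + ["b"] * 10)
        dendro = cluster_profiles(matrix)
        for n in range(1, 10):
            fr = cluster_fractions(dendro, n, matrix.samples)
            assert np.allclose(fr.sum(axis=1), 1.0)

    def test_pooled_mixture_concentrates_per_sample(self, rng):
        """Four equal planted groups pooled (the mixture-experiment design):
        at N=4 each sample concentrates >= 0.9 in its own cluster."""
        templates = np.eye(4)
        samples = [
            SampleSpec(f"ko{i}", 60, [np.repeat(templates[i], 2)]) for i in range(4)
        ]
        cfg = SimConfig(n_sites=8, samples=samples, beta_mod=(30, 2), beta_can=(2, 30))
        matrix, _ = simulate_profile_matrix(cfg, 5)
        dendro = cluster_profiles(matrix)
        fr = cluster_fractions(dendro, 4, matrix.samples)
        assert (fr.max(axis=1) >= 0.9).all()


class TestEventMeanMatrix:
    @pytest.fixture(scope="class")
    def posteriors(self):
        from rnamod.signal_hmm import (
            AlignmentModel,
            forward_backward,
            normalize_events,
            refit_normalization,
        )
        from rnamod.simulate import simulate_dataset

        cfg = SimConfig(
            contig_length=160, n_sites=3, full_length_fraction=1.0,
            samples=[SampleSpec("wt", 60, [np.ones(3)]),
                     SampleSpec("ivt", 60, [np.zeros(3)])],
        )
        ds = simulate_dataset(cfg, 9)
        model = AlignmentModel.build(ds.branch_map, ds.table)
        posts = []
        for name in ("wt", "ivt"):
            for r in ds.reads[name]:
                _, _, nr = normalize_events(r, ds.table, ds.branch_map)
                post = forward_backward(nr, model)
                _, _, nr = refit_normalization(nr, post)
                posts.append(forward_backward(nr, model))
        return ds, posts

    def test_columns_standardized(self, posteriors):
        ds, posts = posteriors
        emm = event_mean_matrix(posts, region=(40, 60))
        assert np.allclose(emm.df.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(emm.df.std(axis=0, ddof=0), 1.0, atol=1e-6)

    def test_planted_signal_classes_separate(self, posteriors):
        """Modified vs canonical reads differ by +3 sigma at the site-covering
        slots: the N=2 cut of the event-mean dendrogram recovers the classes.
        Reads are already model-normalized, so the per-read z is skipped."""
        ds, posts = posteriors
        site = ds.sites[1].pos0
        emm = event_mean_matrix(
            posts, region=(site - 4, site + 1), read_standardize=False
        )
        members = emm.dendrogram.cut(2)
        labels = [i.startswith("wt") for i in members.index]
        assert adjusted_rand_score(labels, members.to_numpy()) >= 0.95

    def test_read_skipping_a_slot_excluded(self, posteriors):
        ds, posts = posteriors
        emm = event_mean_matrix(posts, region=(40, 60))
        # reads in the matrix cover every slot; excluded reads skipped one
        from rnamod.clustering import mea_path
        included = set(emm.df.index)
        for post in posts:
            covered = {
                s.slot for s in mea_path(post) if not s.is_insert and 40 <= s.slot < 60
            }
            assert (post.read.read_id in included) == (len(covered) == 20)


class TestEventsPerKmer:
    @pytest.fixture(scope="class")
    def kmer_posts(self):
        from rnamod.signal_hmm import AlignmentModel, forward_backward, normalize_events
        from rnamod.simulate import simulate_dataset

        cfg = SimConfig(
            contig_length=100, n_sites=2, full_length_fraction=1.0,
            samples=[SampleSpec("ivt", 40, [np.zeros(2)])],
        )
        ds = simulate_dataset(cfg, 21)
        model = AlignmentModel.build(ds.branch_map.forced("canonical"), ds.table)
        posts = []
        for r in ds.reads["ivt"]:
            _, _, nr = normalize_events(r, ds.table, ds.branch_map)
            posts.append(forward_backward(nr, model))
        return ds, posts

    def test_sample_mean_matches_model(self, kmer_posts):
        ds, posts = kmer_posts
        kmer = ds.branch_map.canonical_kmer(50)
        sample = events_per_kmer(posts, kmer, min_prob=0.5)
        assert len(sample) > 20
        mu, sd = ds.table[kmer]
        assert abs(sample.mean() - mu) < 3 * sd / np.sqrt(len(sample)) + 0.3

    def test_absent_kmer_gives_empty_sample(self, kmer_posts):
        _, posts = kmer_posts
        assert len(events_per_kmer(posts, "XXXXX")) == 0

    def test_threshold_monotonicity(self, kmer_posts):
        ds, posts = kmer_posts
        kmer = ds.branch_map.canonical_kmer(50)
        sizes = [len(events_per_kmer(posts, kmer, min_prob=p)) for p in (0.9, 0.5, 0.0)]
        assert sizes == sorted(sizes)
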