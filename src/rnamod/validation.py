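"""Synthetic validation experiments with planted ground truth.

Each function runs one end-to-end check of the package against an independent
reference -- exhaustive path enumeration for the HMM, closed forms for the
decoders and tests, planted-truth simulations for training, calling,
statistics, clustering and site detection -- and returns the measured
quantities as a flat dict.  The test suite asserts on these; the
reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ._enumerate import enumerate_best_path, enumerate_loglik
from .clustering import cluster_profiles
from .model_space import KmerTable, ModificationSite, assign_mod_chars, branch_kmer_sets, build_branch_map
from .modstats import (
    empirical_browns,
    fisher_z_test,
    fishers_method,
    frequency_change_test,
    pairwise_spearman,
)
from .profiles import ModProfileMatrix, call_reads, classification_metrics
from .signal_hmm import (
    AlignmentModel,
    EventSequence,
    decode_site_probabilities,
    forward_backward,
    mea_path,
)
from .simulate import SampleSpec, SimConfig, simulate_dataset, simulate_profile_matrix
from .site_detect import detection_auroc, position_dstats, windowed_dstat
from .training import TrainingConfig, train_emissions


# -- HMM vs exhaustive enumeration -------------------------------------------

def _random_tiny_instance(rng: np.random.Generator):
    k = int(rng.integers(1, 3))
    n_slots = int(rng.integers(1, 4))
    L = n_slots + k - 1
    seq = "".join(rng.choice(list("ACGU"), size=L))
    sites = []
    if rng.random() < 0.7:
        p = int(rng.integers(1, L + 1))
        sites = [ModificationSite("c", p, seq[p - 1], "Y", callable=True)]
        sites, _ = assign_mod_chars(sites)
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


def hmm_enumeration_check(seed: int, n_instances: int = 100) -> dict:
    """Forward likelihood and MEA score vs literal path enumeration on random
    small instances (<=4 events, <=3 slots, <=2 variants/slot)."""
    rng = np.random.default_rng(seed)
    worst_ll = 0.0
    worst_mea = 0.0
    for _ in range(n_instances):
        model, read = _random_tiny_instance(rng)
        post = forward_backward(read, model)
        worst_ll = max(worst_ll, abs(post.loglik - enumerate_loglik(model, read.events)))
        steps = mea_path(post)
        state_of = {
            (int(model.state_slot[s]), model.state_kmer[s], bool(model.is_insert[s])): s
            for s in range(model.n_states)
        }
        score = sum(
            post.gamma[t, state_of[(st.slot - model.slot0, st.kmer, st.is_insert)]]
            for t, st in enumerate(steps)
        )
        ref_score, _ = enumerate_best_path(model, post.gamma)
        worst_mea = max(worst_mea, abs(score - ref_score))
    return {
        "hmm_loglik_max_abs_error": worst_ll,
        "mea_score_max_abs_error": worst_mea,
        "n_instances": n_instances,
    }


def decode_closed_form_check() -> dict:
    """Single-slot k=1 decode vs the two-hypothesis Bayes ratio."""
    table = KmerTable(k=1)
    table.set("A", 100.0, 1.0)
    sites = [ModificationSite("c", 1, "A", "Y", callable=True)]
    sites, _ = assign_mod_chars(sites)
    bm = build_branch_map("c", "A", sites, k=1)
    table.set(sites[0].mod_char, 103.0, 2.0)
    model = AlignmentModel.build(bm, table)
    worst = 0.0
    for x in np.linspace(95.0, 110.0, 31):
        read = EventSequence("r", "c", 1, 1, [x], normalized=True)
        p = decode_site_probabilities(forward_backward(read, model))[0]
        num = stats.norm.pdf(x, 103.0, 2.0)
        ref = num / (num + stats.norm.pdf(x, 100.0, 1.0))
        worst = max(worst, abs(p - ref))
    return {"decode_bayes_max_abs_error": worst}


# -- supervised training recovery --------------------------------------------

def training_recovery(
    seed: int, reads_per_class: int = 500, rounds: int = 30
) -> dict:
    """Train from wild-type-like vs IVT-like reads under the generator's
    default conditions and measure recovery of the planted +3 pA shift."""
    cfg = SimConfig(
        samples=[
            SampleSpec("wt", reads_per_class, [np.ones(12)]),
            SampleSpec("ivt", reads_per_class, [np.zeros(12)]),
        ]
    )
    ds = simulate_dataset(cfg, seed)
    trained, diagnostics = train_emissions(
        ds.reads["wt"], ds.reads["ivt"], ds.table, ds.branch_map,
        TrainingConfig(rounds=rounds, reads_per_class=reads_per_class),
    )
    _, mod_kmers = branch_kmer_sets(ds.branch_map)
    errors = np.array([trained[k][0] - ds.table[k][0] for k in sorted(mod_kmers)])
    return {
        "training_max_abs_mean_error_pa": float(np.abs(errors).max()),
        "training_median_abs_mean_error_pa": float(np.median(np.abs(errors))),
        "n_modified_kmers": len(mod_kmers),
        "final_round_max_delta_pa": diagnostics[-1].max_abs_delta if diagnostics else 0.0,
    }


# -- calling calibration ------------------------------------------------------

def calling_validation(seed: int, n_reads: int = 150) -> dict:
    """Call model-generated reads with the generating model and compare the
    decoded probabilities with the planted per-site states."""
    cfg = SimConfig(
        samples=[SampleSpec("mix", n_reads, [np.full(12, 0.5)])],
    )
    ds = simulate_dataset(cfg, seed)
    matrix = call_reads(ds.reads["mix"], ds.table, ds.branch_map, sample="mix")
    probs, labels = [], []
    for col in matrix.df.columns:
        pos = int(col.rsplit(":", 1)[1])
        joined = pd.concat(
            [matrix.df[col], ds.states[pos]], axis=1, join="inner"
        ).dropna()
        probs.append(joined.iloc[:, 0].to_numpy())
        labels.append(joined.iloc[:, 1].to_numpy())
    bundle = classification_metrics(np.concatenate(probs), np.concatenate(labels))
    cal = bundle.calibration.dropna()
    # expected calibration error: per-bin |predicted - empirical| weighted by
    # bin occupancy (an unweighted mean over near-empty bins is binomial noise)
    cal_err = float(
        ((cal["mean_predicted"] - cal["empirical_fraction"]).abs() * cal["n"]).sum()
        / cal["n"].sum()
    )
    return {
        "calling_auroc": bundle.auroc,
        "calling_mean_calibration_error": cal_err,
        "calling_balanced_accuracy": bundle.balanced_accuracy,
        "n_cells": int(sum(len(p) for p in probs)),
    }


# -- statistics calibration ---------------------------------------------------

def _binary_matrix(rng, n_reads, n_sites, freq, sample="s", prefix="r") -> ModProfileMatrix:
    arr = (rng.random((n_reads, n_sites)) < freq).astype(float)
    idx = pd.Index([f"{prefix}{i}" for i in range(n_reads)], name="read_id")
    cols = [f"c:{20 + 3 * j}" for j in range(n_sites)]
    return ModProfileMatrix(
        df=pd.DataFrame(arr, index=idx, columns=cols),
        samples=pd.Series(sample, index=idx),
    )


def statistics_validation(seed: int, n_null_sites: int = 500) -> dict:
    rng = np.random.default_rng(seed)
    # frequency-change null: experiment drawn from the wild-type generator
    wt = [_binary_matrix(rng, 400, n_null_sites, 0.7) for _ in range(3)]
    ex = [_binary_matrix(rng, 400, n_null_sites, 0.7)]
    results = frequency_change_test(ex, wt)
    flag_rate = float(np.mean([r.passes_q for r in results]))

    # Spearman type-I on independent uniforms
    idx = pd.Index([f"r{i}" for i in range(500)], name="read_id")
    m = ModProfileMatrix(
        df=pd.DataFrame(
            rng.random((500, 20)), index=idx,
            columns=[f"c:{20 + 3 * j}" for j in range(20)],
        ),
        samples=pd.Series("s", index=idx),
    )
    pairs = pairwise_spearman(m)
    spearman_rate = float(np.mean([r.p < 0.05 for r in pairs]))

    # Fisher z closed form
    _, fisher_p = fisher_z_test(0.5, 103, 0.0, 103)

    # Empirical Brown's: independence and duplication limits
    ratios, dofs = [], []
    for _ in range(30):
        data = rng.random((2000, 5))
        ps = rng.uniform(0.001, 0.5, size=5)
        res = empirical_browns(ps, data)
        dofs.append(res.dof)
        ratios.append(res.p / fishers_method(ps))
    x = rng.random(2000)
    dup = empirical_browns([0.02, 0.02], np.column_stack([x, x]))
    return {
        "freq_change_null_flag_rate": flag_rate,
        "freq_change_null_bound": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / n_null_sites)),
        "spearman_null_type1_rate": spearman_rate,
        "fisher_z_closed_form_p": float(fisher_p),
        "ebm_independent_mean_dof": float(np.mean(dofs)),
        "ebm_independent_worst_fisher_ratio": float(
            max(max(ratios), 1.0 / min(ratios))
        ),
        "ebm_duplicated_dof": float(dup.dof),
        "n_pairs": len(pairs),
    }


# -- clustering recovery ------------------------------------------------------

def brute_force_ward_heights(X: np.ndarray) -> np.ndarray:
    """O(n^3) Lance-Williams agglomeration with Ward's update (reference)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    d2 = {}
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
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * d2[(a, b)]) / (na + nb + nc)
            d2[tuple(sorted((next_id, c)))] = new
        sizes[next_id] = na + nb
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return np.array(merges)


def clustering_validation(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    # planted two-population profile design (template flip, noise 0.1)
    t1 = np.concatenate([np.ones(5), np.zeros(5)])
    reads = np.clip(
        np.vstack([np.tile(t1, (100, 1)), np.tile(1 - t1, (100, 1))])
        + rng.normal(0, 0.1, (200, 10)),
        0, 1,
    )
    idx = pd.Index([f"r{i}" for i in range(200)], name="read_id")
    matrix = ModProfileMatrix(
        df=pd.DataFrame(reads, index=idx,
                        columns=[f"c:{20 + 3 * j}" for j in range(10)]),
        samples=pd.Series("s", index=idx),
    )
    labels2 = np.array([0] * 100 + [1] * 100)
    ari2 = adjusted_rand_score(labels2, cluster_profiles(matrix).cut(2).to_numpy())

    # planted four-subpopulation mixture via the profile generator
    templates = [np.repeat(row, 2) for row in np.eye(4)]
    cfg = SimConfig(
        n_sites=8,
        samples=[SampleSpec("mix", 240, templates, weights=[0.25] * 4)],
    )
    pmatrix, truth = simulate_profile_matrix(cfg, seed)
    ari4 = adjusted_rand_score(
        truth["subpop"].to_numpy(), cluster_profiles(pmatrix).cut(4).to_numpy()
    )

    # Ward linkage vs the Lance-Williams reference on 12 rows
    X = rng.random((12, 4))
    idx = pd.Index([f"w{i}" for i in range(12)], name="read_id")
    m12 = ModProfileMatrix(
        df=pd.DataFrame(X, index=idx, columns=[f"c:{20 + 3 * j}" for j in range(4)]),
        samples=pd.Series("s", index=idx),
    )
    heights = np.sort(cluster_profiles(m12).linkage[:, 2])
    ref = np.sort(brute_force_ward_heights(X))
    return {
        "clustering_two_pop_ari": float(ari2),
        "clustering_four_pop_ari": float(ari4),
        "ward_height_max_abs_error": float(np.abs(heights - ref).max()),
    }


# -- site detection -----------------------------------------------------------

def _synthetic_track(rng, length=120, n_mods=8, shift=3.0):
    labels = np.zeros(length, dtype=int)
    positions = np.arange(10, length - 10, (length - 20) // n_mods)[:n_mods]
    labels[positions] = 1
    a = {i: rng.normal(0, 1, 150) for i in range(length)}
    b = {}
    for i in range(length):
        mu = 0.0
        for p in positions:
            if abs(i - p) <= 2:
                mu = max(mu, shift * (1 - 0.35 * abs(i - p)))
        b[i] = rng.normal(mu, 1, 150)
    return windowed_dstat(position_dstats(a, b, length)), labels


def site_detection_validation(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    w, labels = _synthetic_track(rng)
    per_pos = detection_auroc(w, labels, "per_position")
    peak = detection_auroc(w, labels, "window_peak")

    wr = rng.random(400)
    lr = np.zeros(400, dtype=int)
    lr[rng.choice(400, 40, replace=False)] = 1
    permuted = detection_auroc(wr, lr, "per_position")

    we = rng.random(100)
    le = np.zeros(100, dtype=int)
    le[[10, 30, 50, 70, 90]] = 1
    excl = detection_auroc(we, le, "window_peak", window=5, flank_exclusion=2)
    return {
        "sitedetect_per_position_auroc": per_pos.auroc,
        "sitedetect_window_peak_auroc": peak.auroc,
        "sitedetect_permuted_auroc": permuted.auroc,
        "sitedetect_excluded_classified_count": excl.n_classified,
        "sitedetect_excluded_classified_expected": 100 - 4 * 5,
    }


def annotation_fixture_counts() -> dict:
    from .fixtures import yeast_annotation

    sites, _ = yeast_annotation()
    return {
        "annotation_sites_total": len(sites),
        "annotation_sites_18s": sum(s.contig == "18S" for s in sites),
        "annotation_sites_25s": sum(s.contig == "25S" for s in sites),
    }
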