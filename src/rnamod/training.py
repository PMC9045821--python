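"""Supervised iterative estimation of modified/canonical emission Gaussians.

Labels are per-dataset, not per-position: every annotated site of a
"modified" read set (wild-type-like) is treated as modified, every site of a
"canonical" set (IVT-like) as unmodified.  Each round aligns every read with
its labels fixed (no branch ambiguity), pools event means per kmer from the
alignment posteriors, and re-estimates mean = median and sd = MAD of the pool
for every kmer touching a modification branch point.  Kmers outside branch
points keep their default Gaussians.

Pooling is posterior-weighted by default: each event contributes to a kmer's
pool with its posterior occupancy, and medians/MADs are weighted.  Hard
assignment along the maximum-expected-accuracy path is available
(``pooling="mea"``) but systematically biased for kmers whose neighbouring
slot has a nearly equal level -- the path must attribute shared boundary
events to one side, and the transition preferences censor a kmer's pool
asymmetrically; soft weighting splits exactly those events.

The sd estimator is the raw (unscaled) MAD by default; the
Gaussian-consistent scaling (x1.4826) is an opt-in flag because raw MAD
materially narrows the emission Gaussians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_space import BranchMap, KmerTable, branch_kmer_sets
from .signal_hmm import (
    AlignmentFailure,
    AlignmentModel,
    EventSequence,
    HmmParams,
    forward_backward,
    mea_path,
    normalize_events,
    refit_normalization,
)

log = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826


@dataclass
class TrainingConfig:
    rounds: int = 30
    reads_per_class: int = 500
    mad_scaling: str = "raw"        # raw | consistent
    pooling: str = "posterior"      # posterior | mea
    min_pool: float = 10            # effective events; below this, carry forward
    seed: int = 0                   # reserved; training itself is deterministic

    def __post_init__(self):
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.reads_per_class < 1:
            raise ValueError("reads_per_class must be >= 1")
        if self.mad_scaling not in ("raw", "consistent"):
            raise ValueError("mad_scaling must be 'raw' or 'consistent'")
        if self.pooling not in ("posterior", "mea"):
            raise ValueError("pooling must be 'posterior' or 'mea'")


@dataclass
class RoundDiagnostics:
    round: int
    pool_sizes: dict[str, int]
    mean_deltas: dict[str, float]

    @property
    def max_abs_delta(self) -> float:
        return max((abs(d) for d in self.mean_deltas.values()), default=0.0)


def weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    c = np.cumsum(w)
    return float(x[np.searchsorted(c, 0.5 * c[-1])])


def weighted_mad(x: np.ndarray, w: np.ndarray, center: float) -> float:
    return weighted_median(np.abs(x - center), w)


#: events with posterior mass below this are not pooled (mass this small
#: carries no information and would bloat the pools)
MIN_POOL_WEIGHT = 0.01


def _pool_events(
    reads: Sequence[EventSequence],
    forced_map: BranchMap,
    table: KmerTable,
    params: HmmParams,
    pools: dict[str, tuple[list[float], list[float]]],
    pooling: str,
) -> None:
    cache: dict[tuple[int, int], AlignmentModel] = {}
    kmer_states_cache: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for read in reads:
        window = (read.start - 1, read.end)
        model = cache.get(window)
        if model is None:
            model = AlignmentModel.build(forced_map, table, params, window)
            cache[window] = model
            groups: dict[str, list[int]] = {}
            for s in range(model.n_states):
                if not model.is_insert[s]:
                    groups.setdefault(model.state_kmer[s], []).append(s)
            kmer_states_cache[window] = {
                k: np.asarray(v) for k, v in groups.items()
            }
        try:
            post = forward_backward(read, model)
        except AlignmentFailure as exc:
            log.warning("training: %s", exc)
            continue
        if pooling == "posterior":
            for kmer, idx in kmer_states_cache[window].items():
                w = post.gamma[:, idx].sum(axis=1)
                sel = w > MIN_POOL_WEIGHT
                if not sel.any():
                    continue
                xs, ws = pools.setdefault(kmer, ([], []))
                xs.extend(read.events[sel])
                ws.extend(w[sel])
        else:  # hard assignment along the MEA path
            for step in mea_path(post):
                if step.is_insert:
                    continue
                xs, ws = pools.setdefault(step.kmer, ([], []))
                xs.append(float(read.events[step.event_index]))
                ws.append(1.0)


def _refit_reads(
    reads: Sequence[EventSequence],
    forced_map: BranchMap,
    table: KmerTable,
    params: HmmParams,
) -> list[EventSequence]:
    cache: dict[tuple[int, int], AlignmentModel] = {}
    out = []
    for read in reads:
        window = (read.start - 1, read.end)
        model = cache.get(window)
        if model is None:
            model = AlignmentModel.build(forced_map, table, params, window)
            cache[window] = model
        try:
            post = forward_backward(read, model)
        except AlignmentFailure:
            out.append(read)
            continue
        _, _, refit = refit_normalization(read, post)
        out.append(refit)
    return out


def train_emissions(
    modified_reads: Sequence[EventSequence],
    canonical_reads: Sequence[EventSequence],
    table: KmerTable,
    branch_map: BranchMap,
    cfg: TrainingConfig | None = None,
    params: HmmParams | None = None,
) -> tuple[KmerTable, list[RoundDiagnostics]]:
    """Iteratively re-estimate branch-point kmer Gaussians from labeled reads.

    Modified reads are aligned with the modified character forced at every
    callable site, canonical reads with canonical characters; only kmers
    touching a branch point are updated.  A branch kmer whose event pool in a
    round is smaller than ``min_pool`` keeps its previous parameters (logged).
    Deterministic given fixed read order.
    """
    cfg = cfg or TrainingConfig()
    params = params or HmmParams()
    trained = table.copy()
    canon_branch, mod_branch = branch_kmer_sets(branch_map)
    trainable = canon_branch | mod_branch
    mod_map = branch_map.forced("modified")
    can_map = branch_map.forced("canonical")

    mod_reads = list(modified_reads)[: cfg.reads_per_class]
    can_reads = list(canonical_reads)[: cfg.reads_per_class]

    def prep(reads: Sequence[EventSequence]) -> list[EventSequence]:
        out = []
        for r in reads:
            if not r.normalized:
                _, _, r = normalize_events(r, table, branch_map)
            out.append(r)
        return out

    # Normalize once against the initial canonical levels, then refine each
    # read's affine fit from a first labelled alignment; the fit does not
    # chase the moving branch-point parameters across rounds.
    mod_reads = _refit_reads(prep(mod_reads), mod_map, trained, params)
    can_reads = _refit_reads(prep(can_reads), can_map, trained, params)

    diagnostics: list[RoundDiagnostics] = []
    for rnd in range(cfg.rounds):
        pools: dict[str, tuple[list[float], list[float]]] = {}
        _pool_events(mod_reads, mod_map, trained, params, pools, cfg.pooling)
        _pool_events(can_reads, can_map, trained, params, pools, cfg.pooling)
        sizes: dict[str, int] = {}
        deltas: dict[str, float] = {}
        for kmer in sorted(trainable):
            xs, ws = pools.get(kmer, ([], []))
            x, w = np.asarray(xs), np.asarray(ws)
            n_eff = float(w.sum())
            sizes[kmer] = int(round(n_eff))
            if n_eff < cfg.min_pool:
                log.warning(
                    "round %d: kmer %s has %.1f effective events (< %s); "
                    "keeping previous parameters",
                    rnd, kmer, n_eff, cfg.min_pool,
                )
                deltas[kmer] = 0.0
                continue
            med = weighted_median(x, w)
            mad = weighted_mad(x, w, med)
            if cfg.mad_scaling == "consistent":
                mad *= MAD_CONSISTENCY
            if mad <= 0.0:
                log.warning("round %d: kmer %s has zero MAD; keeping previous sd", rnd, kmer)
                mad = trained[kmer][1]
            deltas[kmer] = med - trained[kmer][0]
            trained.set(kmer, med, mad, source="trained")
        diagnostics.append(RoundDiagnostics(round=rnd, pool_sizes=sizes, mean_deltas=deltas))
    return trained, diagnostics
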