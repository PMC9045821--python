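"""Signal-to-reference alignment with a variable-order kmer HMM.

A read is an ordered sequence of segmented nanopore events (mean current, pA).
The HMM walks the reference kmer slots 5'->3'; at slots covering annotated
modification sites it branches over variant kmers (canonical vs modified
character per site).  The variable-order construction ties overlapping slots
together: a transition between slots is admissible only when the two variants
agree on every shared site, so the mass over variants is generated by a single
per-site character choice along each path rather than independent per-slot
choices.

States come in pairs per (slot, variant): a Match state emitting from the
variant kmer's Gaussian and an Insert state emitting from a broad background
Gaussian (spurious events).  Stays re-emit from the same kmer; skips jump a
slot.  Posterior decoding marginalizes the per-event state occupancies into a
per-site modification probability; the maximum-expected-accuracy (MEA) path is
the admissible monotone path maximizing summed posterior mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model_space import BranchMap, KmerTable


class AlignmentFailure(RuntimeError):
    """No admissible path with positive mass (likelihood underflow)."""


@dataclass
class EventSequence:
    """Ordered per-read events mapped to a reference interval.

    ``start``/``end`` are 1-based inclusive reference coordinates.  ``events``
    is stored in reference 5'->3' order regardless of sequencing direction;
    ``sequenced_3p5p`` records that the molecule traversed the pore 3'->5' (the
    nanopore RNA convention), which only affects on-disk ordering.
    """

    read_id: str
    contig: str
    start: int
    end: int
    events: np.ndarray
    spreads: np.ndarray | None = None
    durations: np.ndarray | None = None
    sequenced_3p5p: bool = True
    shift: float = 0.0
    scale: float = 1.0
    normalized: bool = False

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1 or self.events.size < 1:
            raise ValueError("events must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("event means must be finite")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad mapped interval [{self.start}, {self.end}]")

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    def is_full_length(self, dead_zone: int = 15) -> bool:
        """True when the mapping covers the contig 5' terminus (first bases)."""
        return self.start <= dead_zone


@dataclass
class HmmParams:
    """Fixed transition set and background emission of the aligner.

    Transitions are not re-estimated; training touches emission Gaussians only.
    ``stay`` re-emits the current kmer, ``step`` advances one slot, ``skip``
    jumps over one slot, ``insert`` emits a background event.  At reference
    edges the unavailable moves are renormalized away.
    """

    p_stay: float = 0.3
    p_step: float = 0.55
    p_skip: float = 0.1
    p_insert: float = 0.05
    bg_mean: float | None = None   # default: mean of canonical levels in window
    bg_sd: float | None = None     # default: 3x the sd of those levels

    def __post_init__(self):
        probs = (self.p_stay, self.p_step, self.p_skip, self.p_insert)
        if any(not 0.0 < p < 1.0 for p in probs):
            raise ValueError("transition probabilities must be in (0, 1)")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("stay + step + skip + insert must sum to 1")


def normalize_events(
    read: EventSequence,
    table: KmerTable,
    branch_map: BranchMap,
) -> tuple[float, float, EventSequence]:
    """Per-read affine signal normalization against the canonical model.

    Chooses shift (pA) and scale so that the median and MAD of the read's
    event means match the median and MAD of the canonical model levels of the
    mapped slots: ``normalized = (mean - shift) / scale``.
    """
    if read.n_events < 8:
        raise ValueError(f"read {read.read_id}: need >= 8 events to normalize")
    x = read.events
    med_x = float(np.median(x))
    mad_x = float(np.median(np.abs(x - med_x)))
    if mad_x == 0.0:
        raise ValueError(f"read {read.read_id}: constant event means (zero MAD)")
    k = branch_map.k
    j0, j1 = read.start - 1, read.end - k + 1
    if j1 <= j0:
        raise ValueError(f"read {read.read_id}: mapped interval shorter than k")
    levels = np.array(
        [table[branch_map.canonical_kmer(j)][0] for j in range(j0, j1)]
    )
    med_l = float(np.median(levels))
    mad_l = float(np.median(np.abs(levels - med_l)))
    if mad_l == 0.0:
        raise ValueError(f"{branch_map.contig}: degenerate model levels (zero MAD)")
    scale = mad_x / mad_l
    shift = med_x - scale * med_l
    out = replace(read, events=(x - shift) / scale, shift=shift, scale=scale,
                  normalized=True)
    return shift, scale, out


@dataclass
class AlignmentModel:
    """Flattened state space of one read window over a branch map.

    States are ordered by (slot, variant, match-before-insert), which is the
    tie-break order of the MEA path.  ``site_states`` maps each branchable
    site (0-based reference position) to the covering state indices and their
    modified flags.
    """

    branch_map: BranchMap
    table: KmerTable
    params: HmmParams
    window: tuple[int, int]           # 0-based half-open reference interval
    n_states: int = 0
    state_slot: np.ndarray = None     # local slot index per state
    state_kmer: list[str] = None
    is_insert: np.ndarray = None
    mu: np.ndarray = None
    sd: np.ndarray = None
    log_init: np.ndarray = None
    edge_src: np.ndarray = None
    edge_dst: np.ndarray = None
    edge_p: np.ndarray = None
    site_states: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    bg_mu: float = 0.0
    bg_sd: float = 1.0

    @property
    def n_slots(self) -> int:
        k = self.branch_map.k
        return self.window[1] - self.window[0] - k + 1

    @property
    def slot0(self) -> int:
        return self.window[0]

    @classmethod
    def build(
        cls,
        branch_map: BranchMap,
        table: KmerTable,
        params: HmmParams | None = None,
        window: tuple[int, int] | None = None,
    ) -> "AlignmentModel":
        params = params or HmmParams()
        k = branch_map.k
        if window is None:
            window = (0, len(branch_map.seq))
        w0, w1 = window
        n_slots = w1 - w0 - k + 1
        if n_slots < 1:
            raise ValueError("window shorter than k")

        slot_variants = [branch_map.slot_variants[w0 + j] for j in range(n_slots)]
        offsets = np.zeros(n_slots + 1, dtype=int)
        for j in range(n_slots):
            offsets[j + 1] = offsets[j] + 2 * len(slot_variants[j])
        S = int(offsets[-1])

        state_slot = np.empty(S, dtype=np.int64)
        is_insert = np.zeros(S, dtype=np.bool_)
        state_kmer: list[str] = [""] * S
        state_choices: list[dict[int, bool]] = [dict()] * S
        mu = np.empty(S)
        sd = np.empty(S)
        for j in range(n_slots):
            for v, (kmer, choices) in enumerate(slot_variants[j]):
                if kmer not in table:
                    raise KeyError(f"variant kmer {kmer} (slot {w0 + j}) not in table")
                m, d = table[kmer]
                for typ in (0, 1):
                    s = offsets[j] + 2 * v + typ
                    state_slot[s] = j
                    is_insert[s] = bool(typ)
                    state_kmer[s] = kmer
                    state_choices[s] = dict(choices)
                    mu[s] = m
                    sd[s] = d

        levels = np.array(
            [table[branch_map.canonical_kmer(w0 + j)][0] for j in range(n_slots)]
        )
        bg_mu = params.bg_mean if params.bg_mean is not None else float(levels.mean())
        if params.bg_sd is not None:
            bg_sd = params.bg_sd
        else:
            spread = float(levels.std())
            bg_sd = 3.0 * spread if spread > 0 else 3.0 * float(np.mean(sd))

        # Directed edges.  Any state of (j, v) moves with the same distribution;
        # step/skip carry a 1/2 prior factor per site newly entering the window,
        # and moves unavailable at the reference edge are renormalized away.
        esrc: list[int] = []
        edst: list[int] = []
        ep: list[float] = []
        for j in range(n_slots):
            avail = params.p_stay + params.p_insert
            if j + 1 < n_slots:
                avail += params.p_step
            if j + 2 < n_slots:
                avail += params.p_skip
            for v in range(len(slot_variants[j])):
                match_s = offsets[j] + 2 * v
                choices = state_choices[match_s]
                targets: list[tuple[int, float]] = [
                    (match_s, params.p_stay / avail),
                    (match_s + 1, params.p_insert / avail),
                ]
                for dj, p_move in ((1, params.p_step), (2, params.p_skip)):
                    if j + dj >= n_slots:
                        continue
                    for w, (kmer2, choices2) in enumerate(slot_variants[j + dj]):
                        ok = True
                        n_new = 0
                        for pos, is_mod in choices2:
                            if pos in choices:
                                if choices[pos] != is_mod:
                                    ok = False
                                    break
                            else:
                                n_new += 1
                        if not ok:
                            continue
                        targets.append(
                            (offsets[j + dj] + 2 * w, (p_move / avail) * 0.5**n_new)
                        )
                for src in (match_s, match_s + 1):
                    for dst, p in targets:
                        esrc.append(src)
                        edst.append(dst)
                        ep.append(p)

        edge_src = np.asarray(esrc, dtype=np.int64)
        edge_dst = np.asarray(edst, dtype=np.int64)
        edge_p = np.asarray(ep, dtype=np.float64)
        order = np.lexsort((edge_src, edge_dst))
        edge_src, edge_dst, edge_p = edge_src[order], edge_dst[order], edge_p[order]

        # The first event may belong to slot 0, to a slot reached after an
        # initial skip, or be spurious: start mass covers the first few slots
        # (geometric in the skip probability) and their insert twins.
        log_init = np.full(S, -np.inf)
        n_start = min(3, n_slots)
        weights = np.array([params.p_skip**j for j in range(n_start)])
        weights /= weights.sum()
        for j in range(n_start):
            nv = len(slot_variants[j])
            for v in range(nv):
                w = weights[j] / nv
                log_init[offsets[j] + 2 * v] = math.log(w * (1.0 - params.p_insert))
                log_init[offsets[j] + 2 * v + 1] = math.log(w * params.p_insert)

        # Site decode marginalizes over MATCH states only: insert emissions are
        # variant-independent, so their occupancy carries no information about
        # the site character and would only dilute the posterior toward 1/2.
        site_states: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for pos in branch_map.site_pos0:
            if not (w0 <= pos < w1):
                continue
            idx = [
                s for s in range(S)
                if pos in state_choices[s] and not is_insert[s]
            ]
            if not idx:
                continue
            flags = np.array([state_choices[s][pos] for s in idx], dtype=bool)
            site_states[pos] = (np.array(idx, dtype=np.int64), flags)

        return cls(
            branch_map=branch_map, table=table, params=params, window=window,
            n_states=S, state_slot=state_slot, state_kmer=state_kmer,
            is_insert=is_insert, mu=mu, sd=sd, log_init=log_init,
            edge_src=edge_src, edge_dst=edge_dst, edge_p=edge_p,
            site_states=site_states, bg_mu=bg_mu, bg_sd=bg_sd,
        )

    def log_emissions(self, means: np.ndarray) -> np.ndarray:
        return _kernels.log_emissions(
            np.asarray(means, dtype=float), self.mu, self.sd,
            self.is_insert, self.bg_mu, self.bg_sd,
        )


@dataclass
class PosteriorTable:
    """Per-read posterior state occupancies gamma(event, state) and log-likelihood."""

    model: AlignmentModel
    read: EventSequence
    gamma: np.ndarray        # (T, S)
    loglik: float

    def state_mass(self) -> np.ndarray:
        """Total posterior mass per state, summed over events."""
        return self.gamma.sum(axis=0)


def forward_backward(
    read: EventSequence,
    model: AlignmentModel,
) -> PosteriorTable:
    """Posterior decode of one (normalized) read against the model window."""
    loge = model.log_emissions(read.events)
    gamma = np.empty_like(loge)
    ll = _kernels.forward_backward(
        loge, model.log_init, model.edge_src, model.edge_dst, model.edge_p, gamma,
    )
    if not np.isfinite(ll):
        raise AlignmentFailure(
            f"read {read.read_id}: no admissible path with positive mass"
        )
    return PosteriorTable(model=model, read=read, gamma=gamma, loglik=float(ll))


def decode_site_probabilities(
    post: PosteriorTable,
    site_positions: Sequence[int] | None = None,
) -> dict[int, float]:
    """Marginal P(modified) per branchable site covered by the read.

    For a site, the probability is the posterior mass on covering states whose
    variant carries the modified character, over all mass on covering states.
    Sites with (numerically) no covering mass are omitted rather than reported
    as zero.
    """
    mass = post.state_mass()
    out: dict[int, float] = {}
    wanted = set(site_positions) if site_positions is not None else None
    for pos, (idx, is_mod) in post.model.site_states.items():
        if wanted is not None and pos not in wanted:
            continue
        total = float(mass[idx].sum())
        if total <= 1e-300:
            continue
        out[pos] = float(mass[idx[is_mod]].sum()) / total
    return out


def refit_normalization(
    read: EventSequence,
    post: "PosteriorTable",
    steps: "list[MeaStep] | None" = None,
    min_pairs: int = 8,
) -> tuple[float, float, EventSequence]:
    """Second-stage per-read normalization from an alignment.

    The median/MAD first pass slightly overestimates scale (event noise and
    spurious inserts inflate the read's MAD relative to the model levels).
    Given an event-to-kmer path, regressing event means on their assigned
    model levels is free of that bias (the noise sits in the response); a
    single trimming pass guards against misassigned events.  Returns the
    composed (shift, scale) relative to the raw signal and the re-normalized
    read; the read is returned unchanged when too few match pairs survive.
    """
    if steps is None:
        steps = mea_path(post)
    model = post.model
    levels, ev = [], []
    for step in steps:
        if step.is_insert:
            continue
        levels.append(model.table[step.kmer][0])
        ev.append(read.events[step.event_index])
    levels = np.asarray(levels)
    ev = np.asarray(ev)
    for _ in range(2):
        if len(ev) < min_pairs or np.ptp(levels) == 0:
            return read.shift, read.scale, read
        a = np.polyfit(levels, ev, 1)[0]
        # robust intercept: the OLS intercept is dragged by the few percent of
        # misassigned pairs; the median residual is not
        b = float(np.median(ev - a * levels))
        resid = ev - (a * levels + b)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad == 0:
            break
        keep = np.abs(resid - np.median(resid)) <= 4.0 * mad
        if keep.all():
            break
        levels, ev = levels[keep], ev[keep]
    if not np.isfinite(a) or a <= 0.1:
        return read.shift, read.scale, read
    # events' = (events - b)/a; compose with the existing affine state
    shift = read.shift + read.scale * b
    scale = read.scale * a
    out = replace(read, events=(read.events - b) / a, shift=shift, scale=scale)
    return shift, scale, out


@dataclass
class MeaStep:
    event_index: int
    slot: int                 # global 0-based slot (kmer start position)
    kmer: str
    is_insert: bool


def mea_path(post: PosteriorTable) -> list[MeaStep]:
    """Maximum-expected-accuracy event-to-kmer path.

    The admissible monotone path (same transition structure as the HMM)
    maximizing the summed posterior mass of its (event, slot, variant) pairs;
    ties resolve to the smallest slot, then variant, then match-over-insert.
    """
    model = post.model
    start_ok = np.isfinite(model.log_init)
    # probabilities are irrelevant for admissibility; dedupe parallel edges
    pairs = np.unique(
        np.stack([model.edge_dst, model.edge_src], axis=1), axis=0
    )
    states = _kernels.mea_dp(
        post.gamma, start_ok, pairs[:, 1].copy(), pairs[:, 0].copy()
    )
    steps = []
    for t, s in enumerate(states):
        steps.append(
            MeaStep(
                event_index=t,
                slot=model.slot0 + int(model.state_slot[s]),
                kmer=model.state_kmer[s],
                is_insert=bool(model.is_insert[s]),
            )
        )
    return steps


# -- events on disk ----------------------------------------------------------

EVENT_COLUMNS = [
    "read_id", "contig", "start", "end", "orientation",
    "event_index", "mean", "spread", "duration",
]


def write_events_tsv(reads: Sequence[EventSequence], path: str | Path) -> None:
    """Columnar event table, one row per event, measurement order."""
    rows = []
    for r in reads:
        means = r.events[::-1] if r.sequenced_3p5p else r.events
        orient = "3p5p" if r.sequenced_3p5p else "5p3p"
        spreads = r.spreads[::-1] if (r.spreads is not None and r.sequenced_3p5p) else r.spreads
        durs = r.durations[::-1] if (r.durations is not None and r.sequenced_3p5p) else r.durations
        for i, m in enumerate(means):
            rows.append((
                r.read_id, r.contig, r.start, r.end, orient, i, float(m),
                float(spreads[i]) if spreads is not None else float("nan"),
                float(durs[i]) if durs is not None else float("nan"),
            ))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path) -> list[EventSequence]:
    """Read an events table back into per-read sequences (internally 5'->3')."""
    df = pd.read_csv(path, sep="\t", comment="#")
    reads = []
    for read_id, grp in df.groupby("read_id", sort=False):
        grp = grp.sort_values("event_index")
        seq_3p5p = grp["orientation"].iloc[0] == "3p5p"
        means = grp["mean"].to_numpy()
        spreads = grp["spread"].to_numpy() if grp["spread"].notna().any() else None
        durs = grp["duration"].to_numpy() if grp["duration"].notna().any() else None
        if seq_3p5p:
            means = means[::-1].copy()
            spreads = spreads[::-1].copy() if spreads is not None else None
            durs = durs[::-1].copy() if durs is not None else None
        reads.append(
            EventSequence(
                read_id=str(read_id),
                contig=str(grp["contig"].iloc[0]),
                start=int(grp["start"].iloc[0]),
                end=int(grp["end"].iloc[0]),
                events=means,
                spreads=spreads,
                durations=durs,
                sequenced_3p5p=seq_3p5p,
            )
        )
    return reads
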