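"""Exhaustive path enumeration over a small alignment model.

A literal reference for the HMM recursions: every admissible state sequence is
enumerated and its probability accumulated (or its summed posterior mass
maximized).  Exponential in the number of events -- intended for instances of
a handful of events and states only, where it serves as an independent check
of the scaled dynamic-programming kernels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .signal_hmm import AlignmentModel


def _edge_logp(model: AlignmentModel) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for s, d, p in zip(model.edge_src, model.edge_dst, model.edge_p):
        key = (int(s), int(d))
        out[key] = out.get(key, 0.0) + float(p)
    return {k: math.log(v) for k, v in out.items()}


def enumerate_loglik(model: AlignmentModel, events: np.ndarray) -> float:
    """Total log-likelihood by summing over every admissible state sequence."""
    loge = model.log_emissions(np.asarray(events, dtype=float))
    T, S = loge.shape
    logp_edge = _edge_logp(model)
    total = -np.inf
    for seq in itertools.product(range(S), repeat=T):
        lp = model.log_init[seq[0]]
        if not np.isfinite(lp):
            continue
        lp += loge[0, seq[0]]
        ok = True
        for t in range(1, T):
            key = (seq[t - 1], seq[t])
            if key not in logp_edge:
                ok = False
                break
            lp += logp_edge[key] + loge[t, seq[t]]
        if ok:
            total = np.logaddexp(total, lp)
    return float(total)


def enumerate_best_path(model: AlignmentModel, gamma: np.ndarray) -> tuple[float, list[int]]:
    """Max summed posterior mass over admissible sequences, with the
    lexicographically smallest optimal sequence (states ordered by slot,
    variant, match-before-insert)."""
    T, S = gamma.shape
    edges = {(int(s), int(d)) for s, d in zip(model.edge_src, model.edge_dst)}
    best_score = -np.inf
    best_seq: list[int] | None = None
    for seq in itertools.product(range(S), repeat=T):
        if not np.isfinite(model.log_init[seq[0]]):
            continue
        if any((seq[t - 1], seq[t]) not in edges for t in range(1, T)):
            continue
        score = float(sum(gamma[t, s] for t, s in enumerate(seq)))
        if score > best_score + 1e-15:
            best_score = score
            best_seq = list(seq)
    return best_score, best_seq
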