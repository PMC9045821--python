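"""Comparative, model-free detection of modified positions from signal.

Two samples (typically unmodified IVT vs a biological sample) are compared
position by position: the per-position distributions of normalized event
means are scored with the two-sample Kolmogorov-Smirnov D statistic, smoothed
with a 3-position windowed mean, and evaluated against the annotation with
two AUROC protocols -- strict per-position scoring, and a relaxed
window-peak protocol in which each modification is scored by the maximum
statistic within a 5-position window and the 2 positions flanking each
modification are excluded from the negative set (signal bleeds into
neighbouring kmers, so localization within a couple of nucleotides is not
penalized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .model_space import BranchMap, KmerTable
from .signal_hmm import (
    AlignmentModel,
    EventSequence,
    HmmParams,
    forward_backward,
    mea_path,
    normalize_events,
)

DEFAULT_MIN_COVERAGE = 10


def collect_position_samples(
    reads: Sequence[EventSequence],
    table: KmerTable,
    branch_map: BranchMap,
    params: HmmParams | None = None,
) -> dict[int, np.ndarray]:
    """Per-position normalized event-mean samples via canonical-only alignment.

    The detector must not presume a trained modified model, so reads are
    aligned against the canonical reference only; each MEA-assigned event is
    attributed to the CENTER position of its kmer (0-based), so a modified
    site perturbs the positions within +-(k//2) of itself.
    """
    params = params or HmmParams()
    canonical = branch_map.forced("canonical")
    k = branch_map.k
    cache: dict[tuple[int, int], AlignmentModel] = {}
    samples: dict[int, list[float]] = {}
    for read in reads:
        if not read.normalized:
            _, _, read = normalize_events(read, table, branch_map)
        window = (read.start - 1, read.end)
        model = cache.get(window)
        if model is None:
            model = AlignmentModel.build(canonical, table, params, window)
            cache[window] = model
        post = forward_backward(read, model)
        for step in mea_path(post):
            if step.is_insert:
                continue
            samples.setdefault(step.slot + k // 2, []).append(
                float(read.events[step.event_index])
            )
    return {pos: np.asarray(v) for pos, v in samples.items()}


@dataclass
class SiteStatTrack:
    """Per-position comparative statistics over one contig."""

    contig: str
    d: np.ndarray                  # KS D per position (NaN where masked)
    w: np.ndarray                  # 3-window mean of d (NaN where undefined)
    labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "contig": self.contig,
                "position": np.arange(1, len(self.d) + 1),
                "d": self.d,
                "w": self.w,
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        df["mask"] = np.isnan(self.w)
        return df


def position_dstats(
    samples_a: Mapping[int, np.ndarray],
    samples_b: Mapping[int, np.ndarray],
    length: int,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> np.ndarray:
    """Two-sample KS D per reference position (0-based index into the result).

    Positions with fewer than ``min_coverage`` events in either sample are
    masked (NaN) rather than scored.
    """
    d = np.full(length, np.nan)
    for pos in range(length):
        a = samples_a.get(pos)
        b = samples_b.get(pos)
        if a is None or b is None or len(a) < min_coverage or len(b) < min_coverage:
            continue
        d[pos] = float(stats.ks_2samp(a, b).statistic)
    return d


def windowed_dstat(d: np.ndarray, halfwidth: int = 1) -> np.ndarray:
    """w_i = mean(d_{i-h} ... d_{i+h}); undefined wherever the window is not
    fully covered (boundaries and masked neighbourhoods)."""
    L = len(d)
    w = np.full(L, np.nan)
    for i in range(halfwidth, L - halfwidth):
        window = d[i - halfwidth : i + halfwidth + 1]
        if np.isnan(window).any():
            continue
        w[i] = float(window.mean())
    return w


@dataclass
class DetectionResult:
    auroc: float
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]
    n_positives: int
    n_negatives: int

    @property
    def n_classified(self) -> int:
        return self.n_positives + self.n_negatives


def detection_auroc(
    w: np.ndarray,
    labels: np.ndarray,
    protocol: str = "per_position",
    window: int = 5,
    flank_exclusion: int = 2,
) -> DetectionResult:
    """AUROC of a statistic track against annotated modification labels.

    per_position: every unmasked position is scored by its own w_i.
    window_peak: each modified position is scored by the maximum w over the
    ``window`` positions centred on it, and the ``flank_exclusion`` positions
    on each side of every modification are excluded from the negative set
    (overlapping exclusion zones are unioned).  AUROC uses midranks.
    """
    w = np.asarray(w, dtype=float)
    labels = np.asarray(labels).astype(int)
    if w.shape != labels.shape:
        raise ValueError("w and labels must have the same length")
    L = len(w)
    mod_pos = np.flatnonzero(labels == 1)
    if protocol == "per_position":
        ok = ~np.isnan(w)
        scores, ys = w[ok], labels[ok]
    elif protocol == "window_peak":
        half = window // 2
        excluded = np.zeros(L, dtype=bool)
        for p in mod_pos:
            lo = max(p - flank_exclusion, 0)
            hi = min(p + flank_exclusion + 1, L)
            excluded[lo:hi] = True
            excluded[p] = False
        scores_list, ys_list = [], []
        for p in mod_pos:
            win = w[max(p - half, 0) : min(p + half + 1, L)]
            if np.isnan(win).all():
                continue
            scores_list.append(float(np.nanmax(win)))
            ys_list.append(1)
        for p in np.flatnonzero((labels == 0) & ~excluded):
            if np.isnan(w[p]):
                continue
            scores_list.append(float(w[p]))
            ys_list.append(0)
        scores, ys = np.asarray(scores_list), np.asarray(ys_list)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    n_pos = int((ys == 1).sum())
    n_neg = int((ys == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative positions after masking")
    fpr, tpr, thr = skm.roc_curve(ys, scores)
    return DetectionResult(
        auroc=float(skm.roc_auc_score(ys, scores)),
        roc=(fpr, tpr, thr),
        n_positives=n_pos,
        n_negatives=n_neg,
    )


def site_stat_track(
    samples_a: Mapping[int, np.ndarray],
    samples_b: Mapping[int, np.ndarray],
    contig: str,
    length: int,
    labels: np.ndarray | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> SiteStatTrack:
    d = position_dstats(samples_a, samples_b, length, min_coverage)
    return SiteStatTrack(contig=contig, d=d, w=windowed_dstat(d), labels=labels)
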