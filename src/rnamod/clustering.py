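"""Hierarchical clustering of single-molecule profiles and raw event means.

Modification profiles (reads x sites probability matrices) are clustered with
Ward's method on Euclidean distance after full-coverage filtering; cutting the
dendrogram into N branches and counting reads per branch quantifies
subpopulations per sample.  As an independent check that does not rely on the
trained model, the underlying standardized event means over a region can be
clustered the same way: if modification fully determines the signal shift, the
two clusterings agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .profiles import ModProfileMatrix, filter_full_coverage
from .signal_hmm import EventSequence, PosteriorTable, mea_path


@dataclass
class Dendrogram:
    """Ward/Euclidean linkage over labelled rows."""

    linkage: np.ndarray            # scipy linkage records (merge, merge, height, size)
    ids: list[str]                 # row labels in input order
    method: str = "ward"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def cut(self, n_clusters: int) -> pd.Series:
        """Cluster membership at N branches, ids stable by dendrogram leaf order."""
        if not 1 <= n_clusters <= self.n_leaves:
            raise ValueError(f"N must be in [1, {self.n_leaves}]")
        raw = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        relabel: dict[int, int] = {}
        for leaf in self.leaf_order:
            relabel.setdefault(raw[leaf], len(relabel) + 1)
        return pd.Series(
            [relabel[c] for c in raw], index=pd.Index(self.ids, name="read_id"),
            name="cluster",
        )


def cluster_profiles(matrix: ModProfileMatrix) -> Dendrogram:
    """Ward/Euclidean dendrogram of modification profiles.

    Full-coverage filtering is enforced internally (reads missing any site are
    dropped before clustering); deterministic for a given input.
    """
    full = filter_full_coverage(matrix)
    if full.n_reads < 2:
        raise ValueError("need at least 2 complete reads to cluster")
    X = full.df.to_numpy()
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, ids=list(full.df.index))


def cluster_fractions(
    dendro: Dendrogram,
    n_clusters: int,
    sample_labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Fraction of each sample's reads falling in each dendrogram branch.

    Rows are samples, columns cluster ids (ordered by leaf order); each row
    sums to 1.
    """
    members = dendro.cut(n_clusters)
    labels = pd.Series(sample_labels).reindex(members.index)
    counts = (
        pd.crosstab(labels, members)
        .reindex(columns=range(1, members.max() + 1), fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass
class EventMeanMatrix:
    """Reads x slots standardized event means over a region, plus clustering."""

    df: pd.DataFrame               # rows read_id, columns global slot index
    read_params: pd.DataFrame      # per-read raw mean/sd used to standardize
    column_params: pd.DataFrame    # per-column mean/sd of the pooled standardization
    dendrogram: Dendrogram | None = None


def event_mean_matrix(
    posteriors: Sequence[PosteriorTable],
    region: tuple[int, int],
    cluster: bool = True,
    read_standardize: bool = True,
) -> EventMeanMatrix:
    """Raw-signal matrix over a slot region from MEA paths.

    Per read, event means are z-standardized over the whole read (spurious
    insert-assigned events excluded from the location/scale estimate),
    assigned to slots by the maximum-expected-accuracy path, and multi-event
    slots averaged.  Reads missing any slot in the region are dropped; the
    pooled matrix is then standardized by column (mean 0, sd 1) and clustered
    with the same Ward/Euclidean procedure as profiles.

    ``read_standardize=False`` keeps event means on their existing scale --
    appropriate when the reads were already affine-normalized against the
    model (the per-read z would then only re-estimate, noisily, a correction
    that has already been applied).

    ``region`` is a 0-based half-open range of global slot indices.
    """
    lo, hi = region
    slots = list(range(lo, hi))
    rows, params, index = [], [], []
    for post in posteriors:
        read = post.read
        x = read.events
        steps = mea_path(post)
        match_idx = [s.event_index for s in steps if not s.is_insert]
        if len(match_idx) < 2:
            continue
        mu = float(x[match_idx].mean())
        sd = float(x[match_idx].std())
        if sd == 0:
            continue
        z = (x - mu) / sd if read_standardize else x
        per_slot: dict[int, list[float]] = {}
        for step in steps:
            if step.is_insert:
                continue
            if lo <= step.slot < hi:
                per_slot.setdefault(step.slot, []).append(z[step.event_index])
        if any(s not in per_slot for s in slots):
            continue  # a skipped slot in the region excludes the read
        rows.append([float(np.mean(per_slot[s])) for s in slots])
        params.append({"read_mean": mu, "read_sd": sd})
        index.append(read.read_id)
    if not rows:
        raise ValueError("no read covers every slot of the region")
    df = pd.DataFrame(rows, index=pd.Index(index, name="read_id"), columns=slots)
    col_mu = df.mean(axis=0)
    col_sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    df = (df - col_mu) / col_sd
    dendro = None
    if cluster and len(df) >= 2:
        Z = hierarchy.linkage(df.to_numpy(), method="ward", metric="euclidean")
        dendro = Dendrogram(linkage=Z, ids=list(df.index))
    return EventMeanMatrix(
        df=df,
        read_params=pd.DataFrame(params, index=df.index),
        column_params=pd.DataFrame({"mean": col_mu, "sd": col_sd}),
        dendrogram=dendro,
    )


def events_per_kmer(
    posteriors: Sequence[PosteriorTable],
    kmer: str,
    min_prob: float = 0.5,
) -> np.ndarray:
    """Normalized event means assigned to one kmer with posterior > min_prob.

    The per-event posterior of emitting from the kmer is the summed occupancy
    of its match states; the resulting sample is what a kernel density
    estimate is overlaid against the model Gaussian (empty samples allowed).
    """
    out: list[float] = []
    for post in posteriors:
        model = post.model
        idx = np.array(
            [
                s
                for s in range(model.n_states)
                if model.state_kmer[s] == kmer and not model.is_insert[s]
            ],
            dtype=int,
        )
        if idx.size == 0:
            continue
        mass = post.gamma[:, idx].sum(axis=1)
        out.extend(post.read.events[mass > min_prob])
    return np.asarray(out)
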