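"""Reads x sites modification-probability matrices and classification metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .model_space import BranchMap, KmerTable, ModificationSite
from .signal_hmm import (
    AlignmentFailure,
    AlignmentModel,
    EventSequence,
    HmmParams,
    decode_site_probabilities,
    forward_backward,
    normalize_events,
    refit_normalization,
)

log = logging.getLogger(__name__)


def site_column(contig: str, position: int) -> str:
    return f"{contig}:{position}"


@dataclass
class ModProfileMatrix:
    """Per-read modification profiles: rows are molecules, columns annotated sites.

    Cells hold P(modified) in [0, 1], NaN for sites the read does not cover.
    Columns are ordered by (contig, position); ``samples`` labels each read
    with the experiment it came from.
    """

    df: pd.DataFrame
    samples: pd.Series
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.samples = self.samples.reindex(self.df.index)

    @property
    def n_reads(self) -> int:
        return len(self.df)

    @property
    def site_columns(self) -> list[str]:
        return list(self.df.columns)

    def subset(self, index: pd.Index) -> "ModProfileMatrix":
        return ModProfileMatrix(
            df=self.df.loc[index],
            samples=self.samples.loc[index],
            meta=self.meta.loc[index] if self.meta is not None else None,
        )

    def concat(self, other: "ModProfileMatrix") -> "ModProfileMatrix":
        return ModProfileMatrix(
            df=pd.concat([self.df, other.df]),
            samples=pd.concat([self.samples, other.samples]),
            meta=(
                pd.concat([self.meta, other.meta])
                if self.meta is not None and other.meta is not None
                else None
            ),
        )

    # -- on-disk dialects ---------------------------------------------------

    def to_wide_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "sample", self.samples)
        out.to_csv(path, sep="\t", index_label="read_id")

    @classmethod
    def from_wide_tsv(cls, path: str | Path) -> "ModProfileMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="read_id")
        samples = df.pop("sample")
        return cls(df=df, samples=samples)

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for read_id, row in self.df.iterrows():
            sample = self.samples.loc[read_id]
            for col, prob in row.items():
                if pd.isna(prob):
                    continue
                contig, pos = col.rsplit(":", 1)
                rows.append((read_id, sample, contig, int(pos), float(prob)))
        pd.DataFrame(
            rows, columns=["read_id", "sample", "contig", "position", "prob"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "ModProfileMatrix":
        long = pd.read_csv(path, sep="\t", comment="#")
        long["col"] = [
            site_column(c, p) for c, p in zip(long["contig"], long["position"])
        ]
        df = long.pivot_table(index="read_id", columns="col", values="prob")
        order = sorted(
            df.columns, key=lambda c: (c.rsplit(":", 1)[0], int(c.rsplit(":", 1)[1]))
        )
        samples = long.drop_duplicates("read_id").set_index("read_id")["sample"]
        return cls(df=df[order], samples=samples)


def call_reads(
    reads: Sequence[EventSequence],
    table: KmerTable,
    branch_map: BranchMap,
    sites: Sequence[ModificationSite] | None = None,
    params: HmmParams | None = None,
    sample: str = "sample",
    normalize: bool = True,
    refit: bool = True,
    model_cache: dict | None = None,
) -> ModProfileMatrix:
    """Align every read and decode its per-site modification probabilities.

    One row per read; sites outside the read's mapped interval stay missing.
    Reads that fail alignment are dropped with a logged reason.  Full-length
    status is recorded in ``meta`` but not enforced -- filtering is explicit
    via :func:`filter_full_coverage`.
    """
    params = params or HmmParams()
    if sites is not None:
        columns = [
            site_column(s.contig, s.position)
            for s in sorted(sites, key=lambda s: (s.contig, s.position))
            if s.callable and s.contig == branch_map.contig
        ]
        pos_to_col = {
            s.pos0: site_column(s.contig, s.position)
            for s in sites
            if s.contig == branch_map.contig
        }
    else:
        columns = [
            site_column(branch_map.contig, p + 1) for p in branch_map.site_pos0
        ]
        pos_to_col = {
            p: site_column(branch_map.contig, p + 1) for p in branch_map.site_pos0
        }
    cache: dict = model_cache if model_cache is not None else {}
    rows, meta_rows, index = [], [], []
    for read in reads:
        try:
            if normalize and not read.normalized:
                _, _, read = normalize_events(read, table, branch_map)
            window = (read.start - 1, read.end)
            model = cache.get(window)
            if model is None:
                model = AlignmentModel.build(branch_map, table, params, window)
                cache[window] = model
            post = forward_backward(read, model)
            if refit:
                _, _, read = refit_normalization(read, post)
                post = forward_backward(read, model)
            probs = decode_site_probabilities(post)
        except (AlignmentFailure, ValueError) as exc:
            log.warning("dropping read %s: %s", read.read_id, exc)
            continue
        row = {pos_to_col[p]: v for p, v in probs.items() if p in pos_to_col}
        rows.append(row)
        index.append(read.read_id)
        meta_rows.append(
            {
                "shift": read.shift,
                "scale": read.scale,
                "loglik": post.loglik,
                "n_events": read.n_events,
                "full_length": read.is_full_length(),
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(index, name="read_id"), columns=columns)
    samples = pd.Series(sample, index=df.index, name="sample")
    meta = pd.DataFrame(meta_rows, index=df.index)
    return ModProfileMatrix(df=df, samples=samples, meta=meta)


def filter_full_coverage(matrix: ModProfileMatrix) -> ModProfileMatrix:
    """Keep only reads with a probability at every site (order preserved)."""
    keep = matrix.df.notna().all(axis=1)
    return matrix.subset(matrix.df.index[keep])


def site_frequencies(matrix: ModProfileMatrix, cutoff: float = 0.5) -> pd.DataFrame:
    """Per-site fraction of molecules called modified (strictly above cutoff).

    Returns a frame indexed by site column with ``frequency`` (NaN when no
    read covers the site), ``n_modified`` and ``n`` (non-missing reads).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    n = matrix.df.notna().sum(axis=0)
    n_mod = (matrix.df > cutoff).sum(axis=0)
    freq = n_mod / n.replace(0, np.nan)
    return pd.DataFrame(
        {"frequency": freq, "n_modified": n_mod, "n": n, "defined": n > 0}
    )


@dataclass
class MetricsBundle:
    """Binary-classification quality of modification calls at a fixed cutoff."""

    auroc: float | None
    roc: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    pr: tuple[np.ndarray, np.ndarray, np.ndarray] | None
    calibration: pd.DataFrame = None
    confusion: dict[str, int] = field(default_factory=dict)
    sensitivity: float = np.nan
    specificity: float = np.nan
    balanced_accuracy: float = np.nan
    per_position_balanced_accuracy: pd.Series | None = None
    average_balanced_accuracy: float = np.nan
    single_class: bool = False


def _balanced_accuracy(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    pos = labels == 1
    neg = ~pos
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    return sens, spec, (sens + spec) / 2.0


def classification_metrics(
    probs: np.ndarray,
    labels: np.ndarray,
    cutoff: float = 0.5,
    positions: np.ndarray | None = None,
    n_bins: int = 10,
) -> MetricsBundle:
    """ROC/PR/calibration/confusion against known modification states.

    Balanced accuracy is (sensitivity + specificity) / 2 at the cutoff, with
    P = cutoff counting as unmodified (strict >).  With ``positions`` given,
    a per-position balanced accuracy and its average are also reported.
    AUROC uses midranks for ties (trapezoidal ROC area).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = ~np.isnan(probs)
    probs, labels = probs[ok], labels[ok]
    if positions is not None:
        positions = np.asarray(positions)[ok]
    single_class = len(np.unique(labels)) < 2
    if single_class:
        auroc, roc, pr = None, None, None
    else:
        fpr, tpr, thr = skm.roc_curve(labels, probs)
        auroc = float(skm.roc_auc_score(labels, probs))
        prec, rec, pthr = skm.precision_recall_curve(labels, probs)
        roc, pr = (fpr, tpr, thr), (prec, rec, pthr)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(probs, edges) - 1, 0, n_bins - 1)
    cal_rows = []
    for b in range(n_bins):
        in_bin = bin_idx == b
        cal_rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(in_bin.sum()),
                "mean_predicted": float(probs[in_bin].mean()) if in_bin.any() else np.nan,
                "empirical_fraction": float(labels[in_bin].mean()) if in_bin.any() else np.nan,
            }
        )
    calibration = pd.DataFrame(cal_rows)

    pred = probs > cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens, spec, bal = _balanced_accuracy(pred, labels)

    per_pos = None
    avg_bal = np.nan
    if positions is not None:
        vals = {}
        for p in np.unique(positions):
            sel = positions == p
            if len(np.unique(labels[sel])) < 2:
                continue
            _, _, b = _balanced_accuracy(pred[sel], labels[sel])
            vals[p] = b
        per_pos = pd.Series(vals, name="balanced_accuracy")
        avg_bal = float(per_pos.mean()) if len(per_pos) else np.nan

    return MetricsBundle(
        auroc=auroc,
        roc=roc,
        pr=pr,
        calibration=calibration,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
        per_position_balanced_accuracy=per_pos,
        average_balanced_accuracy=avg_bal,
        single_class=single_class,
    )
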