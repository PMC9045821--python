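"""Synthetic nanopore-signal data with known ground truth.

Emulates the event-level output of a direct RNA sequencing run over a
reference carrying annotated modified sites: per-read binary modification
states drawn from subpopulation templates (optionally with a Gaussian-copula
dependence structure between sites), events drawn from per-kmer Gaussians with
stays, skips and spurious inserts, and a per-read affine signal distortion.
Every draw is reproducible from the seed, and the planted truth (states,
distortions, subpopulation labels) is returned alongside the data, so model
training, calling, statistics and clustering can all be validated against a
known answer without any real sequencing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import model_space
from .model_space import (
    BranchMap,
    KmerTable,
    ModificationSite,
    assign_mod_chars,
    build_branch_map,
    derive_branch_kmers,
    write_kmer_table,
)
from .profiles import ModProfileMatrix, site_column
from .signal_hmm import EventSequence, write_events_tsv


@dataclass
class SampleSpec:
    """One simulated experiment: a mixture of per-site modification templates.

    ``templates`` holds one per-site modification-probability vector per
    subpopulation; ``weights`` are the mixture proportions.  ``correlations``
    plants pairwise dependence between site states as (site_index_a,
    site_index_b, target_spearman).
    """

    name: str
    n_reads: int = 500
    templates: list[np.ndarray] = None
    weights: list[float] = None
    correlations: list[tuple[int, int, float]] = field(default_factory=list)

    def resolved(self, n_sites: int) -> "SampleSpec":
        templates = self.templates
        if templates is None:
            templates = [np.full(n_sites, 0.95)]
        templates = [np.asarray(t, dtype=float) for t in templates]
        for t in templates:
            if t.shape != (n_sites,) or np.any((t < 0) | (t > 1)):
                raise ValueError(f"sample {self.name}: bad template shape/values")
        weights = self.weights if self.weights is not None else [1.0 / len(templates)] * len(templates)
        if len(weights) != len(templates) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"sample {self.name}: weights must match templates and sum to 1")
        return replace(self, templates=templates, weights=list(weights))


@dataclass
class SimConfig:
    """Study conditions of a simulated run.

    Defaults: a 300-nt contig with 12 well-separated sites, a +3 pA modified
    kmer shift at sigma = 1 pA -- separations where calling is reliable but not
    trivial -- nanopore-like stay/skip/insert rates, a mild per-read affine
    distortion, and a wild-type-like (95% modified) plus an IVT (unmodified)
    sample of 500 reads each.
    """

    contig: str = "sim"
    contig_length: int = 300
    n_sites: int = 12
    k: int = 5
    dead_zone: int = model_space.DEAD_ZONE
    adjacent_cluster: bool = False      # make the last 3 sites consecutive
    level_mean: float = 100.0           # canonical kmer level center, pA
    level_spread: float = 10.0          # sd of kmer-to-kmer level means, pA
    level_sd: float = 1.0               # per-kmer event noise, pA
    mod_shift: float = 3.0              # modified kmer mean offset, pA
    mod_sd: float = 1.0
    p_stay: float = 0.3
    p_skip: float = 0.1
    p_insert: float = 0.05
    shift_range: tuple[float, float] = (-5.0, 5.0)
    scale_range: tuple[float, float] = (0.95, 1.05)
    full_length_fraction: float = 0.9
    beta_mod: tuple[float, float] = (8.0, 2.0)   # profile-matrix draws, modified
    beta_can: tuple[float, float] = (2.0, 8.0)
    degenerate_probs: bool = False      # point masses at 0/1 instead of Betas
    samples: list[SampleSpec] = None

    def resolved_samples(self) -> list[SampleSpec]:
        samples = self.samples
        if samples is None:
            samples = [
                SampleSpec("wt", 500, [np.full(self.n_sites, 0.95)]),
                SampleSpec("ivt", 500, [np.zeros(self.n_sites)]),
            ]
        return [s.resolved(self.n_sites) for s in samples]


def _site_positions(cfg: SimConfig) -> list[int]:
    """Deterministic 1-based site placement: evenly spaced past the dead zone."""
    lo = cfg.dead_zone + cfg.k + 1
    hi = cfg.contig_length - cfg.k
    if cfg.n_sites < 1 or hi <= lo:
        raise ValueError("contig too short for the requested sites")
    n_spread = cfg.n_sites - (3 if cfg.adjacent_cluster else 0)
    span = hi - lo
    positions = [lo + round(i * span / max(n_spread - 1, 1)) for i in range(n_spread)]
    if cfg.adjacent_cluster:
        anchor = hi - 3 * cfg.k
        while any(abs(anchor + d - p) < cfg.k for d in range(3) for p in positions):
            anchor -= cfg.k
        positions += [anchor, anchor + 1, anchor + 2]
    positions = sorted(set(positions))
    if len(positions) != cfg.n_sites:
        raise ValueError("site placement collision; adjust geometry")
    if not cfg.adjacent_cluster:
        if min(b - a for a, b in itertools.pairwise(positions)) < 2 * cfg.k:
            raise ValueError("sites too dense for the configured contig length")
    return positions


def synthetic_reference(cfg: SimConfig, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGU"), size=cfg.contig_length))


def synthetic_sites(
    cfg: SimConfig, seq: str, mod_code: str = "Y"
) -> list[ModificationSite]:
    sites = [
        ModificationSite(
            contig=cfg.contig, position=p, canonical=seq[p - 1],
            mod_code=mod_code, callable=p > cfg.dead_zone,
        )
        for p in _site_positions(cfg)
    ]
    sites, _ = assign_mod_chars(sites)
    return sites


def synthetic_kmer_table(
    cfg: SimConfig, branch_map: BranchMap, rng: np.random.Generator
) -> KmerTable:
    """The planted "true" model: i.i.d. canonical levels, modified kmers
    offset by ``mod_shift``."""
    table = KmerTable(k=cfg.k)
    for combo in itertools.product("ACGU", repeat=cfg.k):
        table.set("".join(combo), rng.normal(cfg.level_mean, cfg.level_spread), cfg.level_sd)
    table = derive_branch_kmers(table, branch_map)
    for j, variants in enumerate(branch_map.slot_variants):
        canonical_mean = table[branch_map.canonical_kmer(j)][0]
        for kmer, choices in variants:
            if any(m for _, m in choices):
                table.set(kmer, canonical_mean + cfg.mod_shift, cfg.mod_sd)
    return table


# -- dependent site states ---------------------------------------------------

def _latent_correlation(p_a: float, p_b: float, target: float) -> float:
    """Latent Gaussian correlation whose thresholded binary states have the
    requested correlation (phi == Spearman for binary variables)."""
    if target == 0.0:
        return 0.0
    a, b = stats.norm.ppf(p_a), stats.norm.ppf(p_b)
    denom = np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    if denom == 0:
        raise ValueError("cannot correlate a site with degenerate frequency 0 or 1")

    def phi(r: float) -> float:
        p11 = stats.multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([a, b])
        return (p11 - p_a * p_b) / denom

    lo, hi = -0.9999, 0.9999
    if not phi(lo) - 1e-9 <= target <= phi(hi) + 1e-9:
        raise ValueError(
            f"target correlation {target} unattainable for frequencies ({p_a}, {p_b})"
        )
    return float(optimize.brentq(lambda r: phi(r) - target, lo, hi, xtol=1e-6))


def _draw_states(
    spec: SampleSpec, rng: np.random.Generator, n_sites: int
) -> tuple[np.ndarray, int]:
    subpop = int(rng.choice(len(spec.templates), p=spec.weights))
    p = spec.templates[subpop]
    L = getattr(spec, "_chol", None)
    if spec.correlations and L is None:
        R = np.eye(n_sites)
        for i, j, rho in spec.correlations:
            r = _latent_correlation(p[i], p[j], rho)
            R[i, j] = R[j, i] = r
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation targets are jointly infeasible") from exc
        spec._chol = L
    if spec.correlations:
        z = L @ rng.standard_normal(n_sites)
        with np.errstate(divide="ignore"):
            states = (z < stats.norm.ppf(p)).astype(int)
    else:
        states = (rng.random(n_sites) < p).astype(int)
    return states, subpop


# -- event-level simulation --------------------------------------------------

def _simulate_read_events(
    cfg: SimConfig,
    branch_map: BranchMap,
    table: KmerTable,
    states: np.ndarray,
    site_pos0: np.ndarray,
    start0: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk slots 5'->3' emitting stay/step/skip/insert events (undistorted)."""
    mod_at = {
        p: branch_map.mod_char_at[p]
        for p, s in zip(site_pos0, states)
        if s == 1 and p in branch_map.mod_char_at
    }
    k = cfg.k
    L = len(branch_map.seq)
    events: list[float] = []
    bg_mu = cfg.level_mean
    bg_sd = 3.0 * cfg.level_spread
    for j in range(start0, L - k + 1):
        if rng.random() < cfg.p_skip:
            continue
        kmer = list(branch_map.seq[j : j + k])
        for p, c in mod_at.items():
            if j <= p < j + k:
                kmer[p - j] = c
        mean, sd = table["".join(kmer)]
        n = int(rng.geometric(1.0 - cfg.p_stay))
        events.extend(rng.normal(mean, sd, size=n))
        if rng.random() < cfg.p_insert:
            events.append(rng.normal(bg_mu, bg_sd))
    if not events:
        events.append(rng.normal(bg_mu, bg_sd))
    return np.asarray(events)


@dataclass
class SimulatedDataset:
    """A complete synthetic run plus its planted truth."""

    config: SimConfig
    reference: dict[str, str]
    sites: list[ModificationSite]
    branch_map: BranchMap
    table: KmerTable                       # planted truth model
    reads: dict[str, list[EventSequence]]  # sample -> reads
    truth: pd.DataFrame                    # per read: sample, subpop, shift, scale, ...
    states: pd.DataFrame                   # per read: planted 0/1 state per site

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference.fa", "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n{seq}\n")
        with open(outdir / "annotation.tsv", "w") as fh:
            fh.write("contig\tposition\tcanonical\tmod_code\tguide\n")
            for s in self.sites:
                fh.write(f"{s.contig}\t{s.position}\t{s.canonical}\t{s.mod_code}\t{s.guide}\n")
        write_kmer_table(self.table, outdir / "true_model.tsv")
        for sample, reads in self.reads.items():
            write_events_tsv(reads, outdir / f"events_{sample}.tsv")
        self.truth.to_csv(outdir / "truth_reads.tsv", sep="\t")
        self.states.to_csv(outdir / "truth_states.tsv", sep="\t")


def simulate_dataset(cfg: SimConfig, seed: int) -> SimulatedDataset:
    """Generate reference, annotation, true model and event-level reads.

    Fully reproducible: the same config and seed give byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    seq = synthetic_reference(cfg, rng)
    sites = synthetic_sites(cfg, seq)
    branch_map = build_branch_map(cfg.contig, seq, sites, k=cfg.k)
    table = synthetic_kmer_table(cfg, branch_map, rng)
    site_pos0 = np.array([s.pos0 for s in sites])
    callable_pos0 = [s.pos0 for s in sites if s.callable]

    reads: dict[str, list[EventSequence]] = {}
    truth_rows, state_rows, index = [], [], []
    for spec in cfg.resolved_samples():
        sample_reads: list[EventSequence] = []
        for i in range(spec.n_reads):
            read_id = f"{spec.name}_{i:05d}"
            states, subpop = _draw_states(spec, rng, cfg.n_sites)
            full_length = bool(rng.random() < cfg.full_length_fraction)
            if full_length:
                start0 = 0
            else:
                start0 = int(rng.integers(cfg.dead_zone + 1, cfg.contig_length // 2))
            raw = _simulate_read_events(
                cfg, branch_map, table, states, site_pos0, start0, rng
            )
            scale = float(rng.uniform(*cfg.scale_range))
            shift = float(rng.uniform(*cfg.shift_range))
            sample_reads.append(
                EventSequence(
                    read_id=read_id, contig=cfg.contig,
                    start=start0 + 1, end=cfg.contig_length,
                    events=scale * raw + shift, sequenced_3p5p=True,
                )
            )
            truth_rows.append(
                {
                    "sample": spec.name, "subpop": subpop,
                    "true_shift": shift, "true_scale": scale,
                    "start": start0 + 1, "full_length": full_length,
                }
            )
            state_rows.append(dict(zip((s.position for s in sites), states)))
            index.append(read_id)
        reads[spec.name] = sample_reads

    idx = pd.Index(index, name="read_id")
    return SimulatedDataset(
        config=cfg, reference={cfg.contig: seq}, sites=sites,
        branch_map=branch_map, table=table, reads=reads,
        truth=pd.DataFrame(truth_rows, index=idx),
        states=pd.DataFrame(state_rows, index=idx),
    )


def simulate_profile_matrix(
    cfg: SimConfig, seed: int
) -> tuple[ModProfileMatrix, pd.DataFrame]:
    """Probability matrices with planted truth, bypassing the signal level.

    Cells are drawn from state-conditional Beta distributions (modified near 1,
    canonical near 0); with ``degenerate_probs`` the cells equal the planted
    states exactly.  Used to exercise the statistics and clustering layers in
    isolation.
    """
    rng = np.random.default_rng(seed)
    positions = _site_positions(cfg)
    columns = [site_column(cfg.contig, p) for p in positions]
    rows, srows, samples, index = [], [], [], []
    for spec in cfg.resolved_samples():
        for i in range(spec.n_reads):
            states, subpop = _draw_states(spec, rng, cfg.n_sites)
            if cfg.degenerate_probs:
                probs = states.astype(float)
            else:
                a1, b1 = cfg.beta_mod
                a0, b0 = cfg.beta_can
                probs = np.where(
                    states == 1,
                    rng.beta(a1, b1, size=cfg.n_sites),
                    rng.beta(a0, b0, size=cfg.n_sites),
                )
            read_id = f"{spec.name}_{i:05d}"
            rows.append(probs)
            srows.append({"sample": spec.name, "subpop": subpop, **dict(zip(positions, states))})
            samples.append(spec.name)
            index.append(read_id)
    idx = pd.Index(index, name="read_id")
    matrix = ModProfileMatrix(
        df=pd.DataFrame(rows, index=idx, columns=columns),
        samples=pd.Series(samples, index=idx, name="sample"),
    )
    return matrix, pd.DataFrame(srows, index=idx)
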