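"""Frequency-change and correlation statistics on modification profiles.

Per-site modification frequencies of an experiment are compared against
wild-type replicates with 2x2 chi-square tests (worst p over replicate
pairings, Benjamini-Hochberg across sites, plus a global frequency-change
cutoff and a per-site wild-type-range batch filter).  Concerted modification
is measured as the Spearman correlation between per-site probabilities on the
same molecule; correlation changes between conditions use Fisher's
z-transformation, and higher-order claims aggregate dependent tests with the
Empirical Brown's method.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ModProfileMatrix, site_frequencies

log = logging.getLogger(__name__)

ALPHA = 0.05
GLOBAL_FREQ_CUTOFF = 0.10  # conservative minimum change in modification fraction


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# -- percent modification change --------------------------------------------

@dataclass
class FreqChangeResult:
    site: str
    wt_freqs: list[float]
    wt_counts: list[tuple[int, int]]       # (n_modified, n) per replicate
    expt_freqs: list[float]
    expt_counts: list[tuple[int, int]]
    min_abs_delta: float
    max_p: float
    wt_range: float                        # max pairwise |delta f| among WT reps
    q: float = np.nan
    passes_q: bool = False
    passes_global_cutoff: bool = False
    passes_wt_range: bool = False

    @property
    def changed(self) -> bool:
        return self.passes_q and self.passes_global_cutoff and self.passes_wt_range


def _chi_square_2x2(a_mod: int, a_n: int, b_mod: int, b_n: int) -> float:
    """Two-sample chi-square on a modified/unmodified x sample table.

    Continuity correction is applied automatically when any expected count is
    below 5 (logged); degenerate tables (an empty margin) give p = 1.
    """
    table = np.array([[a_mod, a_n - a_mod], [b_mod, b_n - b_mod]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    expected = stats.contingency.expected_freq(table)
    correction = bool((expected < 5).any())
    if correction:
        log.debug("chi-square: expected count < 5; using continuity correction")
    if np.array_equal(table[0] * table[1].sum(), table[1] * table[0].sum()):
        return 1.0  # identical proportions: statistic exactly 0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


def frequency_change_test(
    expt_matrices: Sequence[ModProfileMatrix],
    wt_matrices: Sequence[ModProfileMatrix],
    alpha: float = ALPHA,
    global_cutoff: float = GLOBAL_FREQ_CUTOFF,
    cutoff: float = 0.5,
) -> list[FreqChangeResult]:
    """Per-site test for a change in modification frequency vs wild type.

    For every site, a 2x2 chi-square is run for every (WT replicate x
    experiment repeat) pairing; the *highest* p is kept and BH-corrected
    across sites.  A site is flagged changed only when q < alpha, the minimum
    |delta frequency| across pairings exceeds the global cutoff, and it
    exceeds the maximum frequency spread among the WT replicates (batch
    control).
    """
    if not expt_matrices or not wt_matrices:
        raise ValueError("need at least one experiment and one wild-type matrix")
    wt_tables = [site_frequencies(m, cutoff) for m in wt_matrices]
    ex_tables = [site_frequencies(m, cutoff) for m in expt_matrices]
    sites = list(wt_tables[0].index)
    for t in wt_tables + ex_tables:
        if list(t.index) != sites:
            raise ValueError("matrices do not share the same site set")
    results: list[FreqChangeResult] = []
    for site in sites:
        wt_rows = [t.loc[site] for t in wt_tables]
        ex_rows = [t.loc[site] for t in ex_tables]
        deltas, pvals = [], []
        for wt, ex in itertools.product(wt_rows, ex_rows):
            deltas.append(abs(ex["frequency"] - wt["frequency"]))
            pvals.append(
                _chi_square_2x2(
                    int(ex["n_modified"]), int(ex["n"]),
                    int(wt["n_modified"]), int(wt["n"]),
                )
            )
        wt_range = max(
            (abs(a["frequency"] - b["frequency"])
             for a, b in itertools.combinations(wt_rows, 2)),
            default=0.0,
        )
        results.append(
            FreqChangeResult(
                site=site,
                wt_freqs=[float(r["frequency"]) for r in wt_rows],
                wt_counts=[(int(r["n_modified"]), int(r["n"])) for r in wt_rows],
                expt_freqs=[float(r["frequency"]) for r in ex_rows],
                expt_counts=[(int(r["n_modified"]), int(r["n"])) for r in ex_rows],
                min_abs_delta=float(np.nanmin(deltas)),
                max_p=float(np.nanmax(pvals)),
                wt_range=float(wt_range),
            )
        )
    qs = bh_qvalues([r.max_p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.passes_q = bool(q < alpha)
        r.passes_global_cutoff = bool(r.min_abs_delta >= global_cutoff)
        r.passes_wt_range = bool(r.min_abs_delta >= r.wt_range)
    return results


def frequency_change_table(results: list[FreqChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [r.site for r in results],
            "wt_freqs": [";".join(f"{f:.4f}" for f in r.wt_freqs) for r in results],
            "expt_freqs": [";".join(f"{f:.4f}" for f in r.expt_freqs) for r in results],
            "min_abs_delta": [r.min_abs_delta for r in results],
            "max_p": [r.max_p for r in results],
            "q": [r.q for r in results],
            "wt_range": [r.wt_range for r in results],
            "changed": [r.changed for r in results],
        }
    ).set_index("site")


# -- pairwise correlation ----------------------------------------------------

@dataclass
class CorrPairResult:
    site_a: str
    site_b: str
    rho: float
    n: int
    p: float
    q: float = np.nan

    @property
    def pair(self) -> tuple[str, str]:
        return (self.site_a, self.site_b)


def pairwise_spearman(matrix: ModProfileMatrix) -> list[CorrPairResult]:
    """Spearman rank correlation between all site pairs on the same molecule.

    Works on the continuous probability columns with midrank ties; the matrix
    must be full-coverage filtered.  p-values come from the two-sided t
    approximation t = rho*sqrt((n-2)/(1-rho^2)), df = n-2, BH-corrected over
    all pairs.  Constant columns give undefined correlations (emitted as NaN
    with a warning).
    """
    df = matrix.df
    if df.isna().any().any():
        raise ValueError("matrix must be filtered to full coverage first")
    n = len(df)
    cols = list(df.columns)
    results: list[CorrPairResult] = []
    rho_mat = stats.spearmanr(df.to_numpy()).statistic if len(cols) > 2 else None
    for i, j in itertools.combinations(range(len(cols)), 2):
        a, b = cols[i], cols[j]
        if df[a].nunique() < 2 or df[b].nunique() < 2:
            log.warning("constant column in pair (%s, %s); correlation undefined", a, b)
            results.append(CorrPairResult(a, b, np.nan, n, np.nan))
            continue
        rho = float(rho_mat[i, j]) if rho_mat is not None else float(
            stats.spearmanr(df[a], df[b]).statistic
        )
        if n < 4 or abs(rho) >= 1.0:
            p = np.nan if n < 4 else 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        results.append(CorrPairResult(a, b, rho, n, p))
    qs = bh_qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# -- comparing correlations between samples ----------------------------------

@dataclass
class CorrCompareResult:
    site_a: str
    site_b: str
    min_abs_delta_rho: float
    max_p: float                       # worst Fisher-z p over repeat pairings
    q: float = np.nan
    zero_p: float = np.nan             # worst test of rho_A == 0 over A repeats
    zero_q: float = np.nan
    comparable: bool = True
    star: bool = False


def fisher_z_test(rho_a: float, n_a: int, rho_b: float, n_b: int) -> tuple[float, float]:
    """Two-sided z-test for a difference between two independent correlations."""
    if n_a <= 3 or n_b <= 3:
        raise ValueError("need n > 3 in both samples")
    if abs(rho_a) >= 1.0 - 1e-12 or abs(rho_b) >= 1.0 - 1e-12:
        return np.inf, 0.0
    z = (np.arctanh(rho_a) - np.arctanh(rho_b)) / np.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _as_repeats(pairs) -> list[list[CorrPairResult]]:
    if pairs and isinstance(pairs[0], CorrPairResult):
        return [list(pairs)]
    return [list(rep) for rep in pairs]


def compare_correlations(
    pairs_a,
    n_a: int | Sequence[int],
    pairs_b,
    n_b: int | Sequence[int],
    alpha: float = ALPHA,
) -> list[CorrCompareResult]:
    """Fisher-z comparison of pairwise correlations between two conditions.

    ``pairs_a``/``pairs_b`` are :func:`pairwise_spearman` outputs -- a single
    list or a list of per-repeat lists.  To absorb repeat-to-repeat variation,
    each site pair reports the *minimum* |delta rho| and the *highest* p over
    all (A repeat x B repeat) pairings, BH-corrected across site pairs.  A
    pair is starred only when the corrected comparison is significant AND the
    focal (A) correlation is significantly different from zero (both at
    alpha, corrected).
    """
    reps_a = _as_repeats(pairs_a)
    reps_b = _as_repeats(pairs_b)
    ns_a = [n_a] * len(reps_a) if np.isscalar(n_a) else list(n_a)
    ns_b = [n_b] * len(reps_b) if np.isscalar(n_b) else list(n_b)
    index_a = [{r.pair: r for r in rep} for rep in reps_a]
    index_b = [{r.pair: r for r in rep} for rep in reps_b]
    keys = [k for k in index_a[0] if all(k in d for d in index_a + index_b)]
    results: list[CorrCompareResult] = []
    for key in keys:
        deltas, ps, zero_ps = [], [], []
        comparable = True
        for (da, na), (db, nb) in itertools.product(
            zip(index_a, ns_a), zip(index_b, ns_b)
        ):
            ra, rb = da[key].rho, db[key].rho
            if np.isnan(ra) or np.isnan(rb):
                comparable = False
                continue
            if abs(ra) >= 1.0 - 1e-12 or abs(rb) >= 1.0 - 1e-12:
                comparable = False
                continue
            deltas.append(abs(ra - rb))
            ps.append(fisher_z_test(ra, na, rb, nb)[1])
        for da, na in zip(index_a, ns_a):
            ra = da[key].rho
            if np.isnan(ra) or abs(ra) >= 1.0 - 1e-12:
                continue
            z0 = np.arctanh(ra) * np.sqrt(na - 3)
            zero_ps.append(float(2.0 * stats.norm.sf(abs(z0))))
        results.append(
            CorrCompareResult(
                site_a=key[0], site_b=key[1],
                min_abs_delta_rho=float(min(deltas)) if deltas else np.nan,
                max_p=float(max(ps)) if ps else np.nan,
                zero_p=float(max(zero_ps)) if zero_ps else np.nan,
                comparable=comparable and bool(deltas),
            )
        )
    qs = bh_qvalues([r.max_p for r in results])
    zero_qs = bh_qvalues([r.zero_p for r in results])
    for r, q, zq in zip(results, qs, zero_qs):
        r.q = float(q)
        r.zero_q = float(zq)
        r.star = bool(r.comparable and q < alpha and zq < alpha)
    return results


def correlation_table(
    pairs: list[CorrPairResult],
    compared: list[CorrCompareResult] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "site_a": [r.site_a for r in pairs],
            "site_b": [r.site_b for r in pairs],
            "rho": [r.rho for r in pairs],
            "n": [r.n for r in pairs],
            "p": [r.p for r in pairs],
            "q": [r.q for r in pairs],
        }
    )
    if compared is not None:
        cmp_index = {(c.site_a, c.site_b): c for c in compared}
        df["delta_rho"] = [
            cmp_index.get((a, b), CorrCompareResult(a, b, np.nan, np.nan)).min_abs_delta_rho
            for a, b in zip(df["site_a"], df["site_b"])
        ]
        df["compare_p"] = [
            cmp_index.get((a, b), CorrCompareResult(a, b, np.nan, np.nan)).max_p
            for a, b in zip(df["site_a"], df["site_b"])
        ]
        df["compare_q"] = [
            cmp_index.get((a, b), CorrCompareResult(a, b, np.nan, np.nan)).q
            for a, b in zip(df["site_a"], df["site_b"])
        ]
        df["star"] = [
            cmp_index.get((a, b), CorrCompareResult(a, b, np.nan, np.nan)).star
            for a, b in zip(df["site_a"], df["site_b"])
        ]
    return df


# -- Empirical Brown's method ------------------------------------------------

@dataclass
class BrownResult:
    p: float
    scale: float       # c: chi-square rescaling factor
    dof: float         # f: effective degrees of freedom
    fisher_p: float    # the independence-assuming combination, for reference


def fishers_method(pvalues: Sequence[float]) -> float:
    p = np.asarray(pvalues, dtype=float)
    stat = float(-2.0 * np.log(p).sum())
    return float(stats.chi2.sf(stat, 2 * p.size))


def empirical_browns(
    pvalues: Sequence[float],
    data: np.ndarray,
    covariance: np.ndarray | None = None,
) -> BrownResult:
    """Combine m dependent p-values using an empirically re-scaled chi-square.

    ``data`` is the reads x m matrix of per-read quantities underlying each
    test (here: the per-site probability columns).  Each column is transformed
    through its empirical right-tail probability, w = -2 ln P(X >= x); the
    covariance of the transformed columns inflates the variance of Fisher's
    statistic T = sum(-2 ln p_i), which is then referred to a chi-square with
    f = 2E^2/Var degrees of freedom after rescaling by c = Var/(2E), E = 2m.
    With a zero covariance (independent columns) this reduces exactly to
    Fisher's method.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 1:
        raise ValueError("need at least one p-value")
    tiny = np.finfo(float).tiny
    if (p <= 0).any():
        log.warning("p-value of 0 clipped to machine minimum")
        p = np.clip(p, tiny, 1.0)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != m:
        raise ValueError(f"data must be (reads, {m})")
    n = X.shape[0]
    if covariance is None:
        W = np.empty_like(X)
        for j in range(m):
            col = X[:, j]
            # empirical right-tail probability P(X >= x), in [1/n, 1]
            ge = n - np.searchsorted(np.sort(col), col, side="left")
            W[:, j] = -2.0 * np.log(ge / n)
        cov = np.cov(W, rowvar=False)
        cov = np.atleast_2d(cov)
    else:
        cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    expected = 2.0 * m
    var = 4.0 * m + 2.0 * sum(
        cov[i, j] for i, j in itertools.combinations(range(m), 2)
    )
    var = max(var, 1e-12)
    f = 2.0 * expected**2 / var
    c = var / (2.0 * expected)
    t = float(-2.0 * np.log(p).sum())
    return BrownResult(
        p=float(stats.chi2.sf(t / c, f)),
        scale=float(c),
        dof=float(f),
        fisher_p=fishers_method(p),
    )
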