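"""Per-tile two-group differential methylation testing and DMT calling.

Two tests are provided:

``logistic``
    Binomial logistic regression of methylated counts on the group label
    across replicates, with a likelihood-ratio test against the intercept-only
    model. Because group membership is the only covariate the maximum
    likelihood fit is analytic — the fitted proportion of each group is its
    pooled count proportion — so the statistic is computed in closed form and
    vectorised over tiles:

        G = 2 [ ll(mF, tF, pF) + ll(mM, tM, pM) − ll(mF+mM, tF+tM, p0) ]

    with ll the binomial log-likelihood kernel and p the pooled proportions;
    G ~ χ²(1) under the null. This is the replicate-aware test methylKit's
    logistic mode reduces to for a two-group design.

``fisher-pooled``
    Counts pooled within group and a two-sided Fisher exact test on the 2×2
    table. Exact for single-replicate groups and a useful cross-check, but it
    ignores replicate structure.

The methylation difference is always the pooled-count percentage difference,
oriented first-group minus second-group, so with groups ("female", "male") a
positive difference means hypermethylation in females.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .tiling import TileMatrix

TEST_METHODS = ("logistic", "fisher-pooled")


@dataclass(frozen=True)
class DMTCall:
    """One differentially methylated tile passing both calling thresholds."""

    chrom: str
    start: int
    end: int
    meth_diff: float  # signed percentage points, group1 − group2
    p: float
    q: float
    direction: str  # "<group1>-hyper" if meth_diff > 0 else "<group2>-hyper"


def _binom_ll(m, t, p):
    # log-likelihood kernel; xlogy handles the p∈{0,1} boundary (0·log0 = 0)
    return xlogy(m, p) + xlogy(t - m, 1.0 - p)


def logistic_lrt(m1, t1, m2, t2):
    """Vectorised closed-form binomial LRT for a two-group design.

    Arguments are pooled per-group methylated / total counts (arrays or
    scalars). Returns (p_values, meth_diff in percentage points).
    """
    m1 = np.asarray(m1, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    p1 = np.divide(m1, t1, out=np.zeros_like(m1), where=t1 > 0)
    p2 = np.divide(m2, t2, out=np.zeros_like(m2), where=t2 > 0)
    p0 = (m1 + m2) / (t1 + t2)
    stat = 2.0 * (_binom_ll(m1, t1, p1) + _binom_ll(m2, t2, p2) - _binom_ll(m1 + m2, t1 + t2, p0))
    stat = np.maximum(stat, 0.0)  # guard tiny negative round-off
    pvals = stats.chi2.sf(stat, df=1)
    return pvals, 100.0 * (p1 - p2)


def fisher_pooled(m1, t1, m2, t2):
    """Two-sided Fisher exact test on the pooled 2×2 table (scalar)."""
    table = np.array([[m1, t1 - m1], [m2, t2 - m2]], dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    p1 = m1 / t1 if t1 > 0 else 0.0
    p2 = m2 / t2 if t2 > 0 else 0.0
    return p, 100.0 * (p1 - p2)


def test_tile(counts_group1, counts_group2, method: str = "logistic"):
    """Test one tile. ``counts_group*`` are per-sample (n_meth, n_total) pairs.

    Returns (p_value, meth_diff). Requires at least one sample with reads in
    each group; otherwise the test is undefined and a ValueError is raised.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {TEST_METHODS}")
    a = np.asarray(counts_group1, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(counts_group2, dtype=np.int64).reshape(-1, 2)
    m1, t1 = a[:, 0].sum(), a[:, 1].sum()
    m2, t2 = b[:, 0].sum(), b[:, 1].sum()
    if t1 == 0 or t2 == 0:
        raise ValueError("a group has zero total reads; the tile test is undefined")
    if method == "logistic":
        p, d = logistic_lrt(m1, t1, m2, t2)
        return float(p), float(d)
    return fisher_pooled(m1, t1, m2, t2)


def adjust_q(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def tile_statistics(
    tm: TileMatrix,
    method: str = "logistic",
    group_order=("female", "male"),
) -> pd.DataFrame:
    """Per-tile statistics for every tile of the matrix.

    Returns a frame with chrom, start, end, meth_diff, p, q, direction and a
    boolean ``tested`` column; untestable tiles (a group with zero pooled
    reads) get NaN statistics and tested=False but stay in the table so the
    enrichment universe is explicit.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {TEST_METHODS}")
    g1, g2 = group_order
    idx1, idx2 = tm.sample_indices(g1), tm.sample_indices(g2)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError(f"each group needs >=1 sample; got {idx1.size} {g1!r}, {idx2.size} {g2!r}")
    m1 = tm.meth[:, idx1].sum(axis=1)
    t1 = tm.total[:, idx1].sum(axis=1)
    m2 = tm.meth[:, idx2].sum(axis=1)
    t2 = tm.total[:, idx2].sum(axis=1)
    tested = (t1 > 0) & (t2 > 0)

    pvals = np.full(tm.n_tiles, np.nan)
    diffs = np.full(tm.n_tiles, np.nan)
    if method == "logistic":
        pv, dv = logistic_lrt(m1[tested], t1[tested], m2[tested], t2[tested])
        pvals[tested], diffs[tested] = pv, dv
    else:
        for i in np.flatnonzero(tested):
            pvals[i], diffs[i] = fisher_pooled(m1[i], t1[i], m2[i], t2[i])

    qvals = np.full(tm.n_tiles, np.nan)
    qvals[tested] = adjust_q(pvals[tested])
    out = tm.tiles.copy()
    out["meth_diff"] = diffs
    out["p"] = pvals
    out["q"] = qvals
    out["direction"] = np.where(diffs > 0, f"{g1}-hyper", f"{g2}-hyper")
    out.loc[~tested, "direction"] = ""
    out["tested"] = tested
    return out


def call_dmts(
    tm: TileMatrix,
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
    method: str = "logistic",
    group_order=("female", "male"),
    strict_q: bool = False,
):
    """Call differentially methylated tiles at the given thresholds.

    A tile is called when |meth_diff| >= diff_threshold and q <= q_threshold
    (strictly below with ``strict_q``). Returns ``(calls, stats)`` where
    ``stats`` is the full per-tile table from :func:`tile_statistics` — the
    universe for downstream enrichment — and ``calls`` its passing subset.
    """
    stats_df = tile_statistics(tm, method=method, group_order=group_order)
    tested = stats_df["tested"].to_numpy()
    absdiff = np.abs(stats_df["meth_diff"].to_numpy())
    q = stats_df["q"].to_numpy()
    q_ok = (q < q_threshold) if strict_q else (q <= q_threshold)
    pass_mask = tested & (absdiff >= diff_threshold) & q_ok
    calls = (
        stats_df.loc[pass_mask, ["chrom", "start", "end", "meth_diff", "p", "q", "direction"]]
        .reset_index(drop=True)
    )
    return calls, stats_df
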