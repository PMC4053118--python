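"""Significance Analysis of Microarrays (two-class unpaired) with
permutation-estimated FDR, and signature extraction.

The per-gene statistic is a moderated t:

    d_i = (mean_1 - mean_2) / (s_i + s0)

with s_i the pooled standard error over both classes and s0 a small
"exchangeability" constant that stops low-variance genes from dominating.
Significance is judged against permutation expected order statistics: a
gene at sorted position (i) is called when d_(i) deviates from the
permutation mean d-bar_(i) by more than a threshold delta, and the false
discovery rate at each delta is the median permutation false-call count
over the observed call count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import as_generator
from .containers import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class SamResult:
    """SAM statistics, the delta table, and the significance calls."""

    gene_ids: pd.Index
    d: np.ndarray
    s: np.ndarray
    s0: float
    fold_change: np.ndarray            # linear scale, 2^(mean1 - mean2)
    class_order: tuple                 # (class of interest, reference)
    delta_table: pd.DataFrame | None = None   # delta, n_called, median_false, fdr
    called: np.ndarray | None = None
    chosen_delta: float | None = None
    target_fdr: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    # permutation artifacts needed to re-call at a new delta
    _dbar: np.ndarray | None = field(default=None, repr=False)
    _perm_d: np.ndarray | None = field(default=None, repr=False)

    @property
    def log2_fold(self) -> np.ndarray:
        return np.log2(self.fold_change)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "gene_id": self.gene_ids,
            "d": self.d,
            "s": self.s,
            "fold_change": self.fold_change,
        })
        if self.called is not None:
            out["called"] = self.called
        return out


def _class_split(matrix: ExpressionMatrix):
    """Column indices of (class of interest, reference).

    The class of interest is the first label in sorted order unless the
    labels are the derivation pair {migratory, average}, where migratory
    is always the class of interest.
    """
    c1, c2 = matrix.classes()
    if {c1, c2} == {"migratory", "average"}:
        c1, c2 = "migratory", "average"
    labels = matrix.class_labels.loc[matrix.values.columns].to_numpy()
    idx1 = np.flatnonzero(labels == c1)
    idx2 = np.flatnonzero(labels == c2)
    return (c1, c2), idx1, idx2


def _d_statistic(values: np.ndarray, idx1, idx2, s0: float):
    """d, s and mean difference for a two-class split of the columns."""
    x1, x2 = values[:, idx1], values[:, idx2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    diff = m1 - m2
    return diff / (s + s0), s, diff


def _choose_s0(values, idx1, idx2, n_windows: int = 0) -> float:
    """Percentile-of-s grid s0 minimizing the coefficient of variation of
    the MAD of d across s-quantile windows (the standard SAM tuning rule).
    """
    _, s, diff = _d_statistic(values, idx1, idx2, 0.0)
    n = len(s)
    if n_windows <= 0:
        n_windows = int(np.clip(n // 20, 5, 100))
    qs = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(qs[1:-1], s, side="right"), 0, n_windows - 1)
    candidates = np.quantile(s, np.linspace(0.0, 1.0, 21))
    best_s0, best_cv = float(np.median(s)), np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = np.array([
            np.median(np.abs(d[window == wdw] - np.median(d[window == wdw])))
            for wdw in range(n_windows) if np.any(window == wdw)
        ])
        mads = mads / 0.6745
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistics(matrix: ExpressionMatrix, s0="auto") -> SamResult:
    """Compute per-gene SAM d statistics, pooled SEs, and fold changes.

    ``s0``: "auto" (CV-of-MAD percentile rule), "median" (median of s), or
    a non-negative number.  Fold change is 2^(mean difference) on log2
    input, class of interest over reference.
    """
    (c1, c2), idx1, idx2 = _class_split(matrix)
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each class needs at least 2 samples")
    values = matrix.values.to_numpy(dtype=float)

    if s0 == "auto":
        s0_val = _choose_s0(values, idx1, idx2)
    elif s0 == "median":
        _, s_tmp, _ = _d_statistic(values, idx1, idx2, 0.0)
        s0_val = float(np.median(s_tmp))
    else:
        s0_val = float(s0)
        if s0_val < 0:
            raise ValueError("s0 must be >= 0")

    d, s, diff = _d_statistic(values, idx1, idx2, s0_val)
    return SamResult(
        gene_ids=matrix.gene_ids, d=d, s=s, s0=s0_val,
        fold_change=np.exp2(diff), class_order=(c1, c2),
    )


def _permutation_indices(n1: int, n2: int, n_permutations: int,
                         rng: np.random.Generator):
    """Label permutations as index arrays into the concatenated columns.

    When the number of distinct assignments of n1 labels to n1+n2 slots is
    at most ``n_permutations``, enumerate them all instead of sampling.
    """
    n = n1 + n2
    n_distinct = math.comb(n, n1)
    if n_distinct <= n_permutations:
        logger.info("enumerating all %d distinct label arrangements", n_distinct)
        perms = []
        for combo in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perms.append((np.flatnonzero(mask), np.flatnonzero(~mask)))
        return perms
    perms = []
    for _ in range(n_permutations):
        order = rng.permutation(n)
        perms.append((order[:n1], order[n1:]))
    return perms


def _delta_calls(d_sorted, dbar, delta):
    """SAM thresholding: find cut points where the sorted observed d
    leaves the band dbar +/- delta, then call everything beyond them.

    Returns (cut_low, cut_up): genes with d <= cut_low or d >= cut_up are
    called; infinities mean no cut on that side.
    """
    diff = d_sorted - dbar
    up = np.flatnonzero((diff > delta) & (d_sorted > 0))
    cut_up = d_sorted[up.min()] if up.size else np.inf
    lo = np.flatnonzero((-diff > delta) & (d_sorted < 0))
    cut_low = d_sorted[lo.max()] if lo.size else -np.inf
    return cut_low, cut_up


def sam_permutation_fdr(matrix: ExpressionMatrix, n_permutations: int = 300,
                        seed=None, s0="auto", n_delta: int = 60,
                        false_call_quantile: float = 0.5) -> SamResult:
    """Fill the delta table by label permutation.

    For each permutation the d order statistics are recomputed; their
    per-rank means form the expected order statistics.  For each delta on
    a grid, the estimated FDR is the ``false_call_quantile`` (default:
    median) permutation false-call count divided by the observed call
    count, capped at 1 and regularized to be non-increasing in delta.
    """
    if n_permutations < 25:
        raise ValueError("need at least 25 permutations")
    result = sam_statistics(matrix, s0=s0)
    (c1, c2), idx1, idx2 = _class_split(matrix)
    values = matrix.values.to_numpy(dtype=float)
    n1, n2 = len(idx1), len(idx2)
    rng = as_generator(seed)

    all_cols = np.concatenate([idx1, idx2])
    perms = _permutation_indices(n1, n2, n_permutations, rng)
    perm_d = np.empty((len(perms), matrix.n_genes))
    for i, (p1, p2) in enumerate(perms):
        d_p, _, _ = _d_statistic(values, all_cols[p1], all_cols[p2], result.s0)
        perm_d[i] = np.sort(d_p)
    dbar = perm_d.mean(axis=0)

    order = np.argsort(result.d, kind="stable")
    d_sorted = result.d[order]
    max_dev = np.max(np.abs(d_sorted - dbar))
    deltas = np.linspace(0.0, max_dev, n_delta)

    rows = []
    for delta in deltas:
        cut_low, cut_up = _delta_calls(d_sorted, dbar, delta)
        n_called = int(np.sum((result.d >= cut_up) | (result.d <= cut_low)))
        false_calls = np.sum((perm_d >= cut_up) | (perm_d <= cut_low), axis=1)
        med_false = float(np.quantile(false_calls, false_call_quantile))
        fdr = min(med_false / n_called, 1.0) if n_called > 0 else 0.0
        rows.append((float(delta), n_called, med_false, fdr))
    table = pd.DataFrame(rows, columns=["delta", "n_called", "median_false", "fdr"])
    # regularize: estimated FDR non-increasing as delta grows
    table["fdr"] = np.maximum.accumulate(table["fdr"].to_numpy()[::-1])[::-1]

    result.delta_table = table
    result.n_permutations = len(perms)
    result.seed = seed if isinstance(seed, int) else None
    result._dbar = dbar
    result._perm_d = perm_d
    return result


def call_significant(result: SamResult, target_fdr: float = 0.10) -> SamResult:
    """Choose the smallest tabulated delta with estimated FDR <= target
    and set the per-gene significance flags.
    """
    if result.delta_table is None:
        raise ValueError("run sam_permutation_fdr first")
    tab = result.delta_table
    ok = tab[tab["fdr"] <= target_fdr]
    if ok.empty:
        logger.warning("no delta reaches FDR %.3f; empty call set", target_fdr)
        result.called = np.zeros(len(result.d), dtype=bool)
        result.chosen_delta = float(tab["delta"].iloc[-1])
        result.target_fdr = target_fdr
        return result
    delta = float(ok["delta"].iloc[0])
    order = np.argsort(result.d, kind="stable")
    cut_low, cut_up = _delta_calls(result.d[order], result._dbar, delta)
    result.called = (result.d >= cut_up) | (result.d <= cut_low)
    result.chosen_delta = delta
    result.target_fdr = target_fdr
    return result


def extract_signature(result: SamResult, k: int = 80) -> GeneSignature:
    """Top-k called genes by absolute log2 fold change, ties included.

    Direction is the sign of the log2 fold (class of interest over
    reference).  If fewer than k genes are called, all are returned; ties
    in |fold| at the k-th rank expand the signature.
    """
    if result.called is None:
        raise ValueError("run call_significant first")
    idx = np.flatnonzero(result.called)
    if idx.size == 0:
        return GeneSignature(pd.DataFrame(
            columns=["gene_id", "direction", "fold_change", "rank"]))
    log2f = result.log2_fold[idx]
    if k >= idx.size:
        if k > idx.size:
            logger.info("k=%d exceeds called count %d; returning all", k, idx.size)
        chosen = idx
    else:
        absf = np.abs(log2f)
        threshold = np.sort(absf)[::-1][k - 1]
        keep = absf >= threshold - 1e-12
        if keep.sum() > k:
            logger.info("|fold| tie at rank %d expands signature to %d genes",
                        k, int(keep.sum()))
        chosen = idx[keep]

    absf = np.abs(result.log2_fold[chosen])
    order = np.lexsort((result.gene_ids[chosen], -absf))  # fold desc, id asc
    chosen = chosen[order]
    table = pd.DataFrame({
        "gene_id": result.gene_ids[chosen],
        "direction": np.where(result.log2_fold[chosen] > 0, 1, -1),
        "fold_change": result.fold_change[chosen],
        "rank": np.arange(1, len(chosen) + 1),
    })
    return GeneSignature(table)
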