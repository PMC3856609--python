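"""Minimum-FDR significance calling over asymmetric rejection regions.

Two entry points:

* :func:`minimize_fdr_at_n` — for a fixed total number of calls N, evaluate
  all N + 1 positive/negative splits (n, N − n) and return the one with the
  lowest estimated FDR.  Within a sign, a larger |d| is always more
  significant, so a split is fully described by its two counts.
* :func:`max_features` — for an FDR cut-off Ψ, scan candidate totals k from
  an upper bound M_ρ downward and return the first (hence largest) k whose
  minimized FDR is strictly below Ψ.  Because the minimized FDR at k below Ψ
  certifies k and the minimized FDR at k at-or-above Ψ rules out every split
  of k, this downward scan returns the true maximum.

Both share :func:`precompute_counts`: one-sided observed counts TP±_k and
per-permutation counts FP±_{k,b} for k = 0..M_ρ, computed once, after which
any split (n, k − n) is scored in O(B).  This is what makes the full search
O(M_ρ·M·B + M_ρ²·B) instead of O(M_ρ²·M·B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError
from .fdr import _as_pi0
from .permutation import PermutationNull, Pi0Estimate

__all__ = ["MifdrResult", "PrecomputedCounts", "precompute_counts",
           "minimize_fdr_at_n", "max_features"]


@dataclass
class MifdrResult:
    """A chosen rejection region: total calls, split, FDR and feature indices."""

    n_total: int
    n_pos: int
    n_neg: int
    fdr: float
    feature_pos: np.ndarray  # indices of the n_pos largest d-values
    feature_neg: np.ndarray  # indices of the n_neg smallest d-values

    @property
    def called(self) -> np.ndarray:
        return np.concatenate([self.feature_pos, self.feature_neg])


@dataclass
class PrecomputedCounts:
    """One-sided observed and permuted strict exceedance counts.

    ``tp_pos[k]`` counts observed d-values strictly above the (k+1)-th
    largest observed d-value (so k with distinct values); ``fp_pos[k, b]``
    counts permutation b's d-values above the same cut-off.  ``tp_neg`` /
    ``fp_neg`` mirror this below the (k+1)-th smallest.  All four families
    are nondecreasing in k.
    """

    tp_pos: np.ndarray   # (K+1,)
    tp_neg: np.ndarray   # (K+1,)
    fp_pos: np.ndarray   # (K+1, B)
    fp_neg: np.ndarray   # (K+1, B)
    tau_pos: np.ndarray  # (K+1,) positive cut-offs, descending in k
    tau_neg: np.ndarray  # (K+1,) negative cut-offs, ascending in k
    m_rho: int
    n_features: int = 0


def precompute_counts(d: np.ndarray, null: PermutationNull, m_rho: int) -> PrecomputedCounts:
    """Fill the one-sided count families for k = 0..m_rho.

    ``m_rho`` must satisfy 1 ≤ m_rho ≤ M; cut-offs for k = M are the infinite
    sentinels (every feature on that side called).
    """
    d = np.asarray(d, float)
    m = d.shape[0]
    if not 1 <= m_rho <= m:
        raise DataValidationError("m_rho must lie in [1, M]")
    d_sorted = np.sort(d, kind="stable")
    ks = np.arange(m_rho + 1)
    tau_pos = np.where(ks < m, d_sorted[np.minimum(m - 1 - ks, m - 1)], -np.inf)
    tau_neg = np.where(ks < m, d_sorted[np.minimum(ks, m - 1)], np.inf)

    # observed one-sided counts against each cut-off (strict)
    tp_pos = m - np.searchsorted(d_sorted, tau_pos, side="right")
    tp_neg = np.searchsorted(d_sorted, tau_neg, side="left")

    # permuted one-sided counts: cut-offs are monotone in k, so one
    # searchsorted per permutation row covers every k at once
    srt = null.sorted_d_hat
    b, m_null = srt.shape
    fp_pos = np.empty((m_rho + 1, b), dtype=np.int64)
    fp_neg = np.empty((m_rho + 1, b), dtype=np.int64)
    tau_pos_asc = tau_pos[::-1]  # ascending
    for j in range(b):
        fp_pos[:, j] = (m_null - np.searchsorted(srt[j], tau_pos_asc, side="right"))[::-1]
        fp_neg[:, j] = np.searchsorted(srt[j], tau_neg, side="left")
    return PrecomputedCounts(tp_pos=tp_pos, tp_neg=tp_neg, fp_pos=fp_pos,
                             fp_neg=fp_neg, tau_pos=tau_pos, tau_neg=tau_neg,
                             m_rho=m_rho, n_features=m)


def best_split_at(counts: PrecomputedCounts, k: int,
                  pi0: float | Pi0Estimate) -> tuple[int, float] | None:
    """Best positive count n for total k: (n*, min capped FDR), or None.

    Splits whose realized call count is zero (possible only under heavy ties)
    are skipped, as are splits calling every feature on one side (no observed
    order statistic anchors such a cut-off); exact FDR ties go to the
    smallest n.  Returns None when no split is evaluable.
    """
    if k > counts.m_rho:
        raise DataValidationError("k exceeds the precomputed range")
    p0 = _as_pi0(pi0)
    fp = counts.fp_pos[: k + 1] + counts.fp_neg[k::-1]
    tp = counts.tp_pos[: k + 1] + counts.tp_neg[k::-1]
    med = np.median(fp, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cfdr = np.minimum(1.0, med * p0 / tp)
    ns = np.arange(k + 1)
    invalid = (tp == 0) | (ns >= counts.n_features) | (k - ns >= counts.n_features)
    # crossed cut-offs (possible only when k = M and the boundary values are
    # distinct) would double-count permuted values between them
    invalid |= counts.tau_pos[: k + 1] < counts.tau_neg[k::-1]
    cfdr[invalid] = np.inf
    n = int(np.argmin(cfdr))  # first minimum -> smallest n_pos
    if not np.isfinite(cfdr[n]):
        return None
    return n, float(cfdr[n])


def _features_for_split(d: np.ndarray, n_pos: int, n_neg: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the n_pos largest / n_neg smallest d (stable ties by index)."""
    order = np.argsort(d, kind="stable")
    m = d.shape[0]
    feature_pos = order[m - n_pos:][::-1] if n_pos else np.empty(0, dtype=int)
    feature_neg = order[:n_neg] if n_neg else np.empty(0, dtype=int)
    return feature_pos.copy(), feature_neg


def minimize_fdr_at_n(d: np.ndarray, null: PermutationNull, pi0: float | Pi0Estimate,
                      n: int, counts: PrecomputedCounts | None = None) -> MifdrResult:
    """Minimize the estimated FDR over all splits of N = n total calls.

    Equivalent by construction to a brute-force scan of
    ``estimate_fdr(d, null, pi0, a, n - a)`` for a = 0..n, with exact ties
    broken toward the smaller positive count.
    """
    d = np.asarray(d, float)
    if not 1 <= n <= d.shape[0]:
        raise DataValidationError("N must lie in [1, M]")
    if counts is None:
        counts = precompute_counts(d, null, n)
    best = best_split_at(counts, n, pi0)
    if best is None:
        raise DataValidationError("no split of N has a nonzero realized call count")
    n_pos, fdr = best
    feature_pos, feature_neg = _features_for_split(d, n_pos, n - n_pos)
    return MifdrResult(n_total=n, n_pos=n_pos, n_neg=n - n_pos, fdr=fdr,
                       feature_pos=feature_pos, feature_neg=feature_neg)


def max_features(d: np.ndarray, null: PermutationNull, pi0: float | Pi0Estimate,
                 psi: float, m_rho: int = 1000,
                 counts: PrecomputedCounts | None = None) -> MifdrResult | None:
    """Largest N whose minimized estimated FDR is strictly below psi.

    Scans k = min(m_rho, M) down to 1 and returns the first qualifying k with
    its minimizing split, or None when no k qualifies.
    """
    d = np.asarray(d, float)
    if not 0.0 < psi < 1.0:
        raise DataValidationError("psi must lie strictly between 0 and 1")
    k_max = min(int(m_rho), d.shape[0])
    if k_max < 1:
        raise DataValidationError("m_rho must be at least 1")
    if counts is None or counts.m_rho < k_max:
        counts = precompute_counts(d, null, k_max)
    for k in range(k_max, 0, -1):
        best = best_split_at(counts, k, pi0)
        if best is None:
            continue
        n_pos, fdr = best
        if fdr < psi:
            feature_pos, feature_neg = _features_for_split(d, n_pos, k - n_pos)
            return MifdrResult(n_total=k, n_pos=n_pos, n_neg=k - n_pos, fdr=fdr,
                               feature_pos=feature_pos, feature_neg=feature_neg)
    return None
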