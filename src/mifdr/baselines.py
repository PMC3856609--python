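"""Baseline significance-calling procedures.

* Benjamini–Hochberg step-up on p-values (assumes π0 = 1);
* Storey's procedure: plug-in π̂0 from the λ tail, q-values, reject q ≤ α;
* SAM's Δ-threshold selection: cut-offs located where the gap between the
  sorted observed d-values and their expected null order statistics first
  reaches ±Δ0, plus a grid search over Δ0 for the largest call count whose
  estimated FDR stays below a cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import DataValidationError
from .fdr import FdrEstimate, RejectionRegion, count_exceedances, estimate_fdr_for_region
from .permutation import PermutationNull, Pi0Estimate, delta_values

__all__ = ["BaselineResult", "bh_select", "storey_select",
           "sam_delta_select", "sam_max_features", "default_delta_grid"]


@dataclass
class BaselineResult:
    method: str
    called: np.ndarray
    threshold_used: float | None
    auxiliary: dict = field(default_factory=dict)

    @property
    def n_called(self) -> int:
        return int(self.called.shape[0])


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return p


def bh_select(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up: indices of rejected hypotheses.

    Rejects hypotheses 1..i for the largest rank i with p_(i) ≤ i·α/M
    (non-strict at the boundary).
    """
    p = _check_p(p)
    if not 0.0 < alpha < 1.0:
        raise DataValidationError("alpha must lie strictly between 0 and 1")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return np.flatnonzero(reject)


def storey_select(p: np.ndarray, alpha: float, lam: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Storey selection: (rejected indices, q-values).

    π̂0 = min(1, #{p_i > λ} / ((1 − λ)·M)), floored at 1/M when zero.
    q_(i) = min_{j ≥ i} π̂0·M·p_(j)/j (cumulative minimum from the largest
    rank down, capped at 1); reject q ≤ α.
    """
    p = _check_p(p)
    if not 0.0 < alpha < 1.0:
        raise DataValidationError("alpha must lie strictly between 0 and 1")
    if not 0.0 < lam < 1.0:
        raise DataValidationError("lambda must lie strictly between 0 and 1")
    m = p.shape[0]
    pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    if pi0 == 0.0:
        pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    raw = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return np.flatnonzero(q <= alpha), q


def sam_delta_select(d: np.ndarray, null: PermutationNull, delta0: float) -> RejectionRegion:
    """SAM's Δ-threshold cut-offs for a given Δ0 > 0.

    Walking the sorted observed d-values upward, τ+ is the d-value of the
    first feature whose Δ reaches Δ0; walking downward, τ− is the d-value of
    the first feature whose Δ reaches −Δ0.  A side with no qualifying feature
    is empty: its cut-off anchors at the extreme observed d-value, so no
    observed feature is called there but permuted values beyond the observed
    range still count as false positives — the same boundary convention the
    count-anchored regions use, which keeps every Δ-selected region a special
    case of a (N+, N−) split.  The region boundaries are strict, so the
    boundary feature itself is not called; the returned counts are the
    realized strict exceedance counts.
    """
    if delta0 <= 0:
        raise DataValidationError("delta0 must be positive")
    d = np.asarray(d, float)
    d_sorted = np.sort(d, kind="stable")
    delta = d_sorted - null.expected_order_stats
    up = np.flatnonzero(delta >= delta0)
    tau_pos = float(d_sorted[up[0]]) if up.size else float(d_sorted[-1])
    down = np.flatnonzero(delta <= -delta0)
    tau_neg = float(d_sorted[down[-1]]) if down.size else float(d_sorted[0])
    if tau_neg > tau_pos:  # overlapping sides can only arise in pathological nulls
        tau_neg = float(d_sorted[0])
    n_pos, n_neg = count_exceedances(d, tau_pos, tau_neg)
    return RejectionRegion(n_pos=n_pos, n_neg=n_neg, tau_pos=tau_pos, tau_neg=tau_neg)


def default_delta_grid(d: np.ndarray, null: PermutationNull, size: int = 100) -> np.ndarray:
    """Log-spaced Δ0 grid between the smallest and largest positive |Δ|."""
    mag = np.abs(delta_values(d, null))
    mag = mag[mag > 0]
    if mag.size == 0:
        return np.empty(0)
    lo, hi = float(mag.min()), float(mag.max())
    if lo == hi:
        return np.array([lo])
    return np.geomspace(lo, hi, size)


def sam_grid_scan(d: np.ndarray, null: PermutationNull, pi0: float | Pi0Estimate,
                  delta_grid: np.ndarray) -> list[tuple[float, RejectionRegion, FdrEstimate]]:
    """Evaluate the Δ grid: (Δ0, region, FDR estimate) for nonempty regions."""
    out = []
    for delta0 in np.asarray(delta_grid, float):
        region = sam_delta_select(d, null, float(delta0))
        if region.n_pos + region.n_neg == 0:
            continue
        est = estimate_fdr_for_region(d, null, pi0, region)
        out.append((float(delta0), region, est))
    return out


def sam_max_features(d: np.ndarray, null: PermutationNull, pi0: float | Pi0Estimate,
                     psi: float, delta_grid: np.ndarray | None = None) -> BaselineResult:
    """Largest call count achievable by some Δ0 with estimated FDR < psi.

    The grid approximates the continuum of Δ0 values a SAM user would try by
    hand; qualifying regions compete on call count, ties going to the lower
    estimated FDR.  With no qualifying region the result calls nothing.
    """
    if not 0.0 < psi < 1.0:
        raise DataValidationError("psi must lie strictly between 0 and 1")
    d = np.asarray(d, float)
    if delta_grid is None:
        delta_grid = default_delta_grid(d, null)
    best: tuple[int, float, float, RejectionRegion, FdrEstimate] | None = None
    for delta0, region, est in sam_grid_scan(d, null, pi0, delta_grid):
        if est.fdr >= psi:
            continue
        ncalled = est.tp_pos + est.tp_neg
        if best is None or (ncalled, -est.fdr) > (best[0], -best[1]):
            best = (ncalled, est.fdr, delta0, region, est)
    if best is None:
        return BaselineResult(method="SAM_delta", called=np.empty(0, dtype=int),
                              threshold_used=None, auxiliary={"fdr": None})
    _, fdr, delta0, region, est = best
    order = np.argsort(d, kind="stable")
    m = d.shape[0]
    called = np.concatenate([
        order[m - est.tp_pos:][::-1] if est.tp_pos else np.empty(0, dtype=int),
        order[: est.tp_neg],
    ])
    return BaselineResult(method="SAM_delta", called=called, threshold_used=delta0,
                          auxiliary={"fdr": fdr, "region": region,
                                     "n_pos": est.tp_pos, "n_neg": est.tp_neg})
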