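"""FDR estimation for an asymmetric rejection region.

A rejection region is the set Γ(τ+, τ−) = {d : d > τ+ or d < τ−} with strict
boundaries.  When the region is specified by counts (N+, N−), the cut-offs
are observed order statistics: τ+ is the (N+ + 1)-th largest observed d-value
and τ− the (N− + 1)-th smallest, so with distinct d-values exactly N+ and N−
features fall strictly beyond them.  The false-positive count of each
permutation is the number of its d-values inside the region, and

    FDR = median_b(FP+_b + FP−_b) · π0 / (TP+ + TP−),   capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError
from .permutation import PermutationNull, Pi0Estimate

__all__ = ["RejectionRegion", "FdrEstimate", "count_exceedances",
           "estimate_fdr", "estimate_fdr_for_region", "region_from_counts"]


@dataclass
class RejectionRegion:
    """Γ(τ+, τ−) together with the nominal call counts that induced it."""

    n_pos: int
    n_neg: int
    tau_pos: float  # +inf means the positive side is empty
    tau_neg: float  # -inf means the negative side is empty

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise DataValidationError("call counts must be nonnegative")


@dataclass
class FdrEstimate:
    """Estimated FDR of a region, with its observed/permuted counts."""

    region: RejectionRegion
    tp_pos: int
    tp_neg: int
    fp_median: float
    pi0: float
    fdr: float


def _as_pi0(pi0: float | Pi0Estimate) -> float:
    return float(pi0.pi0) if isinstance(pi0, Pi0Estimate) else float(pi0)


def count_exceedances(values: np.ndarray, tau_pos: float, tau_neg: float) -> tuple[int, int]:
    """Strict exceedance counts (#{v > τ+}, #{v < τ−}).

    Values exactly equal to a cut-off are *not* counted — the region
    boundaries are open.
    """
    if tau_neg > tau_pos:
        raise DataValidationError("tau_neg must not exceed tau_pos")
    values = np.asarray(values, float)
    return int(np.count_nonzero(values > tau_pos)), int(np.count_nonzero(values < tau_neg))


def region_from_counts(d: np.ndarray, n_pos: int, n_neg: int) -> RejectionRegion:
    """Cut-offs from the sorted observed d-values for nominal counts (N+, N−).

    τ+ = (N+ + 1)-th largest observed d; τ− mirrors it on the negative side.
    A side calling every feature (count = M) has no observed order statistic
    to anchor its cut-off and is rejected — its strict region would also
    swallow the other side.
    """
    d_sorted = np.sort(np.asarray(d, float), kind="stable")
    m = d_sorted.shape[0]
    if not (0 <= n_pos < m and 0 <= n_neg < m):
        raise DataValidationError(
            "one-sided call counts must lie in [0, M-1] (no anchoring cut-off "
            "exists for a side that calls every feature)"
        )
    tau_pos = float(d_sorted[m - 1 - n_pos])
    tau_neg = float(d_sorted[n_neg])
    return RejectionRegion(n_pos=n_pos, n_neg=n_neg, tau_pos=tau_pos, tau_neg=tau_neg)


def _fp_per_permutation(null: PermutationNull, tau_pos: float, tau_neg: float) -> np.ndarray:
    """Strict in-region counts for every permutation row (uses sorted rows)."""
    srt = null.sorted_d_hat
    m = srt.shape[1]
    above = m - np.array([np.searchsorted(row, tau_pos, side="right") for row in srt])
    below = np.array([np.searchsorted(row, tau_neg, side="left") for row in srt])
    return above + below


def estimate_fdr_for_region(d: np.ndarray, null: PermutationNull,
                            pi0: float | Pi0Estimate, region: RejectionRegion) -> FdrEstimate:
    """Estimate the FDR of an explicit rejection region.

    Realized true-positive counts come from the observed d-values (strict
    boundaries, so under ties they may fall short of the nominal counts);
    ``fp_median`` is the median over permutations of the combined in-region
    count, with the midpoint convention for even B.
    """
    d = np.asarray(d, float)
    tp_pos, tp_neg = count_exceedances(d, region.tau_pos, region.tau_neg)
    tp = tp_pos + tp_neg
    if tp == 0:
        raise DataValidationError("FDR undefined: the region contains no observed d-value")
    fp = _fp_per_permutation(null, region.tau_pos, region.tau_neg)
    fp_median = float(np.median(fp))
    p0 = _as_pi0(pi0)
    fdr = min(1.0, fp_median * p0 / tp)
    return FdrEstimate(region=region, tp_pos=tp_pos, tp_neg=tp_neg,
                       fp_median=fp_median, pi0=p0, fdr=fdr)


def estimate_fdr(d: np.ndarray, null: PermutationNull, pi0: float | Pi0Estimate,
                 n_pos: int, n_neg: int) -> FdrEstimate:
    """Estimate the FDR of the region calling the N+ largest / N− smallest d.

    Requires 1 ≤ N+ + N− ≤ M.
    """
    d = np.asarray(d, float)
    if n_pos + n_neg < 1:
        raise DataValidationError("at least one feature must be called")
    if n_pos + n_neg > d.shape[0]:
        raise DataValidationError("cannot call more features than exist")
    return estimate_fdr_for_region(d, null, pi0, region_from_counts(d, n_pos, n_neg))
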