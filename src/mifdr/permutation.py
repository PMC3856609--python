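"""Permutation null distribution of the corrected statistic.

Group labels are permuted over samples; for each permuted labeling the
components (r, s) are recomputed and divided by ``s + s0`` with the fudge
factor taken **once** from the original labeling, so observed and null
d-values share one scale.  Small designs are handled exactly: when the number
of distinct labelings C(W, N_X) is at most B every labeling is enumerated;
when it is at most 10·B distinct labelings are sampled without replacement;
otherwise labelings are drawn independently and uniformly.

The null also carries the per-permutation sorted d-values and their column
means E[d̂*_i] (the expected order statistics behind SAM's Δ-values), and the
Storey-style estimate of the true-null proportion π0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .dataio import ExpressionDataset
from .dstats import components, select_s0
from .errors import DataValidationError

__all__ = ["PermutationNull", "Pi0Estimate", "generate_null", "estimate_pi0", "delta_values"]


@dataclass
class PermutationNull:
    """B × M matrix of permuted d-values and derived order statistics."""

    d_hat: np.ndarray                 # (B, M) permuted d-values
    B: int
    seed: int | None
    sorted_d_hat: np.ndarray          # each row sorted ascending
    expected_order_stats: np.ndarray  # column means of sorted_d_hat, length M
    labelings: np.ndarray | None = None  # (B, W) bool, True where sample plays X
    s0: float | None = None
    mode: str = "auto"

    @classmethod
    def from_d_hat(cls, d_hat: np.ndarray, seed: int | None = None,
                   s0: float | None = None) -> "PermutationNull":
        """Build a null directly from a matrix of permuted d-values."""
        d_hat = np.asarray(d_hat, dtype=float)
        if d_hat.ndim != 2 or d_hat.shape[0] < 1:
            raise DataValidationError("d_hat must be a B x M matrix with B >= 1")
        srt = np.sort(d_hat, axis=1)
        return cls(d_hat=d_hat, B=d_hat.shape[0], seed=seed, sorted_d_hat=srt,
                   expected_order_stats=srt.mean(axis=0), s0=s0)


@dataclass
class Pi0Estimate:
    """Estimated proportion of true-null features, in (0, 1]."""

    pi0: float
    window: tuple[float, float]

    def __float__(self) -> float:
        return self.pi0


def _labelings(w: int, nx: int, b: int, rng: np.random.Generator,
               mode: str) -> tuple[np.ndarray, str]:
    """Return a (b_eff, W) boolean matrix of X-group assignments."""
    n_distinct = comb(w, nx)
    if mode == "exhaustive":
        if b > n_distinct:
            raise DataValidationError(
                f"B={b} exceeds the {n_distinct} distinct labelings in exhaustive mode"
            )
        chosen = list(combinations(range(w), nx))
        used = "exhaustive"
    elif mode == "auto" and n_distinct <= b:
        chosen = list(combinations(range(w), nx))
        used = "exhaustive"
    elif n_distinct <= 10 * b and mode in ("auto", "sample"):
        all_subsets = list(combinations(range(w), nx))
        idx = rng.choice(n_distinct, size=b, replace=False)
        chosen = [all_subsets[i] for i in idx]
        used = "without_replacement"
    else:
        chosen = [tuple(rng.choice(w, size=nx, replace=False)) for _ in range(b)]
        used = "with_replacement"
    lab = np.zeros((len(chosen), w), dtype=bool)
    for row, subset in enumerate(chosen):
        lab[row, list(subset)] = True
    return lab, used


def generate_null(dataset: ExpressionDataset, statistic_kind: str = "t",
                  B: int = 100, seed: int | np.random.Generator = 0,
                  mode: str = "auto", s0: float | None = None) -> PermutationNull:
    """Generate the permutation null of the d-statistic.

    Parameters
    ----------
    mode : {"auto", "exhaustive", "sample"}
        "auto" enumerates all distinct labelings when there are at most B of
        them, samples without replacement up to 10·B, and with replacement
        beyond; "exhaustive" forces full enumeration and errors when B
        exceeds the number of distinct labelings.
    s0 : float, optional
        Fudge factor to reuse; by default it is selected from the original
        labeling and shared by every permutation.

    Fully reproducible from ``seed``.
    """
    if B < 1:
        raise DataValidationError("B must be >= 1")
    if mode not in ("auto", "exhaustive", "sample"):
        raise DataValidationError(f"unknown permutation mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    if s0 is None:
        r0, s_vec0 = components(dataset, statistic_kind)
        s0 = select_s0(r0, s_vec0)

    values = dataset.values
    m, w = values.shape
    nx = int(dataset.mask_x.sum())
    lab, used = _labelings(w, nx, B, rng, mode)
    ny = w - nx

    if statistic_kind == "t":
        lx = lab.T.astype(float)                       # (W, B)
        sums = values @ lx                             # (M, B)
        sq = (values**2) @ lx
        tot = values.sum(axis=1, keepdims=True)
        tot_sq = (values**2).sum(axis=1, keepdims=True)
        mx = sums / nx
        my = (tot - sums) / ny
        ssx = sq - nx * mx**2
        ssy = (tot_sq - sq) - ny * my**2
        # clamp tiny negative round-off in the sums of squares
        np.maximum(ssx, 0.0, out=ssx)
        np.maximum(ssy, 0.0, out=ssy)
        s_hat = np.sqrt((ssx + ssy) * (1.0 / nx + 1.0 / ny) / (w - 2))
        r_hat = mx - my
    elif statistic_kind == "ranksum":
        ranks = sps.rankdata(values, axis=1)
        r_hat = ranks @ lab.T.astype(float) - nx * (w + 1) / 2.0
        s_hat = np.full_like(r_hat, np.sqrt(nx * ny * (w + 1) / 12.0))
    else:
        raise DataValidationError(f"unknown statistic kind {statistic_kind!r}")

    denom = s_hat + s0
    if np.any(denom <= 0):
        raise DataValidationError("zero spread plus zero s0 in a permutation")
    d_hat = (r_hat / denom).T  # (B_eff, M)
    srt = np.sort(d_hat, axis=1)
    return PermutationNull(
        d_hat=d_hat, B=d_hat.shape[0], seed=seed_val, sorted_d_hat=srt,
        expected_order_stats=srt.mean(axis=0), labelings=lab, s0=float(s0), mode=used,
    )


def estimate_pi0(d: np.ndarray, null: PermutationNull,
                 window: tuple[float, float] = (0.25, 0.75)) -> Pi0Estimate:
    """Storey-style π0 from the quantile window of the pooled null.

    π0 = min(1, #{i : q_lo ≤ d_i ≤ q_hi} / ((hi - lo)·M)) where q_lo, q_hi
    are the window quantiles (linear interpolation) of all permuted d-values
    pooled together.  A zero estimate is floored at 1/M so downstream FDR
    estimates never collapse to zero identically.
    """
    d = np.asarray(d, float)
    m = d.shape[0]
    if m < 4:
        raise DataValidationError("pi0 estimation needs at least 4 features")
    lo, hi = window
    if not 0.0 <= lo < hi <= 1.0:
        raise DataValidationError("window must satisfy 0 <= lo < hi <= 1")
    q_lo, q_hi = np.quantile(null.d_hat, [lo, hi])
    frac = np.count_nonzero((d >= q_lo) & (d <= q_hi)) / ((hi - lo) * m)
    pi0 = min(1.0, float(frac))
    if pi0 == 0.0:
        pi0 = 1.0 / m
    return Pi0Estimate(pi0=pi0, window=(lo, hi))


def delta_values(d: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Δ_i = (i-th smallest observed d) − E[d̂*_i], aligned to ascending d."""
    d = np.asarray(d, float)
    if d.shape[0] != null.expected_order_stats.shape[0]:
        raise DataValidationError("observed d and null have different feature counts")
    return np.sort(d, kind="stable") - null.expected_order_stats
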