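"""SAM-style corrected test statistics.

Each feature i gets a difference score ``r_i`` and a spread ``s_i``; the
corrected statistic (*d-value*) is ``d_i = r_i / (s_i + s0)`` where the shared
*fudge factor* ``s0`` damps features whose spread estimate is unstably small.
``s0`` is picked from the pool of observed spreads (plus 0) so that the
dispersion of the d-values is as independent of the spread level as possible:
features are sorted by ``s_i`` into equal-occupancy percentile bins, the
median absolute deviation (MAD) of the d-values is taken within each bin, and
the candidate minimizing the coefficient of variation of those per-bin MADs
wins.  Classical t and Wilcoxon rank-sum p-values are also provided as inputs
for the BH/Storey baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .dataio import ExpressionDataset
from .errors import DataValidationError, DegenerateStatisticError

__all__ = [
    "DStatistics",
    "t_components",
    "ranksum_components",
    "select_s0",
    "s0_objective",
    "d_values",
    "p_values",
]


@dataclass
class DStatistics:
    """Per-feature r, s and corrected d-values plus the shared fudge factor."""

    r: np.ndarray
    s: np.ndarray
    s0: float
    d: np.ndarray
    statistic_kind: str

    @classmethod
    def compute(cls, dataset: ExpressionDataset, statistic_kind: str = "t",
                s0: float | None = None) -> "DStatistics":
        """Compute components, select s0 (unless given) and form d-values."""
        r, s = components(dataset, statistic_kind)
        if s0 is None:
            s0 = select_s0(r, s)
        return cls(r=r, s=s, s0=float(s0), d=d_values(r, s, s0),
                   statistic_kind=statistic_kind)


def components(dataset: ExpressionDataset, statistic_kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to :func:`t_components` or :func:`ranksum_components`."""
    if statistic_kind == "t":
        return t_components(dataset)
    if statistic_kind == "ranksum":
        r, s = ranksum_components(dataset)
        return r, np.full_like(r, s)
    raise DataValidationError(f"unknown statistic kind {statistic_kind!r}")


def t_components(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Unpooled difference of means and pooled-variance spread, per feature.

    r_i = mean(X_i) - mean(Y_i) and
    s_i = sqrt{ [SS_X + SS_Y] * (1/N_X + 1/N_Y) / (N_X + N_Y - 2) },
    where SS denotes the within-group sum of squared deviations.
    """
    x, y = dataset.group_matrices()
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise DataValidationError("both groups need at least 2 samples for the t form")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    ssx = ((x - mx[:, None]) ** 2).sum(axis=1)
    ssy = ((y - my[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((ssx + ssy) * (1.0 / nx + 1.0 / ny) / (nx + ny - 2))
    return mx - my, s


def ranksum_components(dataset: ExpressionDataset) -> tuple[np.ndarray, float]:
    """Centered rank-sum score and its null standard deviation.

    Measurements of each feature are merged across groups and ranked from
    lowest to highest, ties receiving average ranks.  Then
    r_i = (sum of X ranks) - N_X (N_X + N_Y + 1)/2, and the spread is the
    constant sqrt{ N_X N_Y (N_X + N_Y + 1) / 12 } — the standard deviation of
    the rank sum under the null, identical for every feature.
    """
    nx = int(dataset.mask_x.sum())
    w = dataset.n_samples
    ny = w - nx
    ranks = sps.rankdata(dataset.values, axis=1)
    r = ranks[:, dataset.mask_x].sum(axis=1) - nx * (w + 1) / 2.0
    s = float(np.sqrt(nx * ny * (w + 1) / 12.0))
    return r, s


def _binned_layout(s: np.ndarray, n_bins: int) -> tuple[np.ndarray, int, int]:
    """Stable s-ascending feature order trimmed to equal-occupancy bins.

    Returns (order, n_bins_eff, bin_size).  Bin occupancy is ``M // n_bins_eff``
    with at least 2 features per bin; the at most ``n_bins_eff - 1`` features
    with the largest s that do not fill a complete bin are left out of the
    dispersion objective.
    """
    m = s.shape[0]
    nb = max(1, min(n_bins, m // 2))
    size = m // nb
    order = np.argsort(s, kind="stable")[: nb * size]
    return order, nb, size


def s0_objective(r: np.ndarray, s: np.ndarray, candidates: np.ndarray,
                 n_bins: int = 100, chunk: int = 64) -> np.ndarray:
    """Dispersion criterion for each s0 candidate.

    For candidate c the score is the coefficient of variation, across
    s-percentile bins, of the within-bin MAD of d = r/(s + c).  Lower is
    better; degenerate candidates (zero mean MAD, or a zero denominator for
    some feature) score +inf.
    """
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    candidates = np.asarray(candidates, float)
    order, nb, size = _binned_layout(s, n_bins)
    rs, ss = r[order], s[order]
    h1, h2 = (size - 1) // 2, size // 2
    out = np.empty(candidates.shape[0])
    for i in range(0, candidates.shape[0], chunk):
        c = candidates[i : i + chunk]
        denom = ss[None, :] + c[:, None]
        bad = np.any(denom <= 0, axis=1)
        denom[denom <= 0] = np.nan
        d = (rs[None, :] / denom).reshape(len(c), nb, size)
        d.partition((h1, h2), axis=2)
        med = 0.5 * (d[:, :, h1] + d[:, :, h2])
        np.abs(d - med[:, :, None], out=d)
        d.partition((h1, h2), axis=2)
        mad = 0.5 * (d[:, :, h1] + d[:, :, h2])
        mean = mad.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = mad.std(axis=1) / mean
        cv[bad | (mean <= 0) | ~np.isfinite(cv)] = np.inf
        out[i : i + chunk] = cv
    return out


def select_s0(r: np.ndarray, s: np.ndarray, n_bins: int = 100) -> float:
    """Pick the fudge factor from the candidate pool unique{s_i} ∪ {0}.

    The candidate minimizing :func:`s0_objective` wins; exact ties go to the
    smallest candidate.  Deterministic given (r, s).

    Raises
    ------
    DegenerateStatisticError
        If every spread is zero while some r_i is nonzero, so every candidate
        would divide by zero.
    """
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    if r.shape[0] < 2:
        raise DataValidationError("select_s0 needs at least 2 features")
    if np.all(s == 0):
        if np.any(r != 0):
            raise DegenerateStatisticError(
                "degenerate spread: all s_i are zero with nonzero difference scores"
            )
        return 0.0
    candidates = np.unique(np.concatenate(([0.0], s)))  # sorted ascending
    scores = s0_objective(r, s, candidates, n_bins=n_bins)
    if not np.any(np.isfinite(scores)):
        # dispersion criterion uninformative (e.g. constant d in every bin);
        # fall back to the smallest positive candidate that keeps d defined
        ok = candidates[s.min() + candidates > 0]
        return float(ok[0]) if ok.size else 0.0
    return float(candidates[int(np.argmin(scores))])  # argmin -> smallest tie


def d_values(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """Elementwise corrected statistic d = r / (s + s0); no clipping."""
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    denom = s + s0
    if np.any(denom <= 0):
        raise DegenerateStatisticError("s_i + s0 must be positive for every feature")
    return r / denom


def p_values(dataset: ExpressionDataset, test: str = "t_two_sided") -> np.ndarray:
    """Classical per-feature p-values for the BH/Storey baselines.

    Supported tests: ``t_two_sided``, ``t_one_sided`` (alternative X > Y),
    ``ranksum_two_sided``, ``ranksum_one_sided``.  The t form uses the pooled
    variance with ``N_X + N_Y - 2`` degrees of freedom; a zero-variance
    feature with equal means gets p = 1 by convention (no evidence), with
    unequal means p = 0.  The rank-sum form uses the normal approximation with
    average ranks and the tie-corrected variance, no continuity correction.
    """
    if test.startswith("t_"):
        r, s = t_components(dataset)
        df = dataset.n_samples - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r / s
        p = np.empty_like(r)
        zero = s == 0
        if test == "t_two_sided":
            p[~zero] = 2 * sps.t.sf(np.abs(t[~zero]), df)
            p[zero] = np.where(r[zero] == 0, 1.0, 0.0)
        elif test == "t_one_sided":
            p[~zero] = sps.t.sf(t[~zero], df)
            p[zero] = np.where(r[zero] == 0, 1.0, np.where(r[zero] > 0, 0.0, 1.0))
        else:
            raise DataValidationError(f"unknown test {test!r}")
        return p
    if test.startswith("ranksum_"):
        values = dataset.values
        w = dataset.n_samples
        nx = int(dataset.mask_x.sum())
        ny = w - nx
        ranks = sps.rankdata(values, axis=1)
        rsum = ranks[:, dataset.mask_x].sum(axis=1)
        mu = nx * (w + 1) / 2.0
        # tie correction: subtract sum(t^3 - t) over tie groups per feature
        tie_term = np.zeros(values.shape[0])
        sorted_vals = np.sort(values, axis=1)
        for i in range(values.shape[0]):
            _, counts = np.unique(sorted_vals[i], return_counts=True)
            tie_term[i] = float(np.sum(counts**3 - counts))
        var = nx * ny / 12.0 * ((w + 1) - tie_term / (w * (w - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (rsum - mu) / np.sqrt(var)
        p = np.empty_like(z)
        zero = var == 0  # all samples tied: no evidence either way
        if test == "ranksum_two_sided":
            p[~zero] = 2 * sps.norm.sf(np.abs(z[~zero]))
            p[zero] = 1.0
        elif test == "ranksum_one_sided":
            p[~zero] = sps.norm.sf(z[~zero])
            p[zero] = 1.0
        else:
            raise DataValidationError(f"unknown test {test!r}")
        return np.clip(p, 0.0, 1.0)
    raise DataValidationError(f"unknown test {test!r}")
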