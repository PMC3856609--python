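"""Synthetic two-group datasets with ground truth, and the comparison study.

The default scenario mixes six feature categories over 16 samples (8 per
group): 5000 features N(0,1) in both groups, 5000 U[−3,3] in both groups
(the 10000 true nulls), plus 400 alternatives — 50 N(0,1) vs N(−2,1),
150 N(0,1) vs N(1,1), 150 U[−3,3] vs U[−2,4], 50 U[−3,3] vs U[−1.5,4.5].
Half the nulls being uniform deliberately stresses the Gaussian assumption
behind t-test p-values.

:func:`run_study` repeats the scenario, runs each method per replicate, and
aggregates (i) the number of calls at an estimated-FDR cut-off and (ii) the
estimated-FDR and true-FDR curves aligned on the number of significant
features, averaged across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import bh_select, default_delta_grid, sam_grid_scan, storey_select
from .core import best_split_at, max_features, precompute_counts, _features_for_split
from .dataio import ExpressionDataset
from .dstats import DStatistics, p_values
from .errors import DataValidationError
from .permutation import estimate_pi0, generate_null

__all__ = ["Distribution", "Category", "SimulationScenario", "default_scenario",
           "pure_null_scenario", "generate_dataset", "true_fdr", "run_study",
           "StudyCurves", "METHODS"]

METHODS = ("mifdr", "sam", "bh", "storey")


@dataclass(frozen=True)
class Distribution:
    """A per-group sampling law: normal(mean, sd) or uniform(low, high)."""

    kind: str
    a: float
    b: float

    def sample(self, rng: np.random.Generator, size: tuple[int, int]) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.a, self.b, size=size)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        raise DataValidationError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class Category:
    n_features: int
    group1: Distribution
    group2: Distribution

    @property
    def is_null(self) -> bool:
        return self.group1 == self.group2


@dataclass
class SimulationScenario:
    """A mixture of null/alternative feature categories with group sizes."""

    categories: list[Category]
    n_per_group: int = 8

    def __post_init__(self) -> None:
        if any(c.n_features <= 0 for c in self.categories):
            raise DataValidationError("category feature counts must be positive")
        if self.n_per_group < 2:
            raise DataValidationError("need at least 2 samples per group")

    @property
    def n_features(self) -> int:
        return sum(c.n_features for c in self.categories)


def default_scenario(n_per_group: int = 8) -> SimulationScenario:
    """The six-category mixture: 10000 null + 400 alternative features."""
    N, U = "normal", "uniform"
    return SimulationScenario(
        categories=[
            Category(5000, Distribution(N, 0, 1), Distribution(N, 0, 1)),
            Category(5000, Distribution(U, -3, 3), Distribution(U, -3, 3)),
            Category(50, Distribution(N, 0, 1), Distribution(N, -2, 1)),
            Category(150, Distribution(N, 0, 1), Distribution(N, 1, 1)),
            Category(150, Distribution(U, -3, 3), Distribution(U, -2, 4)),
            Category(50, Distribution(U, -3, 3), Distribution(U, -1.5, 4.5)),
        ],
        n_per_group=n_per_group,
    )


def pure_null_scenario(n_per_group: int = 8) -> SimulationScenario:
    """Only the two null categories (5000 Gaussian + 5000 uniform features)."""
    return SimulationScenario(
        categories=default_scenario().categories[:2], n_per_group=n_per_group
    )


def generate_dataset(scenario: SimulationScenario,
                     seed: int | np.random.Generator) -> tuple[ExpressionDataset, np.ndarray]:
    """Draw one dataset; returns (dataset, is_alternative mask).

    Group 1 occupies the first ``n_per_group`` columns and plays the role of
    X (first label encountered), so r = mean(group1) − mean(group2).
    Bit-reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scenario.n_per_group
    blocks, truth = [], []
    for cat in scenario.categories:
        g1 = cat.group1.sample(rng, (cat.n_features, n))
        g2 = cat.group2.sample(rng, (cat.n_features, n))
        blocks.append(np.hstack([g1, g2]))
        truth.append(np.full(cat.n_features, not cat.is_null))
    values = np.vstack(blocks)
    m = values.shape[0]
    dataset = ExpressionDataset(
        values=values,
        feature_ids=[f"f{i:06d}" for i in range(m)],
        sample_ids=[f"s{j:02d}" for j in range(2 * n)],
        labels=np.array(["group1"] * n + ["group2"] * n, dtype=object),
    )
    return dataset, np.concatenate(truth)


def true_fdr(called: np.ndarray, truth: np.ndarray) -> float:
    """Realized fraction of truth-null features among those called."""
    called = np.asarray(called, dtype=int)
    if called.size == 0:
        raise DataValidationError("true FDR is undefined for an empty call set")
    truth = np.asarray(truth, dtype=bool)
    return float(np.mean(~truth[called]))


@dataclass
class StudyCurves:
    """Replicate-level study output with averaging helpers.

    ``calls[m][r]`` is method m's call count at the cut-off in replicate r;
    ``est_fdr[m]`` / ``tru_fdr[m]`` are (replicates × len(curve_ns)) arrays of
    the estimated and true FDR when calling exactly N features (NaN where a
    method cannot realize that N), aligned on ``curve_ns``.
    """

    psi: float
    curve_ns: np.ndarray
    calls: dict[str, np.ndarray] = field(default_factory=dict)
    est_fdr: dict[str, np.ndarray] = field(default_factory=dict)
    tru_fdr: dict[str, np.ndarray] = field(default_factory=dict)
    pi0: np.ndarray | None = None

    @property
    def methods(self) -> list[str]:
        return list(self.calls)

    @property
    def replicates(self) -> int:
        return len(next(iter(self.calls.values())))

    def mean_calls(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.calls.items()}

    @staticmethod
    def _nanmean(a: np.ndarray) -> np.ndarray:
        """Column nanmean that returns NaN (silently) for all-NaN columns."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(a, axis=0)

    def mean_est_curve(self, method: str) -> np.ndarray:
        return self._nanmean(self.est_fdr[method])

    def mean_true_curve(self, method: str) -> np.ndarray:
        return self._nanmean(self.tru_fdr[method])

    def paired_difference(self, a: str = "mifdr", b: str = "sam") -> np.ndarray:
        """Per-replicate calls(a) − calls(b)."""
        return self.calls[a] - self.calls[b]

    def to_frames(self):
        """Curve and summary tables (pandas DataFrames) for TSV export."""
        import pandas as pd

        curves = pd.DataFrame({"n_called": self.curve_ns})
        for m in self.methods:
            curves[f"est_fdr_{m}"] = self.mean_est_curve(m)
            curves[f"true_fdr_{m}"] = self.mean_true_curve(m)
        summary = pd.DataFrame(
            {
                "method": self.methods,
                "mean_calls": [self.mean_calls()[m] for m in self.methods],
                "sd_calls": [float(np.std(self.calls[m], ddof=1)) if self.replicates > 1 else np.nan
                             for m in self.methods],
            }
        )
        return curves, summary


def _rep_seed_sequences(base_seed: int, rep: int) -> tuple[np.random.Generator, int]:
    """Independent per-replicate streams: (data rng, permutation seed)."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
    data_ss, perm_ss = ss.spawn(2)
    perm_seed = int(perm_ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
    return np.random.default_rng(data_ss), perm_seed


def run_study(scenario: SimulationScenario | None = None,
              methods: tuple[str, ...] = METHODS,
              replicates: int = 10, psi: float = 0.05, B: int = 100,
              base_seed: int = 0, m_rho: int = 1000,
              statistic_kind: str = "t", curve_max_n: int | None = 50,
              delta_grid_size: int = 100) -> StudyCurves:
    """Run the replicated comparison study.

    Per replicate: draw a dataset, build the d-statistics and permutation
    null once, then let every requested method pick its calls at the
    estimated-FDR cut-off ``psi``, and (when ``curve_max_n`` is set) record
    each method's estimated/true FDR when calling exactly N features for
    N = 1..curve_max_n.  Curves are averaged over replicates aligned on N.

    BH and Storey use two-sided t p-values; `statistic_kind` controls the
    permutation-based methods.
    """
    if scenario is None:
        scenario = default_scenario()
    if replicates < 1:
        raise DataValidationError("need at least one replicate")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise DataValidationError(f"unknown method name(s): {sorted(unknown)}")

    n_curve = int(curve_max_n) if curve_max_n else 0
    curve_ns = np.arange(1, n_curve + 1)
    calls = {m: np.zeros(replicates) for m in methods}
    est = {m: np.full((replicates, n_curve), np.nan) for m in methods}
    tru = {m: np.full((replicates, n_curve), np.nan) for m in methods}
    pi0s = np.zeros(replicates)

    needs_perm = ("mifdr" in methods) or ("sam" in methods)
    needs_p = ("bh" in methods) or ("storey" in methods)

    for rep in range(replicates):
        data_rng, perm_seed = _rep_seed_sequences(base_seed, rep)
        dataset, truth = generate_dataset(scenario, data_rng)
        m_feat = dataset.n_features

        if needs_perm:
            stats = DStatistics.compute(dataset, statistic_kind)
            null = generate_null(dataset, statistic_kind, B=B, seed=perm_seed, s0=stats.s0)
            pi0 = estimate_pi0(stats.d, null)
            pi0s[rep] = pi0.pi0
            k_cap = min(m_rho, m_feat)
            counts = precompute_counts(stats.d, null, k_cap)

        if "mifdr" in methods:
            res = max_features(stats.d, null, pi0, psi, m_rho=k_cap, counts=counts)
            calls["mifdr"][rep] = 0 if res is None else res.n_total
            for i, k in enumerate(curve_ns):
                if k > k_cap:
                    break
                bs = best_split_at(counts, int(k), pi0)
                if bs is None:
                    continue
                n_pos, fdr_k = bs
                est["mifdr"][rep, i] = fdr_k
                fp, fn = _features_for_split(stats.d, n_pos, int(k) - n_pos)
                tru["mifdr"][rep, i] = true_fdr(np.concatenate([fp, fn]), truth)

        if "sam" in methods:
            grid = default_delta_grid(stats.d, null, size=delta_grid_size)
            scan = sam_grid_scan(stats.d, null, pi0, grid)
            best_n = 0
            for _, region, e in scan:
                nc = e.tp_pos + e.tp_neg
                if e.fdr < psi and nc > best_n:
                    best_n = nc
            calls["sam"][rep] = best_n
            if n_curve:
                order = np.argsort(stats.d, kind="stable")
                for _, region, e in scan:
                    nc = e.tp_pos + e.tp_neg
                    if not 1 <= nc <= n_curve:
                        continue
                    i = nc - 1
                    if np.isnan(est["sam"][rep, i]) or e.fdr < est["sam"][rep, i]:
                        est["sam"][rep, i] = e.fdr
                        idx = np.concatenate([
                            order[m_feat - e.tp_pos:] if e.tp_pos else np.empty(0, int),
                            order[: e.tp_neg],
                        ])
                        tru["sam"][rep, i] = true_fdr(idx, truth)

        if needs_p:
            p = p_values(dataset, "t_two_sided")
            order_p = np.argsort(p, kind="stable")
            p_sorted = p[order_p]
            ranks = np.arange(1, m_feat + 1)
            nc_eff = min(n_curve, m_feat)
            if "bh" in methods:
                calls["bh"][rep] = bh_select(p, psi).shape[0]
                if nc_eff:
                    q = np.minimum(np.minimum.accumulate(
                        (m_feat * p_sorted / ranks)[::-1])[::-1], 1.0)
                    est["bh"][rep, :nc_eff] = q[:nc_eff]
                    tru["bh"][rep, :nc_eff] = [
                        true_fdr(order_p[:k], truth) for k in curve_ns[:nc_eff]
                    ]
            if "storey" in methods:
                sel, q = storey_select(p, psi)
                calls["storey"][rep] = sel.shape[0]
                if nc_eff:
                    est["storey"][rep, :nc_eff] = q[order_p][:nc_eff]
                    tru["storey"][rep, :nc_eff] = [
                        true_fdr(order_p[:k], truth) for k in curve_ns[:nc_eff]
                    ]

    return StudyCurves(psi=psi, curve_ns=curve_ns, calls=calls, est_fdr=est,
                       tru_fdr=tru, pi0=pi0s if needs_perm else None)
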