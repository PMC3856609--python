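"""Shared fixtures: random small instances and independent brute-force oracles.

The oracles deliberately go through :func:`mifdr.estimate_fdr` split by split
(the slow, obviously-correct route) so the precomputed-count search path is
checked against an independent enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from mifdr import DataValidationError, PermutationNull, estimate_fdr


def random_instance(rng: np.random.Generator, max_m: int = 30, max_b: int = 5):
    """A random (d, null, pi0, psi) problem; roughly half have tied values."""
    m = int(rng.integers(4, max_m + 1))
    b = int(rng.integers(1, max_b + 1))
    d = rng.normal(size=m) * rng.uniform(0.5, 2.0)
    d_hat = rng.normal(size=(b, m)) * rng.uniform(0.5, 2.0)
    if rng.random() < 0.5:  # coarse rounding manufactures ties, incl. with d_hat
        d = np.round(d, 1)
        d_hat = np.round(d_hat, 1)
    null = PermutationNull.from_d_hat(d_hat)
    pi0 = float(rng.uniform(0.2, 1.0))
    psi = float(rng.uniform(0.05, 0.9))
    return d, null, pi0, psi


def brute_force_min_split(d, null, pi0, n_total):
    """Naive scan of all (a, n_total − a) splits; ties to the smallest a."""
    best = None
    for a in range(n_total + 1):
        try:
            est = estimate_fdr(d, null, pi0, a, n_total - a)
        except DataValidationError:
            continue
        if best is None or est.fdr < best[1]:
            best = (a, est.fdr)
    return best


def brute_force_max_features(d, null, pi0, psi, m_rho=None):
    """Max N whose best split beats psi, by the naive double loop."""
    m = len(d)
    k_max = m if m_rho is None else min(m_rho, m)
    qualifying = []
    for n_total in range(1, k_max + 1):
        best = brute_force_min_split(d, null, pi0, n_total)
        if best is not None and best[1] < psi:
            qualifying.append((n_total, best[0], best[1]))
    return max(qualifying, key=lambda t: t[0]) if qualifying else None


@pytest.fixture
def make_instance():
    return random_instance


@pytest.fixture
def oracle_min_split():
    return brute_force_min_split


@pytest.fixture
def oracle_max_features():
    return brute_force_max_features


@pytest.fixture
def toy_dataset_files(tmp_path):
    """3-feature, 4-sample TSV fixture (2 samples per group) on disk."""
    matrix = tmp_path / "matrix.tsv"
    labels = tmp_path / "labels.tsv"
    matrix.write_text(
        "feature\ts1\ts2\ts3\ts4\n"
        "g1\t1.0\t3.0\t2.0\t4.0\n"
        "g2\t5.5\t5.5\t1.5\t0.5\n"
        "g3\t-1.0\t0.0\t1.0\t2.0\n"
    )
    labels.write_text("s1\tcase\ns2\tcase\ns3\tcontrol\ns4\tcontrol\n")
    return matrix, labels
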