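"""Pooled two-proportion z-tests on repression shares.

Each gene's (or miRNA–mRNA interaction's) repression mass is treated as a
share of its group's total repression.  With x1/n1 the control share and
x2/n2 the test share, the pooled proportion is

    p0 = (x1 + x2) / (n1 + n2)

and the statistic

    z = (p̂1 − p̂2) / sqrt(p0 (1 − p0) (1/n1 + 1/n2))

is referred to the standard normal, two-sided.  Repression masses are
real-valued and used as-is; the test is stated on masses, not integer
counts.  A degenerate pooled proportion (p0 in {0, 1}) leaves z undefined
(NaN) with p-value 1, which never fabricates significance.  Significance
defaults to raw p < alpha; Benjamini–Hochberg adjustment is opt-in, in
which case the q-value is thresholded instead.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ContributionTable, DifferentialTable, RepressionResult, ZTestResult

__all__ = [
    "two_proportion_z",
    "differential_repression",
    "differential_interactions",
    "bh_adjust",
]


def _pooled_z_arrays(
    x1: np.ndarray, n1: float, x2: np.ndarray, n2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Eq. core; returns (p1, p2, p0, z, p) with NaN z where degenerate."""
    p1 = x1 / n1
    p2 = x2 / n2
    p0 = (x1 + x2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(p0 * (1.0 - p0) * (1.0 / n1 + 1.0 / n2))
        z = (p1 - p2) / se
    degenerate = (p0 <= 0.0) | (p0 >= 1.0)
    z = np.where(degenerate, np.nan, z)
    p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return p1, p2, p0, z, p


def two_proportion_z(x1: float, n1: float, x2: float, n2: float) -> ZTestResult:
    """Pooled two-sample z-test for proportions on real-valued masses."""
    for name, n in (("n1", n1), ("n2", n2)):
        if not (n > 0):
            raise ValueError(f"{name} must be positive, got {n!r}")
    for name, x, n in (("x1", x1, n1), ("x2", x2, n2)):
        if x < 0 or x > n or not math.isfinite(x):
            raise ValueError(f"{name}={x!r} must lie in [0, n]")
    p1, p2, p0, z, p = _pooled_z_arrays(
        np.asarray([x1], dtype=float), float(n1), np.asarray([x2], dtype=float), float(n2)
    )
    return ZTestResult(float(p1[0]), float(p2[0]), float(p0[0]), float(z[0]), float(p[0]))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, ≥ p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _differential(
    keys,
    x1: np.ndarray,
    n1: float,
    x2: np.ndarray,
    n2: float,
    alpha: float,
    adjust: bool,
) -> DifferentialTable:
    p1, p2, p0, z, p = _pooled_z_arrays(x1, n1, x2, n2)
    q = bh_adjust(p) if len(p) else np.asarray([], dtype=float)
    significant = (q if adjust else p) < alpha
    df = pd.DataFrame(
        {
            "p_hat_1": p1,
            "p_hat_2": p2,
            "p0": p0,
            "z": z,
            "p_value": p,
            "q_value": q,
            "significant": significant,
        },
        index=keys,
    )
    return DifferentialTable(df)


def differential_repression(
    control: RepressionResult,
    test: RepressionResult,
    alpha: float = 0.05,
    adjust: bool = False,
) -> DifferentialTable:
    """Per-gene z-tests of repression share, control (group 1) vs test (group 2).

    Keys are the union of both result's genes; a gene absent from one group
    enters with x = 0 against that group's total.
    """
    if not (control.total > 0) or not (test.total > 0):
        raise ValueError("both groups must have positive total repression")
    genes = control.repression.index.union(test.repression.index, sort=False)
    x1 = control.repression.reindex(genes, fill_value=0.0).to_numpy(dtype=float)
    x2 = test.repression.reindex(genes, fill_value=0.0).to_numpy(dtype=float)
    return _differential(pd.Index(genes), x1, control.total, x2, test.total, alpha, adjust)


def differential_interactions(
    control: ContributionTable,
    test: ContributionTable,
    alpha: float = 0.05,
    adjust: bool = False,
) -> DifferentialTable:
    """Per-(miRNA, gene) z-tests of contribution share between the groups."""
    if control.contributions.empty and test.contributions.empty:
        empty = pd.DataFrame(
            columns=list(DifferentialTable.COLUMNS),
            index=pd.MultiIndex.from_arrays([[], []], names=["mirna_id", "gene_id"]),
        )
        return DifferentialTable(empty)
    if not (control.total > 0) or not (test.total > 0):
        raise ValueError("both groups must have positive total contribution")
    pairs = control.contributions.index.union(test.contributions.index, sort=False)
    x1 = control.contributions.reindex(pairs, fill_value=0.0).to_numpy(dtype=float)
    x2 = test.contributions.reindex(pairs, fill_value=0.0).to_numpy(dtype=float)
    return _differential(pairs, x1, control.total, x2, test.total, alpha, adjust)
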