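"""Benchmark statistics: tie-aware Kendall correlation, coefficient of
determination, Mantel permutation test, Lorenz curves, and the
multiple-testing-corrected component-vs-unit correlation screen."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import r2_score

from ._rng import rng_from
from .diversity import Composition, DissimilarityMatrix
from .errors import AlignmentError, UndefinedStatisticError
from .tables import CountTable


@dataclass(frozen=True)
class KendallResult:
    tau_b: float
    p_value: float
    n: int


def kendall_tau_b(x, y) -> KendallResult:
    """Tie-aware Kendall rank correlation.

    tau_b = (Nc - Nd) / sqrt((Nc + Nd + Nt)(Nc + Nd + Nu)), where Nt/Nu
    count pairs tied only in x / only in y; pairs tied in both count in
    neither. Two-sided p-value (exact for small untied samples, otherwise
    the tie-corrected normal approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant vector: tau_b undefined")
    res = stats.kendalltau(x, y)
    return KendallResult(float(res.statistic), float(res.pvalue), len(x))


def r_squared(y_true, y_pred) -> float:
    """1 - SS_res / SS_tot; may be negative for worse-than-mean predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.all(y_true == y_true[0]):
        raise UndefinedStatisticError("constant y_true: R^2 undefined")
    return float(r2_score(y_true, y_pred))


@dataclass(frozen=True)
class MantelResult:
    statistic: float  # Pearson correlation of off-diagonal entries
    p_value: float
    n_permutations: int
    z_m: float  # raw cross-product sum over all i, j


def mantel_test(
    m1: DissimilarityMatrix,
    m2: DissimilarityMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """One-sided Mantel test for positive association of two distance matrices.

    The statistic is the Pearson correlation between the upper-triangle
    entries (the normalized cross-product); the null distribution is built
    by jointly permuting rows and columns of the second matrix, and
    p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1).
    """
    if m1.sample_ids != m2.sample_ids:
        raise AlignmentError("dissimilarity matrices must share sample ids/order")
    n = m1.n
    if n < 3:
        raise ValueError("Mantel test needs n >= 3 samples")
    v1 = m1.condensed()
    v2 = m2.condensed()
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        raise UndefinedStatisticError("constant distances: correlation undefined")

    z_m = float(np.sum(m1.values * m2.values))

    a = (v1 - v1.mean()) / v1.std()
    iu = np.triu_indices(n, k=1)

    def corr_with(mat: np.ndarray) -> float:
        v = mat[iu]
        return float(np.mean(a * (v - v.mean()) / v.std()))

    observed = corr_with(m2.values)
    rng = rng_from(seed, "mantel")
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr_with(m2.values[np.ix_(perm, perm)]) >= observed:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(observed, p, n_permutations, z_m)


def lorenz_curve(comp: Composition) -> np.ndarray:
    """Cumulative abundance vs cumulative unit fraction, ascending order.

    Returns an (S+1, 2) array of points from (0, 0) to (1, 1); the curve is
    convex, and lies on the diagonal for a perfectly even composition.
    """
    p = np.sort(comp.p)
    s = len(p)
    xs = np.arange(s + 1) / s
    ys = np.concatenate([[0.0], np.cumsum(p)])
    ys[-1] = 1.0  # guard rounding
    return np.column_stack([xs, ys])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class CorrelationScreen:
    """Component-vs-unit correlation matrix after BH correction."""

    component_ids: list[str]
    unit_ids: list[str]
    tau: np.ndarray  # components x units, NaN where undefined
    p_adjusted: np.ndarray  # same shape, NaN where undefined
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.p_adjusted, nan=np.inf) <= self.alpha

    def significant_per_unit(self) -> pd.Series:
        return pd.Series(
            self.significant.sum(axis=0), index=self.unit_ids, name="n_significant"
        )


def mixture_strain_correlation(
    fingerprints: CountTable,
    truth: CountTable,
    alpha: float = 0.05,
) -> CorrelationScreen:
    """Correlate every fingerprint column with every ground-truth column.

    Kendall tau_b over samples for each (component, unit) pair, BH-adjusted
    jointly over the whole family; constant columns are marked undefined and
    excluded from the family.
    """
    if fingerprints.sample_ids != truth.sample_ids:
        raise AlignmentError("tables must share sample ids and order")
    K, S = fingerprints.n_components, truth.n_components
    tau = np.full((K, S), np.nan)
    pval = np.full((K, S), np.nan)
    for i in range(K):
        xi = fingerprints.counts[:, i]
        if np.all(xi == xi[0]):
            continue
        for j in range(S):
            yj = truth.counts[:, j]
            if np.all(yj == yj[0]):
                continue
            res = kendall_tau_b(xi, yj)
            tau[i, j] = res.tau_b
            pval[i, j] = res.p_value
    defined = ~np.isnan(pval)
    padj = np.full_like(pval, np.nan)
    if defined.any():
        padj[defined] = bh_adjust(pval[defined])
    return CorrelationScreen(
        component_ids=list(fingerprints.component_ids),
        unit_ids=list(truth.component_ids),
        tau=tau,
        p_adjusted=padj,
        alpha=alpha,
    )
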