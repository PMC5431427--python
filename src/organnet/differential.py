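"""Differential expression across organs.

A fully specified substitute for package-based count tests: one-way F
statistic on log2-CPM values per gene, a permutation null (label shuffles
shared across genes), Benjamini-Hochberg step-up FDR, and the combined call
``q < alpha AND max pairwise |log2 fold change| > lfc`` with both
inequalities strict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "organ_f_statistic",
    "f_statistics",
    "permutation_pvalues",
    "asymptotic_pvalues",
    "bh_fdr",
    "max_abs_log2fc",
    "build_de_table",
    "de_call",
]


def _group_indices(labels) -> list:
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))  # preserve first-appearance order
    idx = [np.flatnonzero(labels == g) for g in groups]
    if len(idx) < 2:
        raise DegenerateInputError("need at least 2 organs")
    for g, i in zip(groups, idx):
        if i.size < 2:
            raise DegenerateInputError(f"organ {g!r} has fewer than 2 replicates")
    return idx


def f_statistics(matrix, labels) -> np.ndarray:
    """Vectorized one-way ANOVA F per row of ``matrix`` (rows = genes).

    F = (SS_between/(g-1)) / (SS_within/(n-g)); 0 when both sums of squares
    vanish, +inf when only the within-group sum vanishes.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    idx = _group_indices(labels)
    n = x.shape[1]
    g = len(idx)
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for i in idx:
        xm = x[:, i].mean(axis=1)
        ssb += i.size * (xm - grand) ** 2
        ssw += ((x[:, i] - xm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (g - 1)) / (ssw / (n - g))
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    return f


def organ_f_statistic(values, labels) -> float:
    """Scalar one-way F for a single gene's expression vector."""
    return float(f_statistics(np.asarray(values, dtype=float), labels)[0])


def permutation_pvalues(
    matrix, labels, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Permutation p-values: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    The same label shuffles (drawn from ``seed``) are reused for every gene.
    """
    if n_perm < 99:
        raise ValidationError(f"n_perm must be >= 99, got {n_perm}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    labels = np.asarray(labels)
    f_obs = f_statistics(x, labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(labels.size)
        f_perm = f_statistics(x, labels[perm])
        exceed += f_perm >= f_obs
    return (1.0 + exceed) / (1.0 + n_perm)


def asymptotic_pvalues(matrix, labels) -> np.ndarray:
    """Classical F-distribution p-values (fast fallback to the permutation null)."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    labels = np.asarray(labels)
    idx = _group_indices(labels)
    g, n = len(idx), x.shape[1]
    f = f_statistics(x, labels)
    p = np.ones_like(f)
    finite = np.isfinite(f)
    p[finite] = stats.f.sf(f[finite], g - 1, n - g)
    p[~finite] = 0.0
    p[f == 0] = 1.0
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def max_abs_log2fc(matrix, labels) -> np.ndarray:
    """Max over organ pairs of |difference of group mean log2-CPM| per gene."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    idx = _group_indices(labels)
    means = np.column_stack([x[:, i].mean(axis=1) for i in idx])
    return means.max(axis=1) - means.min(axis=1)


def build_de_table(
    log_cpm: pd.DataFrame,
    organ_labels,
    alpha: float = 0.05,
    lfc: float = 1.5,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Per-gene DE table: f_stat, p, q, max |log2FC| and the combined call."""
    labels = np.asarray(organ_labels)
    x = log_cpm.to_numpy(dtype=float)
    f = f_statistics(x, labels)
    if method == "permutation":
        p = permutation_pvalues(x, labels, n_perm=n_perm, seed=seed)
    elif method == "asymptotic":
        p = asymptotic_pvalues(x, labels)
    else:
        raise ValidationError(f"unknown method {method!r}")
    q = bh_fdr(p)
    fc = max_abs_log2fc(x, labels)
    table = pd.DataFrame(
        {
            "f_stat": f,
            "p_value": p,
            "q_value": q,
            "max_abs_log2fc": fc,
        },
        index=log_cpm.index,
    )
    table["is_de"] = (table["q_value"] < alpha) & (table["max_abs_log2fc"] > lfc)
    return table


def de_call(table: pd.DataFrame, alpha: float = 0.05, lfc: float = 1.5) -> list:
    """Genes with q strictly below alpha and max |log2FC| strictly above lfc."""
    mask = (table["q_value"] < alpha) & (table["max_abs_log2fc"] > lfc)
    return list(table.index[mask])
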