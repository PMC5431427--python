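"""Signed weighted co-expression network with topological overlap,
module detection on the TOM dendrogram, module eigengenes and merging.

Adjacency is the signed soft-threshold transform a = ((1 + cor)/2)**beta.
Topological overlap for i != j:

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij   = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu

with TOM_ii = 1.  Module detection uses an average-linkage dendrogram of
1 - TOM and a static cut at c(deep_split) * h_max with
c(d) = 0.99 - 0.02 * d — a deterministic stand-in for adaptive tree cutting
that preserves the monotone effect of the deep-split setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import BlockSizeError, ConfigError, DegenerateInputError, ValidationError

__all__ = [
    "NetworkConfig",
    "CoexpressionNetwork",
    "ModulePartition",
    "pearson_matrix",
    "signed_adjacency",
    "tom_matrix",
    "build_network",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
]


@dataclass
class NetworkConfig:
    beta: int = 20
    max_block_size: int = 11000
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.2

    def validate(self) -> None:
        if self.beta < 1:
            raise ConfigError(f"beta must be >= 1, got {self.beta}")
        if self.min_module_size < 2:
            raise ConfigError(f"min_module_size must be >= 2, got {self.min_module_size}")
        if not 0 <= self.deep_split <= 4:
            raise ConfigError(f"deep_split must be in 0..4, got {self.deep_split}")
        if not 0 < self.merge_cut_height < 1:
            raise ConfigError(
                f"merge_cut_height must be in (0, 1), got {self.merge_cut_height}"
            )
        if self.max_block_size < 2:
            raise ConfigError(f"max_block_size must be >= 2, got {self.max_block_size}")


@dataclass
class CoexpressionNetwork:
    genes: List[str]
    cor: pd.DataFrame
    adjacency: pd.DataFrame
    connectivity: pd.Series
    tom: pd.DataFrame

    @property
    def diss_tom(self) -> pd.DataFrame:
        return 1.0 - self.tom


@dataclass
class ModulePartition:
    module_of_gene: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame = field(default=None)  # module x sample
    module_sizes: Dict[int, int] = field(default_factory=dict)


def pearson_matrix(expr: pd.DataFrame, drop_zero_variance: bool = True) -> pd.DataFrame:
    """Pearson correlation across samples for every gene pair.

    Rows of ``expr`` are genes, columns samples.  Zero-variance genes are
    dropped with a warning, or rejected when ``drop_zero_variance=False``.
    """
    if expr.shape[1] < 3:
        raise DegenerateInputError("need at least 3 samples for correlations")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = expr.index[sd == 0]
    if len(flat):
        if not drop_zero_variance:
            raise DegenerateInputError(
                f"zero-variance genes: {list(flat[:10])}"
                + (" ..." if len(flat) > 10 else "")
            )
        warnings.warn(f"dropping {len(flat)} zero-variance gene(s)", stacklevel=2)
        expr = expr.drop(index=flat)
        x = expr.to_numpy(dtype=float)
    cor = np.atleast_2d(np.corrcoef(x))
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame, beta: int = 20) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + cor)/2)**beta, elementwise."""
    c = cor.to_numpy(dtype=float) if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    if (c < -1 - 1e-12).any() or (c > 1 + 1e-12).any():
        raise ValidationError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.clip(c, -1.0, 1.0)) / 2.0) ** beta
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(a, index=cor.index, columns=cor.columns)
    return a


def tom_matrix(adjacency) -> pd.DataFrame:
    """Topological overlap matrix; diagonal fixed at 1."""
    index = adjacency.index if isinstance(adjacency, pd.DataFrame) else None
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValidationError("adjacency values must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # entry ij already excludes u = i and u = j
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return pd.DataFrame(tom)


def build_network(expr: pd.DataFrame, config: NetworkConfig = None) -> CoexpressionNetwork:
    """Correlation -> signed adjacency -> connectivity -> TOM, in one pass."""
    config = config or NetworkConfig()
    config.validate()
    if expr.shape[0] > config.max_block_size:
        raise BlockSizeError(
            f"{expr.shape[0]} genes exceed max_block_size={config.max_block_size}; "
            "blockwise decomposition is unsupported"
        )
    cor = pearson_matrix(expr)
    adj = signed_adjacency(cor, beta=config.beta)
    a0 = adj.to_numpy().copy()
    np.fill_diagonal(a0, 0.0)
    connectivity = pd.Series(a0.sum(axis=1), index=adj.index, name="connectivity")
    tom = tom_matrix(adj)
    return CoexpressionNetwork(
        genes=list(adj.index), cor=cor, adjacency=adj, connectivity=connectivity, tom=tom
    )


def _cut_height_coefficient(deep_split: int) -> float:
    return 0.99 - 0.02 * deep_split


def detect_modules(diss_tom: pd.DataFrame, config: NetworkConfig = None) -> ModulePartition:
    """Average-linkage clustering of the TOM dissimilarity with a static cut.

    Clusters with at least ``min_module_size`` members become modules,
    labeled 1..M by decreasing size (ties: smaller first-member index);
    everything else is labeled 0.
    """
    config = config or NetworkConfig()
    config.validate()
    n = diss_tom.shape[0]
    if n > config.max_block_size:
        raise BlockSizeError(
            f"{n} genes exceed max_block_size={config.max_block_size}; "
            "blockwise decomposition is unsupported"
        )
    d = diss_tom.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValidationError("dissimilarity contains NaN")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    h_max = z[-1, 2]
    cut = _cut_height_coefficient(config.deep_split) * h_max
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = [int(c) for c in sizes.index if sizes[c] >= config.min_module_size]
    # order: decreasing size, then smallest first-member index
    first_idx = {c: int(np.flatnonzero(raw == c)[0]) for c in keep}
    keep.sort(key=lambda c: (-int(sizes[c]), first_idx[c]))
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    labels = np.array([relabel.get(int(c), 0) for c in raw])
    module_sizes = {relabel[c]: int(sizes[c]) for c in keep}
    return ModulePartition(
        module_of_gene=pd.Series(labels, index=diss_tom.index, name="module"),
        module_sizes=module_sizes,
    )


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First-principal-component summary profile per module.

    Member genes are z-scored across samples; the eigengene is the leading
    right singular vector, scaled to unit variance (ddof=1) and sign-oriented
    to correlate non-negatively with the mean member profile.
    """
    labels = labels.reindex(expr.index)
    modules = sorted(int(m) for m in labels.unique() if m > 0)
    if not modules:
        raise DegenerateInputError("no modules to summarize")
    rows = {}
    for m in modules:
        members = expr.loc[labels == m].to_numpy(dtype=float)
        if members.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene; returning its z-profile",
                          stacklevel=2)
            z = _zscore_rows(members)
            rows[m] = z[0]
            continue
        z = _zscore_rows(members)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        sd = e.std(ddof=1)
        if sd > 0:
            e = e / sd
        mean_profile = z.mean(axis=0)
        if mean_profile.std() > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        rows[m] = e
    return pd.DataFrame(rows, index=expr.columns).T


def merge_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float = 0.2
) -> ModulePartition:
    """Iteratively merge modules whose eigengenes cluster below the cut.

    Eigengene dissimilarity is 1 - cor under average linkage; branches below
    ``merge_cut_height`` collapse into one module, eigengenes are recomputed,
    and the loop runs to a fixed point.  Final labels are sorted by size.
    """
    labels = labels.reindex(expr.index).fillna(0).astype(int)
    while True:
        modules = sorted(int(m) for m in labels.unique() if m > 0)
        if len(modules) <= 1:
            break
        eig = module_eigengenes(expr, labels)
        cor = np.corrcoef(eig.to_numpy())
        diss = 1.0 - np.clip(cor, -1.0, 1.0)
        np.fill_diagonal(diss, 0.0)
        z = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        mapping = {m: int(g) for m, g in zip(modules, groups)}
        labels = labels.map(lambda m: mapping.get(int(m), 0) if m > 0 else 0)

    sizes = labels[labels > 0].value_counts()
    first_idx = {m: int(np.flatnonzero(labels.to_numpy() == m)[0]) for m in sizes.index}
    ordered = sorted(sizes.index, key=lambda m: (-int(sizes[m]), first_idx[m]))
    relabel = {int(m): i + 1 for i, m in enumerate(ordered)}
    final = labels.map(lambda m: relabel.get(int(m), 0))
    final.name = "module"
    eig = module_eigengenes(expr, final) if relabel else None
    return ModulePartition(
        module_of_gene=final,
        eigengenes=eig,
        module_sizes={relabel[int(m)]: int(sizes[m]) for m in ordered},
    )
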