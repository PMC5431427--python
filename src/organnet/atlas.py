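"""Organ presence/absence atlas, Venn partitions, exclusive sets,
hierarchical clustering of samples and genes, and concordance scoring.

Presence rules, per organ, from the maximum FPKM over that organ's
replicates: expressed iff max >= 1, absent iff max == 0, and indeterminate
for 0 < max < 1 (the interval the two printed rules leave uncovered).
Exclusivity requires expressed in one organ and *absent* (exact zero) in
every other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PresenceCall",
    "ClusterProfile",
    "presence_call",
    "venn_partition",
    "exclusive_sets",
    "sample_dendrogram",
    "gene_clusters",
    "linkage_to_newick",
    "expression_concordance",
]

EXPRESSED = "expressed"
ABSENT = "absent"
INDETERMINATE = "indeterminate"


@dataclass
class PresenceCall:
    """Per (gene, organ) status and the max replicate FPKM behind it."""

    status: pd.DataFrame  # gene x organ, values in {expressed, absent, indeterminate}
    max_fpkm: pd.DataFrame  # gene x organ

    @property
    def organs(self) -> List[str]:
        return list(self.status.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for organ in self.organs:
            for gene in self.status.index:
                rows.append(
                    {
                        "gene_id": gene,
                        "organ": organ,
                        "status": self.status.at[gene, organ],
                        "max_fpkm": self.max_fpkm.at[gene, organ],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ClusterProfile:
    cluster_id: int
    genes: List[str]
    profile: pd.Series  # per-sample median of the centered matrix


def presence_call(fpkm: pd.DataFrame, design: pd.DataFrame) -> PresenceCall:
    """Classify every (gene, organ) from the max FPKM over replicates."""
    organs = list(dict.fromkeys(design["organ"]))
    max_cols = {}
    for organ in organs:
        cols = [s for s in fpkm.columns
                if s in design.index and design.at[s, "organ"] == organ]
        if not cols:
            raise ValidationError(f"organ {organ!r} has no samples")
        max_cols[organ] = fpkm[cols].max(axis=1)
    max_fpkm = pd.DataFrame(max_cols)
    status = pd.DataFrame(INDETERMINATE, index=max_fpkm.index, columns=organs)
    status = status.mask(max_fpkm >= 1.0, EXPRESSED)
    status = status.mask(max_fpkm == 0.0, ABSENT)
    return PresenceCall(status=status, max_fpkm=max_fpkm)


def venn_partition(presence: PresenceCall) -> Dict[Tuple[str, ...], int]:
    """Count genes per non-empty organ-combination region.

    Keys are tuples of organ names (in atlas organ order); a gene counts in
    exactly the region matching its full expressed-organ set.  Genes
    expressed nowhere are excluded.
    """
    organs = presence.organs
    expressed = presence.status.to_numpy() == EXPRESSED
    counts: Dict[Tuple[str, ...], int] = {}
    for row in expressed:
        region = tuple(o for o, e in zip(organs, row) if e)
        if region:
            counts[region] = counts.get(region, 0) + 1
    return counts


def exclusive_sets(presence: PresenceCall) -> Dict[str, List[str]]:
    """Genes expressed in one organ and absent (max FPKM = 0) in all others."""
    organs = presence.organs
    out: Dict[str, List[str]] = {o: [] for o in organs}
    for gene in presence.status.index:
        row = presence.status.loc[gene]
        for organ in organs:
            if row[organ] != EXPRESSED:
                continue
            if all(row[o] == ABSENT for o in organs if o != organ):
                out[organ].append(gene)
    return out


def _check_matrix(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("matrix contains NaN")
    return x


def sample_dendrogram(matrix: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Complete-linkage dendrogram of samples (columns) under Euclidean
    distance.  Returns the scipy linkage matrix and the leaf labels."""
    if matrix.shape[1] < 2:
        raise DegenerateInputError("need at least 2 samples to cluster")
    x = _check_matrix(matrix).T
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method="complete")
    return z, list(matrix.columns)


def gene_clusters(
    centered: pd.DataFrame, n_clusters: int = 6
) -> List[ClusterProfile]:
    """Cut the complete-linkage gene tree into ``n_clusters`` groups and
    summarize each as the per-sample median of its members' centered values."""
    if centered.shape[0] < 2:
        raise DegenerateInputError("need at least 2 genes to cluster")
    x = _check_matrix(centered)
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method="complete")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    profiles = []
    for cid in sorted(set(labels)):
        members = list(centered.index[labels == cid])
        profile = centered.loc[members].median(axis=0)
        profiles.append(ClusterProfile(cluster_id=int(cid), genes=members, profile=profile))
    return profiles


def linkage_to_newick(z: np.ndarray, labels: List[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def expression_concordance(x_vector, y_vector) -> float:
    """Squared Pearson correlation between paired expression measurements."""
    x = np.asarray(x_vector, dtype=float)
    y = np.asarray(y_vector, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
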