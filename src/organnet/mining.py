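"""Network sparsification, TF family classification and regulator mining.

Sparsification keeps, for every gene, its ``per_gene_k`` strongest TOM
partners, plus the globally strongest ``ceil(q * n(n-1)/2)`` unordered pairs.
Mining ranks TFs by TOM against each pathway gene, keeps the top
``top_tf_k`` per pathway gene, and retains TFs present in at least
``min_list_count`` of those lists.  All ties break on gene identifier so
output is reproducible byte for byte.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, ValidationError

__all__ = [
    "TFRule",
    "DEFAULT_RULES",
    "MiningConfig",
    "SparseNetwork",
    "RegulatorReport",
    "read_rules",
    "write_rules",
    "sparsify",
    "classify_tfs",
    "top_tf_lists",
    "mine_regulators",
    "evaluate_recovery",
    "module_recovery",
]


@dataclass(frozen=True)
class TFRule:
    """One family-assignment rule: required domains present, forbidden absent."""

    family: str
    required: FrozenSet[str]
    forbidden: FrozenSet[str] = frozenset()


# Small configurable subset of plant TF family assignment rules keyed on PFAM
# DNA-binding domains.  Order matters: the first matching rule wins, so the
# more specific ARR-B rule precedes plain MYB.
DEFAULT_RULES: Tuple[TFRule, ...] = (
    TFRule("ARR-B", frozenset({"PF00249", "PF00072"})),
    TFRule("MYB", frozenset({"PF00249"}), frozenset({"PF00072"})),
    TFRule("bHLH", frozenset({"PF00010"})),
    TFRule("NAC", frozenset({"PF02365"})),
    TFRule("TIFY", frozenset({"PF06200"})),
    TFRule("YABBY", frozenset({"PF04690"})),
    TFRule("TCP", frozenset({"PF03634"})),
    TFRule("HB", frozenset({"PF00046"})),
    TFRule("MADS", frozenset({"PF00319"})),
)


@dataclass
class MiningConfig:
    per_gene_k: int = 4
    global_quantile: float = 0.01
    top_tf_k: int = 10
    min_list_count: int = 2

    def validate(self) -> None:
        if self.per_gene_k < 1:
            raise ConfigError(f"per_gene_k must be >= 1, got {self.per_gene_k}")
        if not 0 < self.global_quantile <= 1:
            raise ConfigError(
                f"global_quantile must be in (0, 1], got {self.global_quantile}"
            )
        if self.top_tf_k < 1:
            raise ConfigError(f"top_tf_k must be >= 1, got {self.top_tf_k}")
        if self.min_list_count < 1:
            raise ConfigError(f"min_list_count must be >= 1, got {self.min_list_count}")


@dataclass
class SparseNetwork:
    nodes: List[str]
    edges: List[Tuple[str, str, float]]  # (gene_i, gene_j, tom), i < j in node order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene_i", "gene_j", "tom"])


@dataclass
class RegulatorReport:
    tf_lists: Dict[str, List[Tuple[str, float]]]  # pathway gene -> [(tf, tom)]
    retained_tfs: Dict[str, int]  # tf -> number of lists containing it
    bipartite_edges: List[Tuple[str, str, float]] = field(default_factory=list)


def sparsify(
    tom: pd.DataFrame, per_gene_k: int = 4, global_quantile: float = 0.01
) -> SparseNetwork:
    """Union of per-gene top-k edges and the global top-quantile edges."""
    n = tom.shape[0]
    if per_gene_k >= n:
        raise ConfigError(f"per_gene_k={per_gene_k} must be < number of genes ({n})")
    if not 0 < global_quantile <= 1:
        raise ConfigError(f"global_quantile must be in (0, 1], got {global_quantile}")
    nodes = list(tom.index)
    t = tom.to_numpy(dtype=float).copy()
    np.fill_diagonal(t, -np.inf)

    chosen: Set[Tuple[int, int]] = set()
    order = np.argsort(-t, axis=1, kind="stable")  # ties -> smaller index first
    for i in range(n):
        for j in order[i, :per_gene_k]:
            chosen.add((min(i, int(j)), max(i, int(j))))

    iu, ju = np.triu_indices(n, k=1)
    vals = t[iu, ju]
    m_global = math.ceil(global_quantile * n * (n - 1) / 2)
    top = np.lexsort((ju, iu, -vals))[:m_global]
    for idx in top:
        chosen.add((int(iu[idx]), int(ju[idx])))

    edges = [
        (nodes[i], nodes[j], float(tom.iat[i, j]))
        for i, j in sorted(chosen)
    ]
    return SparseNetwork(nodes=nodes, edges=edges)


def read_rules(path) -> List[TFRule]:
    """Parse a rules TSV: family<TAB>required(;-joined)<TAB>forbidden(;-joined)."""
    rules = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and line.split("\t")[0].lower() == "family":
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValidationError(f"malformed rules row at line {lineno}: {line!r}")
        family = parts[0].strip()
        required = frozenset(d for d in parts[1].split(";") if d)
        forbidden = frozenset(
            d for d in (parts[2].split(";") if len(parts) > 2 else []) if d
        )
        rules.append(TFRule(family, required, forbidden))
    return rules


def write_rules(rules: Iterable[TFRule], path) -> None:
    lines = ["family\trequired\tforbidden"]
    for rule in rules:
        lines.append(
            f"{rule.family}\t{';'.join(sorted(rule.required))}\t"
            f"{';'.join(sorted(rule.forbidden))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def classify_tfs(
    gene_domains: Dict[str, Iterable[str]], rules: Sequence[TFRule] = DEFAULT_RULES
) -> Dict[str, str]:
    """Assign each gene the first rule family whose required domains are all
    present and whose forbidden domains are all absent; unmatched genes are
    omitted from the result."""
    out: Dict[str, str] = {}
    for gene, domains in gene_domains.items():
        dom = set(domains)
        for rule in rules:
            if rule.required <= dom and not (rule.forbidden & dom):
                out[gene] = rule.family
                break
    return out


def top_tf_lists(
    tom: pd.DataFrame,
    pathway_genes: Iterable[str],
    tf_genes: Iterable[str],
    top_tf_k: int = 10,
) -> Dict[str, List[Tuple[str, float]]]:
    """Per pathway gene: TFs sorted by TOM descending (ties: identifier
    ascending), truncated to ``top_tf_k``.  A gene annotated as both pathway
    member and TF is excluded from its own candidate list."""
    tf_set = sorted(set(tf_genes))
    if not tf_set:
        raise ValidationError("TF set is empty")
    missing = [g for g in list(pathway_genes) + tf_set if g not in tom.index]
    if missing:
        raise ValidationError(f"genes absent from the network: {missing[:10]}")
    lists: Dict[str, List[Tuple[str, float]]] = {}
    for pg in pathway_genes:
        candidates = [t for t in tf_set if t != pg]
        ranked = sorted(candidates, key=lambda t: (-float(tom.at[pg, t]), t))
        lists[pg] = [(t, float(tom.at[pg, t])) for t in ranked[:top_tf_k]]
    return lists


def mine_regulators(
    tf_lists: Dict[str, List[Tuple[str, float]]], min_list_count: int = 2
) -> RegulatorReport:
    """Retain TFs found in at least ``min_list_count`` top lists and emit the
    bipartite TF -> pathway-gene edges supporting them."""
    counts: Dict[str, int] = {}
    for entries in tf_lists.values():
        for tf, _ in entries:
            counts[tf] = counts.get(tf, 0) + 1
    retained = {tf: c for tf, c in sorted(counts.items()) if c >= min_list_count}
    edges = [
        (tf, pg, w)
        for pg in sorted(tf_lists)
        for tf, w in tf_lists[pg]
        if tf in retained
    ]
    return RegulatorReport(tf_lists=tf_lists, retained_tfs=retained, bipartite_edges=edges)


def evaluate_recovery(report: RegulatorReport, truth) -> Tuple[float, float]:
    """Precision and recall of the retained TF set against the planted TFs."""
    planted = set(truth.planted_tfs())
    retained = set(report.retained_tfs)
    if not planted:
        raise ValidationError("truth contains no planted links")
    if not retained:
        warnings.warn("no TFs retained; precision undefined", stacklevel=2)
        return float("nan"), 0.0
    hits = len(retained & planted)
    return hits / len(retained), hits / len(planted)


def module_recovery(labels: pd.Series, truth) -> float:
    """Adjusted Rand index between detected and planted module labels."""
    planted = truth.module_of_gene.reindex(labels.index)
    return float(adjusted_rand_score(planted.to_numpy(), labels.to_numpy()))
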