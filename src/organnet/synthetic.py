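"""Synthetic multi-organ count datasets with planted structure.

Counts are negative-binomial with mean

    mu_gs = L_g * 2**(b_g + e[m(g), o(s)] + lambda_g * f[m(g), s]) * d_s

where ``L_g`` is the gene length (bp), ``b_g`` a gene baseline, ``e`` the
organ effect of the gene's module, ``f`` a per-(module, sample) latent factor,
``lambda_g`` the gene's loading on that factor and ``d_s`` a per-sample depth
multiplier.  Genes flagged organ-specific have mean forced to exactly 0 in
every other organ, so downstream absent calls (max FPKM = 0) are reachable.

Planted regulator->target links are all hosted in module 1: its leading genes
are the pathway genes followed by the planted TF genes, so every planted pair
shares both module membership and latent factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .normalization import ExpressionStudy

__all__ = [
    "DEFAULT_ORGANS",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "make_annotation",
    "write_truth",
    "read_truth",
]

DEFAULT_ORGANS: Tuple[str, ...] = ("root", "leaf", "spathe", "spadix")


@dataclass
class SimulationConfig:
    """Parameters of the generator; see the module docstring for the model."""

    n_genes: int = 2000
    organs: Sequence[str] = DEFAULT_ORGANS
    reps_per_organ: int = 3
    n_modules: int = 5
    module_sizes: Optional[Sequence[int]] = None
    # scalar: each module is shifted by this log2 amount in its "preferred"
    # organ (modules cycle over organs); array: explicit (n_modules, n_organs)
    organ_effect: Union[float, np.ndarray] = 2.0
    factor_loading_range: Tuple[float, float] = (0.7, 1.0)
    dispersion: float = 0.1
    depth_range: Tuple[float, float] = (0.6, 1.6)
    length_logmean: float = 7.3
    length_logsd: float = 0.4
    baseline_logmean: float = -3.0
    baseline_logsd: float = 0.8
    n_tfs: int = 0
    n_pathway_genes: int = 0
    n_planted_links: int = 0
    n_organ_specific: int = 0
    seed: int = 0

    def resolved_module_sizes(self) -> Tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(int(s) for s in self.module_sizes)
        return tuple([100] * self.n_modules)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.organs) < 1:
            raise ConfigError("organs must be non-empty")
        if len(set(self.organs)) != len(self.organs):
            raise ConfigError("organs contains duplicates")
        if self.reps_per_organ < 2:
            raise ConfigError(
                f"reps_per_organ must be >= 2 for DE to be computable, "
                f"got {self.reps_per_organ}"
            )
        sizes = self.resolved_module_sizes()
        if len(sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes has {len(sizes)} entries but n_modules={self.n_modules}"
            )
        if any(s < 0 for s in sizes):
            raise ConfigError("module_sizes must be non-negative")
        if sum(sizes) > self.n_genes:
            raise ConfigError(
                f"sum(module_sizes)={sum(sizes)} exceeds n_genes={self.n_genes}"
            )
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        lo, hi = self.factor_loading_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"factor_loading_range invalid: {(lo, hi)}")
        dlo, dhi = self.depth_range
        if dlo <= 0 or dhi < dlo:
            raise ConfigError(f"depth_range invalid: {(dlo, dhi)}")
        for name in ("n_tfs", "n_pathway_genes", "n_planted_links", "n_organ_specific"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_planted_links > 0:
            if self.n_tfs == 0 or self.n_pathway_genes == 0:
                raise ConfigError("n_planted_links > 0 requires n_tfs and n_pathway_genes")
            if self.n_modules < 1:
                raise ConfigError("n_planted_links > 0 requires n_modules >= 1")
            n_planted_tfs = min(self.n_planted_links, self.n_tfs)
            if sizes[0] < self.n_pathway_genes + n_planted_tfs:
                raise ConfigError(
                    "module_sizes[0] too small to host pathway genes and planted TFs"
                )
        n_background = self.n_genes - sum(sizes)
        if self.n_planted_links > 0:
            n_free = self.n_tfs - min(self.n_planted_links, self.n_tfs)
        else:
            n_free = self.n_tfs + self.n_pathway_genes
        if n_free + self.n_organ_specific > n_background:
            raise ConfigError(
                "not enough background genes for TFs, pathway and organ-specific genes"
            )
        if isinstance(self.organ_effect, np.ndarray):
            if self.organ_effect.shape != (self.n_modules, len(self.organs)):
                raise ConfigError(
                    f"organ_effect array must be (n_modules, n_organs)="
                    f"({self.n_modules}, {len(self.organs)}), "
                    f"got {self.organ_effect.shape}"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth used to score the pipeline."""

    module_of_gene: pd.Series  # gene -> module id, 0 = background
    tf_genes: FrozenSet[str]
    pathway_genes: FrozenSet[str]
    planted_links: FrozenSet[Tuple[str, str]]  # (tf, pathway_gene)
    organ_specific_genes: Dict[str, str]  # gene -> organ
    latent_factors: pd.DataFrame = field(default=None)  # module x sample
    organ_effects: pd.DataFrame = field(default=None)  # module x organ

    def planted_tfs(self) -> Set[str]:
        return {tf for tf, _ in self.planted_links}

    def validate(self) -> None:
        if self.tf_genes & self.pathway_genes:
            raise ConfigError("tf_genes and pathway_genes overlap")
        for tf, pg in self.planted_links:
            if tf not in self.tf_genes or pg not in self.pathway_genes:
                raise ConfigError(f"planted link ({tf}, {pg}) not in TF x pathway sets")


def _effect_matrix(config: SimulationConfig) -> np.ndarray:
    """(n_modules + 1) x n_organs log2 shifts; row 0 is the background."""
    n_org = len(config.organs)
    e = np.zeros((config.n_modules + 1, n_org))
    if isinstance(config.organ_effect, np.ndarray):
        e[1:, :] = config.organ_effect
    else:
        for m in range(1, config.n_modules + 1):
            e[m, (m - 1) % n_org] = float(config.organ_effect)
    return e


def generate_dataset(config: SimulationConfig) -> Tuple[ExpressionStudy, SyntheticTruth]:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    organs = list(config.organs)
    samples, sample_organ = [], []
    for organ in organs:
        for r in range(1, config.reps_per_organ + 1):
            samples.append(f"{organ}_{r}")
            sample_organ.append(organ)
    n_samples = len(samples)
    organ_idx = np.array([organs.index(o) for o in sample_organ])

    sizes = config.resolved_module_sizes()
    module_of = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(sizes, start=1):
        module_of[pos : pos + size] = m
        pos += size
    background_start = pos

    # planted links: pathway genes then planted TFs at the head of module 1
    pathway: list = []
    tfs: list = []
    links: Set[Tuple[str, str]] = set()
    if config.n_planted_links > 0:
        n_planted_tfs = min(config.n_planted_links, config.n_tfs)
        pathway = genes[: config.n_pathway_genes]
        planted_tfs = genes[config.n_pathway_genes : config.n_pathway_genes + n_planted_tfs]
        for i in range(config.n_planted_links):
            links.add((planted_tfs[i % n_planted_tfs], pathway[i % len(pathway)]))
        tfs = list(planted_tfs)
        n_free_tfs = config.n_tfs - n_planted_tfs
    else:
        n_free_tfs = config.n_tfs

    free_pos = background_start
    tfs += genes[free_pos : free_pos + n_free_tfs]
    free_pos += n_free_tfs
    organ_specific: Dict[str, str] = {}
    for i in range(config.n_organ_specific):
        organ_specific[genes[free_pos + i]] = organs[i % len(organs)]
    free_pos += config.n_organ_specific
    if config.n_planted_links == 0 and config.n_pathway_genes > 0:
        pathway = genes[free_pos : free_pos + config.n_pathway_genes]
        free_pos += config.n_pathway_genes

    lengths = np.maximum(
        np.round(rng.lognormal(config.length_logmean, config.length_logsd, config.n_genes)),
        50.0,
    )
    baselines = rng.normal(config.baseline_logmean, config.baseline_logsd, config.n_genes)
    lo, hi = config.factor_loading_range
    loadings = np.where(module_of > 0, rng.uniform(lo, hi, config.n_genes), 0.0)
    effects = _effect_matrix(config)
    factors = np.zeros((config.n_modules + 1, n_samples))
    raw_f = rng.standard_normal((config.n_modules, n_samples))
    # standardize each realization so a module's signal sd is exactly its
    # loading; an unlucky flat draw would otherwise erase the planted module
    if n_samples >= 2:
        raw_f = (raw_f - raw_f.mean(axis=1, keepdims=True)) / raw_f.std(
            axis=1, keepdims=True
        )
    factors[1:, :] = raw_f
    depth = rng.uniform(*config.depth_range, n_samples)

    log2_mean = (
        baselines[:, None]
        + effects[module_of][:, organ_idx]
        + loadings[:, None] * factors[module_of, :]
    )
    mu = lengths[:, None] * np.exp2(log2_mean) * depth[None, :]

    for gene, organ in organ_specific.items():
        gi = genes.index(gene)
        mu[gi, organ_idx != organs.index(organ)] = 0.0

    phi = config.dispersion
    size_param = 1.0 / phi
    counts = np.zeros(mu.shape, dtype=np.int64)
    positive = mu > 0
    p = size_param / (size_param + mu[positive])
    counts[positive] = rng.negative_binomial(size_param, p)

    study = ExpressionStudy(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length=pd.Series(lengths, index=genes, name="length_bp"),
        design=pd.DataFrame(
            {
                "organ": sample_organ,
                "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            },
            index=pd.Index(samples, name="sample_id"),
        ),
    )
    truth = SyntheticTruth(
        module_of_gene=pd.Series(module_of, index=genes, name="module"),
        tf_genes=frozenset(tfs),
        pathway_genes=frozenset(pathway),
        planted_links=frozenset(links),
        organ_specific_genes=organ_specific,
        latent_factors=pd.DataFrame(
            factors[1:, :], index=range(1, config.n_modules + 1), columns=samples
        ),
        organ_effects=pd.DataFrame(
            effects[1:, :], index=range(1, config.n_modules + 1), columns=organs
        ),
    )
    truth.validate()
    return study, truth


def make_annotation(truth: SyntheticTruth, study: ExpressionStudy) -> pd.DataFrame:
    """Gene annotation table: length, pathway tags and PFAM domains.

    TF genes receive the required domain set of a TF family (cycling over the
    shipped rules) so that rule-based classification recovers them; pathway
    genes are tagged ``flavonoid``.
    """
    from .mining import DEFAULT_RULES

    genes = list(study.counts.index)
    tf_sorted = sorted(truth.tf_genes)
    family_of = {g: DEFAULT_RULES[i % len(DEFAULT_RULES)] for i, g in enumerate(tf_sorted)}
    rows = []
    for g in genes:
        domains: list = []
        tags: list = []
        if g in family_of:
            domains = sorted(family_of[g].required)
        if g in truth.pathway_genes:
            tags.append("flavonoid")
        rows.append(
            {
                "gene_id": g,
                "length_bp": int(study.gene_length[g]),
                "pathway_tags": ";".join(tags),
                "pfam_domains": ";".join(domains),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize the ground truth as JSON (lossless round-trip)."""
    payload = {
        "module_of_gene": {g: int(m) for g, m in truth.module_of_gene.items()},
        "tf_genes": sorted(truth.tf_genes),
        "pathway_genes": sorted(truth.pathway_genes),
        "planted_links": sorted([list(pair) for pair in truth.planted_links]),
        "organ_specific_genes": dict(sorted(truth.organ_specific_genes.items())),
        "latent_factors": None,
        "organ_effects": None,
    }
    if truth.latent_factors is not None:
        payload["latent_factors"] = {
            "index": [int(i) for i in truth.latent_factors.index],
            "columns": list(truth.latent_factors.columns),
            "data": truth.latent_factors.to_numpy().tolist(),
        }
    if truth.organ_effects is not None:
        payload["organ_effects"] = {
            "index": [int(i) for i in truth.organ_effects.index],
            "columns": list(truth.organ_effects.columns),
            "data": truth.organ_effects.to_numpy().tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def _frame_from(payload) -> Optional[pd.DataFrame]:
    if payload is None:
        return None
    return pd.DataFrame(payload["data"], index=payload["index"], columns=payload["columns"])


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        module_of_gene=pd.Series(payload["module_of_gene"], name="module"),
        tf_genes=frozenset(payload["tf_genes"]),
        pathway_genes=frozenset(payload["pathway_genes"]),
        planted_links=frozenset(tuple(pair) for pair in payload["planted_links"]),
        organ_specific_genes=dict(payload["organ_specific_genes"]),
        latent_factors=_frame_from(payload.get("latent_factors")),
        organ_effects=_frame_from(payload.get("organ_effects")),
    )
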