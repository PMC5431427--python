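"""End-to-end orchestration: normalize -> DE -> atlas -> network -> modules
-> sparsify -> mine, with input validation and a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import atlas, differential, io, mining, network
from .errors import OrganNetError, ValidationError
from .normalization import normalize_study

logger = logging.getLogger("organnet")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    genes: str
    out_dir: str
    rules: Optional[str] = None
    seed: int = 0
    alpha: float = 0.05
    lfc: float = 1.5
    n_perm: int = 1000
    de_method: str = "permutation"
    prior: float = 0.5
    n_gene_clusters: int = 6
    beta: int = 20
    max_block_size: int = 11000
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.2
    per_gene_k: int = 4
    global_quantile: float = 0.01
    top_tf_k: int = 10
    min_list_count: int = 2
    pathway_tag: str = "flavonoid"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def network_config(self) -> network.NetworkConfig:
        return network.NetworkConfig(
            beta=self.beta,
            max_block_size=self.max_block_size,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            merge_cut_height=self.merge_cut_height,
        )


def validate_inputs(counts_path, samples_path, genes_path) -> List[str]:
    """Itemized pre-flight report; an empty list means the inputs are clean."""
    failures: List[str] = []
    try:
        counts = io.read_counts(counts_path)
    except (OSError, ValidationError, ValueError) as exc:
        return [f"counts: {exc}"]
    try:
        design = io.read_samples(samples_path)
    except (OSError, ValidationError, ValueError) as exc:
        return [f"samples: {exc}"]
    try:
        genes = io.read_gene_table(genes_path)
    except (OSError, ValidationError, ValueError) as exc:
        return [f"genes: {exc}"]

    for s in counts.columns:
        if s not in design.index:
            failures.append(f"sample {s!r} in counts but not in sample sheet")
    for s in design.index:
        if s not in counts.columns:
            failures.append(f"sample {s!r} in sample sheet but not in counts")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        failures.append("counts matrix contains non-numeric values")
    else:
        neg = np.argwhere(values < 0)
        for gi, si in neg[:20]:
            failures.append(
                f"negative count at gene {counts.index[gi]!r}, "
                f"sample {counts.columns[si]!r}"
            )
        frac = values[np.isfinite(values)] % 1
        if (frac != 0).any():
            failures.append("counts matrix contains non-integer values")
    for g in counts.index:
        if g not in genes.index:
            failures.append(f"gene {g!r} missing from gene table")
    lengths = pd.to_numeric(genes["length_bp"], errors="coerce")
    bad_len = genes.index[(lengths.isna()) | (lengths <= 0)]
    for g in bad_len[:20]:
        failures.append(f"gene {g!r} has non-positive or missing length")
    return failures


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and write all output tables plus manifest.json.

    Returns the manifest.  Reruns with the same config and inputs are
    byte-identical.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for name in ("counts", "samples", "genes"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} file not found: {p}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)
        logger.info("wrote %s", path)

    failures = validate_inputs(config.counts, config.samples, config.genes)
    if failures:
        raise ValidationError("input validation failed: " + "; ".join(failures[:10]))

    stage = "normalize"
    try:
        study = io.read_study(config.counts, config.samples, config.genes)
        norm = normalize_study(study, prior=config.prior)
        emit("tmm_factors.tsv",
             lambda p: norm.tmm_factor.rename_axis("sample_id").to_csv(p, sep="\t"))
        emit("fpkm.tsv", lambda p: io.write_matrix(norm.fpkm, p))
        emit("log_cpm.tsv", lambda p: io.write_matrix(norm.log_cpm, p))
        emit("centered.tsv", lambda p: io.write_matrix(norm.centered, p))

        stage = "differential_expression"
        organ_labels = study.organ_labels.to_numpy()
        de_table = differential.build_de_table(
            norm.log_cpm,
            organ_labels,
            alpha=config.alpha,
            lfc=config.lfc,
            n_perm=config.n_perm,
            seed=config.seed,
            method=config.de_method,
        )
        emit("de_table.tsv", lambda p: io.write_matrix(de_table, p))
        de_genes = differential.de_call(de_table, alpha=config.alpha, lfc=config.lfc)
        logger.info("%d differentially expressed genes", len(de_genes))

        stage = "organ_atlas"
        presence = atlas.presence_call(norm.fpkm, study.design)
        emit("presence.tsv",
             lambda p: presence.to_long().to_csv(p, sep="\t", index=False))
        venn = atlas.venn_partition(presence)
        organs = presence.organs

        def write_venn(p):
            rows = []
            for region, count in sorted(venn.items()):
                mask = "".join("1" if o in region else "0" for o in organs)
                rows.append({"region": "+".join(region), "bitmask": mask, "count": count})
            pd.DataFrame(rows, columns=["region", "bitmask", "count"]).to_csv(
                p, sep="\t", index=False
            )

        emit("venn.tsv", write_venn)
        excl = atlas.exclusive_sets(presence)
        for organ in organs:
            emit(f"exclusive_{organ}.txt",
                 lambda p, o=organ: p.write_text("\n".join(excl[o]) + "\n"))
        z, leaves = atlas.sample_dendrogram(np.log2(norm.fpkm + 1.0))
        emit("sample_dendrogram.nwk",
             lambda p: p.write_text(atlas.linkage_to_newick(z, leaves) + "\n"))

        stage = "coexpression_network"
        if len(de_genes) < 3:
            raise OrganNetError(f"only {len(de_genes)} DE genes; cannot build a network")
        expr = np.log2(norm.fpkm.loc[de_genes] + 1.0)
        net_config = config.network_config()
        net = network.build_network(expr, net_config)

        stage = "module_detection"
        detected = network.detect_modules(net.diss_tom, net_config)
        if detected.module_sizes:
            merged = network.merge_modules(
                expr, detected.module_of_gene, config.merge_cut_height
            )
        else:
            merged = detected
        emit("modules.tsv",
             lambda p: merged.module_of_gene.rename_axis("gene_id").to_csv(p, sep="\t"))
        if merged.eigengenes is not None:
            emit("eigengenes.tsv",
                 lambda p: io.write_matrix(merged.eigengenes, p, index_name="module"))

        stage = "sparsify"
        sparse = mining.sparsify(
            net.tom, per_gene_k=config.per_gene_k, global_quantile=config.global_quantile
        )
        emit("edges.tsv", lambda p: sparse.to_frame().to_csv(p, sep="\t", index=False))
        emit("edges.sif",
             lambda p: p.write_text(
                 "".join(f"{a}\tco\t{b}\n" for a, b, _ in sparse.edges)))

        stage = "regulator_mining"
        genes_table = io.read_gene_table(config.genes)
        rules = mining.read_rules(config.rules) if config.rules else list(mining.DEFAULT_RULES)
        domains = io.gene_domains_from_table(genes_table)
        families = mining.classify_tfs(domains, rules)
        emit("tf_families.tsv",
             lambda p: pd.Series(families, name="family")
             .rename_axis("gene_id").sort_index().to_csv(p, sep="\t"))
        pathway = [g for g in io.pathway_genes_from_table(genes_table, config.pathway_tag)
                   if g in net.tom.index]
        tf_in_net = [g for g in families if g in net.tom.index]
        report = None
        if pathway and tf_in_net:
            lists = mining.top_tf_lists(net.tom, pathway, tf_in_net, config.top_tf_k)
            report = mining.mine_regulators(lists, config.min_list_count)

            def write_regulators(p):
                rows = []
                for tf, count in sorted(report.retained_tfs.items()):
                    targets = sorted({pg for t, pg, _ in report.bipartite_edges if t == tf})
                    rows.append(
                        {
                            "tf": tf,
                            "family": families.get(tf, ""),
                            "n_lists": count,
                            "pathway_genes": ";".join(targets),
                        }
                    )
                pd.DataFrame(
                    rows, columns=["tf", "family", "n_lists", "pathway_genes"]
                ).to_csv(p, sep="\t", index=False)

            emit("regulators.tsv", write_regulators)
        else:
            logger.warning("no pathway genes or TFs in the network; mining skipped")
    except OrganNetError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "parameters": asdict(config),
        "seed": config.seed,
        "inputs": {
            name: _sha256(Path(getattr(config, name)))
            for name in ("counts", "samples", "genes")
        },
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "n_de_genes": len(de_genes),
        "n_modules": len(merged.module_sizes),
        "n_edges": len(sparse.edges),
        "n_retained_tfs": len(report.retained_tfs) if report else 0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
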