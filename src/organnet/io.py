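"""Tab-delimited readers/writers for the pipeline's standard tables.

All files are UTF-8 TSV with a header row: counts.tsv (gene_id + one column
per sample, integers), samples.tsv (sample_id, organ, replicate) and
genes.tsv (gene_id, length_bp, pathway_tags, pfam_domains).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Set

import pandas as pd

from .errors import ValidationError
from .normalization import ExpressionStudy


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0)
    if df.index.name is None:
        raise ValidationError(f"{path}: missing header row")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0)
    missing = {"organ", "replicate"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_samples(design: pd.DataFrame, path) -> None:
    design.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", index_col=0, keep_default_na=False)
    if "length_bp" not in df.columns:
        raise ValidationError(f"{path}: missing column 'length_bp'")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.rename_axis("gene_id").to_csv(path, sep="\t")


def gene_domains_from_table(genes: pd.DataFrame) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    col = genes.get("pfam_domains")
    for gene in genes.index:
        raw = "" if col is None else str(col[gene])
        out[gene] = {d for d in raw.split(";") if d}
    return out


def pathway_genes_from_table(genes: pd.DataFrame, tag: str = "flavonoid") -> List[str]:
    col = genes.get("pathway_tags")
    if col is None:
        return []
    return [g for g in genes.index if tag in str(col[g]).split(";")]


def read_study(counts_path, samples_path, genes_path) -> ExpressionStudy:
    counts = read_counts(counts_path)
    design = read_samples(samples_path)
    genes = read_gene_table(genes_path)
    study = ExpressionStudy(
        counts=counts,
        gene_length=genes["length_bp"].astype(float),
        design=design,
    )
    study.validate()
    return study


def write_matrix(matrix: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    matrix.rename_axis(index_name).to_csv(path, sep="\t")


def read_matrix(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t", index_col=0, **kwargs)
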