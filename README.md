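# organnet

Organ-resolved co-expression network pipeline for bulk RNA-seq count data:

- **synthetic** — negative-binomial multi-organ count simulator with planted
  co-expression modules, organ-specific genes, TF annotations and
  regulator→target links (every downstream stage is testable offline).
- **normalization** — TMM scaling factors (double-trimmed, inverse-variance
  weighted, geometric mean 1), FPKM on TMM-effective library sizes, log-CPM
  with a prior count, per-gene median centering.
- **differential** — one-way F statistic on log2-CPM across organs, a
  permutation null (shared label shuffles), Benjamini–Hochberg FDR, and the
  combined call `q < 0.05 AND max pairwise |log2FC| > 1.5` (both strict).
- **atlas** — per-organ expressed/absent/indeterminate calls from max
  replicate FPKM (expressed ⇔ max ≥ 1, absent ⇔ max = 0), Venn partitions,
  organ-exclusive gene sets, Euclidean/complete-linkage dendrograms with
  Newick export, and R² concordance scoring.
- **network** — signed soft-threshold adjacency `((1+cor)/2)^β` (β = 20),
  topological overlap matrix, average-linkage module detection with a
  deterministic static cut, first-PC module eigengenes, eigengene-similarity
  module merging (cut height 0.2).
- **mining** — TOM sparsification (per-gene top-4 edges ∪ global top 1%),
  PFAM-rule TF family classification, per-pathway-gene top-10 TF lists, and
  retention of TFs appearing in ≥ 2 lists; recovery scoring (precision/
  recall, adjusted Rand index) against planted truth.
- **pipeline** — config-driven end-to-end orchestration with input
  validation and a hash manifest for reproducibility.

## CLI

```bash
# generate a synthetic study
organnet simulate --n-genes 2000 --n-modules 5 --n-tfs 50 \
    --n-pathway-genes 10 --n-planted-links 10 --seed 1 --out-dir study/

# run every stage from a YAML config
organnet run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
counts: study/counts.tsv
samples: study/samples.tsv
genes: study/genes.tsv
out_dir: results/run1
seed: 1
```

Individual stages are also exposed (`normalize`, `de`, `atlas`, `network`,
`modules`, `sparsify`, `mine`, `evaluate`); every stage reads and writes
plain TSV so any step can be rerun from files. Exit codes: 0 ok,
2 validation/configuration error, 3 runtime error.

## File formats

Tab-delimited UTF-8 with header rows: `counts.tsv` (gene_id + one integer
column per sample), `samples.tsv` (sample_id, organ, replicate), `genes.tsv`
(gene_id, length_bp, pathway_tags, pfam_domains ;-joined), rules tables
(family, required, forbidden ;-joined), `truth.json` for planted ground
truth, Newick for dendrograms, and SIF for network export.
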