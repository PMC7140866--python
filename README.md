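# scvaf

Single-cell expressed variant allele fraction (VAF) analysis from barcoded,
UMI-tagged scRNA-seq alignments.

At each heterozygous SNV locus, the per-cell VAF is
`n_var / (n_var + n_ref)` computed from deduplicated reads (one molecule per
cell-barcode/UMI pair, highest mapping quality kept). A cell/locus pair
qualifies only when its informative depth reaches a threshold `minR`
(typically 3, 5 or 10). Per-cell estimates are summarized per SNV
(mean, median, fractions of strictly monoallelic, predominantly monoallelic
and bi-allelic cells) and classified into allelic patterns — bi-allelic,
skewed, or random monoallelic expression (RME) — then aggregated to gene
level with intronic vs non-intronic comparisons.

## Components

| module | purpose |
| --- | --- |
| `scvaf.simulate` | seeded synthetic datasets (reference FASTA, tagged SAM, VCF, annotation TSV, MTX matrix) with full ground truth |
| `scvaf.counting` | per-cell, per-SNV deduplicated ref/var/other molecule counts; pooled totals |
| `scvaf.selection` | heterozygous SNV selection (pooled-count rule, QUAL/MQ/QD/FS gates, annotation exclusion) with per-SNV rejection reasons |
| `scvaf.qc` | cell QC on raw gene counts (detected genes, mitochondrial fraction) |
| `scvaf.vaf` | VAF estimation per minR, per-SNV summaries, pattern classification, gene aggregation, histograms, intronic chi-square |
| `scvaf.pipeline` / `scvaf.cli` | orchestration, YAML config, manifest, report tables |

## CLI

```sh
# full pipeline from a YAML config (simulate -> qc -> count -> select -> count -> vaf -> report)
scvaf run --config cfg.yaml --out outdir --seed 1

# individual stages
scvaf simulate --config cfg.yaml --out sim --seed 1
scvaf qc --mtx sim/matrix --out cells.tsv --min-genes 3000 --max-pct-mito 6
scvaf count --bam sim/alignment.sam --vcf sim/variants.vcf \
    --annot sim/annotation.tsv --out counts.tsv --whitelist whitelist.txt
scvaf select-snvs --vcf sim/variants.vcf --counts counts.tsv \
    --annot sim/annotation.tsv --out het.vcf --audit rejects.tsv
scvaf vaf --counts counts.tsv --annot sim/annotation.tsv --minr 3,5,10 --out vafdir
```

Example config:

```yaml
seed: 1
simulate:
  n_cells: 200
  n_genes: 25
  snvs_per_gene: 2
  depth_model: {kind: poisson, lam: 8}
  class_fractions: {symmetric: 0.7, rme: 0.2, skewed: 0.1}
  pcr_duplication_rate: 2.0
  n_bad_cells_low_genes: 3
  n_bad_cells_high_mito: 2
select: {min_reads_per_allele: 50}
qc: {min_genes: 3000, max_pct_mito: 6.0}
vaf: {lower: 0.2, upper: 0.8, min_cells_pattern: 50, minr_grid: [3, 5, 10]}
```

To analyze real data, replace the `simulate` section with an `inputs`
section pointing at an alignment (SAM/BAM with `CB`/`UB` tags, optional
WASP `vW` tag), a VCF of candidate SNVs, an annotation TSV
(`snv_id`, `gene`, `category`) and a MatrixMarket count-matrix directory.

Runs are deterministic: identical config and seed reproduce byte-identical
output trees, recorded in `manifest.json` (config snapshot, input
checksums, per-stage row counts).

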