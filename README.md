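# cansys

Single-sample pathway disturbance scoring from DNA variants.

`cansys` integrates per-variant deleteriousness (CADD Phred scores) with
gene essentiality (DepMap dependency probabilities) into gene-level impact
scores, maps them onto GO/KEGG gene sets with a modified gene set
enrichment analysis using a gene-permutation null, and reports:

- per-pathway disturbance records (ES, NES, permutation p, BH-adjusted p,
  and the disturbance score NES × mean member impact) per sample and per
  variant origin (somatic / germline),
- cohort-level pathway alteration frequencies and phenotypic-convergence
  statistics (shared-gene sample pairs vs a size-matched random-set null),
- significant-pathway subnetworks extracted from the GO DAG (significant
  nodes plus the connectors on their paths to the biological-process root)
  or the KEGG relation graph.

An optional expression matrix gates unexpressed genes out of the analysis
via a 5-component Gaussian mixture whose components are split into
low/high groups by k-means on their (weight, mean, sd) parameters; genes
below the smallest group boundary are considered not expressed.

## Command line

Generate a fully synthetic input bundle and score it:

```sh
cansys fixtures --kind sample --outdir demo
cansys score \
    --somatic-vcf demo/somatic.vcf --germline-vcf demo/germline.vcf \
    --expression demo/expression.tsv \
    --cadd demo/cadd.tsv --gnomad demo/gnomad.tsv --gene-table demo/genes.tsv \
    --depmap demo/depmap_precomputed.tsv --gmt demo/pathways.gmt \
    --seed 1 --outdir demo/run
```

`score` writes `results_<origin>.tsv` (one row per pathway), an audit
table of retained variants, and a `manifest.json` that reproduces the run.
Default filters follow the method: somatic AD ≥ 5 and VAF > 5%; germline
AD ≥ 5, VAF > 20%, gnomAD AF ≤ 0.001 and CADD ≥ 15; 6,000 permutations
for somatic and 1,000 for germline; pathways with BH-adjusted p < 0.25
are flagged disturbed. All thresholds are flags.

Aggregate several scored samples and test convergence:

```sh
cansys cohort demo/run other/run \
    --alterations cohort/alterations.tsv --gmt demo/pathways.gmt \
    --outdir cohort/reports
```

Export the significant-pathway subgraph for visualization:

```sh
cansys graph --results demo/run/results_somatic.tsv \
    --obo go.obo --gmt demo/pathways.gmt --out-prefix demo/run/subgraph
```

## Input formats

- VCF 4.x (plain or bgzipped), GRCh38, 1-based; AD/DP FORMAT fields.
  Multi-allelic records are split per alternate allele and VAF is
  recomputed as AD/DP.
- Lookup tables: tab-separated with header, columns
  `chrom  pos  ref  alt  value` (CADD Phred, gnomAD AF, gene symbol).
  Indel keys are parsimony-trimmed before matching.
- Dependency scores: either a precomputed two-column gene → score table or
  a gene × cell-line matrix plus a cell-line → lineage map (use
  `--cancer-type`, with `pan-cancer` averaging all lines).
- Gene sets: GMT. Ontology: OBO 1.2/1.4 (GO biological process) or a
  two-column KEGG pathway edge list.
- Expression: tab-separated raw counts, gene ids in the first column;
  transformed internally as log2(count + 1).

## A note on the ES normalization

The default running-sum statistic divides P_Hit by the impact total over
*all* universe genes (`--p-hit-denom total`). Under this form the
positive-part ES of a random gene set is very often exactly 0, so
permutation p-values concentrate rather than spread uniformly.
`--p-hit-denom set` restores the classical GSEA within-set normalization,
whose null is atom-free and yields calibrated p-values; use it when
p-value calibration across pathways matters.
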