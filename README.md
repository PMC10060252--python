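# ircohort

Intron-retention (IR) cohort analysis for case/control RNA-seq studies:

- **gene_model** — GTF parsing and derivation of constitutive ("shared")
  exonic/intronic regions per gene, plus the ordered intron list of a
  reference isoform with flanking exons (BED writers included).
- **ir_quant** — RPKM, per-gene Intron Retention Index (IRI = intronic /
  exonic read density over shared regions, detectable at RPKM > 1), and
  per-intron splicing ratios (intron RPKM over the mean RPKM of its two
  flanking exons); cohort matrices over the genes detectable in every
  sample.
- **cohort_stats** — log2-IRI histograms, pairwise Pearson sample
  correlations, Z-score average-linkage hierarchical clustering, exact
  Mann–Whitney group tests (full enumeration of the rank-sum null), and
  IRI/expression fold-change coupling with equal-count bin summaries.
- **pca_enrichment** — PCA of standardized matrices via rank-limited SVD
  (never materializing the gene×gene covariance), PC1 orientation and
  book-end gene selection (default 50 most-negative / 100 most-positive
  coefficients), hypergeometric gene-set enrichment against GMT files.
- **differential_ir** — per-intron case/control screen on splicing
  ratios: fold change ≥ 2 (or ≤ 0.5) with exact Mann–Whitney p ≤ 0.05
  defines up/down classes; volcano summaries and dual-regulation /
  first-intron reports.
- **synthetic_data** — deterministic generator of gene models and
  two-group region-count cohorts with configured ground truth (per-gene
  log2 IRI, expression, expression–IRI fold-change correlation, planted
  per-intron effects, negative-binomial noise).

## CLI

Each pipeline stage is a subcommand working on plain TSV/GTF/GMT files;
`all` chains them end to end on a synthetic cohort:

```sh
ircohort all --preset t_like --n-genes 500 --seed 7 --outdir out/
# or stage by stage:
ircohort simulate --preset b_like --seed 1 --outdir out/
ircohort regions  --gtf out/genes.gtf --outdir out/
ircohort quantify --gtf out/genes.gtf --counts out/counts.tsv \
                  --library-sizes out/library_sizes.tsv --outdir out/
ircohort cohort   --iri out/iri.tsv --metadata out/metadata.tsv --outdir out/
ircohort pca      --matrix out/cohort_matrix.tsv --metadata out/metadata.tsv --outdir out/
ircohort enrich   --subset out/book_end_positive.txt --population pop.txt \
                  --gmt sets.gmt --outdir out/
ircohort diffir   --ratios out/splicing_ratios.tsv --metadata out/metadata.tsv --outdir out/
```

Counts are consumed as a long TSV
(`sample_id gene_id region_class chrom start end count`) with region
classes `shared_exon`, `shared_intron`, `intron#<k>`,
`exon_flank#<k>#up|down`; a library-size TSV supplies total mapped reads
per sample. Presets `t_like` (14 case / 4 control) and `b_like`
(16 / 4) mirror the two study designs at desk scale.

## Conventions

All genomic coordinates are 0-based half-open internally; GTF (1-based
closed) is converted at the reader boundary. No pseudocounts anywhere:
undefined ratios are excluded, never imputed. Fold changes are ratios of
group means of linear values. All randomness flows from explicit seeds.
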