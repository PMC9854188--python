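# csscan

Composite selection-signal (CSS) genome scans for two-cohort contrasts.

Given phased diploid genotypes for a "selected" cohort and a contrasting
"reference" cohort, `csscan` computes three per-SNP component statistics —
Weir–Cockerham FST, the signed change in alternate-allele frequency
(ΔSAF), and cross-population extended haplotype homozygosity (XP-EHH) —
and combines them through fractional ranks and inverse-normal scores
into a single composite statistic per SNP (reported as −log10 of the
combined null p-value). The composite track is smoothed in centered
sliding windows over physical position, thresholded at genome-wide
empirical quantiles (top 0.1% / top 1%), and significant SNPs are
grouped into cluster regions (≥1 top-0.1% SNP supported by ≥5 top-1%
SNPs), merged when <1 Mb apart, extended with ±0.5 Mb flanks, ranked by
peak score, and intersected with a protein-coding gene annotation.

A seeded synthetic-cohort module generates phased two-population panels
with a Balding–Nichols neutral background and one implanted selective
sweep (joint frequency-shift, differentiation, and haplotype-length
signal), so the whole pipeline is testable without external data.

## Command line

```sh
# simulate a phased two-cohort panel with an implanted sweep
csscan simulate --out-dir sim/ --seed 1

# run the full scan (VCF or PLINK prefix; BED or GFF3 gene annotation)
csscan scan --genotypes sim/panel.vcf --contrast sim/contrast.tsv \
    --out-dir out/ --window-bp 100000 --genes genes.bed

# genotype-class frequencies at one SNP per sample group
csscan summarize --genotypes sim/panel.vcf --snp-id chr1.12345 --groups groups.tsv
```

`scan` writes `qc_report.tsv`, `components.tsv` (per-SNP FST/ΔSAF/XP-EHH),
`scan.tsv` (raw + smoothed CSS with top-0.1%/1% flags), `regions.tsv`,
`regions.bed` (0-based half-open peak and flank intervals), `scan.log`,
and optionally a two-panel Manhattan plot with the top-0.1% threshold
drawn as a dashed line (`--plot`). Use `--window-bp 1000000` for sparse
(~36K-scale) panels. The contrast file is two tab-separated columns:
`sample<TAB>selected|reference`.

Inputs: phased VCF (strict mode rejects unphased genotypes), PLINK
`.ped`/`.map` or `.bed`/`.bim`/`.fam` (read as unphased genotypes —
usable for frequency statistics and QC, refused for XP-EHH). QC removes
markers with missing rate > 0.05 or MAF < 0.01 (strict inequalities,
pooled samples). Coordinates are 1-based inclusive internally; BED
output converts to 0-based half-open.

## Package layout

- `csscan.genotype_io` — VCF/PLINK ingestion, QC filtering, cohort
  splitting, haplotype/marker containers.
- `csscan.component_stats` — per-SNP FST, ΔSAF, EHH/iHH, XP-EHH.
- `csscan.css_core` — fractional ranks, composite combination,
  sliding-window smoothing, empirical thresholds.
- `csscan.region_caller` — cluster calling, merging, ranking, gene
  overlap, report/BED output.
- `csscan.synthetic_cohort` — seeded two-cohort simulator with sweep
  implantation and truth records.
- `csscan.pipeline` / `csscan.cli` — end-to-end orchestration and the
  `csscan` command.
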