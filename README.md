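# karyoscope

Immortalized cell lines accumulate chromosomal abnormalities — whole-chromosome
and segmental aneuploidies, hemizygous regions, large deletions — and these
reshape their transcriptome and epigenome. `karyoscope` is a Python toolkit for
characterizing such cell-line genomes from standard sequencing summaries:

* **Ploidy inference** from whole-genome sequencing, combining binned read
  depth with the allele-support ratio of heterozygous SNPs. At a het site on a
  chromosome with `c` copies, `k` of which carry the alternate allele, the
  fraction of reads supporting the alternate concentrates around `k/c` and
  `1 − k/c`: a diploid AB chromosome peaks at 0.5, a triploid AAB at
  1/3 and 2/3, an AAAB segment at 1/4 and 3/4, while a balanced tetraploid
  AABB peaks at 0.5 and is separated from diploidy only by its doubled depth.
  A beta-binomial mixture likelihood scores candidate states per chromosome,
  binary segmentation finds segmental events and heterozygosity deserts, and
  run detection on binned depth flags large deletions/duplications.
* **Regulatory peak analysis**: the operational enhancer rule (H3K27ac peaks
  not within 1000 bp of any H3K4me3 peak), replicate concordance of peak sets
  (overlap counts, read-coverage and signal-value Pearson correlations), the
  fraction of expressed-gene TSSs carrying a mark, and chromosome-size
  normalized rates.
* **Methylome summaries**: per-context (CpG/CHG/CHH) methylation means at a
  ≥ 10× coverage threshold, sites informative in RRBS but not in WGBS
  (merged into regions and overlaid on promoters/enhancers).
* **Integrative analysis**: a per-gene table of TPM, expression class,
  TSS/gene-body methylation and per-mark peak scores; pairwise-complete
  Pearson correlation matrices; and rank-sum comparisons of expression between
  aneuploid and diploid chromosomes.
* **A truth-labelled simulator** (`karyosim`) that generates the whole input
  stack — depth tracks, het-site VCF, TPM tables, peak files, RRBS/WGBS
  CGmap tables — from an explicit karyotype description, so every inference
  step can be validated against known truth.

## Worked example

Simulate a mostly-diploid genome with one trisomic chromosome, a distal
four-copy segment, a hemizygous half-chromosome and an 8-Mb deletion, then
call ploidy from the written VCF and depth track:

```
$ karyoscope simulate --preset ipecj2 --seed 3 --out-dir sim/
wrote synthetic ipecj2 dataset to sim

$ karyoscope ploidy --vcf sim/wgs.vcf --depth sim/depth.bedGraph --out-dir calls/
baseline depth 30.52; wrote calls to calls
```

`calls/calls.tsv` then contains, per chromosome, the winning state with its
evidence:

```
chromosome best_state  confidence  depth_ratio  het_density
      chr1       2:AB     517.119        0.983      983.667
     chr16       2:AB     615.407        0.885      734.867
     chr17      3:AAB    6333.843        1.474     1004.583
     chr18       2:AB     517.119        0.983     1012.900
      chr2      3:AAB    9871.797        1.114      999.400
      chr8     4:AAAB    4640.016        1.032      495.875
```

chr17 is called `3:AAB` (depth ratio ≈ 1.5, ratio modes at 1/3 and 2/3).
chr2 and chr8 are *mixtures* of states, so their whole-chromosome calls are
compromises — `calls/segments.tsv` resolves them: chr2 into a diploid part
and a distal `4:AAAB` segment with the breakpoint placed at 12,000,196
(truth: 12 Mb), chr8 into a het-desert `1` half and a `4:AAAB` half.  The
chr16 deletion appears in `calls/depth_anomalies.tsv` as
`chr16 9000000 17000000 15.28 loss`.  Confidence is the log-likelihood margin
of the best state over the runner-up; margins below 10 are flagged
low-confidence ("possible").

The same dataset feeds the peak, methylation and integration subcommands:

```
$ karyoscope peaks enhancers --k27ac sim/H3K27ac.narrowPeak --k4me3 sim/H3K4me3.narrowPeak --out enh.bed
$ karyoscope methyl exclusive --rrbs sim/rrbs.cgmap --wgbs sim/wgbs.cgmap --out excl.bed
$ karyoscope integrate --tpm sim/tpm.tsv --gtf sim/genes.gtf \
    --rrbs sim/rrbs.cgmap --wgbs sim/wgbs.cgmap \
    --peaks H3K4me3=sim/H3K4me3.narrowPeak --out-dir tables/
```

`tables/correlations.tsv` shows the expected qualitative structure: promoter
marks (H3K4me3, H3K27ac) correlate positively with TPM, while H3K27me3 and
TSS methylation correlate negatively.

## Scope

The toolkit consumes called summaries (VCF, bedGraph, narrowPeak/broadPeak,
CGmap, GTF, TPM tables); read trimming, alignment, SNV/SV calling, peak
calling and methylation calling are upstream of it and out of scope, as are
chromatin-state learning and motif discovery.
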