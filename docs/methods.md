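# Methods

## Ploidy inference from depth and allele balance

### Model

A chromosome (or segment) is assumed to carry `c` copies, `k` of which bear
the alternate allele at a heterozygous site.  Because which haplotype group
carries the alternate is exchangeable, the per-site expected alternate-support
ratio is `k/c` or `1 − k/c` with equal probability.  Observed alternate read
counts are modelled as a two-component beta-binomial mixture:

    log L_site(s) = Σ_i log[ ½·BB(a_i | n_i, k/c, ρ) + ½·BB(a_i | n_i, 1 − k/c, ρ) ]

where `a_i`/`n_i` are alternate/total reads and ρ is the beta-binomial
intraclass correlation absorbing mapping bias and other per-site wobble
(default ρ = 0.01; ρ = 0 degenerates to a binomial).  States with no expected
heterozygosity (monosomy/LOH) instead charge each observed het site a
genotyping-error probability (default 10⁻³), so the monosomy hypothesis is
penalized in proportion to how many het sites are nevertheless observed and
favored where there are none.

Depth evidence enters as a weighted Gaussian term on the chromosome's median
binned depth: `w_d · N(median_depth | baseline·c/2, σ_d)` with
σ_d = 0.1 × baseline.  With 0.1 × baseline noise, adjacent copy-number
hypotheses differ by ≈ 12.5 log-units in this term, while ~500 het sites
typically separate ratio-distinguishable states by 100–200 log-units; the
default weight w_d = 10 therefore makes depth and a few hundred sites
comparably influential, and makes depth decisive for the states the ratios
cannot distinguish (2:AB vs 4:AABB, both peaked at 0.5).

The default candidate set is capped at four copies — `1`, `2:AB`, `3:AAB`,
`4:AABB`, `4:AAAB` — and is extensible.  Ties break toward the smaller copy
number (parsimony).  The confidence of a call is the log-likelihood margin of
the winner over the runner-up; margins below 10 are flagged low-confidence,
echoing the hedged "possible" language appropriate for such calls.  With no
het sites and no usable depth the call is `unknown`.

Classification uses the alternate-allele ratio; exported histograms use the
reference-allele ratio, matching the published plotting convention.

### Baseline estimation

The diploid depth baseline is the kernel-density mode of per-chromosome
median bin depths (the majority of chromosomes is assumed diploid), or the
median over an explicit list of trusted diploid chromosomes when supplied.
Missing bins (no covered bases) are excluded from medians, not imputed.

### Segmentation

Segmental events are found on the per-site indicator "alt ratio within ± 0.1
of 0.5" by recursive least-squares binary segmentation with a deviance-gain
threshold (gain > 10 · var · log n) and a minimum segment size of 100 sites.
The indicator is segmented directly rather than a sliding-window profile of
it: the two describe the same piecewise-constant mean model, but windowing
smears change-points by half a window.  Heterozygosity deserts — runs of
1-Mb bins with het density below 10% of the chromosome's typical per-Mb
density, spanning at least 2 Mb — contribute additional boundaries, since a
hemizygous region shows no sites at all and is invisible to site-indexed
segmentation.  Each segment is then re-classified with the chromosome
classifier restricted to its sites and depth bins, and adjacent segments with
identical states are merged.

### Depth anomalies

Loss/gain intervals are detected by binary segmentation of the binned depth
track followed by thresholding of segment means (loss below 0.6 × median,
gain above 1.4 × median, ≥ 1 Mb).  Plain run-detection on raw bins was
rejected: with negative-binomial bin noise at 50-kb resolution, a
half-depth region's bins straddle the 0.6 threshold and maximal runs
fragment.  The segmentation penalty uses a noise variance estimated from
successive bin differences, which is robust to the level shifts being
sought; segment edges are trimmed to bins that individually qualify so that
a sub-threshold-length event smeared across a minimum-size segment does not
leak past the length gate.

## Peak operations

"Within 1000 bp" in the enhancer rule is read as edge-to-edge gap ≤ 1000
(overlap counts as gap 0, and a gap of exactly 1000 bp is within), the most
permissive reading that still excludes promoter-proximal H3K27ac.  Overlap
anywhere in the package means ≥ 1 bp intersection in half-open coordinates.
Replicate concordance reports overlap counts in both directions (which set is
"round 1" is a reporting choice); read-coverage correlation is computed over
intersection intervals, and signal correlation over 1-to-1 peak pairs matched
greedily by largest overlap, since the published pairing convention for
one-to-many overlaps is not specified.

## Methylome

Context summaries use unweighted per-site means over sites with coverage
≥ 10; a context with no surviving site is reported missing rather than 0.
RRBS-exclusive sites are RRBS records with coverage ≥ 10 (CpG context by
default) whose position is absent from WGBS or present below 10×.
Opposite-strand CpG records are distinct positions by default; an optional
strand merge sums counts onto the plus-strand coordinate of the dinucleotide.
Exclusive sites are merged into regions when consecutive sites lie ≤ 200 bp
apart (a CpG-island-scale default; no published value exists) and annotated
with every promoter (H3K4me3 peak) or enhancer interval they intersect.

## Integration

Expression classes: C0 (TPM ≤ 1), C1 (1, 5], C2 (5, 20], C3 (20, 100],
C4 (> 100).  The outer bounds (1 and 100) and the 20/100 interior edge follow
the published banding; the 5 and 20 edges are configuration-exposed defaults.
TSS methylation is the mean CpG level within ± 1 kb of the start site; the
gene body is the transcribed span minus that window (whole-span alternatives
differ negligibly for the simulated architecture and the definition is
configurable).  Peak score per gene is the maximum score among peaks
intersecting TSS ± 2 kb — a maximum is robust to sub-peak fragmentation.
Correlation matrices use pairwise-complete Pearson correlations because the
assays have different missingness patterns.  The aneuploid-vs-diploid
expression comparison uses a two-sided rank-sum test with the median TPM
ratio as effect size, matching the boxplot-level (model-free) published
comparison; only genes with TPM > 2 enter, and chromosomes with fewer than
five qualifying genes are excluded.

## The simulator

`karyosim` generates data with the statistical structure the analysis
assumes, plus truth labels:

* **WGS.**  Per-50-kb-bin depth is negative-binomial with mean
  baseline · c/2 (size parameter 100, mild overdispersion relative to
  Poisson, as real WGS bins show) and copy-weighted means across segment
  boundaries.  Het sites are placed at `het_rate` (default 10⁻³/bp, a
  typical het density) on segments with c ≥ 2; per-site total depth is
  Poisson(baseline · c/2) and alternate support is beta-binomial around
  `k/c` or `1 − k/c` (fair coin per site) with ρ = 0.01.  Sites whose
  sampled counts look homozygous are dropped, as a genotype-aware caller
  would not emit them.  Monosomic segments emit no het sites.
* **Expression.**  Baseline TPM is a zero-inflated log-normal (45% of genes
  from a near-zero component), scaled by (c/2)^dosage_exponent at the gene's
  TSS (default exponent 1: proportional dosage, the neutral choice absent a
  published effect size) and renormalized to sum to 10⁶.  With a desk-scale
  gene count the renormalized TPM of expressed genes is inflated by roughly
  (true transcriptome size / n_genes); analyses should therefore read
  dosage effects as relative shifts, and the median-ratio shift test needs
  on the order of a thousand genes per chromosome group for a stable ratio
  given the heavy-tailed TPM distribution.
* **Epigenome.**  Genes above an activity threshold (the 40th TPM percentile
  by default, robust to the scale inflation above) receive an H3K4me3
  promoter peak with score increasing in log TPM, usually co-located
  H3K27ac; silent genes attract H3K27me3 domains.  Truth enhancers are
  distal H3K27ac-only peaks placed ≥ 3 kb (center) from every TSS, far
  enough that the 1000-bp enhancer rule recovers them exactly.  TSS CpG
  methylation decreases sigmoidally in log relative expression; the
  gene-body slope sign is configurable (positive by default, negative as an
  alternative regime).  RRBS covers promoter CpGs at ~70× and a 15% sample
  of gene-body CpGs at ~15×; WGBS covers everything at ~30×, except a
  configurable fraction (default 15%) of active-promoter CpGs emitted with
  WGBS coverage < 10 — the truth RRBS-exclusive set, planted inside
  H3K4me3 peaks to emulate promoter-marked regions visible only to RRBS.

### What the simulator does not model

Read-level artifacts (FASTQ/BAM), sequence content, GC or mappability bias,
SV breakpoint signatures, replicate structure in peak calling, bisulfite
conversion error, and linkage between neighboring het sites.  Passing tests
therefore demonstrate correctness of the inference machinery under the
stated generative assumptions, not robustness to every real-data artifact.

## Numerical and convention choices

* All internal coordinates are 0-based half-open; VCF/GTF/CGmap are converted
  on ingest and back on write (round trips are the identity).
* Methylation levels are always recomputed from counts; stored levels
  inconsistent by > 10⁻⁶ only trigger a warning.
* Heterozygosity is taken from the genotype field, never from ratio
  thresholds, which would bias non-diploid sites.  The het-site depth filter
  defaults to ≥ 10 (consistent with the methylation coverage rule; no
  published value exists for SNPs) and is exposed as a flag.
* KDE mode positions are read off a 512-point grid on (0, 1) from a Gaussian
  KDE with Scott bandwidth; for bimodal targets the two highest local maxima
  are reported in position order.
* Problem sizes in the test suite (10,000-site ratio-mode checks,
  200-chromosome recovery panels, 50-seed breakpoint panels, 20-seed sign
  panels at ~600 genes) were chosen as the smallest sizes at which the
  checked quantities are statistically stable.

## Known limitations

Whole-chromosome calls on mixed chromosomes are composition compromises
(e.g. a 60/40 diploid/AAAB chromosome can rank `3:AAB` highest overall);
the segment table is the authoritative view for such chromosomes.  The
candidate set caps at c = 4 by default; higher ploidies require extending
it.  Depth-only evidence cannot distinguish copy-neutral LOH from diploidy
when het sites are absent but depth is normal — such regions surface as het
deserts with state `1` and a depth ratio near 1, and deserve manual review.
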