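"""Truth-labelled synthetic karyotype / transcriptome / epigenome generator.

The simulator emulates the statistical structure every downstream stage
assumes, with explicit ground-truth labels:

* WGS: binned read depth scales with copy number (negative-binomial noise per
  bin) and heterozygous sites draw alternate-allele support from a
  beta-binomial around k/c for a segment with c copies, k of them carrying
  the alternate allele.  Hemizygous/LOH segments (c <= 1) emit no het sites.
* Expression: log-normal baseline TPM scaled by (c/2)^dosage_exponent and
  renormalized to sum to 1e6 (true TPM semantics).
* Epigenome: active promoters carry H3K4me3 (and usually H3K27ac) peaks whose
  scores rise with log TPM; silent genes attract H3K27me3 domains; distal
  H3K27ac-only peaks are the truth enhancers; TSS CpG methylation decreases
  with log TPM while the gene-body slope sign is configurable; a configurable
  fraction of promoter CpGs is emitted with RRBS coverage >= 10 but WGBS
  coverage < 10 (the truth RRBS-exclusive set).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (
    AlleleBalanceRecord,
    DepthTrack,
    GeneRecord,
    GenomeLayout,
    MethylationSite,
    Peak,
    PeakSet,
)
from .ploidy import state_label

__all__ = [
    "SegmentState",
    "KaryotypeSpec",
    "SimTruth",
    "WgsSim",
    "EpigenomeParams",
    "EpigenomeSim",
    "simulate_wgs",
    "simulate_expression",
    "simulate_epigenome",
    "ipecj2_like_spec",
    "sl29_like_spec",
    "preset_spec",
]


# ---------------------------------------------------------------------------
# karyotype description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentState:
    """Copy state of one genomic segment: c total copies, k alternate-bearing
    copies at heterozygous sites (absent when c <= 1)."""

    chromosome: str
    start: int
    end: int
    total_copies: int
    alt_copies_at_het: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        k = self.alt_copies_at_het
        if self.total_copies >= 2:
            if k is None or not (0 < k < self.total_copies):
                raise ValueError(
                    f"segment with c={self.total_copies} needs 0 < k < c (got {k})"
                )
        elif k is not None:
            raise ValueError("c <= 1 segments must not set alt_copies_at_het")

    @property
    def label(self) -> str:
        return state_label(self.total_copies, self.alt_copies_at_het)

    @property
    def is_het_capable(self) -> bool:
        return self.total_copies >= 2


@dataclass
class KaryotypeSpec:
    """Truth description of a simulated genome.

    ``baseline_depth`` is the mean per-base depth of a diploid segment;
    ``het_rate`` the heterozygous-site density (sites per bp) on het-capable
    segments; ``overdispersion`` the beta-binomial intraclass correlation of
    allele-support counts (0 = pure binomial); ``nb_dispersion`` the
    negative-binomial size parameter of per-bin depth noise.
    """

    layout: GenomeLayout
    segments: list[SegmentState] = field(default_factory=list)
    baseline_depth: float = 30.0
    het_rate: float = 1e-3
    overdispersion: float = 0.01
    nb_dispersion: float = 100.0

    def __post_init__(self) -> None:
        if self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be positive")
        if self.het_rate <= 0:
            raise ValueError("het_rate must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        self.segments = self._tiled(self.segments)

    def _tiled(self, segments: Sequence[SegmentState]) -> list[SegmentState]:
        """Validate non-overlap and fill uncovered stretches with diploid 2:AB."""
        out: list[SegmentState] = []
        by_chrom: dict[str, list[SegmentState]] = {c: [] for c in self.layout.names}
        for seg in segments:
            if seg.chromosome not in self.layout:
                raise ValueError(f"segment on unknown chromosome {seg.chromosome!r}")
            if seg.end > self.layout[seg.chromosome]:
                raise ValueError(f"segment exceeds chromosome {seg.chromosome!r}")
            by_chrom[seg.chromosome].append(seg)
        for chrom in self.layout.names:
            segs = sorted(by_chrom[chrom], key=lambda s: s.start)
            cursor = 0
            for seg in segs:
                if seg.start < cursor:
                    raise ValueError(f"overlapping segments on {chrom}")
                if seg.start > cursor:
                    out.append(SegmentState(chrom, cursor, seg.start, 2, 1))
                out.append(seg)
                cursor = seg.end
            if cursor < self.layout[chrom]:
                out.append(SegmentState(chrom, cursor, self.layout[chrom], 2, 1))
        return out

    def segments_of(self, chromosome: str) -> list[SegmentState]:
        return [s for s in self.segments if s.chromosome == chromosome]

    def state_at(self, chromosome: str, position: int) -> SegmentState:
        for seg in self.segments_of(chromosome):
            if seg.start <= position < seg.end:
                return seg
        raise ValueError(f"position {chromosome}:{position} outside layout")

    def dominant_label(self, chromosome: str) -> str:
        """Span-weighted most common state label on a chromosome."""
        spans: dict[str, int] = {}
        for seg in self.segments_of(chromosome):
            spans[seg.label] = spans.get(seg.label, 0) + (seg.end - seg.start)
        return max(spans, key=spans.get)


@dataclass
class SimTruth:
    """Ground-truth labels for one simulated dataset; JSON-serializable."""

    chromosome_states: dict[str, str] = field(default_factory=dict)
    segment_states: list[tuple[str, int, int, str]] = field(default_factory=list)
    baseline_depth: float | None = None
    dosage_factors: dict[str, float] = field(default_factory=dict)
    enhancers: list[tuple[str, int, int]] = field(default_factory=list)
    rrbs_exclusive: list[tuple[str, int]] = field(default_factory=list)
    silent_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def merge(self, other: "SimTruth") -> "SimTruth":
        merged = SimTruth(**asdict(self))
        for key, val in asdict(other).items():
            if isinstance(val, dict):
                getattr(merged, key).update(val)
            elif isinstance(val, list):
                getattr(merged, key).extend(val)
            elif val is not None:
                setattr(merged, key, val)
        return merged


# ---------------------------------------------------------------------------
# WGS simulation
# ---------------------------------------------------------------------------


@dataclass
class WgsSim:
    depth: dict[str, DepthTrack]
    records: dict[str, list[AlleleBalanceRecord]]
    truth: SimTruth


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    return np.random.default_rng(seed)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if np.any(pos):
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_wgs(spec: KaryotypeSpec, seed: int | None = None, bin_size: int = 50_000) -> WgsSim:
    """Simulate binned depth and heterozygous allele-support counts.

    Per-bin depth ~ NegBin with mean baseline * c/2 (copy-weighted across
    segment boundaries); per-het-site total depth ~ Poisson(baseline * c/2)
    and alternate support ~ BetaBinomial(total, k/c, overdispersion).  Sites
    whose sampled counts are homozygous-looking (0 or total alternate reads)
    are dropped, as a genotype-aware caller would not report them as het.
    """
    rng = _require_seed(seed)
    depth: dict[str, DepthTrack] = {}
    records: dict[str, list[AlleleBalanceRecord]] = {}
    rho = spec.overdispersion

    for chrom in spec.layout.names:
        length = spec.layout[chrom]
        n_bins = -(-length // bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        # copy-weighted mean copy number per bin
        cbar = np.zeros(n_bins)
        for seg in spec.segments_of(chrom):
            ov_lo = np.maximum(starts, seg.start)
            ov_hi = np.minimum(ends, seg.end)
            ov = np.clip(ov_hi - ov_lo, 0, None)
            cbar += ov * seg.total_copies
        cbar /= ends - starts
        mean = spec.baseline_depth * cbar / 2.0
        depth[chrom] = DepthTrack(chrom, starts, ends, _nb_draw(rng, mean, spec.nb_dispersion))

        recs: list[AlleleBalanceRecord] = []
        for seg in spec.segments_of(chrom):
            if not seg.is_het_capable:
                continue
            c, k = seg.total_copies, seg.alt_copies_at_het
            n_sites = rng.poisson(spec.het_rate * (seg.end - seg.start))
            if n_sites == 0:
                continue
            pos = np.sort(rng.choice(np.arange(seg.start, seg.end), size=n_sites, replace=False))
            total = rng.poisson(spec.baseline_depth * c / 2.0, size=n_sites)
            total = np.maximum(total, 1)
            # which haplotype group carries the alternate allele is exchangeable,
            # so per site the expected alt ratio is k/c or 1 - k/c with equal odds
            p = np.where(rng.random(n_sites) < 0.5, k / c, 1 - k / c)
            if rho > 0:
                a = p * (1 - rho) / rho
                b = (1 - p) * (1 - rho) / rho
                psite = rng.beta(a, b)
            else:
                psite = p
            alt = rng.binomial(total, psite)
            keep = (alt > 0) & (alt < total)
            for po, t, al in zip(pos[keep], total[keep], alt[keep]):
                recs.append(AlleleBalanceRecord(chrom, int(po), int(t - al), int(al)))
        records[chrom] = recs

    truth = SimTruth(
        chromosome_states={c: spec.dominant_label(c) for c in spec.layout.names},
        segment_states=[(s.chromosome, s.start, s.end, s.label) for s in spec.segments],
        baseline_depth=spec.baseline_depth,
    )
    return WgsSim(depth, records, truth)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    spec: KaryotypeSpec,
    n_genes: int = 2000,
    dosage_exponent: float = 1.0,
    seed: int | None = None,
    silent_fraction: float = 0.45,
    silent_log_mu: float = -4.0,
    silent_log_sigma: float = 1.0,
    log_mu: float = 5.7,
    log_sigma: float = 1.5,
    gene_length_mean: int = 20_000,
) -> tuple[list[GeneRecord], SimTruth]:
    """Dosage-scaled TPM: zero-inflated log-normal baseline, multiplied by
    (c/2)^dosage_exponent at the gene's TSS segment, renormalized so the
    table sums to 1e6.

    A ``silent_fraction`` of genes draws from a near-zero log-normal
    component, emulating the large not-expressed fraction of a real
    transcriptome; note that with a desk-scale gene count the renormalized
    TPM of expressed genes is inflated relative to a full transcriptome
    (mean TPM is 1e6 / n_genes by construction).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _require_seed(seed)
    lengths = np.array([spec.layout[c] for c in spec.layout.names], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_genes, p=lengths / lengths.sum())
    silent = rng.random(n_genes) < silent_fraction
    baseline = np.where(
        silent,
        rng.lognormal(mean=silent_log_mu, sigma=silent_log_sigma, size=n_genes),
        rng.lognormal(mean=log_mu, sigma=log_sigma, size=n_genes),
    )
    genes: list[GeneRecord] = []
    factors: dict[str, float] = {}
    scaled = np.empty(n_genes)
    for i in range(n_genes):
        chrom = spec.layout.names[chrom_idx[i]]
        length = spec.layout[chrom]
        glen = int(np.clip(rng.lognormal(math.log(gene_length_mean), 0.5), 1_000, length // 4))
        start = int(rng.integers(0, length - glen))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, start + glen) if strand == "+" else (start + glen, start)
        c = spec.state_at(chrom, tss).total_copies
        factor = (c / 2.0) ** dosage_exponent if c > 0 else 0.0
        gene_id = f"gene{i:05d}"
        factors[gene_id] = factor
        scaled[i] = baseline[i] * factor
        genes.append(GeneRecord(gene_id, chrom, strand, tss, tes))
    tpm = scaled / scaled.sum() * 1e6
    genes = [GeneRecord(g.gene_id, g.chromosome, g.strand, g.tss, g.tes, float(t)) for g, t in zip(genes, tpm)]
    truth = SimTruth(dosage_factors=factors, baseline_depth=spec.baseline_depth)
    return genes, truth


# ---------------------------------------------------------------------------
# epigenome simulation
# ---------------------------------------------------------------------------


@dataclass
class EpigenomeParams:
    """Knobs of the synthetic epigenome; defaults emulate an active-promoter
    architecture with an inverse TSS-methylation/expression relation."""

    promoter_halfwidth: int = 750
    enhancer_halfwidth: int = 400
    enhancer_per_gene: float = 0.5
    enhancer_min_tss_dist: int = 3_000  # center-to-TSS; keeps gap to K4me3 > 1 kb
    p_k27ac_given_active: float = 0.8
    p_k4me1_promoter: float = 0.3
    p_k4me1_enhancer: float = 0.7
    p_k27me3_silent: float = 0.8
    n_tss_cpg: int = 8
    n_gb_cpg: int = 12
    tss_window: int = 1_000
    gb_slope: float = 0.05  # per log10 TPM; >0 "pig mode", <0 "chicken mode"
    meth_concentration: float = 12.0
    wgbs_mean_cov: float = 30.0
    rrbs_promoter_cov: float = 70.0
    rrbs_gb_cov: float = 15.0
    rrbs_gb_fraction: float = 0.15
    rrbs_exclusive_fraction: float = 0.15
    # activity threshold: explicit TPM, or None to use the active_quantile of
    # the supplied TPMs (robust to the 1e6/n_genes scale inflation of small
    # simulated transcriptomes)
    active_tpm: float | None = None
    active_quantile: float = 0.4


@dataclass
class EpigenomeSim:
    peaks: dict[str, PeakSet]
    rrbs: list[MethylationSite]
    wgbs: list[MethylationSite]
    truth: SimTruth


def _peak(chrom: str, center: int, halfwidth: int, name: str, signal: float) -> Peak:
    start = max(0, center - halfwidth)
    return Peak(
        chrom, start, center + halfwidth, name=name,
        score=min(1000.0, round(10 * signal)), signal_value=float(signal),
        summit_offset=center - start,
    )


def simulate_epigenome(
    genes: Sequence[GeneRecord],
    seed: int | None = None,
    params: EpigenomeParams | None = None,
) -> EpigenomeSim:
    """Place promoter/enhancer/repressive peaks and per-CpG methylation counts.

    Active genes (probabilistic in TPM) get an H3K4me3 promoter peak, usually
    co-located H3K27ac; silent genes get H3K27me3 domains.  Distal
    H3K27ac-only peaks are the truth enhancers, placed far enough from every
    TSS that the enhancer distance rule can recover them exactly.  TSS CpG
    methylation decreases with log TPM; a configurable fraction of promoter
    CpGs receives RRBS coverage >= 10 with WGBS coverage < 10.
    """
    p = params or EpigenomeParams()
    rng = _require_seed(seed)
    if any(g.tpm is None for g in genes):
        raise ValueError("genes must carry TPM before epigenome simulation")
    tpms = np.array([g.tpm for g in genes])
    thresh = p.active_tpm if p.active_tpm is not None else float(np.quantile(tpms, p.active_quantile))
    thresh = max(thresh, 1e-6)
    used_cpg: set[tuple[str, int]] = set()

    k4me3: list[Peak] = []
    k27ac: list[Peak] = []
    k4me1: list[Peak] = []
    k27me3: list[Peak] = []
    rrbs: list[MethylationSite] = []
    wgbs: list[MethylationSite] = []
    truth_enh: list[tuple[str, int, int]] = []
    truth_excl: list[tuple[str, int]] = []
    silent_ids: list[str] = []

    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chromosome, []).append(g.tss)

    def meth_site(chrom: str, pos: int, mu: float, cov: float) -> MethylationSite | None:
        total = int(rng.poisson(cov))
        if total == 0:
            return None
        level = rng.beta(mu * p.meth_concentration, (1 - mu) * p.meth_concentration)
        return MethylationSite(chrom, pos, "+", "CpG", int(rng.binomial(total, level)), total)

    for g in genes:
        # expression relative to the activity threshold, in decades
        rel = math.log10((g.tpm + 1e-3) / thresh)
        active = rng.random() < (0.9 if g.tpm > thresh else 0.05)
        if active:
            sig = max(0.5, 2.0 + 1.5 * rel * rng.lognormal(0, 0.25))
            k4me3.append(_peak(g.chromosome, g.tss, p.promoter_halfwidth, f"{g.gene_id}_k4me3", sig))
            if rng.random() < p.p_k27ac_given_active:
                k27ac.append(
                    _peak(g.chromosome, g.tss, p.promoter_halfwidth, f"{g.gene_id}_k27ac", sig * rng.lognormal(0, 0.2))
                )
            if rng.random() < p.p_k4me1_promoter:
                k4me1.append(
                    _peak(g.chromosome, g.tss, p.promoter_halfwidth, f"{g.gene_id}_k4me1", rng.lognormal(0.5, 0.3))
                )
        else:
            if g.tpm <= thresh:
                silent_ids.append(g.gene_id)
            if g.tpm <= thresh and rng.random() < p.p_k27me3_silent:
                lo, hi = g.span
                k27me3.append(
                    Peak(
                        g.chromosome, max(0, lo - 1000), hi + 1000,
                        name=f"{g.gene_id}_k27me3",
                        score=round(10 * rng.lognormal(1.0, 0.3)),
                        signal_value=float(rng.lognormal(1.0, 0.3)),
                    )
                )

        # TSS methylation: decreasing in log TPM
        mu_tss = 1.0 / (1.0 + math.exp(-(1.2 - 1.0 * rel)))
        mu_tss = min(max(mu_tss, 0.03), 0.97)
        tss_pos = np.sort(
            rng.choice(
                np.arange(max(0, g.tss - p.tss_window), g.tss + p.tss_window),
                size=p.n_tss_cpg, replace=False,
            )
        )
        tss_pos = [int(x) for x in tss_pos if (g.chromosome, int(x)) not in used_cpg]
        used_cpg.update((g.chromosome, x) for x in tss_pos)
        # RRBS-exclusive sites are planted inside active-promoter H3K4me3 peaks,
        # emulating the promoter-marked regions seen only in RRBS data
        eligible = np.array(
            [active and abs(x - g.tss) < p.promoter_halfwidth for x in tss_pos], dtype=bool
        )
        exclusive = (rng.random(len(tss_pos)) < p.rrbs_exclusive_fraction) & eligible
        for pos, excl in zip(tss_pos, exclusive):
            r = meth_site(g.chromosome, int(pos), mu_tss, p.rrbs_promoter_cov)
            if r is not None and r.total_reads >= 10:
                rrbs.append(r)
            else:
                excl = False  # no qualifying RRBS record -> not a truth exclusive site
            if excl:
                # WGBS present but under-covered at this site
                total = int(rng.integers(1, 10))
                level = rng.beta(mu_tss * p.meth_concentration, (1 - mu_tss) * p.meth_concentration)
                wgbs.append(MethylationSite(g.chromosome, int(pos), "+", "CpG", int(rng.binomial(total, level)), total))
                truth_excl.append((g.chromosome, int(pos)))
            else:
                w = meth_site(g.chromosome, int(pos), mu_tss, p.wgbs_mean_cov)
                if w is not None:
                    wgbs.append(w)

        # gene-body methylation with configurable slope sign
        lo, hi = g.span
        body_lo, body_hi = g.tss + p.tss_window, hi
        if g.strand == "-":
            body_lo, body_hi = lo, g.tss - p.tss_window
        if body_hi - body_lo > p.n_gb_cpg:
            mu_gb = min(max(0.6 + p.gb_slope * rel, 0.05), 0.95)
            gb_pos = np.sort(rng.choice(np.arange(body_lo, body_hi), size=p.n_gb_cpg, replace=False))
            gb_pos = [int(x) for x in gb_pos if (g.chromosome, int(x)) not in used_cpg]
            used_cpg.update((g.chromosome, x) for x in gb_pos)
            for pos in gb_pos:
                w = meth_site(g.chromosome, int(pos), mu_gb, p.wgbs_mean_cov)
                if w is not None:
                    wgbs.append(w)
                if rng.random() < p.rrbs_gb_fraction:
                    rs = meth_site(g.chromosome, int(pos), mu_gb, p.rrbs_gb_cov)
                    if rs is not None:
                        rrbs.append(rs)

    # distal truth enhancers: H3K27ac only, >= enhancer_min_tss_dist from every TSS
    n_enh = int(p.enhancer_per_gene * len(genes))
    chroms = sorted(tss_by_chrom)
    chrom_max = {c: max(tss_by_chrom[c]) + 200_000 for c in chroms}
    placed = 0
    attempts = 0
    while placed < n_enh and attempts < 50 * n_enh:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(p.enhancer_halfwidth, chrom_max[chrom]))
        tss_arr = np.asarray(tss_by_chrom[chrom])
        if np.min(np.abs(tss_arr - center)) < p.enhancer_min_tss_dist:
            continue
        sig = float(rng.lognormal(1.2, 0.5))
        pk = _peak(chrom, center, p.enhancer_halfwidth, f"enh{placed:05d}", sig)
        k27ac.append(pk)
        truth_enh.append((pk.chromosome, pk.start, pk.end))
        if rng.random() < p.p_k4me1_enhancer:
            k4me1.append(_peak(chrom, center, p.enhancer_halfwidth, f"enh{placed:05d}_k4me1", rng.lognormal(0.8, 0.3)))
        placed += 1

    peaks = {
        "H3K4me3": PeakSet(k4me3, mark="H3K4me3"),
        "H3K27ac": PeakSet(k27ac, mark="H3K27ac"),
        "H3K4me1": PeakSet(k4me1, mark="H3K4me1"),
        "H3K27me3": PeakSet(k27me3, mark="H3K27me3"),
    }
    rrbs.sort(key=lambda s: (s.chromosome, s.position))
    wgbs.sort(key=lambda s: (s.chromosome, s.position))
    truth = SimTruth(
        enhancers=sorted(truth_enh),
        rrbs_exclusive=sorted(truth_excl),
        silent_genes=silent_ids,
    )
    return EpigenomeSim(peaks, rrbs, wgbs, truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def ipecj2_like_spec(
    baseline_depth: float = 30.0,
    het_rate: float = 1e-3,
    overdispersion: float = 0.01,
) -> KaryotypeSpec:
    """Mostly diploid genome with one whole-chromosome trisomy, a distal
    higher-ploidy segment, a proximal monosomic half and an 8-Mb deletion."""
    layout = GenomeLayout(
        {"chr1": 12_000_000, "chr2": 20_000_000, "chr8": 16_000_000,
         "chr16": 30_000_000, "chr17": 12_000_000, "chr18": 10_000_000}
    )
    segments = [
        SegmentState("chr17", 0, 12_000_000, 3, 1),                 # whole-chromosome trisomy
        SegmentState("chr2", 12_000_000, 20_000_000, 4, 1),         # distal 0.25/0.75 segment
        SegmentState("chr8", 0, 8_000_000, 1),                      # proximal het desert
        SegmentState("chr8", 8_000_000, 16_000_000, 4, 1),
        SegmentState("chr16", 9_000_000, 17_000_000, 1),            # 8-Mb deletion
    ]
    return KaryotypeSpec(layout, segments, baseline_depth, het_rate, overdispersion)


def sl29_like_spec(
    baseline_depth: float = 30.0,
    het_rate: float = 1e-3,
    overdispersion: float = 0.01,
) -> KaryotypeSpec:
    """As the IPEC-J2-like preset, plus a balanced tetraploid chromosome."""
    base = ipecj2_like_spec(baseline_depth, het_rate, overdispersion)
    lengths = base.layout.lengths
    lengths["chr20"] = 14_000_000
    layout = GenomeLayout(lengths)
    segments = [s for s in base.segments if s.label != "2:AB"]
    segments.append(SegmentState("chr20", 0, 14_000_000, 4, 2))
    return KaryotypeSpec(layout, segments, baseline_depth, het_rate, overdispersion)


def preset_spec(name: str, **kwargs) -> KaryotypeSpec:
    presets = {"ipecj2": ipecj2_like_spec, "sl29": sl29_like_spec}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name](**kwargs)
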