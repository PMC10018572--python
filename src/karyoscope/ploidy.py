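"""Chromosome and segment ploidy inference from depth and allele balance.

At a heterozygous site on a chromosome with ``c`` total copies of which ``k``
carry the alternate allele, the fraction of reads supporting the alternate
allele concentrates around ``k/c`` (and, by exchangeability of which haplotype
carries the alternate, around ``1 - k/c``).  A diploid AB site sits at 0.5, a
triploid AAB site at 1/3 or 2/3, a tetraploid AAAB site at 1/4 or 3/4 while a
balanced tetraploid AABB site is back at 0.5 and is only separable from
diploidy through its doubled read depth.  The classifier scores a candidate
copy configuration by a beta-binomial mixture over the two expected ratios,
adds a Gaussian depth term on the chromosome's median binned depth relative
to a diploid baseline, and penalizes het-capable states in het deserts.
Segmental events are found by binary segmentation of the per-site
"allele ratio near 0.5" indicator, and copy-loss regions by run detection on
the binned depth track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import argrelextrema
from scipy.special import logsumexp

from .formats_io import AlleleBalanceRecord, DepthTrack

__all__ = [
    "AlleleBalanceRecord",
    "CandidateState",
    "ChromosomePloidyCall",
    "SegmentCall",
    "DepthAnomaly",
    "expected_allele_ratios",
    "state_label",
    "make_state",
    "DEFAULT_CANDIDATES",
    "site_log_likelihood",
    "classify_chromosome_ploidy",
    "bin_depth",
    "diploid_baseline",
    "segment_allele_ratio",
    "detect_depth_anomalies",
    "ratio_kde_modes",
]


# ---------------------------------------------------------------------------
# candidate states
# ---------------------------------------------------------------------------


def expected_allele_ratios(total_copies: int, alt_copies: int) -> set[float]:
    """Expected alt-allele support ratios {k/c, 1 - k/c} for 0 < k < c.

    Empty for homozygous or hemizygous configurations, which present no
    heterozygous sites at all.
    """
    c, k = int(total_copies), int(alt_copies)
    if c < 0 or k < 0:
        raise ValueError("copy numbers must be non-negative")
    if k > c:
        raise ValueError(f"alt copies ({k}) exceed total copies ({c})")
    if c < 2 or k == 0 or k == c:
        return set()
    # (c-k)/c rather than 1 - k/c keeps the pair exactly symmetric in k <-> c-k
    return {k / c, (c - k) / c}


def state_label(total_copies: int, alt_copies: int | None = None) -> str:
    """Canonical label: "1" for monosomy, else e.g. "3:AAB", "4:AABB"."""
    c = int(total_copies)
    if c <= 1:
        return str(c)
    if alt_copies is None:
        raise ValueError("het-capable state needs alt_copies")
    k = min(int(alt_copies), c - int(alt_copies))
    return f"{c}:{'A' * (c - k)}{'B' * k}"


@dataclass(frozen=True)
class CandidateState:
    """A copy-number/allele configuration hypothesis."""

    label: str
    total_copies: int
    alt_copies: int | None = None

    @property
    def expected_ratios(self) -> tuple[float, ...]:
        if self.alt_copies is None:
            return ()
        return tuple(sorted(expected_allele_ratios(self.total_copies, self.alt_copies)))

    @property
    def expected_depth_factor(self) -> float:
        return self.total_copies / 2.0

    @property
    def is_het_capable(self) -> bool:
        return len(self.expected_ratios) > 0


def make_state(total_copies: int, alt_copies: int | None = None) -> CandidateState:
    if total_copies >= 2 and alt_copies is not None:
        if not expected_allele_ratios(total_copies, alt_copies):
            raise ValueError(f"({total_copies},{alt_copies}) is not heterozygous")
    return CandidateState(state_label(total_copies, alt_copies), total_copies, alt_copies)


# candidate set capped at c <= 4; ordered by copy number so argmax ties
# resolve toward the more parsimonious (smaller c) state
DEFAULT_CANDIDATES: tuple[CandidateState, ...] = (
    make_state(1),
    make_state(2, 1),
    make_state(3, 1),
    make_state(4, 2),
    make_state(4, 1),
)

UNKNOWN_STATE = "unknown"


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _component_logpmf(alt: np.ndarray, total: np.ndarray, p: float, rho: float) -> np.ndarray:
    if rho <= 0:
        return stats.binom.logpmf(alt, total, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return stats.betabinom.logpmf(alt, total, a, b)


def site_log_likelihood(
    alt: np.ndarray,
    total: np.ndarray,
    state: CandidateState,
    rho: float = 0.01,
    err_rate: float = 1e-3,
) -> float:
    """Summed per-site log-likelihood of the allele-support counts under a state.

    Het-capable states use an equal-weight beta-binomial mixture over the two
    expected ratios; states with no expected heterozygosity charge every
    observed het site a genotyping-error probability ``err_rate``.
    """
    alt = np.asarray(alt)
    total = np.asarray(total)
    if not state.is_het_capable:
        return float(len(alt) * math.log(err_rate))
    ratios = state.expected_ratios
    if len(ratios) == 1 or math.isclose(ratios[0], ratios[-1]):
        return float(np.sum(_component_logpmf(alt, total, ratios[0], rho)))
    comps = np.stack([_component_logpmf(alt, total, p, rho) for p in ratios])
    return float(np.sum(logsumexp(comps + math.log(0.5), axis=0)))


@dataclass
class ChromosomePloidyCall:
    """Per-chromosome inferred state with full per-candidate evidence."""

    chromosome: str
    best_state: str
    log_likelihoods: dict[str, float]
    median_bin_depth: float | None
    depth_ratio_to_baseline: float | None
    het_density: float | None  # sites per Mb
    confidence: float
    low_confidence: bool


def classify_chromosome_ploidy(
    records: Sequence[AlleleBalanceRecord],
    median_depth: float | None,
    baseline: float | None,
    candidates: Sequence[CandidateState] = DEFAULT_CANDIDATES,
    *,
    rho: float = 0.01,
    depth_weight: float = 10.0,
    depth_sigma_frac: float = 0.1,
    err_rate: float = 1e-3,
    het_density: float | None = None,
    expected_het_density: float | None = None,
    desert_fraction: float = 0.1,
    desert_penalty: float = 10.0,
    confidence_floor: float = 10.0,
    chromosome: str = "",
) -> ChromosomePloidyCall:
    """Score candidate copy configurations and return the maximum-likelihood call.

    log L(s) = sum_sites log[ 0.5 BB(alt | n, k/c, rho) + 0.5 BB(alt | n, 1-k/c, rho) ]
             + depth_weight * Normal(median_depth | baseline * c/2, depth_sigma_frac * baseline)
             + het-density term (desert penalty against het-capable states).

    Ties break toward smaller total copy number via candidate ordering.  With
    zero het sites and no depth evidence the call is "unknown".
    """
    alt = np.array([r.alt_reads for r in records], dtype=np.int64)
    total = np.array([r.total for r in records], dtype=np.int64)
    n_sites = len(records)
    depth_ratio = None
    if median_depth is not None and baseline:
        depth_ratio = median_depth / baseline

    if n_sites == 0 and median_depth is None:
        return ChromosomePloidyCall(
            chromosome, UNKNOWN_STATE, {}, None, None, het_density, 0.0, True
        )

    is_desert = (
        het_density is not None
        and expected_het_density is not None
        and het_density < desert_fraction * expected_het_density
    )

    lls: dict[str, float] = {}
    ordered = sorted(candidates, key=lambda s: s.total_copies)
    for state in ordered:
        ll = site_log_likelihood(alt, total, state, rho=rho, err_rate=err_rate)
        if median_depth is not None and baseline:
            ll += depth_weight * stats.norm.logpdf(
                median_depth, loc=baseline * state.expected_depth_factor, scale=depth_sigma_frac * baseline
            )
        if is_desert and state.is_het_capable:
            ll -= desert_penalty
        lls[state.label] = ll

    best = ordered[0].label
    for state in ordered[1:]:
        if lls[state.label] > lls[best]:
            best = state.label
    values = sorted(lls.values(), reverse=True)
    confidence = values[0] - values[1] if len(values) > 1 else 0.0
    return ChromosomePloidyCall(
        chromosome,
        best,
        lls,
        median_depth,
        depth_ratio,
        het_density,
        confidence,
        confidence < confidence_floor,
    )


# ---------------------------------------------------------------------------
# depth binning, baseline, anomalies
# ---------------------------------------------------------------------------


def bin_depth(track: DepthTrack, bin_size: int = 50_000, chrom_length: int | None = None) -> DepthTrack:
    """Rebin a depth track into fixed bins (coverage-weighted means).

    The trailing partial bin is averaged over its own width; bins with no
    covered bases get NaN depth (flagged missing).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(track) == 0:
        return DepthTrack(track.chromosome, np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([]))
    length = int(chrom_length) if chrom_length is not None else int(track.ends[-1])
    n_bins = max(1, -(-length // bin_size))
    wsum = np.zeros(n_bins)
    cov = np.zeros(n_bins)
    for s, e, d in track.intervals():
        if not np.isfinite(d):
            continue
        b0, b1 = s // bin_size, (min(e, length) - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(s, b * bin_size)
            hi = min(e, (b + 1) * bin_size, length)
            if hi > lo:
                wsum[b] += d * (hi - lo)
                cov[b] += hi - lo
    depths = np.full(n_bins, np.nan)
    covered = cov > 0
    depths[covered] = wsum[covered] / cov[covered]
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, length)
    return DepthTrack(track.chromosome, starts, ends, depths)


def diploid_baseline(
    binned: Mapping[str, DepthTrack],
    prior_diploid: Sequence[str] | None = None,
) -> float:
    """Estimate the diploid depth baseline from per-chromosome median bin depths.

    With a prior list of trusted diploid chromosomes, the median over those;
    otherwise the kernel-density mode of the per-chromosome medians (the
    majority of chromosomes is assumed diploid).
    """
    medians = {c: t.median_depth() for c, t in binned.items()}
    medians = {c: m for c, m in medians.items() if m is not None}
    if not medians:
        raise ValueError("no chromosome has usable depth")
    if prior_diploid is not None:
        vals = [medians[c] for c in prior_diploid]
        return float(np.median(vals))
    vals = np.array(sorted(medians.values()))
    if len(vals) < 3 or np.ptp(vals) == 0:
        return float(np.median(vals))
    kde = stats.gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass(frozen=True)
class DepthAnomaly:
    start: int
    end: int
    mean_depth: float
    kind: str  # "loss" | "gain"


def detect_depth_anomalies(
    binned: DepthTrack,
    chromosome_median: float | None = None,
    drop_factor: float = 0.6,
    min_length: int = 1_000_000,
    penalty_scale: float = 10.0,
) -> list[DepthAnomaly]:
    """Depth-loss/gain intervals of at least min_length.

    The binned track is first cut into homogeneous runs by least-squares
    binary segmentation (robust to per-bin counting noise); runs whose mean
    depth falls below drop_factor x median are reported as losses, above
    (2 - drop_factor) x median as gains.  A constant track yields nothing and
    events shorter than min_length are gated out.
    """
    med = chromosome_median if chromosome_median is not None else binned.median_depth()
    if med is None:
        return []
    finite = np.isfinite(binned.depths)
    depths = binned.depths[finite]
    starts = binned.starts[finite]
    ends = binned.ends[finite]
    n = len(depths)
    if n == 0:
        return []
    widths = ends - starts
    min_bins = max(2, int(np.ceil(min_length / float(np.median(widths)))))
    # noise variance from successive differences (robust to the level shifts
    # we are trying to find, unlike the overall variance)
    if n > 1:
        noise_var = (1.4826 * float(np.median(np.abs(np.diff(depths))))) ** 2 / 2.0
    else:
        noise_var = 0.0
    penalty = penalty_scale * max(noise_var, 1e-6) * math.log(max(n, 2))
    bounds = [0, *_binseg(depths, min_bins, penalty), n]

    merged: list[DepthAnomaly] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mean = float(np.mean(depths[lo:hi]))
        if mean < drop_factor * med:
            kind = "loss"
            bin_ok = depths < drop_factor * med
        elif mean > (2 - drop_factor) * med:
            kind = "gain"
            bin_ok = depths > (2 - drop_factor) * med
        else:
            continue
        # trim edge bins that do not themselves qualify (segmentation with a
        # minimum segment size can smear a short event across its boundary)
        while lo < hi and not bin_ok[lo]:
            lo += 1
        while hi > lo and not bin_ok[hi - 1]:
            hi -= 1
        if hi == lo:
            continue
        mean = float(np.mean(depths[lo:hi]))
        start, end = int(starts[lo]), int(ends[hi - 1])
        if merged and merged[-1].kind == kind and merged[-1].end == start:
            w0, w1 = merged[-1].end - merged[-1].start, end - start
            merged[-1] = DepthAnomaly(
                merged[-1].start, end, (merged[-1].mean_depth * w0 + mean * w1) / (w0 + w1), kind
            )
        else:
            merged.append(DepthAnomaly(start, end, mean, kind))
    return [a for a in merged if a.end - a.start >= min_length]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _binseg(x: np.ndarray, min_size: int, penalty: float) -> list[int]:
    """Recursive least-squares binary segmentation; returns split indices."""
    splits: list[int] = []

    def best_split(lo: int, hi: int) -> tuple[float, int]:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_size:
            return -np.inf, -1
        csum = np.cumsum(seg)
        tot = csum[-1]
        t = np.arange(min_size, n - min_size + 1)
        left = csum[t - 1]
        # RSS reduction of splitting at t: n_l*n_r/n * (mean_l - mean_r)^2
        mean_l = left / t
        mean_r = (tot - left) / (n - t)
        gain = t * (n - t) / n * (mean_l - mean_r) ** 2
        i = int(np.argmax(gain))
        return float(gain[i]), lo + int(t[i])

    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        gain, t = best_split(lo, hi)
        if gain > penalty:
            splits.append(t)
            stack.append((lo, t))
            stack.append((t, hi))
    return sorted(splits)


@dataclass
class SegmentCall:
    chromosome: str
    start: int
    end: int
    state: str
    n_sites: int
    mean_depth: float | None
    confidence: float = 0.0
    low_confidence: bool = False


def segment_allele_ratio(
    records: Sequence[AlleleBalanceRecord],
    window_sites: int = 200,
    min_segment_sites: int = 100,
    *,
    band: float = 0.1,
    depth_track: DepthTrack | None = None,
    baseline: float | None = None,
    chrom_length: int | None = None,
    candidates: Sequence[CandidateState] = DEFAULT_CANDIDATES,
    rho: float = 0.01,
    depth_weight: float = 10.0,
    desert_bin: int = 1_000_000,
    desert_fraction: float = 0.1,
    desert_min_length: int = 2_000_000,
    penalty_scale: float = 10.0,
) -> list[SegmentCall]:
    """Segment a chromosome by allele-ratio composition and call each segment.

    Change-points come from binary segmentation of the per-site indicator
    "ratio_alt within +/- band of 0.5"; heterozygosity deserts (>= desert_min_length
    with het density below desert_fraction of the chromosome's typical per-Mb
    density) contribute additional boundaries.  Each segment is re-classified
    with the chromosome classifier restricted to its sites and depth bins and
    adjacent segments with identical state are merged.
    """
    records = sorted(records, key=lambda r: r.position)
    pos = np.array([r.position for r in records], dtype=np.int64)
    n = len(records)
    if chrom_length is None:
        if depth_track is not None and len(depth_track):
            chrom_length = int(depth_track.ends[-1])
        elif n:
            chrom_length = int(pos[-1]) + 1
        else:
            raise ValueError("need records, a depth track, or chrom_length")
    chrom = records[0].chromosome if n else (depth_track.chromosome if depth_track is not None else "")

    breakpoints: set[int] = set()
    if n >= 2 * min_segment_sites:
        indicator = (np.abs([r.ratio_alt for r in records] - np.float64(0.5)) <= band).astype(float)
        var = float(indicator.var())
        penalty = penalty_scale * max(var, 1e-3) * math.log(max(n, 2))
        for t in _binseg(indicator, min_segment_sites, penalty):
            breakpoints.add(int((pos[t - 1] + pos[t]) // 2))

    # het deserts: runs of low-density 1-Mb bins
    overall_density = n / (chrom_length / desert_bin) if chrom_length else 0.0
    if n and chrom_length >= 2 * desert_bin:
        n_dbins = -(-chrom_length // desert_bin)
        counts = np.bincount(pos // desert_bin, minlength=n_dbins)
        nonzero = counts[counts > 0]
        typical = float(np.median(nonzero)) if nonzero.size else 0.0
        low = counts < desert_fraction * max(typical, 1.0)
        i = 0
        while i < n_dbins:
            if not low[i]:
                i += 1
                continue
            j = i
            while j < n_dbins and low[j]:
                j += 1
            start = i * desert_bin
            end = min(j * desert_bin, chrom_length)
            if end - start >= desert_min_length:
                if start > 0:
                    breakpoints.add(start)
                if end < chrom_length:
                    breakpoints.add(end)
            i = j

    bounds = [0] + sorted(b for b in breakpoints if 0 < b < chrom_length) + [chrom_length]

    exp_density_mb = n / (chrom_length / 1e6) if chrom_length else None
    segs: list[SegmentCall] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = [r for r in records if lo <= r.position < hi]
        mean_depth = depth_track.mean_depth(lo, hi) if depth_track is not None else None
        density = len(sel) / ((hi - lo) / 1e6)
        call = classify_chromosome_ploidy(
            sel,
            mean_depth,
            baseline,
            candidates,
            rho=rho,
            depth_weight=depth_weight,
            het_density=density,
            expected_het_density=exp_density_mb,
            chromosome=chrom,
        )
        segs.append(
            SegmentCall(
                chrom, lo, hi, call.best_state, len(sel), mean_depth,
                call.confidence, call.low_confidence or len(sel) < min_segment_sites,
            )
        )

    # merge adjacent identical states
    merged: list[SegmentCall] = []
    for seg in segs:
        if merged and merged[-1].state == seg.state:
            prev = merged[-1]
            w_prev, w_cur = prev.end - prev.start, seg.end - seg.start
            if prev.mean_depth is not None and seg.mean_depth is not None:
                depth = (prev.mean_depth * w_prev + seg.mean_depth * w_cur) / (w_prev + w_cur)
            else:
                depth = prev.mean_depth if prev.mean_depth is not None else seg.mean_depth
            merged[-1] = SegmentCall(
                prev.chromosome, prev.start, seg.end, prev.state,
                prev.n_sites + seg.n_sites, depth,
                min(prev.confidence, seg.confidence),
                prev.low_confidence and seg.low_confidence,
            )
        else:
            merged.append(seg)
    if n < min_segment_sites:
        merged = [SegmentCall(s.chromosome, s.start, s.end, s.state, s.n_sites, s.mean_depth, s.confidence, True) for s in merged]
    return merged


# ---------------------------------------------------------------------------
# histogram / KDE helpers (plotting parity with the allele-ratio figures)
# ---------------------------------------------------------------------------


def ratio_kde_modes(ratios: np.ndarray, n_modes: int = 1, grid_size: int = 512) -> tuple[float, ...]:
    """Positions of the strongest kernel-density modes of an allele-ratio sample.

    Returns the ``n_modes`` highest local maxima of a Gaussian KDE evaluated on
    (0, 1), sorted by position.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least two ratios")
    kde = stats.gaussian_kde(ratios)
    xs = np.linspace(0.005, 0.995, grid_size)
    ys = kde(xs)
    if n_modes == 1:
        return (float(xs[np.argmax(ys)]),)
    peaks = argrelextrema(ys, np.greater)[0]
    if len(peaks) < n_modes:  # fall back to global extremes per half
        peaks = np.array([np.argmax(ys[xs < 0.5]), int(np.argmax(ys[xs >= 0.5]) + np.sum(xs < 0.5))])
    top = peaks[np.argsort(ys[peaks])[::-1][:n_modes]]
    return tuple(sorted(float(xs[i]) for i in top))


def ratio_histogram(
    records: Sequence[AlleleBalanceRecord], bins: int = 50, convention: str = "ref"
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (edges, counts) of per-site allele-support ratios.

    ``convention="ref"`` mirrors the published reference-allele histograms;
    classification itself uses the alt ratio.
    """
    if convention not in ("ref", "alt"):
        raise ValueError("convention must be 'ref' or 'alt'")
    vals = [r.ratio_ref if convention == "ref" else r.ratio_alt for r in records]
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return edges, counts
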