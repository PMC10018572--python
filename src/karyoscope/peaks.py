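"""Peak-set computations: the enhancer distance rule, replicate concordance,
TSS mark fraction and per-chromosome rate normalization.

The operational enhancer definition is an H3K27ac peak whose edge-to-edge gap
to every H3K4me3 peak exceeds 1000 bp; overlap counts as gap 0, and a gap of
exactly 1000 bp is "within" and therefore removed (the most permissive reading
that still excludes promoter-proximal H3K27ac).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import DepthTrack, GeneRecord, GenomeLayout, Peak, PeakSet

__all__ = [
    "PeakSet",
    "ConcordanceReport",
    "call_enhancers",
    "replicate_concordance",
    "tss_mark_fraction",
    "per_chromosome_rate",
]


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 when overlapping."""
    return max(b_start - a_end, a_start - b_end, 0)


def call_enhancers(h3k27ac: PeakSet, h3k4me3: PeakSet, distance: int = 1000) -> PeakSet:
    """H3K27ac peaks farther than ``distance`` bp from every H3K4me3 peak.

    Output is a subset of the input in the same order.  Idempotent, and
    anti-monotone in ``distance`` (a larger distance never yields more
    enhancers).
    """
    k4 = h3k4me3.by_chromosome()
    kept: list[Peak] = []
    for p in h3k27ac:
        if p.chromosome not in k4:
            kept.append(p)
            continue
        starts, ends, _ = k4[p.chromosome]
        # within <=> k4.start <= p.end + distance and k4.end >= p.start - distance
        within = (starts <= p.end + distance) & (ends >= p.start - distance)
        if not np.any(within):
            kept.append(p)
    return PeakSet(kept, mark=h3k27ac.mark or "enhancer", replicate=h3k27ac.replicate)


@dataclass
class ConcordanceReport:
    """Replicate agreement: overlap counts and Pearson correlations.

    ``n_overlapping`` counts peaks of ``a`` intersecting >= 1 bp of any peak in
    ``b``; ``n_overlapping_b`` gives the transposed direction.  Correlations
    are reported as None when fewer than two overlapping regions exist.
    """

    n_a: int
    n_b: int
    n_overlapping: int
    n_overlapping_b: int
    coverage_correlation: float | None
    signal_correlation: float | None


def _overlap_pairs(a: PeakSet, b: PeakSet) -> list[tuple[int, int, int, int]]:
    """All intersecting (i_a, i_b, inter_start, inter_end) pairs."""
    pairs = []
    bb = b.by_chromosome()
    for i, p in enumerate(a):
        if p.chromosome not in bb:
            continue
        starts, ends, idx = bb[p.chromosome]
        hit = (starts < p.end) & (ends > p.start)
        for j in np.nonzero(hit)[0]:
            pairs.append((i, int(idx[j]), max(p.start, int(starts[j])), min(p.end, int(ends[j]))))
    return pairs


def _pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    if len(x) < 2:
        return None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


def replicate_concordance(
    a: PeakSet,
    b: PeakSet,
    coverage_a: Mapping[str, DepthTrack] | None = None,
    coverage_b: Mapping[str, DepthTrack] | None = None,
) -> ConcordanceReport:
    """Compare two replicate peak sets.

    Coverage correlation is the Pearson r of the two replicates' mean read
    coverage over each intersection interval; signal correlation is the
    Pearson r of signal values over 1-to-1 matched overlapping peak pairs,
    where pairs are matched greedily by largest overlap.
    """
    pairs = _overlap_pairs(a, b)
    n_overlap_a = len({i for i, _, _, _ in pairs})
    n_overlap_b = len({j for _, j, _, _ in pairs})

    cov_r = None
    if coverage_a is not None and coverage_b is not None and pairs:
        xs, ys = [], []
        for i, _, s, e in pairs:
            chrom = a[i].chromosome
            ta, tb = coverage_a.get(chrom), coverage_b.get(chrom)
            if ta is None or tb is None:
                continue
            ma, mb = ta.mean_depth(s, e), tb.mean_depth(s, e)
            if ma is not None and mb is not None:
                xs.append(ma)
                ys.append(mb)
        cov_r = _pearson(xs, ys)

    # greedy largest-overlap 1-to-1 matching for the signal correlation
    sig_r = None
    scored = [(e - s, i, j) for i, j, s, e in pairs]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    xs, ys = [], []
    for _, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        sa, sb = a[i].signal_value, b[j].signal_value
        if sa is not None and sb is not None:
            xs.append(sa)
            ys.append(sb)
    sig_r = _pearson(xs, ys)

    return ConcordanceReport(len(a), len(b), n_overlap_a, n_overlap_b, cov_r, sig_r)


def tss_mark_fraction(
    peaks: PeakSet,
    genes: Sequence[GeneRecord],
    window: int = 1000,
    min_tpm: float = 1.0,
) -> float:
    """Fraction of expressed genes (TPM > min_tpm) with a peak within
    +/- window bp of the TSS."""
    expressed = [g for g in genes if g.tpm is not None and g.tpm > min_tpm]
    if not expressed:
        raise ValueError(f"no genes with TPM > {min_tpm}")
    by_chrom = peaks.by_chromosome()
    hits = 0
    for g in expressed:
        if g.chromosome not in by_chrom:
            continue
        starts, ends, _ = by_chrom[g.chromosome]
        lo, hi = g.tss - window, g.tss + window
        if np.any((starts < hi) & (ends > lo)):
            hits += 1
    return hits / len(expressed)


def per_chromosome_rate(items: Sequence, layout: GenomeLayout) -> dict[str, float]:
    """Events per Mb per chromosome (counts normalized for chromosome size)."""
    counts = {c: 0 for c in layout.names}
    for item in items:
        chrom = item.chromosome
        if chrom not in counts:
            raise KeyError(f"item on chromosome {chrom!r} absent from layout")
        counts[chrom] += 1
    return {c: counts[c] / (layout[c] / 1e6) for c in layout.names}
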