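"""Methylation summaries by cytosine context, RRBS-vs-WGBS complementarity,
site merging and regulatory overlay.

RRBS targets CpG-dense (largely promoter-proximal) fractions of the genome at
high coverage; WGBS covers everything at moderate coverage.  Sites well
covered by RRBS but effectively absent from WGBS therefore flag CpG-dense
regulatory regions a WGBS-only design would miss; they are identified here
with the >= 10x informativeness threshold, merged into regions and annotated
against promoter (H3K4me3) and enhancer intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats_io import MethylationSite, PeakSet, VALID_CONTEXTS

__all__ = [
    "ContextSummary",
    "ExclusiveRegion",
    "context_summary",
    "rrbs_exclusive_sites",
    "merge_strands",
    "merge_sites_to_regions",
    "overlay_regulatory",
]


@dataclass
class ContextSummary:
    """Per-context mean methylation level and surviving-site counts.

    Means are unweighted across sites; a context with no site at or above the
    coverage threshold is reported as None (missing), not 0.
    """

    assay: str
    mean_level: dict[str, float | None]
    n_sites: dict[str, int]


def context_summary(sites: Iterable[MethylationSite], min_cov: int = 10, assay: str = "") -> ContextSummary:
    levels: dict[str, list[float]] = {c: [] for c in VALID_CONTEXTS}
    for s in sites:
        if s.total_reads < min_cov:
            continue
        levels[s.context].append(s.level)
    mean = {c: (float(np.mean(v)) if v else None) for c, v in levels.items()}
    n = {c: len(v) for c, v in levels.items()}
    return ContextSummary(assay, mean, n)


def merge_strands(sites: Sequence[MethylationSite]) -> list[MethylationSite]:
    """Combine opposite-strand CpG records of one dinucleotide by summing counts.

    The minus-strand cytosine of a CpG sits one bp downstream of the
    plus-strand one; both are mapped to the plus-strand coordinate.  Non-CpG
    sites pass through unchanged.
    """
    merged: dict[tuple[str, int], list[int]] = {}
    out: list[MethylationSite] = []
    for s in sites:
        if s.context != "CpG":
            out.append(s)
            continue
        pos = s.position if s.strand == "+" else s.position - 1
        key = (s.chromosome, pos)
        acc = merged.setdefault(key, [0, 0])
        acc[0] += s.methylated_reads
        acc[1] += s.total_reads
    for (chrom, pos), (m, t) in merged.items():
        out.append(MethylationSite(chrom, pos, "+", "CpG", m, t))
    out.sort(key=lambda s: (s.chromosome, s.position))
    return out


def rrbs_exclusive_sites(
    rrbs: Sequence[MethylationSite],
    wgbs: Sequence[MethylationSite],
    min_cov: int = 10,
    contexts: Iterable[str] = ("CpG",),
) -> list[MethylationSite]:
    """RRBS sites informative at >= min_cov whose position is absent from WGBS
    or present there with coverage < min_cov.

    Opposite-strand records are treated as distinct positions; apply
    :func:`merge_strands` to both tables first to combine them.
    """
    contexts = set(contexts)
    covered = {
        (s.chromosome, s.position, s.strand)
        for s in wgbs
        if s.total_reads >= min_cov
    }
    return [
        s
        for s in rrbs
        if s.context in contexts
        and s.total_reads >= min_cov
        and (s.chromosome, s.position, s.strand) not in covered
    ]


@dataclass
class ExclusiveRegion:
    chromosome: str
    start: int
    end: int
    n_sites: int
    mean_level: float
    annotations: set[str] = field(default_factory=set)


def merge_sites_to_regions(sites: Sequence[MethylationSite], max_gap: int = 200) -> list[ExclusiveRegion]:
    """Merge consecutive sites with inter-site gap <= max_gap into regions.

    Singleton sites become 1-bp regions; output regions are sorted, disjoint
    and cover exactly the input sites.
    """
    ordered = sorted(sites, key=lambda s: (s.chromosome, s.position))
    regions: list[ExclusiveRegion] = []
    run: list[MethylationSite] = []

    def flush() -> None:
        if run:
            regions.append(
                ExclusiveRegion(
                    run[0].chromosome,
                    run[0].position,
                    run[-1].position + 1,
                    len(run),
                    float(np.mean([s.level for s in run])),
                )
            )

    for s in ordered:
        if run and (s.chromosome != run[-1].chromosome or s.position - run[-1].position > max_gap):
            flush()
            run = []
        run.append(s)
    flush()
    return regions


def overlay_regulatory(
    regions: Sequence[ExclusiveRegion],
    promoters: PeakSet,
    enhancers: PeakSet,
) -> tuple[list[ExclusiveRegion], dict[str, int]]:
    """Annotate regions with every regulatory category they intersect.

    ``promoters`` are H3K4me3 peak intervals; ``enhancers`` the output of the
    enhancer distance rule.  Returns annotated regions plus summary counts per
    category (promoter / enhancer / none).
    """
    prom = promoters.by_chromosome()
    enh = enhancers.by_chromosome()
    out: list[ExclusiveRegion] = []
    counts = {"promoter": 0, "enhancer": 0, "none": 0}
    for r in regions:
        ann: set[str] = set()
        for label, table in (("promoter", prom), ("enhancer", enh)):
            if r.chromosome in table:
                starts, ends, _ = table[r.chromosome]
                if np.any((starts < r.end) & (ends > r.start)):
                    ann.add(label)
        if not ann:
            ann.add("none")
        for label in ann:
            counts[label] += 1
        out.append(ExclusiveRegion(r.chromosome, r.start, r.end, r.n_sites, r.mean_level, ann))
    return out, counts
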