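"""Readers, writers and shared domain types for the pipeline's text formats.

All coordinates are held internally in the 0-based half-open convention used
by BED arithmetic.  One-based sources (VCF, GTF, CGmap) are converted on
ingest and converted back on write, so a read-after-write round trip is the
identity.

Formats handled here: VCF 4.x with GT+AD genotype fields (via cyvcf2), ENCODE
narrowPeak/broadPeak and BED3, bedGraph depth tracks, CGmap per-cytosine
methylation tables, GTF gene annotation (via gffutils) and a two-column
``gene_id<TAB>TPM`` expression table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("karyoscope")

VALID_CONTEXTS = ("CpG", "CHG", "CHH")
_CONTEXT_ALIASES = {"CG": "CpG", "CPG": "CpG", "CpG": "CpG", "CHG": "CHG", "CHH": "CHH"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    Houses the per-chromosome length denominators used when normalizing
    counts for chromosome size.
    """

    def __init__(self, lengths: Mapping[str, int]):
        lengths = dict(lengths)
        if len(lengths) == 0:
            raise ValueError("layout needs at least one chromosome")
        for name, length in lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths = {str(k): int(v) for k, v in lengths.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({self._lengths!r})"

    @property
    def total(self) -> int:
        return sum(self._lengths.values())


@dataclass
class DepthTrack:
    """Per-chromosome read-depth intervals (sorted, non-overlapping)."""

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.depths)):
            raise ValueError("starts/ends/depths length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must satisfy end > start")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")
        finite = self.depths[np.isfinite(self.depths)]
        if np.any(finite < 0):
            raise ValueError("depth must be non-negative")

    @classmethod
    def from_intervals(
        cls, chromosome: str, intervals: Iterable[tuple[int, int, float]]
    ) -> "DepthTrack":
        rows = sorted(intervals)
        if rows:
            s, e, d = zip(*rows)
        else:
            s, e, d = (), (), ()
        return cls(chromosome, np.array(s, dtype=np.int64), np.array(e, dtype=np.int64), np.array(d))

    def __len__(self) -> int:
        return len(self.starts)

    def intervals(self) -> Iterator[tuple[int, int, float]]:
        for s, e, d in zip(self.starts, self.ends, self.depths):
            yield int(s), int(e), float(d)

    def mean_depth(self, start: int, end: int) -> float | None:
        """Coverage-weighted mean depth over [start, end); None if uncovered."""
        ov = np.minimum(self.ends, end) - np.maximum(self.starts, start)
        ov = np.clip(ov, 0, None).astype(float)
        ok = (ov > 0) & np.isfinite(self.depths)
        if not np.any(ok):
            return None
        return float(np.sum(ov[ok] * self.depths[ok]) / np.sum(ov[ok]))

    def median_depth(self) -> float | None:
        finite = self.depths[np.isfinite(self.depths)]
        if finite.size == 0:
            return None
        return float(np.median(finite))


@dataclass(frozen=True)
class AlleleBalanceRecord:
    """One heterozygous site: position plus ref/alt supporting read counts."""

    chromosome: str
    position: int  # 0-based
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def ratio_alt(self) -> float:
        return self.alt_reads / self.total

    @property
    def ratio_ref(self) -> float:
        return self.ref_reads / self.total


@dataclass
class Peak:
    """A genomic interval with an enrichment signal, ENCODE-peak style.

    ``score`` is the integer score column of narrowPeak/broadPeak (used as the
    peak score in downstream aggregation); ``signal_value`` is the
    per-peak enrichment statistic from column 7.
    """

    chromosome: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal_value: float | None = None
    p_value: float = -1.0
    q_value: float = -1.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak end must exceed start ({self.chromosome}:{self.start}-{self.end})")
        if self.start < 0:
            raise ValueError("negative peak coordinate")
        if self.signal_value is not None and self.signal_value < 0:
            raise ValueError("signal_value must be non-negative")

    @property
    def peak_score(self) -> float:
        return self.score

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A sorted collection of peaks for one mark/replicate."""

    peaks: list[Peak] = field(default_factory=list)
    mark: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chromosome, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(p.chromosome for p in self.peaks))

    def by_chromosome(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, index-into-self.peaks) arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in self.chromosomes():
            idx = np.array([i for i, p in enumerate(self.peaks) if p.chromosome == chrom])
            starts = np.array([self.peaks[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.peaks[i].end for i in idx], dtype=np.int64)
            out[chrom] = (starts, ends, idx)
        return out


@dataclass
class MethylationSite:
    """One cytosine with methylated/total read counts and context."""

    chromosome: str
    position: int  # 0-based
    strand: str
    context: str
    methylated_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.methylated_reads < 0 or self.total_reads < 0:
            raise ValueError("negative read counts")
        if self.methylated_reads > self.total_reads:
            raise ValueError("methylated_reads exceeds total_reads")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def level(self) -> float:
        return self.methylated_reads / self.total_reads


@dataclass
class GeneRecord:
    """A gene with strand-aware TSS/TES point coordinates and (optional) TPM."""

    gene_id: str
    chromosome: str
    strand: str
    tss: int  # 0-based point
    tes: int
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.tpm is not None and self.tpm < 0:
            raise ValueError("tpm must be non-negative")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open transcribed span."""
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return lo, hi + 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_allele_depths(
    path: str | Path,
    min_site_depth: int = 10,
    sample: str | None = None,
) -> dict[str, list[AlleleBalanceRecord]]:
    """Heterozygous biallelic sites with ref+alt allele depth >= min_site_depth.

    Read support ratios are derived from the AD (allele depth) field; sites
    where either allele has zero support are dropped (a genotype-aware caller
    would not emit them as heterozygous).  The first sample is used unless
    ``sample`` names another one.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        si = 0
    else:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in VCF ({vcf.samples})")
        si = vcf.samples.index(sample)

    out: dict[str, list[AlleleBalanceRecord]] = {}
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = v.genotypes[si]
        alleles = gt[:-1]
        if any(a < 0 for a in alleles):
            n_skipped += 1
            continue
        if len(set(alleles)) < 2:
            continue  # homozygous
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"missing AD (allele depth) field at {v.CHROM}:{v.POS}")
        ref_reads, alt_reads = int(ad[si][0]), int(ad[si][1])
        if ref_reads < 0 or alt_reads < 0:
            n_skipped += 1
            continue
        if ref_reads + alt_reads < min_site_depth:
            continue
        if ref_reads == 0 or alt_reads == 0:
            n_skipped += 1
            continue
        out.setdefault(v.CHROM, []).append(
            AlleleBalanceRecord(v.CHROM, v.start, ref_reads, alt_reads)
        )
    if n_skipped:
        logger.warning("skipped %d malformed/unsupported het sites", n_skipped)
    for chrom in out:
        out[chrom].sort(key=lambda r: r.position)
    return out


_BASES = ("A", "C", "G", "T")


def write_vcf(
    records: Mapping[str, Sequence[AlleleBalanceRecord]],
    layout: GenomeLayout,
    path: str | Path,
    sample_name: str = "sample1",
) -> None:
    """Write heterozygous sites as a minimal single-sample VCF (GT:AD:DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in layout.names:
            fh.write(f"##contig=<ID={name},length={layout[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for chrom in layout.names:
            for rec in sorted(records.get(chrom, ()), key=lambda r: r.position):
                ref = _BASES[rec.position % 4]
                alt = _BASES[(rec.position + 1) % 4]
                fh.write(
                    f"{chrom}\t{rec.position + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\t"
                    f"GT:AD:DP\t0/1:{rec.ref_reads},{rec.alt_reads}:{rec.total}\n"
                )


# ---------------------------------------------------------------------------
# peaks (narrowPeak / broadPeak / BED3)
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"narrowPeak": 10, "broadPeak": 9, "bed3": 3}


def read_peaks(path: str | Path, dialect: str = "narrowPeak", mark: str = "", replicate: str = "") -> PeakSet:
    """Read an ENCODE narrowPeak/broadPeak or BED3 file into a sorted PeakSet."""
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    want = _DIALECT_COLS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != want:
                raise ValueError(
                    f"{path}:{ln}: expected {want} columns for {dialect}, got {len(cols)}"
                )
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if dialect == "bed3":
                peaks.append(Peak(chrom, start, end))
                continue
            summit = None
            if dialect == "narrowPeak":
                s = int(cols[9])
                summit = None if s < 0 else s
            peaks.append(
                Peak(
                    chrom,
                    start,
                    end,
                    name=cols[3],
                    score=float(cols[4]),
                    strand=cols[5],
                    signal_value=float(cols[6]),
                    p_value=float(cols[7]),
                    q_value=float(cols[8]),
                    summit_offset=summit,
                )
            )
    return PeakSet(peaks, mark=mark, replicate=replicate)


def write_peaks(peakset: PeakSet, path: str | Path, dialect: str = "narrowPeak") -> None:
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peakset:
            if dialect == "bed3":
                fh.write(f"{p.chromosome}\t{p.start}\t{p.end}\n")
                continue
            sv = 0.0 if p.signal_value is None else p.signal_value
            base = (
                f"{p.chromosome}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.4f}\t{p.strand}\t"
                f"{sv:.4f}\t{p.p_value:.4f}\t{p.q_value:.4f}"
            )
            if dialect == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(f"{base}\t{summit}\n")
            else:
                fh.write(f"{base}\n")


# ---------------------------------------------------------------------------
# bedGraph depth
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> dict[str, DepthTrack]:
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns, got {len(cols)}")
            rows.setdefault(cols[0], []).append((int(cols[1]), int(cols[2]), float(cols[3])))
    return {c: DepthTrack.from_intervals(c, ivals) for c, ivals in rows.items()}


def write_bedgraph(tracks: Mapping[str, DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in tracks:
            for s, e, d in tracks[chrom].intervals():
                if not np.isfinite(d):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{d:.4f}\n")


# ---------------------------------------------------------------------------
# CGmap methylation tables
# ---------------------------------------------------------------------------

_CGMAP_COLS = ["chrom", "nucleotide", "position", "context", "dinucleotide", "level", "methylated", "total"]


def read_methylation_table(path: str | Path) -> list[MethylationSite]:
    """Read a CGmap-style table; per-site levels are recomputed from counts.

    Sites with zero total reads are excluded (their level is undefined); a
    stored level inconsistent with the counts by more than 1e-6 triggers a
    warning, negative counts are an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_CGMAP_COLS, dtype={"chrom": str})
    if (df["methylated"] < 0).any() or (df["total"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df = df[df["total"] > 0].copy()
    recomputed = df["methylated"] / df["total"]
    bad = (recomputed - df["level"]).abs() > 1e-6
    if bad.any():
        logger.warning("%s: %d sites with stored level inconsistent with counts", path, int(bad.sum()))
    sites: list[MethylationSite] = []
    for row in df.itertuples(index=False):
        ctx = _CONTEXT_ALIASES.get(str(row.context).upper().replace("PG", "pG"))
        if ctx is None:
            ctx = _CONTEXT_ALIASES.get(str(row.context))
        if ctx is None:
            raise ValueError(f"{path}: unknown context {row.context!r}")
        strand = "+" if row.nucleotide == "C" else "-"
        sites.append(
            MethylationSite(
                chromosome=str(row.chrom),
                position=int(row.position) - 1,
                strand=strand,
                context=ctx,
                methylated_reads=int(row.methylated),
                total_reads=int(row.total),
            )
        )
    sites.sort(key=lambda s: (s.chromosome, s.position))
    return sites


_CONTEXT_TO_CGMAP = {"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}


def write_methylation_table(sites: Sequence[MethylationSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.chromosome, x.position)):
            nuc = "C" if s.strand == "+" else "G"
            dinuc = _CONTEXT_TO_CGMAP[s.context][:2]
            fh.write(
                f"{s.chromosome}\t{nuc}\t{s.position + 1}\t{_CONTEXT_TO_CGMAP[s.context]}\t"
                f"{dinuc}\t{s.level:.6f}\t{s.methylated_reads}\t{s.total_reads}\n"
            )


# ---------------------------------------------------------------------------
# GTF genes
# ---------------------------------------------------------------------------


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """One GeneRecord per ``gene`` feature; TSS is the 5' end given the strand."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        id_spec={"gene": "gene_id"},
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise ValueError(f"gene feature at {feat.seqid}:{feat.start} lacks gene_id")
        gene_id = gene_ids[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        start0, end0 = feat.start - 1, feat.end - 1  # 1-based inclusive -> 0-based points
        if feat.strand == "-":
            tss, tes = end0, start0
        else:
            tss, tes = start0, end0
        genes.append(GeneRecord(gene_id, feat.seqid, feat.strand, tss, tes))
    return genes


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "TPM"]:
        raise ValueError(f"{path}: expected header 'gene_id<TAB>TPM', got {list(df.columns)}")
    return dict(zip(df["gene_id"].astype(str), df["TPM"].astype(float)))


def write_expression_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tTPM\n")
        for g in genes:
            tpm = 0.0 if g.tpm is None else g.tpm
            fh.write(f"{g.gene_id}\t{tpm:.6f}\n")


def attach_expression(genes: Sequence[GeneRecord], tpm: Mapping[str, float]) -> list[GeneRecord]:
    """Return genes with TPM filled in (0.0, with a warning, when absent)."""
    out = []
    missing = 0
    for g in genes:
        if g.gene_id in tpm:
            out.append(replace(g, tpm=float(tpm[g.gene_id])))
        else:
            missing += 1
            out.append(replace(g, tpm=0.0))
    if missing:
        logger.warning("%d genes missing from expression table; TPM set to 0", missing)
    return out
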