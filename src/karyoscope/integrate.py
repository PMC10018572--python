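"""Gene-level integration of expression, methylation and peak scores.

Builds a per-gene feature table (TPM, expression class, TSS/gene-body
methylation per assay, per-mark peak score near the TSS), computes
pairwise-complete Pearson correlation matrices, and compares per-chromosome
expression distributions between declared aneuploid and diploid chromosome
sets with a rank-sum shift test.

Expression classes follow the published banding: C0 (TPM <= 1, not
expressed), then 1 < TPM <= 5, 5 < TPM <= 20, 20 < TPM <= 100, and C4 for
very highly expressed genes (TPM > 100).  Interior edges (5, 20) are
configuration-exposed defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import GeneRecord, MethylationSite, PeakSet

__all__ = [
    "ExpressionClass",
    "DEFAULT_CLASS_EDGES",
    "assign_expression_class",
    "methylation_at_feature",
    "peak_score_at_gene",
    "build_gene_feature_table",
    "correlation_matrix",
    "chromosome_expression_summary",
    "ShiftTest",
]

DEFAULT_CLASS_EDGES: tuple[float, ...] = (1.0, 5.0, 20.0, 100.0)


@dataclass(frozen=True)
class ExpressionClass:
    label: str
    lower: float  # exclusive
    upper: float  # inclusive


def _classes(edges: Sequence[float]) -> list[ExpressionClass]:
    bounds = [0.0, *edges, np.inf]
    return [
        ExpressionClass(f"C{i}", -np.inf if i == 0 else bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
    ]


def assign_expression_class(tpm: float, edges: Sequence[float] = DEFAULT_CLASS_EDGES) -> str:
    """Class label for a TPM value; classes partition [0, inf) with half-open
    upper edges inclusive (TPM exactly 100 is C3, not C4)."""
    if tpm < 0:
        raise ValueError("tpm must be non-negative")
    for cls in _classes(edges):
        if cls.lower < tpm <= cls.upper or (cls.label == "C0" and tpm <= cls.upper):
            return cls.label
    raise AssertionError("unreachable: classes partition [0, inf)")


# ---------------------------------------------------------------------------
# per-gene feature extraction
# ---------------------------------------------------------------------------


class _SiteIndex:
    """Per-chromosome sorted CpG positions with prefix sums for O(log n)
    interval means."""

    def __init__(self, sites: Sequence[MethylationSite], min_cov: int):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for s in sites:
            if s.context == "CpG" and s.total_reads >= min_cov:
                by_chrom.setdefault(s.chromosome, []).append((s.position, s.level))
        for chrom, rows in by_chrom.items():
            rows.sort()
            pos = np.array([p for p, _ in rows], dtype=np.int64)
            lev = np.array([l for _, l in rows])
            self._data[chrom] = (pos, np.concatenate([[0.0], np.cumsum(lev)]), lev)

    def sum_count(self, chrom: str, lo: int, hi: int) -> tuple[float, int]:
        if chrom not in self._data or hi <= lo:
            return 0.0, 0
        pos, csum, _ = self._data[chrom]
        i, j = np.searchsorted(pos, [lo, hi])
        return float(csum[j] - csum[i]), int(j - i)


def methylation_at_feature(
    sites: Sequence[MethylationSite],
    genes: Sequence[GeneRecord],
    feature: str = "TSS",
    tss_window: int = 1000,
    min_cov: int = 10,
) -> dict[str, float | None]:
    """Per-gene mean CpG methylation level over a gene feature.

    ``TSS`` is the +/- tss_window interval around the start site; ``gene_body``
    is the transcribed span minus that window.  Genes with no qualifying site
    get None and should be excluded from correlations.
    """
    if feature not in ("TSS", "gene_body"):
        raise ValueError("feature must be 'TSS' or 'gene_body'")
    index = _SiteIndex(sites, min_cov)
    out: dict[str, float | None] = {}
    for g in genes:
        tss_lo, tss_hi = g.tss - tss_window, g.tss + tss_window
        if feature == "TSS":
            windows = [(tss_lo, tss_hi)]
        else:
            lo, hi = g.span
            windows = [(lo, min(hi, tss_lo)), (max(lo, tss_hi), hi)]
        total, count = 0.0, 0
        for lo, hi in windows:
            s, c = index.sum_count(g.chromosome, lo, hi)
            total += s
            count += c
        out[g.gene_id] = total / count if count else None
    return out


def peak_score_at_gene(
    peaks: PeakSet,
    genes: Sequence[GeneRecord],
    window: int = 2000,
    use: str = "peak_score",
) -> dict[str, float]:
    """Maximum peak score among peaks intersecting TSS +/- window; 0 when none."""
    if use not in ("peak_score", "signal_value"):
        raise ValueError("use must be 'peak_score' or 'signal_value'")
    by_chrom = peaks.by_chromosome()
    out: dict[str, float] = {}
    for g in genes:
        score = 0.0
        if g.chromosome in by_chrom:
            starts, ends, idx = by_chrom[g.chromosome]
            hit = (starts < g.tss + window) & (ends > g.tss - window)
            for j in np.nonzero(hit)[0]:
                p = peaks[int(idx[j])]
                v = p.score if use == "peak_score" else (p.signal_value or 0.0)
                score = max(score, float(v))
        out[g.gene_id] = score
    return out


def build_gene_feature_table(
    genes: Sequence[GeneRecord],
    rrbs: Sequence[MethylationSite] | None = None,
    wgbs: Sequence[MethylationSite] | None = None,
    peak_sets: Mapping[str, PeakSet] | None = None,
    tss_window: int = 1000,
    peak_window: int = 2000,
    min_cov: int = 10,
    class_edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Assemble the per-gene feature table used by the correlation analysis."""
    if any(g.tpm is None for g in genes):
        raise ValueError("genes must carry TPM")
    table: dict[str, object] = {
        "chromosome": [g.chromosome for g in genes],
        "TPM": [g.tpm for g in genes],
        "expression_class": [assign_expression_class(g.tpm, class_edges) for g in genes],
    }
    idx = [g.gene_id for g in genes]
    for assay, sites in (("RRBS", rrbs), ("WGBS", wgbs)):
        if sites is None:
            continue
        for feat, col in (("TSS", f"{assay}_TSS"), ("gene_body", f"{assay}_GB")):
            vals = methylation_at_feature(sites, genes, feat, tss_window, min_cov)
            table[col] = [vals[g.gene_id] for g in genes]
    for mark, ps in (peak_sets or {}).items():
        vals = peak_score_at_gene(ps, genes, peak_window)
        table[mark] = [vals[g.gene_id] for g in genes]
    return pd.DataFrame(table, index=pd.Index(idx, name="gene_id"))


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations; symmetric with unit diagonal.

    Constant columns produce missing entries (including their diagonal).
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[list(columns)].astype(float)
    corr = sub.corr(method="pearson", min_periods=3)
    for c in columns:
        vals = sub[c].dropna()
        if len(vals) >= 3 and vals.nunique() > 1:
            corr.loc[c, c] = 1.0
    return corr


# ---------------------------------------------------------------------------
# per-chromosome dosage / expression comparison
# ---------------------------------------------------------------------------


@dataclass
class ShiftTest:
    """Rank-sum comparison of aneuploid vs diploid gene expression."""

    statistic: float
    p_value: float
    median_ratio: float
    n_aneuploid: int
    n_diploid: int


def chromosome_expression_summary(
    genes: Sequence[GeneRecord],
    min_tpm: float = 2.0,
    aneuploid: Sequence[str] | None = None,
    diploid: Sequence[str] | None = None,
    min_genes: int = 5,
) -> tuple[pd.DataFrame, ShiftTest | None]:
    """Per-chromosome TPM quartiles among genes with TPM > min_tpm, plus an
    optional rank-sum shift test between declared chromosome sets.

    Chromosomes with fewer than ``min_genes`` qualifying genes are flagged and
    excluded from the test.
    """
    rows = []
    by_chrom: dict[str, list[float]] = {}
    for g in genes:
        if g.tpm is not None and g.tpm > min_tpm:
            by_chrom.setdefault(g.chromosome, []).append(g.tpm)
    for chrom in sorted(by_chrom):
        vals = np.array(by_chrom[chrom])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "chromosome": chrom,
                "n_genes": len(vals),
                "q1": q1,
                "median": med,
                "q3": q3,
                "flagged": len(vals) < min_genes,
            }
        )
    summary = pd.DataFrame(rows).set_index("chromosome") if rows else pd.DataFrame(
        columns=["n_genes", "q1", "median", "q3", "flagged"]
    )

    test = None
    if aneuploid and diploid:
        usable = {c for c in by_chrom if len(by_chrom[c]) >= min_genes}
        a_vals = np.concatenate([by_chrom[c] for c in aneuploid if c in usable]) if any(
            c in usable for c in aneuploid
        ) else np.array([])
        d_vals = np.concatenate([by_chrom[c] for c in diploid if c in usable]) if any(
            c in usable for c in diploid
        ) else np.array([])
        if len(a_vals) and len(d_vals):
            stat, p = stats.mannwhitneyu(a_vals, d_vals, alternative="two-sided")
            test = ShiftTest(
                float(stat),
                float(p),
                float(np.median(a_vals) / np.median(d_vals)),
                len(a_vals),
                len(d_vals),
            )
    return summary, test
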