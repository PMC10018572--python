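"""Shared fixtures: small hand-built files and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from karyoscope import karyosim as ks
from karyoscope.formats_io import GenomeLayout, MethylationSite, Peak, PeakSet


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
"""


@pytest.fixture
def vcf_100_sites(tmp_path):
    """100 biallelic sites: 70 het at >=10x, 20 hom-alt, 10 het below 10x."""
    lines = []
    pos = 100
    for _ in range(70):
        lines.append(f"chr1\t{pos}\t.\tA\tC\t50\tPASS\t.\tGT:AD\t0/1:6,6")
        pos += 100
    for _ in range(20):
        lines.append(f"chr1\t{pos}\t.\tA\tC\t50\tPASS\t.\tGT:AD\t1/1:0,12")
        pos += 100
    for _ in range(10):
        lines.append(f"chr1\t{pos}\t.\tA\tC\t50\tPASS\t.\tGT:AD\t0/1:3,3")
        pos += 100
    path = tmp_path / "sites.vcf"
    path.write_text(VCF_HEADER + "\n".join(lines) + "\n")
    return path


@pytest.fixture
def cgmap_50_rows(tmp_path):
    """50 CGmap rows; 5 have zero total reads and must be excluded."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(50):
        total = 0 if i % 10 == 9 else int(rng.integers(5, 40))
        meth = int(rng.integers(0, total + 1)) if total else 0
        level = meth / total if total else 0.0
        ctx = ["CG", "CHG", "CHH"][i % 3]
        rows.append(f"chr1\tC\t{1000 + i * 50}\t{ctx}\t{ctx[:2]}\t{level:.6f}\t{meth}\t{total}")
    path = tmp_path / "sites.cgmap"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def enhancer_fixture():
    """5 H3K27ac and 3 H3K4me3 peaks; one K27ac at exactly a 1000-bp gap.

    By the distance rule only a3 (gap 9000) and a4 (gap 1500) are enhancers.
    """
    k4 = PeakSet(
        [
            Peak("chr1", 10_000, 11_000, "p1", signal_value=5.0),
            Peak("chr1", 50_000, 51_000, "p2", signal_value=5.0),
            Peak("chr1", 90_000, 91_000, "p3", signal_value=5.0),
        ],
        mark="H3K4me3",
    )
    k27 = PeakSet(
        [
            Peak("chr1", 10_500, 11_500, "a1", signal_value=3.0),  # overlaps p1
            Peak("chr1", 12_000, 12_800, "a2", signal_value=3.0),  # gap exactly 1000
            Peak("chr1", 20_000, 20_800, "a3", signal_value=3.0),  # far from all
            Peak("chr1", 52_500, 53_000, "a4", signal_value=3.0),  # gap 1500
            Peak("chr1", 91_500, 92_500, "a5", signal_value=3.0),  # gap 500
        ],
        mark="H3K27ac",
    )
    return k27, k4, {"a3", "a4"}


def _site(chrom, pos, meth, total, context="CpG", strand="+"):
    return MethylationSite(chrom, pos, strand, context, meth, total)


@pytest.fixture
def rrbs_wgbs_fixture():
    """12 RRBS sites of which exactly 5 are RRBS-exclusive by construction.

    Includes the characteristic pattern of ~70x RRBS coverage against <10x
    WGBS coverage at the same position.
    """
    rrbs = [
        _site("chr1", 100, 50, 70),   # exclusive: WGBS at 4x
        _site("chr1", 200, 10, 70),   # exclusive: WGBS absent
        _site("chr1", 300, 30, 60),   # not: WGBS 30x
        _site("chr1", 400, 5, 9),     # RRBS below threshold -> not exclusive
        _site("chr1", 500, 12, 20),   # exclusive: WGBS 9x
        _site("chr1", 600, 8, 15),    # not: WGBS 15x
        _site("chr1", 700, 40, 80),   # exclusive: WGBS absent
        _site("chr1", 800, 3, 12, context="CHG"),  # non-CpG -> filtered out
        _site("chr2", 100, 22, 44),   # not: WGBS 44x
        _site("chr2", 200, 11, 30),   # exclusive: WGBS 2x
        _site("chr2", 300, 6, 12),    # not: WGBS 12x
        _site("chr2", 400, 2, 8),     # RRBS below threshold
    ]
    wgbs = [
        _site("chr1", 100, 2, 4),
        _site("chr1", 300, 15, 30),
        _site("chr1", 500, 4, 9),
        _site("chr1", 600, 7, 15),
        _site("chr2", 100, 20, 44),
        _site("chr2", 200, 1, 2),
        _site("chr2", 300, 6, 12),
    ]
    exclusive_positions = {("chr1", 100), ("chr1", 200), ("chr1", 500), ("chr1", 700), ("chr2", 200)}
    return rrbs, wgbs, exclusive_positions


@pytest.fixture(scope="session")
def ipecj2_sim():
    """One seeded WGS simulation of the mostly-diploid aneuploid preset."""
    spec = ks.ipecj2_like_spec()
    return spec, ks.simulate_wgs(spec, seed=1234)


@pytest.fixture(scope="session")
def epigenome_sim():
    """Seeded expression + epigenome simulation on the preset genome."""
    spec = ks.ipecj2_like_spec()
    genes, etruth = ks.simulate_expression(spec, n_genes=1200, seed=41)
    epi = ks.simulate_epigenome(genes, seed=42)
    return genes, etruth, epi
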