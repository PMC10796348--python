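"""Shared fixtures: simulated tumour/normal pairs and tiny VCF texts."""

from __future__ import annotations

import numpy as np
import pytest

import tinc


@pytest.fixture(scope="session")
def contaminated_pair() -> tinc.SimulatedPair:
    """High-purity tumour (90%) with 16% contamination on a diploid genome —
    the canonical worked-example geometry (clonal VAF ~0.45 / ~0.08)."""
    return tinc.simulate_pair(tinc.SimConfig(tit_true=0.9, tin_true=0.16, seed=7))


@pytest.fixture(scope="session")
def contaminated_result(contaminated_pair) -> tinc.TincResult:
    return tinc.run_tinc_on_records(
        contaminated_pair.snvs, contaminated_pair.segments, tinc.TincConfig(seed=7)
    )


@pytest.fixture(scope="session")
def clean_pair() -> tinc.SimulatedPair:
    """Uncontaminated normal (TIN = 0)."""
    return tinc.simulate_pair(tinc.SimConfig(tit_true=0.8, tin_true=0.0, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


STRELKA_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowEVS,Description="low score">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2">
##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2">
##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2">
##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2">
##contig=<ID=chr9>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
chr9\t5073770\t.\tG\tT\t.\tPASS\t.\tDP:AU:CU:GU:TU\t34:0,0:0,0:30,30:4,4\t110:0,0:0,0:60,60:50,50
chr9\t5073801\t.\tA\tC\t.\tPASS\t.\tDP:AU:CU:GU:TU\t30:30,30:0,0:0,0:0,0\t100:55,55:45,45:0,0:0,0
chr9\t5073900\t.\tT\tG\t.\tLowEVS\t.\tDP:AU:CU:GU:TU\t30:0,0:0,0:0,0:30,30\t100:0,0:0,0:50,50:50,50
chr9\t5074000\t.\tC\tA\t.\tPASS\t.\tDP:AU:CU:GU:TU\t28:1,1:27,27:0,0:0,0\t95:40,40:55,55:0,0:0,0
"""

INDEL_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
chr17\t7675100\t.\tCA\tC\t.\tPASS\t.\tGT:AD\t0/0:15,6\t0/1:49,41
chr17\t7675200\t.\tG\tA\t.\tPASS\t.\tGT:AD\t0/0:28,2\t0/1:60,40
chr17\t7675300\t.\tT\tC\t.\tPASS\t.\tGT:AD\t0/0:30,0\t0/1:55,45
chr17\t7675400\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/0:29,1\t0/1:50,50
"""

EMPTY_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""

CANVAS_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=END,Number=1,Type=Integer,Description="segment end">
##FORMAT=<ID=CN,Number=1,Type=Integer,Description="total copy number">
##FORMAT=<ID=MCC,Number=1,Type=Integer,Description="major chromosome count">
##ALT=<ID=CNV,Description="copy number variant">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
chr1\t1\tCanvas:LOH:chr1\tN\t<CNV>\t.\tPASS\tEND=50000000\tCN:MCC\t2:2
chr2\t1\tCanvas:REF:chr2\tN\t<CNV>\t.\tPASS\tEND=80000000\tCN:MCC\t2:1
"""


@pytest.fixture()
def strelka_vcf(tmp_path):
    p = tmp_path / "strelka.vcf"
    p.write_text(STRELKA_VCF)
    return p


@pytest.fixture()
def indel_vcf(tmp_path):
    p = tmp_path / "generic.vcf"
    p.write_text(INDEL_VCF)
    return p


@pytest.fixture()
def empty_vcf(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text(EMPTY_VCF)
    return p


@pytest.fixture()
def canvas_vcf(tmp_path):
    p = tmp_path / "canvas.vcf"
    p.write_text(CANVAS_VCF)
    return p
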