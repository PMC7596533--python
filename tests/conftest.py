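"""Shared fixtures: tiny hand-built VCFs and AFe record helpers."""

from __future__ import annotations

import textwrap

import pytest

from xpgwas.pool_afe import AFeRecord

POOLS = ("CBDA", "THCVA")

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##FILTER=<ID=PASS,Description="All filters passed">
    ##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCBDA\tTHCVA
    """)


def vcf_line(pos, ref="A", alt="T", a="0/0:30,0:30:99", b="1/1:0,30:30:99",
             chrom="chr1"):
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tNS=2\tGT:AD:DP:GQ\t{a}\t{b}\n"


def make_afe(pos, afe_a, afe_b, depth_a=55, depth_b=55, chrom="chr1"):
    """AFeRecord with the requested frequencies at the given depths."""
    return AFeRecord(
        chrom=chrom, pos=pos,
        afe_a=afe_a, afe_b=afe_b,
        used_a=depth_a, used_b=depth_b,
    )


# The 12-record hard-filter fixture: each removal rule exercised once
# (multiallelic twice to check reason precedence), boundary DP/GQ values on
# both sides of the thresholds. Exactly 7 designed survivors.
FILTER_FIXTURE_LINES = [
    # (line, expected_fate)
    (vcf_line(100), "pass"),
    (vcf_line(200, alt="T,G",
              a="0/1:20,10,5:35:99", b="1/2:0,20,15:35:99"), "multiallelic"),
    (vcf_line(300, b="./.:0,30:30:99"), "missing_genotype"),
    (vcf_line(400, a="0/0:14,0:14:99"), "DP"),                 # 14 < 15
    (vcf_line(500, b="1/1:0,30:30:19"), "GQ"),                 # 19 < 20
    (vcf_line(600, a="0/0:15,0:15:99"), "pass"),               # DP boundary
    (vcf_line(700, b="1/1:0,30:30:20"), "pass"),               # GQ boundary
    (vcf_line(800, ref="A", alt="AT"), "pass"),                # InDel passes
    (vcf_line(900), "pass"),
    # multiallelic takes precedence over its low DP
    (vcf_line(1000, alt="T,G",
              a="0/1:5,4,3:12:99", b="1/2:0,6,6:12:99"), "multiallelic"),
    (vcf_line(1100), "pass"),
    (vcf_line(1200, a="0/1:15,15:30:50", b="0/1:16,14:30:50"), "pass"),
]

FILTER_FIXTURE_SURVIVOR_POS = [
    pos for (line, fate), pos in zip(FILTER_FIXTURE_LINES,
                                     range(100, 1300, 100)) if fate == "pass"
]


@pytest.fixture
def filter_fixture_vcf(tmp_path):
    path = tmp_path / "filter_fixture.vcf"
    path.write_text(VCF_HEADER + "".join(line for line, _ in FILTER_FIXTURE_LINES))
    return path


@pytest.fixture
def two_scaffold_fasta(tmp_path):
    """scaffoldA (100 bp) + scaffoldB (200 bp), plus one chromosome."""
    path = tmp_path / "scaffolds.fasta"
    seq_a = ("ACGT" * 25)
    seq_b = ("TGCA" * 50)
    chrom = "GATTACA" * 20
    path.write_text(
        f">chr1\n{chrom}\n>scaffoldA\n{seq_a}\n>scaffoldB\n{seq_b}\n")
    return path
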