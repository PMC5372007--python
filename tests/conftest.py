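"""Shared fixtures: tiny hand-built barcode regions with known haplotypes."""

import pytest

from metagaap.haplotype_db import BarcodeRegion
from metagaap.variants import PipelineConfig, Polymorphism


def make_poly(position, ref, alt, contig="chr", gq=99, depth=100):
    from metagaap.variants import classify_variant

    return Polymorphism(
        contig=contig,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        kind=classify_variant(ref, alt),
        genotype_quality=gq,
        depth=depth,
    )


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def sub_only_region():
    """10 bp region with two substitutions: C3>G and T8>A."""
    return BarcodeRegion(
        label="sub",
        contig="chr",
        start=1,
        end=10,
        consensus_seq="ACCTGATTGA",
        polymorphisms=(make_poly(3, "C", "G"), make_poly(8, "T", "A")),
    )


@pytest.fixture
def indel_region():
    """ACGTACGT with a 1 bp deletion (pos 4, TA>T) and a substitution (pos 7, G>C)."""
    return BarcodeRegion(
        label="indel",
        contig="chr",
        start=1,
        end=8,
        consensus_seq="ACGTACGT",
        polymorphisms=(make_poly(4, "TA", "T"), make_poly(7, "G", "C")),
    )


@pytest.fixture
def degenerate_region():
    """Two disjoint homopolymer deletions with identical effect.

    Deleting either A from the AAAA run yields the same sequence, so
    bitmasks 0b01 and 0b10 build identical haplotypes.
    """
    return BarcodeRegion(
        label="degen",
        contig="chr",
        start=1,
        end=6,
        consensus_seq="TAAAAT",
        polymorphisms=(make_poly(2, "AA", "A"), make_poly(4, "AA", "A")),
    )


@pytest.fixture
def single_sub_region():
    """Derived-strain-like barcode: one T>A substitution at barcode position 293."""
    consensus = ("ACGT" * 100)[:365]
    assert consensus[292] == "A"
    consensus = consensus[:292] + "T" + consensus[293:]
    return BarcodeRegion(
        label="BRO-A",
        contig="chr",
        start=1,
        end=365,
        consensus_seq=consensus,
        polymorphisms=(make_poly(293, "T", "A"),),
    )
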