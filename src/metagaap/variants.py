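"""Polymorphism parsing, hard filtering and barcode-window discovery.

A *polymorphism* here is a biallelic substitution, insertion or deletion
relative to an isolate's consensus sequence, called from deep shotgun data
and surviving hard quality filters (genotype quality and site depth).  A
*barcode window* is a short, polymorphism-dense interval of the consensus —
shorter than one sequencing read — chosen so that a single amplicon read
spans every polymorphic site at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "Polymorphism",
    "PipelineConfig",
    "classify_variant",
    "filter_variants",
    "scan_barcode_windows",
    "read_vcf_records",
    "read_consensus",
    "read_bed_intervals",
    "write_variant_report",
    "VariantParseError",
    "ConsensusMismatchError",
]

_VALID_BASES = frozenset("ACGT")


class VariantParseError(ValueError):
    """A raw variant record could not be interpreted."""


class ConsensusMismatchError(ValueError):
    """A record's REF allele disagrees with the consensus sequence."""


def classify_variant(ref_allele: str, alt_allele: str) -> str:
    """Classify an allele pair as ``substitution``, ``insertion`` or ``deletion``.

    The rule is purely length based (VCF convention, indels left-anchored):
    equal lengths are substitutions, a longer ALT is an insertion, a shorter
    ALT a deletion.

    Raises
    ------
    ValueError
        If either allele is empty or contains a non-ACGT character.
    """
    for name, allele in (("ref", ref_allele), ("alt", alt_allele)):
        if not allele:
            raise ValueError(f"{name} allele is empty")
        if not set(allele) <= _VALID_BASES:
            raise ValueError(f"{name} allele {allele!r} contains non-ACGT characters")
    if len(ref_allele) == len(alt_allele):
        return "substitution"
    if len(alt_allele) > len(ref_allele):
        return "insertion"
    return "deletion"


@dataclass(frozen=True, order=True)
class Polymorphism:
    """One filtered variant site.

    ``position`` is the 1-based coordinate of the first reference base
    (VCF convention).  ``index`` is the site's 0-based rank within its
    barcode region, ordered by ascending position with ties broken by
    (ref_allele, alt_allele); it is the bit position of this site in a
    genotype bitmask and is assigned when a region is built, not at parse
    time (-1 until then).
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    kind: str = field(compare=False)
    genotype_quality: int = field(compare=False, default=0)
    depth: int = field(compare=False, default=0)
    index: int = field(compare=False, default=-1)

    def __post_init__(self) -> None:
        expected = classify_variant(self.ref_allele, self.alt_allele)
        if self.kind != expected:
            raise ValueError(
                f"kind {self.kind!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele} (expected {expected})"
            )

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based closed interval covered by the reference allele."""
        return self.position, self.position + len(self.ref_allele) - 1

    @property
    def length_delta(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the pipeline.

    Defaults follow the hard filters used throughout: genotype quality
    ≥ 60 (Phred, i.e. 0.0001% error), site depth ≥ 20x, read quality
    Q20, per-genotype coverage 20x, and a practical cap of 30
    polymorphisms per barcode because the database grows as 2^y.
    """

    min_genotype_quality: int = 60
    min_site_depth: int = 20
    min_read_quality: int = 20
    min_genotype_coverage: int = 20
    max_polymorphisms: int = 30
    window_length: int = 365
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_genotype_quality",
            "min_site_depth",
            "min_read_quality",
            "min_genotype_coverage",
            "max_polymorphisms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        # bitmask identifiers must fit a 64-bit integer
        if self.max_polymorphisms > 62:
            raise ValueError("max_polymorphisms must be <= 62")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def read_consensus(path: str | Path) -> dict[str, str]:
    """Read a consensus FASTA into {contig: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_vcf_records(path: str | Path) -> list[dict]:
    """Read raw variant records from a VCF 4.x file.

    Returns one dict per (record, alt allele): multi-allelic sites are split
    into biallelic records.  GQ and DP are taken from the first sample if a
    FORMAT column is present, otherwise from INFO.
    """
    records: list[dict] = []
    with pysam.VariantFile(str(path)) as vcf:
        for line_no, rec in enumerate(vcf, start=1):
            gq, dp = _quality_annotations(rec, line_no)
            for alt in rec.alts or ():
                records.append(
                    {
                        "contig": rec.chrom,
                        "position": rec.pos,
                        "ref": (rec.ref or "").upper(),
                        "alt": str(alt).upper(),
                        "genotype_quality": gq,
                        "depth": dp,
                        "line": line_no,
                    }
                )
    return records


def _quality_annotations(rec: "pysam.VariantRecord", line_no: int) -> tuple[int, int]:
    gq = dp = None
    if rec.samples:
        sample = rec.samples[next(iter(rec.samples))]
        gq = sample.get("GQ")
        dp = sample.get("DP")
    if gq is None:
        gq = rec.info.get("GQ")
    if dp is None:
        dp = rec.info.get("DP")
    if gq is None or dp is None:
        raise VariantParseError(
            f"VCF record {line_no} ({rec.chrom}:{rec.pos}) lacks GQ/DP annotations"
        )
    return int(gq), int(dp)


def filter_variants(
    records: Iterable[dict],
    config: PipelineConfig,
    consensus: dict[str, str] | str | None = None,
) -> list[Polymorphism]:
    """Hard-filter raw variant records and classify the survivors.

    Keeps records with genotype quality >= ``min_genotype_quality`` and
    depth >= ``min_site_depth``; each survivor is classified and validated
    against the consensus if one is supplied.  Output is sorted by
    (contig, position, ref, alt).

    Raises
    ------
    VariantParseError
        If a record lacks required fields or has malformed alleles.
    ConsensusMismatchError
        If a surviving record's REF allele does not match the consensus.
    """
    kept: list[Polymorphism] = []
    for rec in records:
        line = rec.get("line", "?")
        try:
            contig = rec["contig"]
            position = int(rec["position"])
            ref = rec["ref"].upper()
            alt = rec["alt"].upper()
            gq = int(rec["genotype_quality"])
            dp = int(rec["depth"])
        except (KeyError, TypeError, ValueError) as exc:
            raise VariantParseError(f"malformed variant record at line {line}: {exc}") from exc
        if gq < config.min_genotype_quality or dp < config.min_site_depth:
            continue
        try:
            kind = classify_variant(ref, alt)
        except ValueError as exc:
            raise VariantParseError(f"variant record at line {line}: {exc}") from exc
        if consensus is not None:
            seq = consensus if isinstance(consensus, str) else consensus.get(contig)
            if seq is None:
                raise ConsensusMismatchError(f"contig {contig!r} absent from consensus")
            observed = seq[position - 1 : position - 1 + len(ref)]
            if observed != ref:
                raise ConsensusMismatchError(
                    f"REF allele {ref!r} at {contig}:{position} does not match "
                    f"consensus ({observed!r})"
                )
        kept.append(
            Polymorphism(
                contig=contig,
                position=position,
                ref_allele=ref,
                alt_allele=alt,
                kind=kind,
                genotype_quality=gq,
                depth=dp,
            )
        )
    kept.sort(key=lambda p: (p.contig, p.position, p.ref_allele, p.alt_allele))
    return kept


def scan_barcode_windows(
    polymorphisms: Sequence[Polymorphism],
    consensus_length: int,
    window_length: int,
    excluded_intervals: Sequence[tuple[int, int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Rank every window placement by the number of polymorphisms it contains.

    A polymorphism belongs to a window iff its full REF-allele span lies
    inside the window (a variant truncated by the window edge cannot be
    typed from a read of that window).  Windows overlapping any excluded
    interval (1-based closed; e.g. homologous-repeat or non-coding
    regions) are removed.  Result rows are ``(start, end, count)`` with
    1-based inclusive coordinates, sorted by descending count then
    ascending start.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if window_length > consensus_length:
        raise ValueError("window_length exceeds consensus length")

    n_windows = consensus_length - window_length + 1
    # difference array over window start positions: a polymorphism spanning
    # [a, b] is contained in windows starting in [b - window_length + 1, a]
    diff = np.zeros(n_windows + 1, dtype=np.int64)
    for poly in polymorphisms:
        a, b = poly.ref_span
        lo = max(1, b - window_length + 1)
        hi = min(n_windows, a)
        if lo <= hi:
            diff[lo - 1] += 1
            diff[hi] -= 1
    counts = np.cumsum(diff[:-1])

    allowed = np.ones(n_windows, dtype=bool)
    for lo, hi in excluded_intervals or ():
        # window [s, s+w-1] overlaps [lo, hi] iff s <= hi and s+w-1 >= lo
        s_lo = max(1, lo - window_length + 1)
        s_hi = min(n_windows, hi)
        if s_lo <= s_hi:
            allowed[s_lo - 1 : s_hi] = False

    starts = np.flatnonzero(allowed) + 1
    order = np.lexsort((starts, -counts[starts - 1]))
    return [
        (int(s), int(s + window_length - 1), int(counts[s - 1]))
        for s in starts[order]
    ]


def read_bed_intervals(path: str | Path, contig: str | None = None) -> list[tuple[int, int]]:
    """Read BED intervals (0-based half-open) as 1-based closed tuples.

    Only the first three columns are used; lines for other contigs are
    skipped when ``contig`` is given.
    """
    intervals: list[tuple[int, int]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line has fewer than 3 columns: {raw!r}")
        if contig is not None and fields[0] != contig:
            continue
        start0, end0 = int(fields[1]), int(fields[2])
        intervals.append((start0 + 1, end0))
    return intervals


def write_variant_report(polymorphisms: Sequence[Polymorphism], path: str | Path) -> None:
    """Write the filtered-variant table as TSV."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "contig": p.contig,
                "position": p.position,
                "ref": p.ref_allele,
                "alt": p.alt_allele,
                "kind": p.kind,
                "GQ": p.genotype_quality,
                "depth": p.depth,
            }
            for p in polymorphisms
        ],
        columns=["contig", "position", "ref", "alt", "kind", "GQ", "depth"],
    )
    frame.to_csv(path, sep="\t", index=False)
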