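"""Combinatorial enumeration of barcode haplotypes.

A barcode region carrying y biallelic polymorphisms defines 2^y possible
haplotypes ("genotypes"): every subset of the alternate alleles applied to
the consensus.  Each haplotype is identified by a bitmask integer whose
bit i records whether polymorphism i (0-based, ordered by ascending
position) carries its alternate allele; the all-reference haplotype has
bitmask 0 and is the consensus itself.  Enumeration streams records so the
full database (10^7+ sequences for y = 25) is never held in memory.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from .variants import PipelineConfig, Polymorphism

__all__ = [
    "BarcodeRegion",
    "HaplotypeRecord",
    "build_haplotype",
    "enumerate_database",
    "write_database_fasta",
    "read_database_fasta",
    "OverlapError",
    "TooManyPolymorphismsError",
]


class OverlapError(ValueError):
    """Two applied polymorphisms have overlapping reference spans."""


class TooManyPolymorphismsError(ValueError):
    """Enumeration refused: the database would grow beyond the practical cap."""


@dataclass(frozen=True)
class BarcodeRegion:
    """A contiguous consensus subsequence and its ordered polymorphisms.

    ``start``/``end`` are 1-based inclusive coordinates on the parent
    contig; ``consensus_seq`` has length end - start + 1.  Polymorphisms
    are re-indexed 0..y-1 on construction, ordered by ascending position
    (ties by ref then alt allele), and validated against the consensus.
    """

    label: str
    contig: str
    start: int
    end: int
    consensus_seq: str
    polymorphisms: tuple[Polymorphism, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.consensus_seq):
            raise ValueError(
                f"consensus_seq length {len(self.consensus_seq)} does not match "
                f"span {self.start}-{self.end}"
            )
        ordered = sorted(
            self.polymorphisms,
            key=lambda p: (p.position, p.ref_allele, p.alt_allele),
        )
        reindexed = []
        for i, poly in enumerate(ordered):
            a, b = poly.ref_span
            if a < self.start or b > self.end:
                raise ValueError(
                    f"polymorphism at {poly.contig}:{poly.position} "
                    f"(span {a}-{b}) lies outside barcode {self.start}-{self.end}"
                )
            local = a - self.start
            observed = self.consensus_seq[local : local + len(poly.ref_allele)]
            if observed != poly.ref_allele:
                raise ValueError(
                    f"REF allele {poly.ref_allele!r} at position {poly.position} "
                    f"does not match barcode consensus ({observed!r})"
                )
            reindexed.append(
                Polymorphism(
                    contig=poly.contig,
                    position=poly.position,
                    ref_allele=poly.ref_allele,
                    alt_allele=poly.alt_allele,
                    kind=poly.kind,
                    genotype_quality=poly.genotype_quality,
                    depth=poly.depth,
                    index=i,
                )
            )
        object.__setattr__(self, "polymorphisms", tuple(reindexed))

    @property
    def y(self) -> int:
        """Number of polymorphisms (the exponent of the 2^y database size)."""
        return len(self.polymorphisms)

    @property
    def length(self) -> int:
        return len(self.consensus_seq)

    def local_position(self, poly: Polymorphism) -> int:
        """0-based offset of a polymorphism within the barcode sequence."""
        return poly.position - self.start

    def has_indels(self) -> bool:
        return any(p.kind != "substitution" for p in self.polymorphisms)

    def achievable_lengths(self) -> frozenset[int]:
        """All sequence lengths reachable by some subset of the indels."""
        deltas = {0}
        for poly in self.polymorphisms:
            d = poly.length_delta
            if d:
                deltas |= {x + d for x in deltas}
        return frozenset(len(self.consensus_seq) + d for d in deltas)


@dataclass(frozen=True)
class HaplotypeRecord:
    """One generated reference sequence, named ``<label>_G_<bitmask>``."""

    bitmask: int
    name: str
    sequence: str


def build_haplotype(region: BarcodeRegion, bitmask: int) -> HaplotypeRecord:
    """Construct the haplotype sequence selected by ``bitmask``.

    For every set bit i the reference span of polymorphism i is replaced
    by its alternate allele.  Edits are applied in strictly descending
    position order so that indels never shift the coordinates of edits
    still to be applied.

    Raises
    ------
    ValueError
        If ``bitmask`` is outside [0, 2^y).
    OverlapError
        If two selected polymorphisms have overlapping reference spans.
    """
    y = region.y
    if not 0 <= bitmask < (1 << y):
        raise ValueError(f"bitmask {bitmask} out of range for y={y}")
    selected = [p for p in region.polymorphisms if bitmask >> p.index & 1]
    for prev, cur in zip(selected, selected[1:]):
        if cur.ref_span[0] <= prev.ref_span[1]:
            raise OverlapError(
                f"polymorphisms at positions {prev.position} and {cur.position} "
                "have overlapping reference spans"
            )
    seq = region.consensus_seq
    for poly in reversed(selected):
        local = region.local_position(poly)
        seq = seq[:local] + poly.alt_allele + seq[local + len(poly.ref_allele) :]
    return HaplotypeRecord(
        bitmask=bitmask, name=f"{region.label}_G_{bitmask}", sequence=seq
    )


def enumerate_database(
    region: BarcodeRegion, config: PipelineConfig | None = None
) -> Iterator[HaplotypeRecord]:
    """Yield all 2^y haplotypes of a region, bitmasks ascending.

    Refuses regions whose polymorphism count exceeds
    ``config.max_polymorphisms``: the database doubles with every added
    polymorphism (2^y records), so enumeration past ~30 sites is not a
    desk-scale operation.
    """
    config = config or PipelineConfig()
    y = region.y
    if y > config.max_polymorphisms:
        raise TooManyPolymorphismsError(
            f"region {region.label!r} carries y={y} polymorphisms; the database "
            f"holds 2^y = {2**y:,} sequences, beyond the practical cap of "
            f"2^{config.max_polymorphisms}"
        )
    for bitmask in range(1 << y):
        yield build_haplotype(region, bitmask)


def database_size(region: BarcodeRegion) -> int:
    """Number of haplotypes the region defines (2^y), without enumeration."""
    return 1 << region.y


def write_database_fasta(
    records: Iterable[HaplotypeRecord],
    destination: str | Path | IO[str],
    line_width: int = 70,
) -> int:
    """Write haplotype records as FASTA; ``.gz`` paths are gzip-compressed.

    Returns the number of records written.
    """
    def _dump(handle: IO[str]) -> int:
        n = 0
        for rec in records:
            handle.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), line_width):
                handle.write(rec.sequence[i : i + line_width] + "\n")
            n += 1
        return n

    if hasattr(destination, "write"):
        return _dump(destination)  # type: ignore[arg-type]
    path = Path(destination)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:  # type: ignore[operator]
        return _dump(handle)


def read_database_fasta(path: str | Path) -> list[HaplotypeRecord]:
    """Read a haplotype FASTA back; bitmask recovered from the name suffix."""
    from Bio import SeqIO

    path = Path(path)
    handle = gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
    with handle:
        out = []
        for rec in SeqIO.parse(handle, "fasta"):
            bitmask = int(rec.id.rsplit("_G_", 1)[1])
            out.append(HaplotypeRecord(bitmask=bitmask, name=rec.id, sequence=str(rec.seq)))
    return out
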