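"""Amplicon read quality control and primer trimming.

Reads are kept when their mean Phred quality clears a threshold (Q20 by
default) and they contain no ambiguous bases; surviving reads are oriented
against the consensus, stripped of primer sequence and truncated to the
expected amplicon span so that downstream genotype assignment sees only
the barcode interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from .variants import PipelineConfig

__all__ = [
    "AmpliconRead",
    "quality_filter",
    "trim_to_amplicon",
    "read_fastq",
    "read_fasta_as_reads",
    "write_fastq",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconRead:
    """One amplicon read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    orientation: str = "forward"  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


def quality_filter(
    reads: Iterable[AmpliconRead], config: PipelineConfig | None = None
) -> Iterator[AmpliconRead]:
    """Yield reads whose mean Phred quality >= ``min_read_quality`` and
    which contain no N bases; input order preserved."""
    config = config or PipelineConfig()
    kept = removed = 0
    for read in reads:
        if read.mean_quality >= config.min_read_quality and "N" not in read.sequence:
            kept += 1
            yield read
        else:
            removed += 1
    logger.info("quality_filter: retained %d reads, removed %d", kept, removed)


def _find_primer(sequence: str, primer: str, max_shift: int = 5) -> int | None:
    """Locate a primer near the 5' end; exact match first, then <=1 mismatch.

    Returns the primer start offset, or None.  The primer is allowed to
    start within the first ``max_shift`` bases (leading adapter slop).
    """
    pos = sequence.find(primer, 0, max_shift + len(primer))
    if pos != -1:
        return pos
    k = len(primer)
    for start in range(0, min(max_shift, len(sequence) - k) + 1):
        window = sequence[start : start + k]
        mismatches = sum(a != b for a, b in zip(window, primer))
        if mismatches <= 1:
            return start
    return None


def trim_to_amplicon(
    reads: Iterable[AmpliconRead],
    forward_primer: str,
    reverse_primer: str,
    expected_length: int,
) -> Iterator[AmpliconRead]:
    """Orient reads, strip the forward primer and truncate to the amplicon.

    Each read is searched for the forward primer at its 5' end (exact,
    then allowing one mismatch); if absent, the reverse complement is
    searched, flipping the read's orientation.  Primer and any upstream
    bases are removed, a trailing reverse-primer complement is removed if
    present, and the remainder is truncated to ``expected_length``.
    Reads where neither orientation shows the primer are dropped.
    """
    if not forward_primer or not reverse_primer:
        raise ValueError("primers must be non-empty")
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    if expected_length < len(forward_primer) + len(reverse_primer):
        raise ValueError("expected_length shorter than the combined primers")

    rev_primer_rc = reverse_complement(reverse_primer)
    kept = dropped = 0
    for read in reads:
        seq, quals, orientation = read.sequence, read.qualities, read.orientation
        pos = _find_primer(seq, forward_primer)
        if pos is None:
            seq_rc = reverse_complement(seq)
            pos = _find_primer(seq_rc, forward_primer)
            if pos is not None:
                seq, quals = seq_rc, read.qualities[::-1]
                orientation = "reverse" if read.orientation == "forward" else "forward"
        if pos is None:
            dropped += 1
            logger.debug("trim: dropped %s (forward primer not found)", read.read_id)
            continue
        start = pos + len(forward_primer)
        insert, iq = seq[start:], quals[start:]
        tail = insert.find(rev_primer_rc)
        if tail != -1:
            insert, iq = insert[:tail], iq[:tail]
        insert, iq = insert[:expected_length], iq[:expected_length]
        kept += 1
        yield AmpliconRead(read.read_id, insert, tuple(iq), orientation)
    logger.info("trim_to_amplicon: kept %d reads, dropped %d (no primer)", kept, dropped)


def read_fastq(source: str | Path | IO[str]) -> Iterator[AmpliconRead]:
    """Stream reads from a FASTQ file (Sanger Phred+33)."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(source) if isinstance(source, (str, Path)) else source, "fastq"):
        yield AmpliconRead(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def read_fasta_as_reads(
    source: str | Path | IO[str], assumed_quality: int = 40
) -> Iterator[AmpliconRead]:
    """Stream FASTA records as reads with a uniform assumed quality."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(source) if isinstance(source, (str, Path)) else source, "fasta"):
        seq = str(rec.seq).upper()
        yield AmpliconRead(rec.id, seq, (assumed_quality,) * len(seq))


def write_fastq(reads: Iterable[AmpliconRead], destination: str | Path | IO[str]) -> int:
    """Write reads as Sanger FASTQ; returns the record count."""
    def _dump(handle: IO[str]) -> int:
        n = 0
        for read in reads:
            quals = "".join(chr(min(q, 93) + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
        return n

    if hasattr(destination, "write"):
        return _dump(destination)  # type: ignore[arg-type]
    with open(destination, "w") as handle:
        return _dump(handle)
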