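"""Read-to-genotype assignment and relative-abundance estimation.

Instead of enumerating all 2^y haplotype references and mapping reads
against them, :func:`assign_read` infers the genotype bitmask directly:
it walks the consensus and the read in lockstep, branching only at
polymorphic sites, and accepts a read iff exactly one bitmask yields a
character-perfect, gap-free, full-length reconstruction.  This is
equivalent to enumerate-then-exact-match (:func:`assign_read_bruteforce`
is that oracle, kept for cross-checking) but costs O(L + y) per read
rather than O(2^y · L).

Reads that match no haplotype are rejected with a reason; reads matching
two bitmasks (possible only when distinct allele subsets build identical
sequences) are rejected as ambiguous since their count cannot be
attributed.  Abundances are reported over *all* assigned reads, including
reads in genotypes later dropped by the coverage threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .haplotype_db import BarcodeRegion, HaplotypeRecord
from .read_processing import AmpliconRead
from .variants import PipelineConfig

__all__ = [
    "AssignmentResult",
    "AbundanceTable",
    "assign_read",
    "assign_reads",
    "assign_read_bruteforce",
    "quantify",
    "write_abundance_tsv",
    "write_assignment_tsv",
]

logger = logging.getLogger(__name__)

REJECTION_REASONS = (
    "gapped_or_indel_mismatch",
    "allele_mismatch",
    "length_mismatch",
    "ambiguous",
)


@dataclass(frozen=True)
class AssignmentResult:
    """Per-read outcome: an assigned genotype bitmask or a rejection reason."""

    read_id: str
    bitmask: int | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if (self.bitmask is None) == (self.reason is None):
            raise ValueError("exactly one of bitmask/reason must be set")
        if self.reason is not None and self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")

    @property
    def assigned(self) -> bool:
        return self.bitmask is not None


def _matching_bitmasks(sequence: str, region: BarcodeRegion) -> list[int]:
    """All bitmasks whose haplotype sequence equals ``sequence`` exactly.

    Depth-first walk over polymorphic sites.  Between sites the consensus
    and the read must agree character for character; at each site the read
    may continue via the reference or the alternate allele (both are tried
    when both match locally, which happens for indels whose alleles share
    a prefix — the walk disambiguates downstream).
    """
    polys = region.polymorphisms
    cons = region.consensus_seq
    matches: list[int] = []
    # frames: (site index, consensus offset, read offset, bitmask so far)
    stack: list[tuple[int, int, int, int]] = [(0, 0, 0, 0)]
    while stack:
        i, cp, rp, mask = stack.pop()
        if i == len(polys):
            if cons[cp:] == sequence[rp:]:
                matches.append(mask)
            continue
        poly = polys[i]
        lp = region.local_position(poly)
        seg = lp - cp
        if seg < 0:  # previous edit overlapped this site; path invalid
            continue
        if sequence[rp : rp + seg] != cons[cp:lp]:
            continue
        rp += seg
        ref, alt = poly.ref_allele, poly.alt_allele
        ncp = lp + len(ref)
        if sequence[rp : rp + len(ref)] == ref:
            stack.append((i + 1, ncp, rp + len(ref), mask))
        if sequence[rp : rp + len(alt)] == alt:
            stack.append((i + 1, ncp, rp + len(alt), mask | 1 << poly.index))
    return matches


def _rejection_reason(read_length: int, lengths: frozenset[int]) -> str:
    """Reason for a read with no perfect haplotype match.

    ``lengths`` is the set of sequence lengths the haplotype database can
    produce.  A read whose length matches no haplotype is a length
    mismatch; otherwise, in a region whose haplotypes vary in length
    (i.e. one carrying indels) the failure may be an indel misplacement,
    reported as gapped; in a fixed-length (substitution-only) region the
    failure is necessarily a base-level allele mismatch.
    """
    if read_length not in lengths:
        return "length_mismatch"
    if len(lengths) > 1:
        return "gapped_or_indel_mismatch"
    return "allele_mismatch"


def assign_read(
    read: AmpliconRead,
    region: BarcodeRegion,
    config: PipelineConfig | None = None,
) -> AssignmentResult:
    """Assign one trimmed read to a genotype bitmask, or reject it.

    The read must already be trimmed to the barcode span.  Assignment
    succeeds iff exactly one bitmask reconstructs the read perfectly
    (no gaps, no mismatches, full length).
    """
    config = config or PipelineConfig()
    if region.y > config.max_polymorphisms:
        from .haplotype_db import TooManyPolymorphismsError

        raise TooManyPolymorphismsError(
            f"region {region.label!r} carries y={region.y} polymorphisms "
            f"(cap {config.max_polymorphisms}; the search space grows as 2^y)"
        )
    matches = _matching_bitmasks(read.sequence, region)
    if len(matches) == 1:
        return AssignmentResult(read.read_id, bitmask=matches[0])
    if len(matches) > 1:
        return AssignmentResult(read.read_id, reason="ambiguous")
    reason = _rejection_reason(len(read.sequence), region.achievable_lengths())
    return AssignmentResult(read.read_id, reason=reason)


def assign_reads(
    reads: Iterable[AmpliconRead],
    region: BarcodeRegion,
    config: PipelineConfig | None = None,
) -> Iterator[AssignmentResult]:
    """Assign a stream of reads (see :func:`assign_read`)."""
    config = config or PipelineConfig()
    for read in reads:
        yield assign_read(read, region, config)


def assign_read_bruteforce(
    read: AmpliconRead, database: Iterable[HaplotypeRecord]
) -> AssignmentResult:
    """Oracle assignment by exact comparison against every enumerated haplotype.

    Mirrors the map-against-all-references procedure directly; practical
    only for small y.  Returns the same contract as :func:`assign_read`.
    """
    matches: list[int] = []
    lengths: set[int] = set()
    for rec in database:
        lengths.add(len(rec.sequence))
        if rec.sequence == read.sequence:
            matches.append(rec.bitmask)
    if len(matches) == 1:
        return AssignmentResult(read.read_id, bitmask=matches[0])
    if len(matches) > 1:
        return AssignmentResult(read.read_id, reason="ambiguous")
    reason = _rejection_reason(len(read.sequence), frozenset(lengths))
    return AssignmentResult(read.read_id, reason=reason)


@dataclass
class AbundanceTable:
    """Per-genotype read counts and relative abundances after filtering.

    ``rows`` has columns Genotype, Reads, RelativeAbundancePct, sorted by
    descending read count; genotypes below ``threshold_used`` reads are
    excluded from the rows but their reads stay in ``total_assigned``, the
    denominator of every percentage.
    """

    rows: pd.DataFrame
    total_assigned: int
    total_rejected: int
    threshold_used: int
    rejection_counts: dict[str, int]

    @property
    def n_genotypes_detected(self) -> int:
        """Genotypes with at least one assigned read (before thresholding)."""
        return self._n_detected

    _n_detected: int = 0


def quantify(
    assignments: Iterable[AssignmentResult],
    region: BarcodeRegion,
    config: PipelineConfig | None = None,
) -> AbundanceTable:
    """Count assigned reads per genotype and compute relative abundances.

    Relative abundance = count / total_assigned x 100, reported to two
    decimals, where total_assigned counts every assigned read including
    those in genotypes that fall below the coverage threshold.
    """
    config = config or PipelineConfig()
    counts: dict[int, int] = {}
    rejections = {reason: 0 for reason in REJECTION_REASONS}
    for res in assignments:
        if res.assigned:
            counts[res.bitmask] = counts.get(res.bitmask, 0) + 1
        else:
            rejections[res.reason] += 1
    total_assigned = sum(counts.values())
    total_rejected = sum(rejections.values())
    threshold = config.min_genotype_coverage
    if total_assigned == 0:
        logger.warning("quantify: no reads assigned; emitting empty table")
        rows = pd.DataFrame(columns=["Genotype", "Reads", "RelativeAbundancePct"])
        table = AbundanceTable(rows, 0, total_rejected, threshold, rejections)
        table._n_detected = 0
        return table
    retained = sorted(
        ((mask, n) for mask, n in counts.items() if n >= threshold),
        key=lambda item: (-item[1], item[0]),
    )
    rows = pd.DataFrame(
        {
            "Genotype": [f"{region.label}_G_{mask}" for mask, _ in retained],
            "Reads": [n for _, n in retained],
            "RelativeAbundancePct": [
                round(n / total_assigned * 100, 2) for _, n in retained
            ],
        }
    )
    table = AbundanceTable(rows, total_assigned, total_rejected, threshold, rejections)
    table._n_detected = len(counts)
    return table


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write the abundance table as TSV (Genotype, Reads, RelativeAbundancePct)."""
    table.rows.to_csv(path, sep="\t", index=False, float_format="%.2f")


def write_assignment_tsv(
    assignments: Sequence[AssignmentResult], path: str | Path
) -> None:
    """Write per-read assignment outcomes as TSV."""
    frame = pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "bitmask": [a.bitmask if a.assigned else "" for a in assignments],
            "outcome": ["assigned" if a.assigned else a.reason for a in assignments],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
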