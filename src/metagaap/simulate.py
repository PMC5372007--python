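"""Synthetic communities with known truth.

Generates a consensus genome with a polymorphism-rich barcode hotspot, the
matching VCF, and error-bearing amplicon reads drawn from a genotype
frequency mixture — so the whole pipeline can be exercised end to end and
its estimates compared against the planted truth.

The error model is i.i.d. per-base substitution at a configurable rate;
platform-specific artefacts (homopolymer indel bias, quality decay along
the read) are deliberately not modelled, so analytic rejection-rate
expectations hold exactly.

Two published community compositions of the HaSNPV-AC53 baculovirus
isolate's BRO-A barcode are bundled as reference mixtures: the wild-type
isolate (28 genotypes above the 20x threshold, one dominant near 97%) and
the tissue-culture derived strain (a near-even two-genotype mix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .haplotype_db import BarcodeRegion, build_haplotype
from .read_processing import AmpliconRead
from .variants import Polymorphism, classify_variant

__all__ = [
    "CommunityTruth",
    "simulate_region",
    "simulate_reads",
    "frequencies_from_counts",
    "write_simulation",
    "BROA_WILDTYPE_COUNTS",
    "BROA_DERIVED_STRAIN_COUNTS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Read counts of the 28 above-threshold genotypes observed in the wild-type
# HaSNPV-AC53 BRO-A barcode community (bitmask genotype ID -> reads); the
# dominant genotype carries all 25 alternate alleles (2^25 - 1).
BROA_WILDTYPE_COUNTS: dict[int, int] = {
    33554431: 258084,
    33554303: 1643,
    33552383: 787,
    16777215: 666,
    33554423: 533,
    25165823: 437,
    33554430: 437,
    33292287: 400,
    31457279: 393,
    33554429: 261,
    33554399: 228,
    33554427: 213,
    33553919: 138,
    33554175: 129,
    33546239: 123,
    33554367: 105,
    29360127: 103,
    33030143: 103,
    33550335: 92,
    33552255: 68,
    33521663: 62,
    33554415: 56,
    33554428: 55,
    20971519: 52,
    33553407: 48,
    23068671: 35,
    33554239: 28,
    33538047: 21,
}

# Two-genotype composition of the derived strain's BRO-A barcode: a single
# T->A substitution segregates at roughly 54/46.
BROA_DERIVED_STRAIN_COUNTS: dict[int, int] = {1: 104065, 0: 87689}


@dataclass(frozen=True)
class CommunityTruth:
    """A simulated community: region, genotype frequencies, read model."""

    region: BarcodeRegion
    genotype_frequencies: Mapping[int, float]
    n_reads: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.genotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies sum to {total!r}, not 1")
        top = 1 << self.region.y
        for mask in self.genotype_frequencies:
            if not 0 <= mask < top:
                raise ValueError(f"bitmask {mask} out of range for y={self.region.y}")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def frequencies_from_counts(counts: Mapping[int, int]) -> dict[int, float]:
    """Normalise read counts into a genotype frequency vector."""
    total = sum(counts.values())
    return {mask: n / total for mask, n in counts.items()}


def simulate_region(
    consensus_length: int,
    y: int,
    kinds_mix: tuple[float, float, float] = (1.0, 0.0, 0.0),
    seed: int = 0,
    window_length: int = 365,
    label: str = "BRO-A",
    contig: str = "sim_contig",
    at_fraction: float = 0.65,
) -> tuple[tuple[str, str], list[dict], BarcodeRegion]:
    """Generate a consensus with a planted polymorphism hotspot.

    ``kinds_mix`` gives the proportions of substitutions, insertions and
    deletions among the y planted sites.  The hotspot (the barcode window)
    is centred in the consensus; sites are spaced at least 10 bp apart so
    reference spans can never overlap.  The background composition is
    AT-rich by default, matching the sort of low-complexity hotspot where
    polymorphism density peaks in practice.

    Returns ``((contig_name, consensus_seq), vcf_record_dicts, region)``;
    deterministic under ``seed``.
    """
    if y < 0 or y > 30:
        raise ValueError("y must be in [0, 30]")
    if consensus_length < max(window_length, y * 10 + 20):
        raise ValueError(
            f"consensus_length {consensus_length} too short for y={y} planted "
            f"sites (needs >= {max(window_length, y * 10 + 20)})"
        )
    if window_length < y * 10 + 10 and y > 0:
        raise ValueError("window_length too short to space the planted sites")
    if len(kinds_mix) != 3 or any(k < 0 for k in kinds_mix) or sum(kinds_mix) <= 0:
        raise ValueError("kinds_mix must be three non-negative proportions")

    rng = np.random.default_rng(seed)
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    seq = rng.choice(_BASES, size=consensus_length, p=[p_at, p_gc, p_gc, p_at])
    consensus = seq.tobytes().decode()

    start = (consensus_length - window_length) // 2 + 1  # 1-based
    end = start + window_length - 1

    kinds = ["substitution", "insertion", "deletion"]
    probs = np.asarray(kinds_mix, dtype=float)
    chosen_kinds = rng.choice(kinds, size=y, p=probs / probs.sum())

    # positions spaced >= 10 bp inside the window, away from its edges so
    # a deletion's ref span stays inside
    if y:
        slots = np.arange(y) * 10
        slack = (window_length - 10) - (slots[-1] + 5)
        offset = rng.integers(2, max(3, slack)) if slack > 2 else 2
        positions = start + offset + slots + rng.integers(0, 5, size=y)

    polymorphisms: list[Polymorphism] = []
    vcf_records: list[dict] = []
    for i in range(y):
        pos = int(positions[i])
        kind = chosen_kinds[i]
        ref_base = consensus[pos - 1]
        if kind == "substitution":
            ref, alt = ref_base, str(rng.choice([b for b in "ACGT" if b != ref_base]))
        elif kind == "insertion":
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            ref, alt = ref_base, ref_base + ins
        else:  # deletion of 1-3 following consensus bases
            k = int(rng.integers(1, 4))
            ref, alt = consensus[pos - 1 : pos + k], ref_base
        depth = int(rng.integers(100, 5000))
        polymorphisms.append(
            Polymorphism(
                contig=contig,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                kind=classify_variant(ref, alt),
                genotype_quality=99,
                depth=depth,
            )
        )
        vcf_records.append(
            {
                "contig": contig,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "genotype_quality": 99,
                "depth": depth,
                "line": i + 1,
            }
        )

    region = BarcodeRegion(
        label=label,
        contig=contig,
        start=start,
        end=end,
        consensus_seq=consensus[start - 1 : end],
        polymorphisms=tuple(polymorphisms),
    )
    return (contig, consensus), vcf_records, region


def _phred_for_error_rate(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, max(2, round(-10 * math.log10(error_rate))))


def simulate_reads(truth: CommunityTruth) -> tuple[list[AmpliconRead], list[tuple[str, int]]]:
    """Draw reads from a community and return them with their truth table.

    Each read's genotype is drawn i.i.d. from the frequency vector; the
    read is that genotype's haplotype sequence with i.i.d. per-base
    substitution errors at ``error_rate`` and flat Phred qualities
    consistent with that rate.  Deterministic under ``truth.seed``.

    Returns ``(reads, [(read_id, true_bitmask), ...])``.
    """
    rng = np.random.default_rng(truth.seed)
    masks = list(truth.genotype_frequencies)
    probs = np.array([truth.genotype_frequencies[m] for m in masks])
    haplotypes = {m: build_haplotype(truth.region, m).sequence for m in masks}
    draws = rng.choice(len(masks), size=truth.n_reads, p=probs / probs.sum())
    qual = _phred_for_error_rate(truth.error_rate)
    width = len(str(truth.n_reads))
    qual_cache: dict[int, tuple[int, ...]] = {}  # share tuples across reads

    reads: list[AmpliconRead] = []
    truth_table: list[tuple[str, int]] = []
    for i, gi in enumerate(draws):
        mask = masks[gi]
        seq = haplotypes[mask]
        if truth.error_rate > 0:
            n_err = rng.binomial(len(seq), truth.error_rate)
            if n_err:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                sites = rng.choice(len(seq), size=n_err, replace=False)
                for s in sites:
                    choices = _BASES[_BASES != arr[s]]
                    arr[s] = rng.choice(choices)
                seq = arr.tobytes().decode()
        read_id = f"read_{i:0{width}d}"
        quals = qual_cache.get(len(seq))
        if quals is None:
            quals = qual_cache.setdefault(len(seq), (qual,) * len(seq))
        reads.append(AmpliconRead(read_id, seq, quals))
        truth_table.append((read_id, mask))
    return reads, truth_table


def write_simulation(
    out_dir: str | Path,
    consensus: tuple[str, str],
    vcf_records: Sequence[dict],
    reads: Sequence[AmpliconRead],
    truth_table: Sequence[tuple[str, int]],
) -> dict[str, Path]:
    """Write consensus FASTA, VCF, reads FASTQ and the truth TSV."""
    import pysam

    from .read_processing import write_fastq

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contig, seq = consensus

    fasta_path = out / "consensus.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    vcf_path = out / "variants.vcf"
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample("sim")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for rec in vcf_records:
            row = vcf.new_record(
                contig=rec["contig"],
                start=rec["position"] - 1,
                alleles=(rec["ref"], rec["alt"]),
            )
            row.samples["sim"]["GT"] = (0, 1)
            row.samples["sim"]["GQ"] = rec["genotype_quality"]
            row.samples["sim"]["DP"] = rec["depth"]
            vcf.write(row)

    fastq_path = out / "reads.fq"
    write_fastq(reads, fastq_path)

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("read_id\ttrue_bitmask\n")
        for read_id, mask in truth_table:
            fh.write(f"{read_id}\t{mask}\n")

    return {
        "consensus": fasta_path,
        "vcf": vcf_path,
        "reads": fastq_path,
        "truth": truth_path,
    }
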