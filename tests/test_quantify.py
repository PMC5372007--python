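"""Genotype assignment (direct vs brute-force oracle) and abundance tables."""

import numpy as np
import pytest

from metagaap.haplotype_db import (
    TooManyPolymorphismsError,
    build_haplotype,
    enumerate_database,
)
from metagaap.quantify import (
    AssignmentResult,
    assign_read,
    assign_read_bruteforce,
    assign_reads,
    quantify,
)
from metagaap.read_processing import AmpliconRead
from metagaap.simulate import simulate_region
from metagaap.variants import PipelineConfig

from .conftest import make_poly


def read_of(seq, read_id="r"):
    return AmpliconRead(read_id, seq, (40,) * len(seq))


class TestAssignRead:
    def test_consensus_read_assigned_zero(self, sub_only_region):
        res = assign_read(read_of(sub_only_region.consensus_seq), sub_only_region)
        assert res.assigned and res.bitmask == 0

    def test_single_substitution_both_alleles(self, single_sub_region):
        """A read carrying A at barcode position 293 is genotype 1; T is 0."""
        with_alt = build_haplotype(single_sub_region, 1).sequence
        assert assign_read(read_of(with_alt), single_sub_region).bitmask == 1
        consensus = single_sub_region.consensus_seq
        assert assign_read(read_of(consensus), single_sub_region).bitmask == 0

    def test_every_bitmask_recovered(self, indel_region):
        for rec in enumerate_database(indel_region):
            res = assign_read(read_of(rec.sequence), indel_region)
            assert res.assigned and res.bitmask == rec.bitmask

    def test_error_at_nonpolymorphic_site_rejected(self, sub_only_region):
        seq = sub_only_region.consensus_seq
        corrupt = seq[:4] + ("A" if seq[4] != "A" else "C") + seq[5:]
        res = assign_read(read_of(corrupt), sub_only_region)
        assert not res.assigned and res.reason == "allele_mismatch"

    def test_wrong_length_read_rejected(self, sub_only_region):
        res = assign_read(read_of(sub_only_region.consensus_seq[:-1]), sub_only_region)
        assert res.reason == "length_mismatch"

    def test_indel_region_mismatch_reported_as_gapped(self, indel_region):
        seq = build_haplotype(indel_region, 0b01).sequence  # 7 bp
        corrupt = "T" + seq[1:]
        res = assign_read(read_of(corrupt), indel_region)
        assert res.reason == "gapped_or_indel_mismatch"

    def test_degenerate_sequences_rejected_ambiguous(self, degenerate_region):
        seq = build_haplotype(degenerate_region, 0b01).sequence
        assert seq == build_haplotype(degenerate_region, 0b10).sequence
        res = assign_read(read_of(seq), degenerate_region)
        assert res.reason == "ambiguous"

    def test_refuses_oversized_region(self):
        consensus = "ACGTACGTAC" * 40
        polys = tuple(make_poly(1 + 10 * i, "A", "T") for i in range(31))
        from metagaap.haplotype_db import BarcodeRegion

        region = BarcodeRegion(
            label="big", contig="chr", start=1, end=400,
            consensus_seq=consensus, polymorphisms=polys,
        )
        with pytest.raises(TooManyPolymorphismsError):
            assign_read(read_of(consensus), region)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_direct_assignment_matches_bruteforce(self, seed):
        """assign_read agrees with enumerate-then-exact-match on randomized
        reads (clean haplotypes, error-bearing and truncated) for y <= 10."""
        rng = np.random.default_rng(seed)
        y = int(rng.integers(1, 11))
        _, _, region = simulate_region(
            1200, y, kinds_mix=(0.5, 0.25, 0.25), seed=seed, window_length=200
        )
        database = list(enumerate_database(region))
        reads = []
        for i in range(300):
            rec = database[rng.integers(len(database))]
            seq = rec.sequence
            roll = rng.random()
            if roll < 0.3:  # plant a substitution error
                pos = int(rng.integers(len(seq)))
                base = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
                seq = seq[:pos] + base + seq[pos + 1 :]
            elif roll < 0.4:  # truncate
                seq = seq[: int(rng.integers(1, len(seq)))]
            reads.append(read_of(seq, f"r{i}"))
        for r in reads:
            direct = assign_read(r, region)
            brute = assign_read_bruteforce(r, database)
            assert (direct.bitmask, direct.reason) == (brute.bitmask, brute.reason)

    def test_bruteforce_consensus_identity(self, sub_only_region):
        db = list(enumerate_database(sub_only_region))
        res = assign_read_bruteforce(read_of(sub_only_region.consensus_seq), db)
        assert res.bitmask == 0

    def test_bruteforce_flags_degenerate_ambiguity(self, degenerate_region):
        db = [
            build_haplotype(degenerate_region, m) for m in (0b00, 0b01, 0b10)
        ]  # 0b11 would co-select overlapping deletions
        seq = build_haplotype(degenerate_region, 0b01).sequence
        assert assign_read_bruteforce(read_of(seq), db).reason == "ambiguous"


def result(read_id, bitmask=None, reason=None):
    return AssignmentResult(read_id, bitmask=bitmask, reason=reason)


class TestQuantify:
    def test_published_two_genotype_counts(self, single_sub_region):
        """Counts of 104,065 vs 87,689 give 54.27% and 45.73%."""
        assignments = [result(f"a{i}", bitmask=1) for i in range(104_065)]
        assignments += [result(f"b{i}", bitmask=0) for i in range(87_689)]
        table = quantify(assignments, single_sub_region)
        assert table.total_assigned == 191_754
        rows = dict(zip(table.rows.Genotype, table.rows.RelativeAbundancePct))
        assert rows == {"BRO-A_G_1": 54.27, "BRO-A_G_0": 45.73}

    def test_subthreshold_genotype_dropped_but_counted(self, sub_only_region):
        assignments = [result(f"r{i}", bitmask=0) for i in range(19)]
        table = quantify(assignments, sub_only_region)
        assert len(table.rows) == 0
        assert table.total_assigned == 19
        assert table.n_genotypes_detected == 1

    def test_percentages(self, sub_only_region):
        config = PipelineConfig(min_genotype_coverage=1)
        assignments = [result(f"a{i}", bitmask=1) for i in range(97)]
        assignments += [result(f"b{i}", bitmask=2) for i in range(3)]
        table = quantify(assignments, sub_only_region, config)
        assert list(table.rows.RelativeAbundancePct) == [97.00, 3.00]

    def test_empty_assignment_stream(self, sub_only_region):
        table = quantify([], sub_only_region)
        assert table.total_assigned == 0 and len(table.rows) == 0

    def test_rejections_tallied(self, sub_only_region):
        assignments = [
            result("a", bitmask=0),
            result("b", reason="allele_mismatch"),
            result("c", reason="length_mismatch"),
        ]
        table = quantify(assignments, sub_only_region, PipelineConfig(min_genotype_coverage=1))
        assert table.total_rejected == 2
        assert table.rejection_counts["allele_mismatch"] == 1

    def test_conservation_on_random_counts(self, sub_only_region):
        """Retained + dropped counts equal total_assigned; abundances over
        all genotypes sum to 100 up to rounding."""
        rng = np.random.default_rng(3)
        assignments = [
            result(f"r{i}", bitmask=int(rng.integers(0, 4))) for i in range(5000)
        ]
        table = quantify(assignments, sub_only_region)
        assert int(table.rows.Reads.sum()) <= table.total_assigned == 5000
        full = quantify(assignments, sub_only_region, PipelineConfig(min_genotype_coverage=1))
        assert abs(full.rows.RelativeAbundancePct.sum() - 100.0) <= 0.02

    def test_result_must_have_exactly_one_outcome(self):
        with pytest.raises(ValueError):
            AssignmentResult("r", bitmask=1, reason="ambiguous")
        with pytest.raises(ValueError):
            AssignmentResult("r")


class TestMixtureRecovery:
    def test_error_free_mixture_recovered_within_binomial_error(self):
        """A dominant-plus-tail mixture at n = 50,000 error-free reads is
        recovered within 3 binomial standard errors per genotype."""
        from metagaap.simulate import CommunityTruth, simulate_reads

        _, _, region = simulate_region(1200, 6, seed=5, window_length=200)
        freqs = {63: 0.97, 62: 0.014, 31: 0.01, 0: 0.006}
        n = 50_000
        truth = CommunityTruth(region, freqs, n, error_rate=0.0, seed=6)
        reads, _ = simulate_reads(truth)
        table = quantify(
            assign_reads(reads, region), region, PipelineConfig(min_genotype_coverage=1)
        )
        assert table.total_assigned == n
        observed = {
            int(g.rsplit("_", 1)[1]): pct / 100
            for g, pct in zip(table.rows.Genotype, table.rows.RelativeAbundancePct)
        }
        for mask, p in freqs.items():
            se = (p * (1 - p) / n) ** 0.5
            assert abs(observed.get(mask, 0.0) - p) <= 3 * se + 1e-4

    def test_rejection_rate_matches_closed_form(self):
        """With i.i.d. per-base errors at rate eps on a substitution-only
        region, reads are rejected unless every non-polymorphic base is
        error-free and polymorphic-site errors miss both alleles; the
        acceptance probability is close to (1 - eps)^(L - y)."""
        from metagaap.simulate import CommunityTruth, simulate_reads

        eps, n = 0.005, 20_000
        _, _, region = simulate_region(
            1200, 4, kinds_mix=(1, 0, 0), seed=7, window_length=365
        )
        truth = CommunityTruth(region, {0: 0.6, 15: 0.4}, n, error_rate=eps, seed=8)
        reads, _ = simulate_reads(truth)
        results = list(assign_reads(reads, region))
        rejected = sum(not r.assigned for r in results)
        L, y = region.length, region.y
        expected = 1 - (1 - eps) ** (L - y)
        assert rejected / n == pytest.approx(expected, rel=0.10)
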