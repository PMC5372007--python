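# Methods

## Model

A barcode region of length L carries y biallelic polymorphisms
(substitutions, insertions, deletions) relative to the isolate consensus,
indexed 0..y−1 by ascending position (ties broken lexicographically by
ref then alt allele, so indexing is deterministic). A *genotype* is a
subset of alternate alleles, encoded as a bitmask b ∈ [0, 2^y): bit i set
⇔ polymorphism i applied. The genotype's haplotype sequence is the
consensus with every selected reference span replaced by its alternate
allele, edits applied in descending position order so indels cannot shift
coordinates of edits still pending. Bitmask 0 is the consensus itself.
Input indels are assumed left-normalised (VCF convention); normalisation
is validated only through the ref-allele-matches-consensus check.

Multi-allelic VCF sites are split into one biallelic polymorphism per
alternate allele. Two alternates at one site have overlapping reference
spans, so a bitmask selecting both is an error in `build_haplotype` and
such combinations simply attract zero reads during assignment — no
special-casing is needed.

## Read assignment

A read trimmed to the barcode span is assigned to genotype b iff the
haplotype of b reconstructs the read *perfectly*: no mismatches, no gaps,
full length. `assign_read` finds all matching bitmasks by a depth-first
lockstep walk: between polymorphic sites consensus and read must agree
character-for-character; at each site the walk branches into the
reference and/or alternate allele whenever the allele matches the read
locally (both can match for indels sharing a prefix; the walk
disambiguates downstream). Cost is O(L + y) per read with negligible
branching in practice. `assign_read_bruteforce` — exact comparison
against every enumerated haplotype — is retained as the independent
oracle; a 10^4-read randomized equivalence check is part of the test
suite and the acceptance script.

Rejection reasons are defined so both routes compute them identically
from observable quantities:

- `length_mismatch` — the read length equals no achievable haplotype
  length (the achievable set is the subset-sums of the indel length
  deltas; for the brute-force route, the set of database record lengths,
  which is the same set).
- `gapped_or_indel_mismatch` — no perfect match in a region whose
  haplotypes vary in length (i.e. one carrying indels): the failure may
  be an indel misplacement, mirroring the exclusion of gapped mappings.
- `allele_mismatch` — no perfect match in a fixed-length
  (substitution-only) region; necessarily a base-level mismatch.
- `ambiguous` — two or more bitmasks build the identical sequence (e.g.
  two disjoint single-base deletions in one homopolymer). The read's
  count cannot be attributed, so it is rejected rather than split.

Reads shorter than the full barcode span are rejected (`length_mismatch`
unless an indel combination happens to produce that length); partial-span
assignment is deliberately not attempted, since a partial read cannot
distinguish genotypes differing outside its span.

## Quantification

Genotype counts are tallied over assigned reads only. Rows with count
< `min_genotype_coverage` (default 20×, ≈1% error on a Phred scale) are
dropped from the report, but their reads remain in the denominator:
relative abundance = count / total_assigned × 100, to two decimals. This
denominator choice (all assigned reads, including sub-threshold
genotypes) reproduces the arithmetic structure of published two-genotype
tables and is the only convention consistent with a dominant-genotype
abundance computed while hundreds of 1-read genotypes exist.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_genotype_quality` | 60 (Phred) | VCF hard filter; GQ ≥ 60 kept. The boundary at exactly 60 is convention — both "below 60 excluded" and "above 60 kept" readings exist — so it is configurable, with ≥ as default. |
| `min_site_depth` | 20 (reads) | VCF hard filter, DP ≥ 20. |
| `min_read_quality` | 20 (Phred) | mean read quality cutoff. Interpreted as the mean, not per-base: per-base Q20 on ion-semiconductor data would discard nearly all reads. |
| `min_genotype_coverage` | 20 (reads) | report threshold per genotype. |
| `max_polymorphisms` | 30 | enumeration/assignment guard: the database grows as 2^y (33.5M sequences at y = 25), which bounds desk-scale use at y ≈ 30. A hard ceiling of 62 keeps bitmasks in a 64-bit integer. |
| `window_length` | 365 (bp) | barcode span for window scanning; 325 and 365 bp are the validated spans. |

Primer trimming allows one mismatch after an exact search fails (zero
tolerance would conflict with realistic per-base error rates) and
reverse-complements reads whose forward primer is found only in the
opposite orientation.

## Simulator

`simulate_region` plants y non-overlapping polymorphisms (spaced ≥ 6 bp,
indels of 1–3 bp) inside a window centred in an AT-rich random consensus
(65% AT by default, matching the low-complexity hotspots where
polymorphism density peaks), and emits VCF records with GQ/DP above the
default filters. `simulate_reads` draws each read's genotype i.i.d. from
a frequency vector and applies i.i.d. per-base substitution errors at a
configurable rate, with flat Phred qualities consistent with that rate
(Q = −10·log10 ε, capped at 40). Two published community compositions are
bundled as reference mixtures: a 28-genotype wild-type composition
(dominant ≈97%, tail to 0.01%) and a 54/46 two-genotype mix.

What the simulator does *not* model — and hence what passing tests do not
show about real data: homopolymer indel error bias typical of
ion-semiconductor chemistry, quality decay along the read, PCR chimeras,
and primer-site mutations. The substitution-only error model is what
makes the closed-form rejection-rate check exact: a read survives iff
every non-polymorphic base is error-free, so the rejection rate is
≈ 1 − (1−ε)^(L−y), and errors reject reads of equal-length genotypes at
the same rate, leaving conditional abundance estimates unbiased for
substitution-only regions (both properties are tested, at ε = 0.005 and
0.002 respectively).

## Numerical and design choices

- Window scan uses a difference-array cumulative sum (O(n + W)); a
  polymorphism belongs to a window only if its full reference span fits,
  since a truncated variant cannot be typed from that window. Ranking is
  by descending count, then ascending start. Verified against an O(n·W)
  brute-force oracle on randomized instances.
- Overlapping reference spans among co-selected polymorphisms raise an
  error rather than being silently resolved: no well-defined haplotype
  sequence exists in that case.
- Enumeration streams records (generator) and never materialises the
  database; writing the FASTA is optional and gzip-compressed on a `.gz`
  path. Assignment never requires the database at all.
- Zero assigned reads yields an explicit empty table with a warning
  status, not a division error.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds carried in configs/truth objects; identical inputs produce
  byte-identical abundance TSVs, and each full run writes a manifest
  (version, config, input SHA-256 digests, per-stage counts).

## Problem sizes used in the checks

The oracle-equivalence check runs 20 random regions (y ≤ 10) × 500 reads
= 10^4 reads; mixture recovery simulates 265,000 error-free reads over a
28-genotype community and requires every recovered frequency within 3
binomial standard errors of truth; consensus identity covers 1,000 random
regions; exhaustive enumeration counts run at y ≤ 12 with the y = 25 size
computed arithmetically. Note that the count of genotypes clearing the
20-read threshold in the simulated 28-genotype community is itself a
binomial quantity: the rarest genotype's expected count is ≈21, so
depending on the seed it finishes at 27 or 28.

## Known limitations

- Biallelic treatment only; co-occurrence of two alternates at one site
  in a single molecule is unrepresentable (and unobservable under the
  2^y model).
- No error correction: any read with a single error outside polymorphic
  sites is discarded, which is wasteful at high error rates but never
  biases equal-length genotype comparisons.
- No uncertainty intervals on abundances; estimates are point estimates,
  as in the original procedure.
- gVCF input, functional annotation and alignment-based mapping are out
  of scope; the package consumes plain VCF + FASTA + FASTQ.
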