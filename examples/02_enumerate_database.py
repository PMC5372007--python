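"""Enumerate every haplotype of a small barcode and export it as FASTA.

A region with y polymorphisms defines 2^y genotypes; each record is named
<label>_G_<bitmask>, where bit i records whether polymorphism i carries
its alternate allele.
"""

import sys

from metagaap import enumerate_database, write_database_fasta
from metagaap.haplotype_db import database_size
from metagaap.simulate import simulate_region

_, _, region = simulate_region(
    consensus_length=1500, y=3, kinds_mix=(0.5, 0.25, 0.25), seed=7, window_length=200
)
print(f"y = {region.y} polymorphisms -> {database_size(region)} haplotypes")
for poly in region.polymorphisms:
    print(f"  bit {poly.index}: {poly.kind} {poly.ref_allele}>{poly.alt_allele} at {poly.position}")

n = write_database_fasta(enumerate_database(region), sys.stdout)
print(f"# wrote {n} records; bitmask 0 is the consensus, 7 applies all three alleles")

# At y = 25 the same database would hold 33,554,432 sequences, which is why
# enumeration streams records and assignment works without the database.
_, _, big = simulate_region(consensus_length=3000, y=25, seed=7)
print(f"y = 25 -> {database_size(big):,} haplotypes (computed, not materialised)")
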