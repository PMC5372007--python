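"""Find the most polymorphism-dense barcode window in a genome.

Plants 30 polymorphisms in a hotspot, then ranks every 365 bp window
placement by how many polymorphisms it fully contains.
"""

from metagaap import scan_barcode_windows
from metagaap.simulate import simulate_region

(contig, consensus), _, region = simulate_region(consensus_length=5000, y=30, seed=3)
ranked = scan_barcode_windows(list(region.polymorphisms), len(consensus), 365)

print(f"{len(ranked)} candidate windows; top 3:")
for start, end, count in ranked[:3]:
    print(f"  {contig}:{start}-{end}  {count} polymorphisms")
print(f"planted hotspot: {region.start}-{region.end} with {region.y} polymorphisms")
# The top-ranked window contains all 30 planted sites; a window carrying y
# polymorphisms distinguishes 2^y genotypes from a single amplicon.
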