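"""Classify mitochondrial introns as cis- or trans-spliced.

Locates each gene's exons on the genome by local alignment of the
reference CDS, calls each intron from the adjacency of consecutive exons,
and maps the breakpoints of one trans intron against its ancestral
(cis-spliced) reference intron.
"""

from mitoshift.introns import (
    DEFAULT_REGISTRY,
    classify_introns,
    locate_exons,
    map_breakpoints,
)
from mitoshift.report import intron_calls_table
from mitoshift.simulate import SimConfig, make_mitogenome

genome, _, truth = make_mitogenome(SimConfig(seed=7))
placements = []
for gene, cds in truth.cds.items():
    placements += locate_exons(cds, genome, gene=gene)
calls = classify_introns(placements, DEFAULT_REGISTRY, genome_len=genome.length)

print(intron_calls_table(calls).to_string(index=False))
n_trans = sum(c.mode == "trans" for c in calls)
print(f"\n{len(calls)} introns: {len(calls) - n_trans} cis, {n_trans} trans")

call = next(c for c in calls if c.intron.name == "nad1i728")
blk = map_breakpoints(call, truth.intron_refs["nad1i728"], genome)
print(f"\nnad1i728 breakpoint synteny vs the ancestral intron "
      f"({len(truth.intron_refs['nad1i728'])} nt):")
print(f"  retained 5' end {blk.retained5_len} nt, retained 3' end "
      f"{blk.retained3_len} nt, lost middle {blk.lost_mid_len} nt")
# The lost middle (~866 nt here) is the part of the ancestral intron that
# disappeared when the genomic break converted it to trans splicing.
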