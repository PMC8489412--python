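"""Scan a mitogenome for plastid-derived insertions (MTPTs).

Aligns the mitogenome against its plastome (>100 bp, >=80% identity),
merges overlapping hits into regions, and calls the functional status of
plastid genes caught inside a transferred region.
"""

from mitoshift.mtpt import call_mtpt_genes, find_mtpt, mtpt_summary, mtpt_table
from mitoshift.simulate import SimConfig, make_mitogenome

genome, _, truth = make_mitogenome(SimConfig(seed=7))
regions = find_mtpt(genome, truth.plastome, min_len=101, min_ident=80)
call_mtpt_genes(regions, truth.plastid_genes, genome, truth.plastome)

s = mtpt_summary(regions, genome.length)
print(f"{s['count']} MTPT regions, {s['min_len']}-{s['max_len']} bp, "
      f"{s['min_identity']}-{s['max_identity']}% identity, "
      f"covering {s['coverage_pct']}% of the mitogenome\n")
print(mtpt_table(regions).to_string(index=False))
# Identity below 100% reflects the divergence applied when each segment
# was copied from the plastome; genes contained in a region are intact or
# classed pseudo_truncated / pseudo_frameshift / pseudo_internal_stop.
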