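"""Classify splice-junction motifs and flag novel junctions.

Simulates coverage for one library, treats its junction evidence as
unstranded, classifies terminal dinucleotides against the genome (GT/AG,
GC/AG, AT/AC or other, strand-aware), applies the rule-based filter and
flags junctions absent from the annotation as novel. A few junctions are
shifted by 2 nt to mimic alignment artifacts: they lose their canonical
motif and/or their annotated status.
"""

from collections import Counter

from dirseq import (
    FilterConfig,
    JunctionRecord,
    SimulationConfig,
    annotate_novelty,
    classify_motifs,
    filter_junctions,
    make_genome,
)
from dirseq.simulate import simulate_coverage

config = SimulationConfig(n_genes=30, seed=2)
sequences, genes, manifest = make_genome(config)
bundle = simulate_coverage(manifest, "leaf|control", 1)

records = [
    JunctionRecord(c, s, e, ".", n, max_overhang=30)
    for (c, s, e), n in sorted(bundle.junction_counts.items()) if n > 0
]
# perturb three junctions by 2 nt
for i in (0, 1, 2):
    r = records[i]
    records[i] = JunctionRecord(r.chrom, r.start + 2, r.end, ".", r.read_count,
                                max_overhang=30)

classified = classify_motifs(records, sequences)
kept, discarded = filter_junctions(classified, FilterConfig(min_overhang=0))
kept = annotate_novelty(kept, genes)

print("motif classes:", dict(Counter(r.motif_class for r in classified)))
print(f"kept {len(kept)} / discarded {len(discarded)} "
      "(non-canonical motifs or weak support removed)")
print("novel junctions among kept:", sum(not r.annotated for r in kept))
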