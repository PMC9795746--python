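"""Hotspot-motif enrichment in CDRs vs FRs of a synthetic IgV set.

Builds 5 annotated V-region sequences with a planted 3x higher WRC/GYW
motif density in CDR1/2 than in FR1-3, then computes the per-region
motifs-per-nucleotide index and the CDR/FR enrichment ratio.
"""

from aidbench.motifs import builtin_motif_sets, species_enrichment
from aidbench.simulate import IgVSimSpec, gen_igv_set

spec = IgVSimSpec(
    n_sequences=5,
    cdr_motif_density=0.06,  # motifs per nt planted in CDR1/2
    fr_motif_density=0.02,  # motifs per nt planted in FR1-3
    region_lengths={"FR1": 250, "CDR1": 250, "FR2": 250, "CDR2": 250, "FR3": 250},
    gc_content=0.5,
    seed=17,
)
seqs = gen_igv_set(spec)
result = species_enrichment(seqs, builtin_motif_sets()["WRC_GYW"])

for region, index in sorted(result.per_region_index.items()):
    print(f"{region}: {index:.4f} motifs/nt")
print(f"CDR mean index: {result.cdr_mean_index:.4f}")
print(f"FR mean index:  {result.fr_mean_index:.4f}")
print(f"enrichment ratio (CDR/FR): {result.enrichment_ratio:.2f}")
# A ratio > 1 means AID hotspots are concentrated in the antigen-binding
# CDR loops; ~1 (as in true-cod V genes) means no hotspot targeting signal.
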