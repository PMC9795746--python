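"""Multi-method ancestral-sequence consensus with ambiguity variants.

Simulates per-site posterior profiles from three reconstruction methods for
a short ancestral peptide with one genuinely uncertain site, combines them
with a 2:1:1 weighting favoring the Bayesian method, calls the consensus,
and enumerates the variants that would be synthesized (posterior >= 0.2 at
a site whose uncertainty is >= 0.2).
"""

from aidbench.consensus import call_consensus, combine_methods
from aidbench.simulate import PosteriorSimSpec, gen_posteriors

spec = PosteriorSimSpec(
    true_sequence="MDSLLMNRRKFLYQF",
    ambiguous_sites={9: ("T", 0.3)},  # site 9: 70 % R, 30 % T
    node_id="GD_ANC",
)
posteriors = gen_posteriors(spec)
combined = combine_methods(posteriors, {"mrbayes": 2, "raxml": 1, "protasr": 1})
result = call_consensus(combined, ambiguity_threshold=0.2)

print(f"consensus: {result.consensus_sequence}")
print(f"ambiguous sites: {[site for site, _ in result.ambiguous_sites]}")
for label, seq in result.variant_sequences().items():
    print(f"variant {label}: {seq}")
# Each variant is one single-substitution sequence to express and assay
# alongside the consensus, covering the reconstruction uncertainty.
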