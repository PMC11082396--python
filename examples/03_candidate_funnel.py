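"""Run the four-stage candidate-gene funnel on the hand-traced demo set.

Ten SNPs over six genes: each funnel step (impact, location, read
support, expression) removes genes for a documented reason, leaving one
candidate — the pattern a real mapping-by-sequencing run aims for.
"""
from oatmap import apply_funnel, gene_max_impact, orthogroup_screen, OrthogroupMap
from oatmap.demo import demo_funnel_dataset

variants, expression, config, expected = demo_funnel_dataset()
result = apply_funnel(variants, expression, config)

labels = {
    "i": "impact >= MODERATE",
    "ii": f"on {config.target_chromosome}",
    "iii": "alt depth >= 15, no ref reads",
    "iv": "> 0.5 TPM in all seed/glume/spikelet samples",
}
print("funnel trace (genes surviving each step):")
for step, count in result.step_counts.items():
    print(f"  {step:>3}) {labels[step]:<45} {count}")
print(f"final candidate(s): {', '.join(result.final_genes)}")
print(result.candidates.to_string(index=False))

# orthogroup screen: the candidate shares an orthogroup with a known
# seed-shape kinase, strengthening the case for it
orthogroups = OrthogroupMap({
    "OG0000448": [("arabidopsis", "at|BIN2"), ("oat", "g1.1"), ("oat", "g7.1")],
    "OG0000001": [("rice", "os|GW2"), ("oat", "g4.1")],
})
known = [("arabidopsis", "at|BIN2"), ("rice", "os|GW2"), ("maize", "zm|ZmDA1")]
impacted = [g for g, imp in gene_max_impact(variants).items() if imp >= 2]
screen = orthogroup_screen(orthogroups, known, impacted_genes=impacted)
print(f"\nscreen: {screen.n_with_orthogroup}/{screen.n_queried} known proteins in "
      f"{screen.n_orthogroups} orthogroups covering {screen.n_oat_proteins} oat proteins")
print(f"impacted genes among them: {screen.intersection}")
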