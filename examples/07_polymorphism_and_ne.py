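"""Polymorphism calling, spacing geometry and effective population size.

Plants SNPs at 4.39% and small indels at 0.98% on a diploid individual,
calls them back from the haplotype alignment, tests the geometric spacing
expected under random mating, and converts heterozygosity to an effective
population size via theta = 4*Ne*mu.
"""
from chordevo import simulate as sim
from chordevo.popgen import (
    call_variants, effective_population_size, spacing_fit,
    summarize_polymorphism, variant_spacings,
)

ancestor = sim.build_ancestor(sim.SimulationParams(n_genes=80, seed=23))
_, sequences, _, _ = ancestor.render()
hap_a, hap_b, truth, blocks = sim.make_diploid(
    sequences, sim.DiploidParams(snp_rate=0.0439, small_indel_rate=0.0098, seed=24)
)

variants = call_variants(blocks)
aligned = sum(
    sum(1 for x, y in zip(b.ref_text, b.query_text) if x != "-" and y != "-")
    for b in blocks
)
summary = summarize_polymorphism(variants, aligned, sum(map(len, hap_a.values())))
print(f"called {len(variants)} variants over {aligned:,} aligned columns")
print(f"SNP rate {summary.snp_rate:.2f}%  "
      f"small-indel event rate {summary.small_indel_event_rate:.2f}%")

fit = spacing_fit(variant_spacings(variants[variants.type == "snp"]))
print(f"spacing geometric fit: p_hat = {fit.p_hat:.4f}, "
      f"GOF chi2 = {fit.statistic:.1f} (df {fit.df}), P = {fit.p_value:.3f}")

pi = (summary.snp_rate + summary.small_indel_event_rate) / 100
for mu in (1e-8, 1e-9):
    ne = effective_population_size(pi, mu)
    print(f"Ne at mu = {mu:.0e}/yr: {ne / 1e6:.2f} million")
# A GOF P above 0.01 is consistent with independently scattered variants,
# the pattern expected for a randomly mating population.
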