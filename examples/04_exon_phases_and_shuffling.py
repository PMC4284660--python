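"""Intron phases, the 1-1 phase bias, and shuffled-exon detection.

Exon shuffling favours symmetric 1-1 exons because they can insert into
phase-1 introns without breaking the reading frame. This script plants
shuffles with a 0.7 preference for 1-1 donors and shows both the phase
spectrum and the recovery of the planted shuffles from exon-level
reciprocal best hits.
"""
from chordevo import simulate as sim
from chordevo.exons import annotate_phases, detect_shuffled_exons, phase_spectrum
from chordevo.orthology import OrthologyMap

ancestor = sim.build_ancestor(
    sim.SimulationParams(n_genes=80, exons_per_gene=6.0, seed=7)
)
la, log_a = sim.evolve_lineage(
    ancestor,
    sim.LineageParams(subst_rate=0.05, n_exon_shuffles=15, phase11_preference=0.7),
    seed=8, name="A",
)
lb, _ = sim.evolve_lineage(ancestor, sim.LineageParams(subst_rate=0.05), seed=9, name="B")

spectrum = phase_spectrum(annotate_phases(la.render()[0]), min_len_bp=100)
print(f"internal exons >100 bp: {spectrum.n}")
print("symmetric phase classes (proportion, 95% CI):")
print(spectrum.symmetric_summary().to_string(index=False))

orthology = OrthologyMap(
    pairs=[(a, b, 100.0, 100.0) for a, b in sim.orthology_truth(la, lb)]
)
hits_ab = sim.hit_table(la.exon_sequences(), lb.exon_sequences(),
                        min_identity=50, kmer_prefilter=11)
hits_ba = sim.hit_table(lb.exon_sequences(), la.exon_sequences(),
                        min_identity=50, kmer_prefilter=11)
found = detect_shuffled_exons(
    hits_ab, hits_ba, orthology, la.exon_to_gene(), lb.exon_to_gene()
)
truth = {e.data["exon_id"] for e in log_a if e.kind == "exon_shuffle"}
print(f"planted shuffles: {len(truth)}; detected: {len(found)}; "
      f"true positives: {len(set(found.shuffled) & truth)}")
# With an uneventful background, nearly all planted shuffles are recovered
# and false positives stay in the low single digits.
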