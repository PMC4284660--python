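import numpy as np
import pytest

from chordevo import simulate as sim
from chordevo.exons import (
    annotate_phases,
    detect_shuffled_exons,
    mark_domain_exons,
    phase_spectrum,
    shuffled_phase_bias,
    subgenic_dcj,
)
from chordevo.models import GeneModel, GenomeAnnotation
from chordevo.rearrangement import GeneOrder


def _gene(gene_id, strand, cds_lengths, seq_len=5000, gap=50):
    """A gene whose CDS pieces have the given lengths in translation order."""
    ivs = []
    pos = 100
    for L in cds_lengths if strand == "+" else reversed(cds_lengths):
        ivs.append((pos, pos + L))
        pos += L + gap
    return GeneModel(gene_id, "chr1", strand, exons=list(ivs), cds=list(ivs))


def _ann(*genes):
    return GenomeAnnotation(sequences={"chr1": 100_000}, genes=list(genes))


class TestPhases:
    def test_worked_example_100_200_150(self):
        ann = _ann(_gene("g", "+", [100, 200, 150]))
        ex = annotate_phases(ann)
        assert [(e.phase5, e.phase3) for e in ex] == [(None, 1), (1, 0), (0, None)]
        assert ex[1].is_internal and not ex[0].is_internal

    def test_minus_strand_mirrors_plus(self):
        plus = annotate_phases(_ann(_gene("g", "+", [100, 200, 150])))
        minus = annotate_phases(_ann(_gene("g", "-", [100, 200, 150])))
        assert [(e.phase5, e.phase3) for e in plus] == [
            (e.phase5, e.phase3) for e in minus
        ]

    def test_single_exon_gene_has_no_internal_exons(self):
        ex = annotate_phases(_ann(_gene("g", "+", [300])))
        assert len(ex) == 1 and not ex[0].is_internal
        assert ex[0].phase5 is None and ex[0].phase3 is None

    def test_incomplete_cds_excluded_with_warning(self):
        ann = _ann(_gene("g", "+", [100, 101]))  # total 201 % 3 == 0? 201 -> ok; use 200
        ann = _ann(_gene("g", "+", [100, 100]))
        with pytest.warns(UserWarning, match="not divisible"):
            ex = annotate_phases(ann)
        assert ex == []

    def test_simulator_truth_reproduced_exactly(self, ancestor):
        ann, _, _, _ = ancestor.render()
        phased = annotate_phases(ann)
        by_gene = {}
        for e in phased:
            by_gene.setdefault(e.gene_id, []).append(e)
        checked = 0
        for g in ancestor.genes():
            exl = sorted(by_gene[g.gene_id], key=lambda e: e.exon_index)
            assert [e.phase3 for e in exl[:-1]] == g.phases_truth
            checked += 1
        assert checked == len(ancestor.genes())


class TestSpectrum:
    def test_all_one_one(self):
        genes = [_gene(f"g{i}", "+", [100 + 3 * i, 201, 150 + 3 * ((100 - i) % 3)]) for i in (0,)]
        # construct explicitly: lengths 100,201,? -> boundary phases (1,1): 100%3=1, 301%3=1
        g = _gene("g", "+", [100, 201, 152])
        ex = annotate_phases(_ann(g))
        spec = phase_spectrum(ex, min_len_bp=100)
        assert spec.proportion((1, 1)) == 1.0

    def test_length_filter_never_increases_counts(self, ancestor):
        ann, _, _, _ = ancestor.render()
        ex = annotate_phases(ann)
        loose = phase_spectrum(ex, min_len_bp=0)
        strict = phase_spectrum(ex, min_len_bp=100)
        assert strict.n <= loose.n
        for cls in loose.counts:
            assert strict.counts[cls] <= loose.counts[cls]

    def test_proportions_sum_to_one(self, ancestor):
        ann, _, _, _ = ancestor.render()
        spec = phase_spectrum(annotate_phases(ann), min_len_bp=0)
        assert sum(spec.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_phases_give_one_ninth_each(self):
        # simulator draws boundary phases uniformly: each of 9 classes ~ 1/9
        anc = sim.build_ancestor(
            sim.SimulationParams(n_genes=400, exons_per_gene=6.0, n_cne_planted=0, seed=17)
        )
        ann, _, _, _ = anc.render()
        spec = phase_spectrum(annotate_phases(ann), min_len_bp=0)
        n = spec.n
        se = np.sqrt((1 / 9) * (8 / 9) / n)
        for cls, prop in spec.proportions.items():
            assert abs(prop - 1 / 9) <= 4 * se

    def test_empty_subset_rejected(self):
        ex = annotate_phases(_ann(_gene("g", "+", [300])))
        with pytest.raises(ValueError, match="no internal"):
            phase_spectrum(ex)

    def test_domain_exon_flagging(self):
        import pandas as pd

        from chordevo.io import DOMAIN_COLUMNS

        g = _gene("g", "+", [99, 99, 99])
        g.protein_id = "g"
        ann = _ann(g)
        # domain over aa [40, 60): CDS bases [120,180) -> overlaps exon 2 only
        doms = pd.DataFrame([("g", "D1", 40, 60, 1e-9)], columns=DOMAIN_COLUMNS)
        ex = mark_domain_exons(annotate_phases(ann), ann, doms)
        assert [e.encodes_domain for e in ex] == [False, True, False]


def _shuffle_bundle(n_shuffles, seed):
    anc = sim.build_ancestor(
        sim.SimulationParams(n_genes=80, exons_per_gene=6.0, n_cne_planted=0, seed=seed)
    )
    la, log_a = sim.evolve_lineage(
        anc,
        sim.LineageParams(subst_rate=0.05, n_exon_shuffles=n_shuffles),
        seed=seed + 1,
        name="A",
    )
    lb, _ = sim.evolve_lineage(anc, sim.LineageParams(subst_rate=0.05), seed=seed + 2, name="B")
    from chordevo.orthology import OrthologyMap

    # detection quality is tested given the true gene orthology (shuffles
    # perturb donor/recipient proteins, which would otherwise confound RBH)
    omap = OrthologyMap(
        pairs=[(a, b, 100.0, 100.0) for a, b in sim.orthology_truth(la, lb)]
    )
    ex_a, ex_b = la.exon_sequences(), lb.exon_sequences()
    hits_ab = sim.hit_table(ex_a, ex_b, min_identity=50.0, kmer_prefilter=11)
    hits_ba = sim.hit_table(ex_b, ex_a, min_identity=50.0, kmer_prefilter=11)
    return anc, la, log_a, lb, omap, hits_ab, hits_ba


class TestShuffledDetection:
    def test_planted_shuffles_recovered_with_few_false_positives(self):
        anc, la, log_a, lb, omap, hits_ab, hits_ba = _shuffle_bundle(20, seed=31)
        found = detect_shuffled_exons(
            hits_ab, hits_ba, omap, la.exon_to_gene(), lb.exon_to_gene(), method="rbh"
        )
        truth = {e.data["exon_id"] for e in log_a if e.kind == "exon_shuffle"}
        hits = set(found.shuffled) & truth
        assert len(hits) >= 18
        assert len(set(found.shuffled) - truth) <= 2

    def test_no_shuffles_no_false_positives(self):
        anc, la, log_a, lb, omap, hits_ab, hits_ba = _shuffle_bundle(0, seed=37)
        found = detect_shuffled_exons(
            hits_ab, hits_ba, omap, la.exon_to_gene(), lb.exon_to_gene(), method="rbh"
        )
        assert len(found) == 0

    def test_chainnet_reports_no_more_than_rbh(self):
        anc, la, log_a, lb, omap, hits_ab, hits_ba = _shuffle_bundle(15, seed=41)
        rbh = detect_shuffled_exons(
            hits_ab, hits_ba, omap, la.exon_to_gene(), lb.exon_to_gene(), method="rbh"
        )
        ann_a, _, _, _ = la.render()
        spans = {g.gene_id: (g.seq_name, *g.span) for g in ann_a.genes}
        chain = detect_shuffled_exons(
            hits_ab, hits_ba, omap, la.exon_to_gene(), lb.exon_to_gene(),
            method="chainnet",
            blocks=sim.truth_alignment(la, lb),
            gene_spans_a=spans,
            exon_positions_b=lb.exon_positions(),
        )
        assert len(chain) <= len(rbh)
        assert set(chain.shuffled) <= set(rbh.shuffled)


class TestSubgenicDcj:
    def test_gene_level_inversions_contribute_nothing(self):
        anc = sim.build_ancestor(
            sim.SimulationParams(n_genes=50, exons_per_gene=4.0, n_cne_planted=0, seed=43)
        )
        la, _ = sim.evolve_lineage(anc, sim.LineageParams(n_inversions=6), seed=44, name="A")
        res = subgenic_dcj(la.exon_order(), anc.exon_order(), la.gene_order(), anc.gene_order())
        assert res.contribution == 0

    def test_planted_shuffles_contribute_between_k_and_2k(self):
        k = 6
        anc = sim.build_ancestor(
            sim.SimulationParams(n_genes=50, exons_per_gene=6.0, n_cne_planted=0, seed=47)
        )
        la, log_a = sim.evolve_lineage(
            anc, sim.LineageParams(n_exon_shuffles=k), seed=48, name="A"
        )
        # restrict both exon orders to exons present in both genomes
        res = subgenic_dcj(la.exon_order(), anc.exon_order(), la.gene_order(), anc.gene_order())
        assert k <= res.contribution <= 2 * k

    def test_contribution_invariant_to_marker_relabeling(self):
        a = GeneOrder.linear(["e1", "e2", "e3", "e4"])
        b = GeneOrder.linear(["e1", "e3", "e2", "e4"])
        g1 = GeneOrder.linear(["g1", "g2"])
        res = subgenic_dcj(a, b, g1, g1)
        relab = {f"e{i}": f"x{i}" for i in range(1, 5)}
        a2 = GeneOrder([("linear", [(relab[m], s) for m, s in a.chromosomes[0][1]])])
        b2 = GeneOrder([("linear", [(relab[m], s) for m, s in b.chromosomes[0][1]])])
        res2 = subgenic_dcj(a2, b2, g1, g1)
        assert res.contribution == res2.contribution


class TestPhaseBias:
    def test_identical_proportions_give_near_zero_statistic(self):
        res = shuffled_phase_bias(30, 100, 300, 1000)
        assert res.statistic < 0.2 and res.p_value > 0.5

    def test_worked_two_by_two_chi_square(self):
        # [[40,60],[28,72]]: chi-square with continuity correction, hand value
        a, b, c, d = 40, 60, 28, 72
        n = a + b + c + d
        expected_stat = (
            n * (abs(a * d - b * c) - n / 2) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        res = shuffled_phase_bias(40, 100, 28, 100)
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(expected_stat, rel=1e-9)

    def test_small_expected_counts_switch_to_fisher(self):
        res = shuffled_phase_bias(2, 4, 1, 8)
        assert res.test == "fisher"

    def test_beta_one_truth_is_all_symmetric(self, ancestor):
        _, log = sim.evolve_lineage(
            ancestor, sim.LineageParams(n_exon_shuffles=8, phase11_preference=1.0), seed=51
        )
        phases = [tuple(e.data["donor_phases"]) for e in log if e.kind == "exon_shuffle"]
        assert phases and all(p == (1, 1) for p in phases)
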