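import math

import numpy as np
import pytest

from chordevo import simulate as sim
from chordevo.models import AlignmentBlock, AlignmentBlockSet
from chordevo.popgen import (
    call_variants,
    dnds_ng86,
    effective_population_size,
    mean_dnds,
    spacing_fit,
    summarize_polymorphism,
    te_attribution,
    variant_spacings,
)


def _blocks(ref, qry, seq="chr1"):
    return AlignmentBlockSet(
        [
            AlignmentBlock(
                seq, 0, len(ref.replace("-", "")),
                seq, 0, len(qry.replace("-", "")), "+", ref, qry,
            )
        ]
    )


class TestCallVariants:
    def test_single_mismatch_is_one_snp(self):
        v = call_variants(_blocks("ACGT", "ACCT"))
        assert list(v.type) == ["snp"]
        assert v.iloc[0].change == "G>C"

    def test_gap_run_is_one_indel_of_its_length(self):
        v = call_variants(_blocks("AAAAACCCCCCCCCCGGGGG", "AAAAA----------GGGGG"))
        assert list(v.type) == ["small_indel"]
        assert v.iloc[0].length == 10

    def test_adjacent_snps_not_merged(self):
        v = call_variants(_blocks("AAAA", "ACCA"))
        assert (v.type == "snp").sum() == 2

    def test_overlapping_reference_blocks_rejected(self):
        b1 = AlignmentBlock("c", 0, 4, "c", 0, 4, "+", "ACGT", "ACGT")
        b2 = AlignmentBlock("c", 2, 6, "c", 10, 14, "+", "ACGT", "ACGT")
        with pytest.raises(ValueError, match="overlapping"):
            call_variants(AlignmentBlockSet([b1, b2]))

    def test_simulated_diploid_recall_and_precision(self, ancestor):
        _, seqs, _, _ = ancestor.render()
        _, _, truth, blocks = sim.make_diploid(
            seqs, sim.DiploidParams(seed=91, large_indel_count=4)
        )
        called = call_variants(blocks)
        t = set(map(tuple, truth[truth.type == "snp"][["seq", "ref_start"]].values))
        c = set(map(tuple, called[called.type == "snp"][["seq", "ref_start"]].values))
        assert len(t & c) / len(t) >= 0.99 and len(t & c) / len(c) >= 0.99
        ti = truth[truth.type.str.endswith("indel")]
        ci = called[called.type.str.endswith("indel")]
        ts = set(map(tuple, ti[["seq", "ref_start", "length"]].values))
        cs = set(map(tuple, ci[["seq", "ref_start", "length"]].values))
        assert len(ts & cs) / len(ts) >= 0.99 and len(ts & cs) / len(cs) >= 0.99


class TestSummary:
    def test_printed_rate_arithmetic(self):
        import pandas as pd

        variants = pd.DataFrame(
            [("snp", "c", i, i + 1, 1, "A>C") for i in range(439)],
            columns=["type", "seq", "ref_start", "ref_end", "length", "change"],
        )
        s = summarize_polymorphism(variants, aligned_length=10_000, genome_length=10_000)
        assert s.snp_rate == pytest.approx(4.39)

    def test_no_variants_all_zero(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["type", "seq", "ref_start", "ref_end", "length", "change"])
        s = summarize_polymorphism(empty, 1000, 1000)
        assert s.snp_rate == 0 and s.large_indel_count == 0

    def test_planted_rates_recovered_within_three_se(self, ancestor):
        _, seqs, _, _ = ancestor.render()
        _, _, truth, blocks = sim.make_diploid(
            seqs, sim.DiploidParams(snp_rate=0.0439, small_indel_rate=0.0098, seed=92)
        )
        called = call_variants(blocks)
        aligned = sum(
            sum(1 for x, y in zip(b.ref_text, b.query_text) if x != "-" and y != "-")
            for b in blocks
        )
        genome = sum(len(s) for s in seqs.values())
        s = summarize_polymorphism(called, aligned, genome)
        se_snp = 100 * math.sqrt(0.0439 * (1 - 0.0439) / aligned)
        assert abs(s.snp_rate - 4.39) <= 3 * se_snp
        se_ind = 100 * math.sqrt(0.0098 * (1 - 0.0098) / aligned)
        assert abs(s.small_indel_event_rate - 0.98) <= 3 * se_ind


class TestSpacing:
    def test_every_site_variant_gives_p_one(self):
        fit = spacing_fit(np.zeros(200, dtype=int))
        assert fit.p_hat == 1.0

    def test_geometric_mle_recovered_and_fit_accepted(self):
        rng = np.random.default_rng(5)
        p = 0.05
        gaps = rng.geometric(p, 10_000) - 1  # zero-based support
        fit = spacing_fit(gaps)
        se = math.sqrt(p**2 * (1 - p) / len(gaps))
        assert abs(fit.p_hat - p) <= 3 * se
        assert fit.p_value > 0.01

    def test_clustered_alternative_rejected_with_power(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            # mixture: clustered variants (tiny gaps) plus long background gaps
            gaps = np.concatenate(
                [rng.geometric(0.5, 5000) - 1, rng.geometric(0.005, 5000) - 1]
            )
            fit = spacing_fit(gaps)
            rejections += fit.p_value < 0.01
        assert rejections / n_rep >= 0.9

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            spacing_fit(np.arange(50))

    def test_spacings_from_variant_table(self):
        import pandas as pd

        variants = pd.DataFrame(
            [("snp", "c", p, p + 1, 1, "A>C") for p in (10, 12, 20)],
            columns=["type", "seq", "ref_start", "ref_end", "length", "change"],
        )
        assert list(variant_spacings(variants)) == [1, 7]


class TestNg86:
    def test_identical_sequences_zero(self):
        r = dnds_ng86("ATGAAAGCT", "ATGAAAGCT")
        assert r.dn == 0 and r.ds == 0

    def test_synonymous_only_worked_example(self):
        # AAA->AAG (Lys, syn) and TTT->TTC (Phe, syn): dN = 0, dS > 0
        r = dnds_ng86("ATGAAAGCTTTTGGG", "ATGAAGGCTTTCGGG")
        assert r.dn == 0.0
        assert r.ds > 0

    def test_hand_counted_site_classes(self):
        # codon TTT (Phe): only third-position T->C is synonymous -> S = 1/3
        from chordevo.popgen import _codon_sites, _codon_table

        s, n = _codon_sites("TTT", _codon_table())
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)
        # CTG (Leu): third position fully synonymous + T->C at first (TTG Leu)
        s, n = _codon_sites("CTG", _codon_table())
        assert s == pytest.approx(1 + 1 / 3)

    def test_internal_stop_rejected_and_skipped_in_mean(self):
        with pytest.raises(ValueError, match="stop"):
            dnds_ng86("TAAAAA", "TAAAAA")
        with pytest.warns(UserWarning, match="skipped"):
            dn, ds, omega = mean_dnds(
                [("TAAAAA", "TAAAAA"), ("ATGAAAGCTTTTGGG", "ATGAAGGCTTTCGGG")]
            )
        assert dn == 0.0

    def test_synonymous_only_simulation_gives_zero_dn(self):
        rng = np.random.default_rng(7)
        from chordevo.popgen import _codon_table

        table = _codon_table()
        codons = [c for c in table if table[c] not in "*M"]
        a = [codons[i] for i in rng.integers(0, len(codons), 2000)]
        b = []
        for c in a:
            syn = [
                c[:p] + x + c[p + 1:]
                for p in range(3)
                for x in "ACGT"
                if x != c[p] and table[c[:p] + x + c[p + 1:]] == table[c]
            ]
            b.append(syn[rng.integers(0, len(syn))] if syn and rng.random() < 0.2 else c)
        r = dnds_ng86("".join(a), "".join(b))
        assert r.dn == pytest.approx(0.0, abs=1e-12)
        assert r.ds > 0.05

    def test_neutral_simulation_ratio_near_one(self):
        rng = np.random.default_rng(8)
        n_codons = 10_000
        a = sim._random_codons(rng, n_codons)
        arr = np.array(list(a))
        flip = rng.random(len(arr)) < 0.08
        bases = np.array(list("ACGT"))
        arr[flip] = bases[
            (np.searchsorted(bases, arr[flip]) + rng.integers(1, 4, flip.sum())) % 4
        ]
        b = "".join(arr)
        # drop codons that became stops
        from chordevo.popgen import _codon_table

        table = _codon_table()
        keep_a, keep_b = [], []
        for i in range(n_codons):
            ca, cb = a[3 * i: 3 * i + 3], b[3 * i: 3 * i + 3]
            if table[cb] != "*":
                keep_a.append(ca)
                keep_b.append(cb)
        r = dnds_ng86("".join(keep_a), "".join(keep_b))
        assert r.omega == pytest.approx(1.0, abs=0.1)


class TestNe:
    def test_arithmetic(self):
        assert effective_population_size(0.04, 1e-8) == pytest.approx(1.0e6)
        assert effective_population_size(0.0537, 1e-8) == pytest.approx(1.3425e6)

    def test_inverse_linear_in_mu(self):
        ne1 = effective_population_size(0.05, 1e-8)
        ne2 = effective_population_size(0.05, 1e-9)
        assert ne2 == pytest.approx(10 * ne1)

    def test_linear_in_pi(self):
        assert effective_population_size(0.08, 1e-8) == pytest.approx(
            2 * effective_population_size(0.04, 1e-8)
        )

    def test_non_positive_inputs_rejected(self):
        for bad in [(0, 1e-8, 1), (0.05, 0, 1), (0.05, 1e-8, 0)]:
            with pytest.raises(ValueError):
                effective_population_size(*bad)


class TestTeAttribution:
    def test_no_annotation_gives_zero(self):
        import pandas as pd

        variants = pd.DataFrame(
            [("large_indel", "c", 100, 500, 400, "del")],
            columns=["type", "seq", "ref_start", "ref_end", "length", "change"],
        )
        assert te_attribution(variants, []) == 0.0

    def test_indel_inside_te_attributed(self):
        import pandas as pd

        variants = pd.DataFrame(
            [
                ("large_indel", "c", 100, 500, 400, "del"),
                ("large_indel", "c", 5000, 5400, 400, "del"),
            ],
            columns=["type", "seq", "ref_start", "ref_end", "length", "change"],
        )
        assert te_attribution(variants, [("c", 0, 600)]) == pytest.approx(0.5)

    def test_planted_fraction_recovered(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        rows, tes = [], []
        n = 300
        for i in range(n):
            pos = 10_000 * i
            inside = rng.random() < 0.7
            if inside:
                tes.append(("c", pos - 100, pos + 600))
            rows.append(("large_indel", "c", pos, pos + 400, 400, "del"))
        variants = pd.DataFrame(
            rows, columns=["type", "seq", "ref_start", "ref_end", "length", "change"]
        )
        frac = te_attribution(variants, tes)
        se = math.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) <= 3 * se
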