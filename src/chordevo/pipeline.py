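"""End-to-end synthetic study driver: simulate -> orthology -> rates ->
exon/domain/CNE/polymorphism summaries -> JSON report.

Every stage is a pure function of the configuration and seed; the report
carries the configuration so a run can be reproduced exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict

import numpy as np

from . import cne as cne_mod
from . import domains as dom_mod
from . import exons as exon_mod
from . import orthology as orth_mod
from . import popgen as pop_mod
from . import profiles as prof_mod
from . import rearrangement as rea_mod
from . import simulate as sim_mod

log = logging.getLogger("chordevo")

DEFAULT_CONFIG = {
    "ancestor": {"n_genes": 120, "exons_per_gene": 5.0, "n_cne_planted": 60},
    "lineage_a": {"subst_rate": 0.05, "n_inversions": 8, "n_translocations": 2,
                  "n_exon_shuffles": 10, "phase11_preference": 0.6,
                  "domain_pair_gain": 10, "domain_pair_loss": 3},
    "lineage_b": {"subst_rate": 0.05, "n_inversions": 8, "n_translocations": 2,
                  "n_exon_shuffles": 10, "phase11_preference": 0.6,
                  "domain_pair_gain": 10, "domain_pair_loss": 3},
    "diploid": {"snp_rate": 0.0439, "small_indel_rate": 0.0098},
    "divergence_time_myr": 120.0,
}


def _merged(config: dict | None) -> dict:
    """Provided sections replace the default section wholesale; parameters
    left out of a provided section take their dataclass defaults."""
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    out.update(config or {})
    return out


def run_pipeline(config: dict | None = None, seed: int = 0, out_dir: str | None = None) -> dict:
    """Run the full synthetic study; returns (and optionally writes) the
    report dictionary."""
    cfg = _merged(config)
    t0 = time.time()
    report: dict = {"seed": seed, "config": cfg}

    log.info("stage: simulate")
    anc = sim_mod.build_ancestor(sim_mod.SimulationParams(seed=seed, **cfg["ancestor"]))
    la, log_a = sim_mod.evolve_lineage(
        anc, sim_mod.LineageParams(**cfg["lineage_a"]), seed=seed + 1, name="lineage_a"
    )
    lb, log_b = sim_mod.evolve_lineage(
        anc, sim_mod.LineageParams(**cfg["lineage_b"]), seed=seed + 2, name="lineage_b"
    )

    log.info("stage: orthology")
    prots_a, prots_b = la.proteins(), lb.proteins()
    hits_ab = sim_mod.hit_table(prots_a, prots_b)
    hits_ba = sim_mod.hit_table(prots_b, prots_a)
    p2g_a = {p: p[:-3] for p in prots_a}
    p2g_b = {p: p[:-3] for p in prots_b}
    orthology = orth_mod.rbh_orthologs(
        hits_ab, hits_ba, p2g_a, p2g_b,
        protein_lengths_a={p: len(s) for p, s in prots_a.items()},
        protein_lengths_b={p: len(s) for p, s in prots_b.items()},
    )
    report["orthology"] = {
        "n_pairs": len(orthology),
        "truth_pairs": len(sim_mod.orthology_truth(la, lb)),
        "mean_identity": float(np.mean([p[2] for p in orthology.pairs])) if orthology.pairs else None,
    }

    log.info("stage: rearrangement rates")
    dist = [
        orth_mod.protein_distance(prots_a[a + ".p1"], prots_b[b + ".p1"]).poisson_distance
        for a, b, *_ in orthology.pairs
        if len(prots_a[a + ".p1"]) == len(prots_b[b + ".p1"])
    ]
    protein_dist = float(np.mean(dist)) if dist else float("nan")
    dcj = rea_mod.dcj_distance(la.gene_order(), lb.gene_order())
    r, per_time = rea_mod.relative_rates(dcj, protein_dist, cfg["divergence_time_myr"])
    report["rearrangement"] = {
        "dcj_distance": dcj.d,
        "n_shared_markers": dcj.n_markers,
        "per_marker_rate": dcj.per_marker_rate,
        "protein_distance": protein_dist,
        "relative_rate": r,
        "per_myr_rate": per_time,
    }

    log.info("stage: exon phases")
    ann_a, seqs_a, doms_a, cnes_a = la.render()
    ann_b, seqs_b, doms_b, cnes_b = lb.render()
    phased = exon_mod.annotate_phases(ann_a)
    spectrum = exon_mod.phase_spectrum(phased, min_len_bp=100)
    report["exon_phases"] = {
        "n_internal_gt100bp": spectrum.n,
        "prop_0_0": spectrum.proportion((0, 0)),
        "prop_1_1": spectrum.proportion((1, 1)),
        "prop_2_2": spectrum.proportion((2, 2)),
        "n_shuffles_planted": log_a.count("exon_shuffle") + log_b.count("exon_shuffle"),
    }

    log.info("stage: domain pairs")
    arch_a = dom_mod.resolve_architecture(doms_a)
    arch_b = dom_mod.resolve_architecture(doms_b)
    matrix = dom_mod.pair_matrix({"lineage_a": arch_a, "lineage_b": arch_b})
    import dendropy

    tree = dendropy.Tree.get(
        data="(lineage_a,lineage_b);", schema="newick", preserve_underscores=True
    )
    gains = dom_mod.dollo_gains(matrix, tree)
    rates = dom_mod.gain_rate(
        gains, {b: cfg["divergence_time_myr"] for b in gains.gains}
    )
    report["domain_pairs"] = {
        "total_pairs": len(matrix.all_pairs),
        "gains_per_branch": gains.gains,
        "gain_rate_per_myr": rates,
    }

    log.info("stage: CNE")
    blocks = sim_mod.truth_alignment(la, lb)
    coarse = cne_mod.coarse_cnes(blocks, ann_a)
    refined, summary = cne_mod.refine_cnes(coarse, ann_a)
    report["cne"] = {
        "n_planted": len(cnes_a),
        "coarse": len(coarse),
        "refined": summary.refined_count,
        "refined_percent": summary.refined_percent,
        "average_length": summary.average_length,
    }

    log.info("stage: polymorphism")
    hap_a, hap_b, truth, dip_blocks = sim_mod.make_diploid(
        seqs_a, sim_mod.DiploidParams(seed=seed + 3, **cfg["diploid"])
    )
    variants = pop_mod.call_variants(dip_blocks)
    aligned = sum(
        sum(1 for x, y in zip(b.ref_text, b.query_text) if x != "-" and y != "-")
        for b in dip_blocks
    )
    summary_p = pop_mod.summarize_polymorphism(variants, aligned, sum(len(s) for s in hap_a.values()))
    pi = (summary_p.snp_rate + summary_p.small_indel_event_rate) / 100.0
    report["polymorphism"] = {
        "snp_rate_percent": summary_p.snp_rate,
        "small_indel_event_rate_percent": summary_p.small_indel_event_rate,
        "ne_at_mu_1e8": (
            pop_mod.effective_population_size(pi, 1e-8) if pi > 0 else None
        ),
    }

    report["runtime_s"] = round(time.time() - t0, 2)
    payload = json.dumps(report, indent=1, sort_keys=True, default=float)
    report["checksum"] = hashlib.sha256(
        json.dumps({k: v for k, v in report.items() if k != "runtime_s"},
                   sort_keys=True, default=float).encode()
    ).hexdigest()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(json.dumps(report, indent=1, sort_keys=True, default=float))
    return report
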