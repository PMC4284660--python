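import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chordevo import simulate as sim


@pytest.fixture(scope="session")
def ancestor():
    return sim.build_ancestor(sim.SimulationParams(n_genes=60, n_cne_planted=30, seed=11))


@pytest.fixture(scope="session")
def lineage_pair(ancestor):
    la, log_a = sim.evolve_lineage(
        ancestor, sim.LineageParams(subst_rate=0.05), seed=21, name="lineage_a"
    )
    lb, log_b = sim.evolve_lineage(
        ancestor, sim.LineageParams(subst_rate=0.05), seed=22, name="lineage_b"
    )
    return la, log_a, lb, log_b


@pytest.fixture(scope="session")
def orthology_bundle(lineage_pair):
    from chordevo import orthology as orth

    la, _, lb, _ = lineage_pair
    pa, pb = la.proteins(), lb.proteins()
    hits_ab = sim.hit_table(pa, pb)
    hits_ba = sim.hit_table(pb, pa)
    omap = orth.rbh_orthologs(
        hits_ab,
        hits_ba,
        {p: p[:-3] for p in pa},
        {p: p[:-3] for p in pb},
        protein_lengths_a={p: len(s) for p, s in pa.items()},
        protein_lengths_b={p: len(s) for p, s in pb.items()},
    )
    return omap, hits_ab, hits_ba, pa, pb
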