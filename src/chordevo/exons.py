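"""Intron phases, phase-combination spectra, shuffled-exon detection and
subgenic (exon-level) DCJ rates.

The phase of an intron is the position at which it interrupts a codon
(0, 1 or 2), computed as the cumulative CDS length modulo 3 at the exon
boundary, in translation order. A symmetric exon has equal upstream and
downstream phases; 1-1 exons can move between phase-1 introns without
breaking the reading frame, which is why exon shuffling concentrates on
them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GenomeAnnotation
from .orthology import OrthologyMap
from .rearrangement import DcjResult, GeneOrder, dcj_distance

PHASE_CLASSES = [(i, j) for i in range(3) for j in range(3)]


@dataclass
class PhasedExon:
    gene_id: str
    exon_index: int  # 0-based, translation order
    cds_len: int
    phase5: int | None  # upstream phase; None if no upstream intron
    phase3: int | None
    is_internal: bool
    encodes_domain: bool = False

    @property
    def phase_class(self) -> tuple[int, int] | None:
        if self.phase5 is None or self.phase3 is None:
            return None
        return (self.phase5, self.phase3)


def annotate_phases(annotation: GenomeAnnotation) -> list[PhasedExon]:
    """Compute intron phases for every coding exon, 5'->3' in translation
    order. Genes flagged complete whose CDS length is not a multiple of 3
    are excluded with a warning.
    """
    out: list[PhasedExon] = []
    for gene in annotation.genes:
        if not gene.cds:
            continue
        if gene.complete and gene.cds_length % 3 != 0:
            warnings.warn(
                f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3; excluded"
            )
            continue
        pieces = gene.cds_in_translation_order()
        lengths = [b - a for a, b in pieces]
        n = len(lengths)
        cum = np.cumsum(lengths)
        for i, length in enumerate(lengths):
            p5 = int(cum[i - 1] % 3) if i > 0 else None
            p3 = int(cum[i] % 3) if i < n - 1 else None
            out.append(
                PhasedExon(
                    gene_id=gene.gene_id,
                    exon_index=i,
                    cds_len=length,
                    phase5=p5,
                    phase3=p3,
                    is_internal=(0 < i < n - 1),
                )
            )
    return out


def mark_domain_exons(
    exons: Sequence[PhasedExon], annotation: GenomeAnnotation, domains: pd.DataFrame
) -> list[PhasedExon]:
    """Flag exons overlapping >=1 protein-domain interval projected onto the
    CDS (codon-exact: aa interval [a,b) covers CDS bases [3a, 3b))."""
    dom_by_protein: dict[str, list[tuple[int, int]]] = {}
    for _, row in domains.iterrows():
        dom_by_protein.setdefault(row.protein_id, []).append(
            (3 * int(row.env_start), 3 * int(row.env_end))
        )
    gene_domains = {
        g.gene_id: dom_by_protein.get(g.protein_id, []) for g in annotation.genes
    }
    offsets: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes:
        pieces = g.cds_in_translation_order()
        cds_offsets = []
        off = 0
        for a, b in pieces:
            cds_offsets.append((off, off + (b - a)))
            off += b - a
        offsets[g.gene_id] = cds_offsets
    flagged = []
    for ex in exons:
        ivs = offsets.get(ex.gene_id)
        doms = gene_domains.get(ex.gene_id, [])
        enc = False
        if ivs and ex.exon_index < len(ivs):
            lo, hi = ivs[ex.exon_index]
            enc = any(lo < db and da < hi for da, db in doms)
        flagged.append(
            PhasedExon(
                ex.gene_id, ex.exon_index, ex.cds_len, ex.phase5, ex.phase3,
                ex.is_internal, encodes_domain=enc,
            )
        )
    return flagged


@dataclass
class PhaseSpectrum:
    counts: dict[tuple[int, int], int]
    subset: str = "all_internal"

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[tuple[int, int], float]:
        n = self.n
        return {k: v / n for k, v in self.counts.items()}

    def proportion(self, phase_class: tuple[int, int]) -> float:
        return self.counts.get(phase_class, 0) / self.n

    def symmetric_summary(self, confidence: float = 0.95) -> pd.DataFrame:
        """Proportions of the symmetric classes with binomial CIs."""
        rows = []
        for cls in [(0, 0), (1, 1), (2, 2)]:
            k = self.counts.get(cls, 0)
            ci = stats.binomtest(k, self.n).proportion_ci(confidence_level=confidence)
            rows.append((f"{cls[0]}-{cls[1]}", k, k / self.n, ci.low, ci.high))
        return pd.DataFrame(rows, columns=["class", "count", "proportion", "ci_low", "ci_high"])


def phase_spectrum(
    exons: Sequence[PhasedExon],
    min_len_bp: int = 100,
    subset: str = "all_internal",
) -> PhaseSpectrum:
    """Counts of the 9 phase combinations over internal exons longer than
    ``min_len_bp``. ``subset`` selects 'all_internal' or 'domain'."""
    counts = {cls: 0 for cls in PHASE_CLASSES}
    for ex in exons:
        if not ex.is_internal or ex.cds_len <= min_len_bp:
            continue
        if subset == "domain" and not ex.encodes_domain:
            continue
        cls = ex.phase_class
        if cls is not None:
            counts[cls] += 1
    if sum(counts.values()) == 0:
        raise ValueError(f"no internal exons in subset {subset!r} above {min_len_bp} bp")
    return PhaseSpectrum(counts=counts, subset=subset)


@dataclass
class ShuffledExonSet:
    shuffled: dict[str, str]  # exon id -> counterpart exon id
    method: str
    counterpart_gene: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.shuffled)


def _exon_rbh(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame, min_identity: float) -> dict[str, str]:
    def best(hits: pd.DataFrame) -> dict[str, str]:
        out: dict[str, str] = {}
        for _, row in hits.sort_values(
            ["query_id", "bitscore", "subject_id"], ascending=[True, False, True]
        ).iterrows():
            if row.percent_identity < min_identity:
                continue
            out.setdefault(row.query_id, row.subject_id)
        return out

    fwd, rev = best(hits_ab), best(hits_ba)
    return {a: b for a, b in fwd.items() if rev.get(b) == a}


def detect_shuffled_exons(
    exon_hits_ab: pd.DataFrame,
    exon_hits_ba: pd.DataFrame,
    orthology: OrthologyMap,
    exon_to_gene_a: Mapping[str, str],
    exon_to_gene_b: Mapping[str, str],
    method: str = "rbh",
    min_identity: float = 60.0,
    blocks=None,
    gene_spans_a: Mapping[str, tuple[str, int, int]] | None = None,
    exon_positions_b: Mapping[str, tuple[str, int, int]] | None = None,
) -> ShuffledExonSet:
    """Flag exons whose reciprocal-best counterpart lies outside the
    orthologue of their own gene.

    rbh mode: an exon is shuffled iff its reciprocal-best exon belongs to a
    gene that is not the orthologue of the exon's gene (or is unpaired).
    chainnet mode additionally requires the counterpart to fall outside the
    syntenic block chain covering the exon's gene, which reports fewer but
    higher-confidence calls; it needs ``blocks`` plus gene/exon coordinates.
    """
    if not orthology.pairs and orthology.unpaired_a == set() and orthology.unpaired_b == set():
        raise ValueError("gene orthology required")
    ortho = orthology.as_dict()
    rbh_pairs = _exon_rbh(exon_hits_ab, exon_hits_ba, min_identity)
    shuffled: dict[str, str] = {}
    counterpart_gene: dict[str, str] = {}
    for ea, eb in sorted(rbh_pairs.items()):
        ga = exon_to_gene_a.get(ea)
        gb = exon_to_gene_b.get(eb)
        if ga is None or gb is None:
            raise ValueError(f"exon without gene mapping: {ea if ga is None else eb}")
        expected = ortho.get(ga)
        if expected is not None and gb == expected:
            continue
        shuffled[ea] = eb
        counterpart_gene[ea] = gb
    if method == "rbh":
        return ShuffledExonSet(shuffled=shuffled, method="rbh", counterpart_gene=counterpart_gene)
    if method != "chainnet":
        raise ValueError(f"unknown method {method!r}")
    if blocks is None or gene_spans_a is None or exon_positions_b is None:
        raise ValueError("chainnet mode needs blocks, gene_spans_a and exon_positions_b")
    # syntenic chain of a gene: query intervals of blocks overlapping it
    confirmed: dict[str, str] = {}
    for ea, eb in shuffled.items():
        ga = exon_to_gene_a[ea]
        span = gene_spans_a.get(ga)
        target = exon_positions_b.get(eb)
        if span is None or target is None:
            continue
        seq_a, lo, hi = span
        chain_q: list[tuple[str, int, int]] = [
            (b.query_seq, b.query_start, b.query_end)
            for b in blocks
            if b.ref_seq == seq_a and b.ref_start < hi and lo < b.ref_end
        ]
        seq_b, s, e = target
        inside = any(qs == seq_b and s < qe and qs_ < e for qs, qs_, qe in chain_q)
        if not inside:
            confirmed[ea] = eb
    return ShuffledExonSet(
        shuffled=confirmed,
        method="chainnet",
        counterpart_gene={e: counterpart_gene[e] for e in confirmed},
    )


@dataclass
class SubgenicDcj:
    exon_level: DcjResult
    gene_level: DcjResult
    contribution: int  # floored at 0
    contribution_raw: int


def subgenic_dcj(
    exon_order_a: GeneOrder,
    exon_order_b: GeneOrder,
    gene_order_a: GeneOrder,
    gene_order_b: GeneOrder,
) -> SubgenicDcj:
    """Exon-level DCJ distance minus gene-level distance: the rearrangement
    attributable to subgenic (exon) shuffling."""
    d_exon = dcj_distance(exon_order_a, exon_order_b)
    d_gene = dcj_distance(gene_order_a, gene_order_b)
    raw = d_exon.d - d_gene.d
    return SubgenicDcj(
        exon_level=d_exon,
        gene_level=d_gene,
        contribution=max(0, raw),
        contribution_raw=raw,
    )


@dataclass
class PhaseBias:
    prop_shuffled: float
    prop_background: float
    statistic: float
    p_value: float
    test: str  # 'chi2' or 'fisher'


def shuffled_phase_bias(
    n11_shuffled: int,
    n_shuffled: int,
    n11_background: int,
    n_background: int,
) -> PhaseBias:
    """Compare the 1-1 proportion of shuffled exons against the background.

    Uses a 2x2 chi-square with continuity correction, switching to Fisher's
    exact test when an expected cell count is below 5.
    """
    if n_shuffled == 0 or n_background == 0:
        raise ValueError("both exon sets must be non-empty")
    table = np.array(
        [
            [n11_shuffled, n_shuffled - n11_shuffled],
            [n11_background, n_background - n11_background],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        test = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
        test = "chi2"
    return PhaseBias(
        prop_shuffled=n11_shuffled / n_shuffled,
        prop_background=n11_background / n_background,
        statistic=float(stat),
        p_value=float(p),
        test=test,
    )
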