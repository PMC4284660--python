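"""Reciprocal-best-hit orthology, protein distances and diversity clustering.

Orthologue assignment follows a gene-level reciprocal best hit: every
isoform is searched, the best-scoring isoform pair represents the gene pair,
alignment segments between the two genes are concatenated (overlaps resolved
best-bitscore-first), and a pair is accepted only if each gene is the
other's best gene-level hit and the concatenated alignment passes the
identity and coverage cutoffs (defaults 60% identity, 40% coverage).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class OrthologyMap:
    """1:1 orthologue pairs (gene_a, gene_b, identity %, coverage %)."""

    pairs: list[tuple[str, str, float, float]]
    unpaired_a: set[str] = field(default_factory=set)
    unpaired_b: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, str]:
        return {a: b for a, b, *_ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ProteinDistance:
    p_distance: float
    poisson_distance: float
    n_sites: int


def _gene_level_hits(hits: pd.DataFrame, protein_to_gene_q: Mapping, protein_to_gene_s: Mapping,
                     protein_lengths_q: Mapping | None) -> pd.DataFrame:
    """Collapse protein-level hits to gene-level rows.

    For each gene pair, the best isoform pair (by total bitscore) represents
    the genes; its segments are concatenated with overlaps on the query
    resolved best-bitscore-first. Returns columns gene_q, gene_s, identity,
    coverage, bitscore.
    """
    df = hits.copy()
    missing_q = set(df.query_id) - set(protein_to_gene_q)
    missing_s = set(df.subject_id) - set(protein_to_gene_s)
    if missing_q or missing_s:
        some = sorted(missing_q | missing_s)[:3]
        raise ValueError(f"protein ids not mappable to genes: {some}")
    df["gene_q"] = df.query_id.map(protein_to_gene_q)
    df["gene_s"] = df.subject_id.map(protein_to_gene_s)

    out = []
    for (gq, gs), sub in df.groupby(["gene_q", "gene_s"], sort=True):
        iso_scores = sub.groupby(["query_id", "subject_id"]).bitscore.sum()
        best_q, best_s = iso_scores.idxmax()
        seg = sub[(sub.query_id == best_q) & (sub.subject_id == best_s)]
        seg = seg.sort_values("bitscore", ascending=False)
        covered: list[tuple[int, int]] = []
        total_len = 0
        weighted_ident = 0.0
        bitscore = 0.0
        for _, row in seg.iterrows():
            a, b = int(min(row.q_start, row.q_end)) - 1, int(max(row.q_start, row.q_end))
            for ca, cb in covered:
                if a < cb and ca < b:  # clip overlap against better segments
                    if a >= ca and b <= cb:
                        a = b = 0
                        break
                    if a < ca:
                        b = min(b, ca)
                    else:
                        a = max(a, cb)
            if b <= a:
                continue
            covered.append((a, b))
            seg_len = b - a
            total_len += seg_len
            weighted_ident += row.percent_identity * seg_len
            bitscore += row.bitscore
        if total_len == 0:
            continue
        qlen = None
        if protein_lengths_q is not None:
            qlen = protein_lengths_q.get(best_q)
        coverage = 100.0 * total_len / qlen if qlen else 100.0
        out.append((gq, gs, weighted_ident / total_len, min(coverage, 100.0), bitscore))
    return pd.DataFrame(out, columns=["gene_q", "gene_s", "identity", "coverage", "bitscore"])


def rbh_orthologs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    protein_to_gene_a: Mapping[str, str],
    protein_to_gene_b: Mapping[str, str],
    min_identity: float = 60.0,
    min_coverage: float = 40.0,
    protein_lengths_a: Mapping[str, int] | None = None,
    protein_lengths_b: Mapping[str, int] | None = None,
) -> OrthologyMap:
    """Gene-level reciprocal best hits with identity/coverage cutoffs.

    Ties for the best hit are broken by bitscore then lexicographic subject
    gene id. Coverage, when protein lengths are supplied, is the
    concatenated aligned length over the length of the aligned isoform; a
    pair must pass the cutoffs in both search directions.
    """
    gl_ab = _gene_level_hits(hits_ab, protein_to_gene_a, protein_to_gene_b, protein_lengths_a)
    gl_ba = _gene_level_hits(hits_ba, protein_to_gene_b, protein_to_gene_a, protein_lengths_b)

    def best_map(gl: pd.DataFrame) -> dict[str, tuple[str, float, float]]:
        best: dict[str, tuple] = {}
        for _, row in gl.sort_values(
            ["gene_q", "bitscore", "gene_s"], ascending=[True, False, True]
        ).iterrows():
            if row.gene_q not in best:
                best[row.gene_q] = (row.gene_s, row.identity, row.coverage)
        return best

    best_ab, best_ba = best_map(gl_ab), best_map(gl_ba)
    pairs = []
    for ga, (gb, ident_ab, cov_ab) in sorted(best_ab.items()):
        back = best_ba.get(gb)
        if back is None or back[0] != ga:
            continue
        _, ident_ba, cov_ba = back
        identity = (ident_ab + ident_ba) / 2.0
        coverage = min(cov_ab, cov_ba)
        if ident_ab < min_identity or ident_ba < min_identity:
            continue
        if cov_ab < min_coverage or cov_ba < min_coverage:
            continue
        pairs.append((ga, gb, round(identity, 3), round(coverage, 3)))
    genes_a = set(protein_to_gene_a.values())
    genes_b = set(protein_to_gene_b.values())
    paired_a = {a for a, *_ in pairs}
    paired_b = {b for _, b, *_ in pairs}
    return OrthologyMap(
        pairs=pairs,
        unpaired_a=genes_a - paired_a,
        unpaired_b=genes_b - paired_b,
    )


def protein_distance(seq_a: str, seq_b: str, column_mask=None) -> ProteinDistance:
    """p-distance and Poisson-corrected distance over comparable columns.

    Columns containing a gap are excluded; an optional boolean column mask
    restricts the comparison to externally defined conserved sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = mism = 0
    for i, (x, y) in enumerate(zip(seq_a.upper(), seq_b.upper())):
        if column_mask is not None and not column_mask[i]:
            continue
        if x == "-" or y == "-":
            continue
        n += 1
        if x != y:
            mism += 1
    if n == 0:
        raise ValueError("no comparable columns")
    p = mism / n
    if p >= 1.0:
        raise ValueError("p-distance saturated (p >= 1)")
    return ProteinDistance(p_distance=p, poisson_distance=-math.log(1.0 - p), n_sites=n)


def cumulative_distance_curve(distances) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of pairwise distances: (sorted distances, F values)."""
    d = np.sort(np.asarray([getattr(x, "poisson_distance", x) for x in distances], dtype=float))
    if len(d) == 0:
        raise ValueError("need at least one orthologous pair")
    f = np.arange(1, len(d) + 1) / len(d)
    return d, f


def family_divergence_summary(
    families: Mapping[str, str], orthology: OrthologyMap
) -> pd.DataFrame:
    """Per-family mean identity, 1:1 orthologue count, species-specific counts."""
    import warnings

    pair_ident = {(a, b): ident for a, b, ident, _ in orthology.pairs}
    paired_a = {a for a, _ in pair_ident}
    paired_b = {b for _, b in pair_ident}
    fam_genes: dict[str, list[str]] = {}
    for gene, fam in families.items():
        fam_genes.setdefault(fam, []).append(gene)
    rows = []
    for fam, genes in sorted(fam_genes.items()):
        if not genes:
            warnings.warn(f"family {fam} is empty; skipped")
            continue
        idents = [pair_ident[(a, b)] for (a, b) in pair_ident if a in genes and b in genes]
        n_pairs = len(idents)
        specific = [
            g for g in genes if g not in paired_a and g not in paired_b
        ]
        rows.append(
            (
                fam,
                float(np.mean(idents)) if idents else np.nan,
                n_pairs,
                len(specific),
            )
        )
    return pd.DataFrame(rows, columns=["family", "mean_identity", "n_orthologues", "n_species_specific"])


@dataclass
class DiversityClustering:
    clusters: list[set[str]]
    thresholds: tuple[float, float]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_diversity(
    sequence_ids,
    hits: pd.DataFrame,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
    lengths: Mapping[str, int] | None = None,
) -> DiversityClustering:
    """Single-linkage clustering over similarity edges (blastclust-style).

    An edge joins two sequences when a hit passes both thresholds in both
    orientations; diversity is the number of connected components.
    """
    ids = list(sequence_ids)
    directed_ok: set[tuple[str, str]] = set()
    for _, row in hits.iterrows():
        if row.percent_identity < min_identity:
            continue
        if lengths is not None:
            qlen = lengths.get(row.query_id)
            if qlen and 100.0 * row.alignment_length / qlen < min_coverage:
                continue
        directed_ok.add((row.query_id, row.subject_id))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in directed_ok:
        if a == b:
            continue
        if (b, a) in directed_ok and a in g and b in g:
            g.add_edge(a, b)
    clusters = [set(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: sorted(c)[0])
    return DiversityClustering(clusters=clusters, thresholds=(min_identity, min_coverage))
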