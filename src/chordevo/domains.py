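"""Domain-combination turnover: pair extraction, Dollo gains per branch,
promiscuity ranking and presence-absence trees.

A domain pair is an unordered combination of two domain types found in one
protein architecture -- either consecutive (adjacent mode, the default) or
anywhere in the same protein (cooccur mode). Under Dollo parsimony each pair
arises exactly once, on the branch above the last common ancestor of the
species that possess it, and is lost parsimoniously below.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

Pair = frozenset


def resolve_architecture(domains: pd.DataFrame) -> dict[str, list[str]]:
    """Ordered N->C domain types per protein, overlaps resolved greedily by
    e-value (better hits keep their interval)."""
    out: dict[str, list[str]] = {}
    for pid, sub in domains.groupby("protein_id"):
        kept: list[tuple[int, int, str]] = []
        for _, row in sub.sort_values(["e_value", "env_start"]).iterrows():
            a, b = int(row.env_start), int(row.env_end)
            if any(a < kb and ka < b for ka, kb, _ in kept):
                continue
            kept.append((a, b, row.domain_type))
        kept.sort()
        out[pid] = [t for _, _, t in kept]
    return out


def extract_pairs(
    architectures: Mapping[str, list[str]],
    mode: str = "adjacent",
    include_self_pairs: bool = False,
) -> set[Pair]:
    """Unordered domain-type pairs present in a set of architectures."""
    pairs: set[Pair] = set()
    for _pid, arch in architectures.items():
        if mode == "adjacent":
            cands = zip(arch, arch[1:])
        elif mode == "cooccur":
            cands = ((a, b) for i, a in enumerate(arch) for b in arch[i + 1:])
        else:
            raise ValueError(f"unknown pair mode {mode!r}")
        for a, b in cands:
            if a == b and not include_self_pairs:
                continue
            pairs.add(frozenset({a, b}))
    return pairs


@dataclass
class PairMatrix:
    """Species x domain-pair presence/absence."""

    presence: dict[str, set[Pair]]  # species -> pairs
    mode: str = "adjacent"

    @property
    def all_pairs(self) -> set[Pair]:
        out: set[Pair] = set()
        for pairs in self.presence.values():
            out |= pairs
        return out

    def vocabulary_split(self, lineage_specific_types: set[str]) -> tuple[set[Pair], set[Pair]]:
        """Split pairs into (containing a lineage-specific type, ancient-only)."""
        specific = {p for p in self.all_pairs if p & lineage_specific_types}
        return specific, self.all_pairs - specific

    def to_frame(self) -> pd.DataFrame:
        pairs = sorted(self.all_pairs, key=lambda p: tuple(sorted(p)))
        cols = ["|".join(sorted(p)) for p in pairs]
        data = {
            sp: [p in have for p in pairs] for sp, have in self.presence.items()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=cols).astype(int)


def pair_matrix(per_species_architectures: Mapping[str, Mapping[str, list[str]]], mode: str = "adjacent") -> PairMatrix:
    return PairMatrix(
        presence={
            sp: extract_pairs(arch, mode=mode)
            for sp, arch in per_species_architectures.items()
        },
        mode=mode,
    )


@dataclass
class BranchGains:
    gains: dict[str, int]  # branch (child-node label) -> pairs gained
    losses: dict[str, int]
    pair_origin: dict[str, str] = field(default_factory=dict)  # pair label -> branch

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())


def _label_nodes(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.label = node.taxon.label
        elif not node.label:
            leaves = sorted(l.taxon.label for l in node.leaf_iter())
            node.label = "+".join(leaves)


def dollo_gains(matrix: PairMatrix, tree: dendropy.Tree) -> BranchGains:
    """Assign each observed pair a single Dollo gain on the branch above the
    LCA of the species possessing it, with parsimonious losses below."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    _label_nodes(tree)
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if not set(matrix.presence) <= leaf_labels:
        missing = set(matrix.presence) - leaf_labels
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    origin: dict[str, str] = {}
    for pair in sorted(matrix.all_pairs, key=lambda p: tuple(sorted(p))):
        have = {sp for sp, pairs in matrix.presence.items() if pair in pairs}
        if not have:
            continue
        taxa = [tree.taxon_namespace.get_taxon(sp) for sp in have]
        if len(have) == 1:
            lca = tree.find_node_with_taxon_label(next(iter(have)))
        else:
            lca = tree.mrca(taxa=taxa)
        gains[lca.label] = gains.get(lca.label, 0) + 1
        origin["|".join(sorted(pair))] = lca.label

        def count_losses(node) -> int:
            below = {l.taxon.label for l in node.leaf_iter()}
            if not below & have:
                losses[node.label] = losses.get(node.label, 0) + 1
                return 1
            if below <= have:
                return 0
            return sum(count_losses(c) for c in node.child_nodes())

        if lca is not None:
            for child in lca.child_nodes():
                count_losses(child)
    return BranchGains(gains=gains, losses=losses, pair_origin=origin)


def gain_rate(gains: BranchGains, branch_durations_myr: Mapping[str, float]) -> dict[str, float]:
    """Pairs gained per Myr per branch; branches without a duration are
    skipped with a warning."""
    import warnings

    rates = {}
    for branch, n in gains.gains.items():
        dur = branch_durations_myr.get(branch)
        if dur is None:
            warnings.warn(f"no duration for branch {branch}; skipped")
            continue
        if dur <= 0:
            raise ValueError(f"branch duration must be > 0 ({branch})")
        rates[branch] = n / dur
    return rates


def promiscuity_rank(
    pairs: Iterable[Pair], novel_by_branch: Mapping[str, set] | None = None
) -> pd.DataFrame:
    """Rank domain types by distinct partner count; optionally report each
    type's share of novel pairs per branch."""
    partners: dict[str, set[str]] = {}
    for pair in pairs:
        items = sorted(pair)
        if len(items) == 1:
            continue
        a, b = items
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    rows = []
    for dtype, ps in partners.items():
        row = {"domain_type": dtype, "n_partners": len(ps)}
        if novel_by_branch:
            for branch, novel in novel_by_branch.items():
                used = sum(1 for p in novel if dtype in p)
                row[f"novel_{branch}"] = used
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["n_partners", "domain_type"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def presence_absence_tree(matrix: PairMatrix):
    """Neighbour-joining tree on Jaccard distances between species' domain
    pair sets; returns an skbio TreeNode (newick-serialisable)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    species = sorted(matrix.presence)
    if len(species) < 4:
        raise ValueError("need >= 4 species for a meaningful NJ tree")
    n = len(species)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.presence[species[i]], matrix.presence[species[j]]
            union = a | b
            d = 1.0 - (len(a & b) / len(union)) if union else 0.0
            dm[i, j] = dm[j, i] = d
    return nj(DistanceMatrix(dm, ids=species))
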