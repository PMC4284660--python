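"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the DCJ oracle is a
breadth-first search over genome space under the full DCJ operation set; the
Dollo oracle enumerates every single-gain scenario on a tree; the Fisher
oracle sums the hypergeometric tail directly.
"""
from __future__ import annotations

import math
from itertools import combinations, permutations, product


# ---------------------------------------------------------------------------
# DCJ: BFS over adjacency-set states
# ---------------------------------------------------------------------------

def genome_state(signed_markers, shape: str = "linear") -> frozenset:
    """Adjacency-set state of a one-chromosome genome; telomeres are
    singleton adjacencies."""
    ends = []
    for m in signed_markers:
        mid, sign = (abs(m), 1 if m > 0 else -1)
        left, right = ((mid, "t"), (mid, "h")) if sign > 0 else ((mid, "h"), (mid, "t"))
        ends.extend([left, right])
    adjacencies = {frozenset({ends[i], ends[i + 1]}) for i in range(1, len(ends) - 1, 2)}
    if shape == "circular":
        adjacencies.add(frozenset({ends[-1], ends[0]}))
    else:
        adjacencies.add(frozenset({ends[0]}))
        adjacencies.add(frozenset({ends[-1]}))
    return frozenset(adjacencies)


def dcj_neighbours(state: frozenset):
    """All states one DCJ operation away."""
    adjacencies = sorted(state, key=repr)
    for p, q in combinations(adjacencies, 2):
        lp, lq = sorted(p, key=repr), sorted(q, key=repr)
        if len(lp) == 2 and len(lq) == 2:
            a, b = lp
            c, d = lq
            yield state - {p, q} | {frozenset({a, c}), frozenset({b, d})}
            yield state - {p, q} | {frozenset({a, d}), frozenset({b, c})}
        elif len(lp) == 2 and len(lq) == 1:
            a, b = lp
            (c,) = lq
            yield state - {p, q} | {frozenset({a, c}), frozenset({b})}
            yield state - {p, q} | {frozenset({b, c}), frozenset({a})}
        elif len(lp) == 1 and len(lq) == 2:
            (a,) = lp
            c, d = lq
            yield state - {p, q} | {frozenset({c, a}), frozenset({d})}
            yield state - {p, q} | {frozenset({d, a}), frozenset({c})}
        else:
            (a,) = lp
            (c,) = lq
            yield state - {p, q} | {frozenset({a, c})}
    for p in adjacencies:  # cut without join
        lp = sorted(p, key=repr)
        if len(lp) == 2:
            a, b = lp
            yield state - {p} | {frozenset({a}), frozenset({b})}


def bfs_dcj_distances(target_state: frozenset) -> dict[frozenset, int]:
    """Shortest DCJ distance from every reachable genome to the target."""
    dist = {target_state: 0}
    frontier = [target_state]
    while frontier:
        nxt = []
        for state in frontier:
            d = dist[state]
            for nb in dcj_neighbours(state):
                if nb not in dist:
                    dist[nb] = d + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def all_signed_one_chromosome_genomes(n: int):
    """Every signed order of markers 1..n on one linear chromosome."""
    for perm in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield [m * s for m, s in zip(perm, signs)]


# ---------------------------------------------------------------------------
# Dollo parsimony oracle
# ---------------------------------------------------------------------------

def dollo_min_single_gain(tree_children: dict, root, present_leaves: set):
    """Minimum (gain branch, n_losses) over all single-gain scenarios.

    ``tree_children`` maps node -> list of children (leaves map to []).
    A gain on the branch above node g is feasible iff all present leaves lie
    under g; losses then cut off every maximal subtree under g without any
    present leaf. Returns (best_gain_node, min_losses, min_total).
    """

    def leaves_under(node):
        kids = tree_children[node]
        if not kids:
            return {node}
        out = set()
        for k in kids:
            out |= leaves_under(k)
        return out

    def losses_under(node):
        below = leaves_under(node)
        if not below & present_leaves:
            return 1
        if below <= present_leaves:
            return 0
        return sum(losses_under(k) for k in tree_children[node])

    best = None
    for node in tree_children:
        if present_leaves <= leaves_under(node):
            n_losses = sum(losses_under(k) for k in tree_children[node]) if tree_children[node] else 0
            total = 1 + n_losses
            if best is None or total < best[2]:
                best = (node, n_losses, total)
    return best


# ---------------------------------------------------------------------------
# Fisher exact (two-sided) by hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided(table) -> float:
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def pmf(k):
        return (
            math.comb(row1, k) * math.comb(row2, col1 - k) / math.comb(n, col1)
        )

    p_obs = pmf(a)
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)
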