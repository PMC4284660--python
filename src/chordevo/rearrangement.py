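"""Genome rearrangement: DCJ distance, rates, aliquoting, synteny clustering.

The double-cut-and-join (DCJ) distance between two genomes over a shared set
of N one-copy markers is N - (C + I/2), where C is the number of cycles and
I the number of odd paths in the adjacency graph over marker extremities
(Bergeron-Mixtacki-Stoye formula). Rates derived from it:

* per-marker rate  rho = d / N
* relative rate    r   = rho / protein distance (substitutions per aa site)
* per-time rate        = rho / divergence time (per Myr)

Genome aliquoting reconstructs a pre-whole-genome-duplication ancestor of a
genome whose markers all occur in m copies, minimising the DCJ distance from
the perfectly m-plicated ancestor to the observed genome.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

Marker = Hashable
SignedMarker = tuple[Marker, int]  # (id, +1/-1)
Extremity = tuple[Marker, str]  # (id, 't'|'h')


def _signed(markers: Iterable) -> list[SignedMarker]:
    out: list[SignedMarker] = []
    for m in markers:
        if isinstance(m, tuple) and len(m) == 2 and m[1] in (1, -1):
            out.append((m[0], m[1]))
        elif isinstance(m, int) and m != 0:
            out.append((abs(m), 1 if m > 0 else -1))
        elif isinstance(m, str) and m.startswith("-"):
            out.append((m[1:], -1))
        elif isinstance(m, str):
            out.append((m.lstrip("+"), 1))
        else:
            raise ValueError(f"cannot interpret signed marker {m!r}")
    return out


@dataclass
class GeneOrder:
    """Signed marker order over linear/circular chromosomes.

    Chromosomes are (shape, markers) with shape 'linear' or 'circular' and
    markers a list of signed ids: ints (sign = strand), '-name' strings, or
    explicit (id, +/-1) tuples.
    """

    chromosomes: list[tuple[str, list]]

    def __post_init__(self) -> None:
        self.chromosomes = [
            (shape, _signed(markers)) for shape, markers in self.chromosomes
        ]
        for shape, _ in self.chromosomes:
            if shape not in ("linear", "circular"):
                raise ValueError(f"unknown chromosome shape {shape!r}")

    @classmethod
    def linear(cls, *chromosomes: Sequence) -> "GeneOrder":
        return cls([("linear", list(c)) for c in chromosomes])

    def marker_counts(self) -> dict[Marker, int]:
        counts: dict[Marker, int] = {}
        for _, markers in self.chromosomes:
            for mid, _sign in markers:
                counts[mid] = counts.get(mid, 0) + 1
        return counts

    @property
    def marker_universe(self) -> set[Marker]:
        return set(self.marker_counts())

    def restricted_to(self, keep: set[Marker]) -> "GeneOrder":
        chroms = []
        for shape, markers in self.chromosomes:
            kept = [(m, s) for m, s in markers if m in keep]
            if kept:
                chroms.append((shape, kept))
        return GeneOrder(chroms)

    def adjacency_set(self) -> frozenset[frozenset]:
        """Genome as a set of adjacencies; telomeres are singletons."""
        adjacencies: list[frozenset] = []
        for shape, markers in self.chromosomes:
            ends: list[Extremity] = []
            for mid, sign in markers:
                left, right = ((mid, "t"), (mid, "h")) if sign > 0 else ((mid, "h"), (mid, "t"))
                ends.extend([left, right])
            inner = [frozenset({ends[i], ends[i + 1]}) for i in range(1, len(ends) - 1, 2)]
            adjacencies.extend(inner)
            if shape == "circular":
                adjacencies.append(frozenset({ends[-1], ends[0]}))
            else:
                adjacencies.append(frozenset({ends[0]}))
                adjacencies.append(frozenset({ends[-1]}))
        return frozenset(adjacencies)


@dataclass
class DcjResult:
    d: int
    n_markers: int
    cycles: int
    odd_paths: int
    dropped_a: int = 0
    dropped_b: int = 0

    @property
    def per_marker_rate(self) -> float:
        """rho = d / N (shared markers)."""
        if self.n_markers == 0:
            raise ValueError("no shared markers")
        return self.d / self.n_markers


def _neighbour_maps(genome: GeneOrder) -> dict[Extremity, Extremity | None]:
    """extremity -> its adjacent extremity, or None at a telomere."""
    nbr: dict[Extremity, Extremity | None] = {}
    for adj in genome.adjacency_set():
        items = list(adj)
        if len(items) == 2:
            nbr[items[0]], nbr[items[1]] = items[1], items[0]
        else:
            nbr[items[0]] = None
    return nbr


def dcj_distance(a: GeneOrder, b: GeneOrder) -> DcjResult:
    """DCJ distance between two genomes, restricted to shared 1:1 markers."""
    counts_a, counts_b = a.marker_counts(), b.marker_counts()
    for name, counts in (("A", counts_a), ("B", counts_b)):
        dups = sorted(str(m) for m, c in counts.items() if c > 1)
        if dups:
            raise ValueError(
                f"genome {name} has duplicated markers {dups[:5]}; "
                "use the aliquoting operations for multi-copy genomes"
            )
    shared = set(counts_a) & set(counts_b)
    ra, rb = a.restricted_to(shared), b.restricted_to(shared)
    n = len(shared)
    if n == 0:
        return DcjResult(0, 0, 0, 0, len(counts_a), len(counts_b))

    nbr_a, nbr_b = _neighbour_maps(ra), _neighbour_maps(rb)
    seen: set[Extremity] = set()
    cycles = odd_paths = 0
    # Components alternate A- and B-adjacency edges. A component is a path
    # iff it contains an extremity that is a telomere in A or in B; the
    # number of vertices on a path equals its edge count in the bipartite
    # adjacency graph (each extremity is one graph edge), so parity of the
    # vertex count decides odd vs even paths.
    endpoints = [e for e in nbr_a if nbr_a[e] is None or nbr_b[e] is None]
    for start in endpoints:
        if start in seen:
            continue
        n_vertices = 1
        seen.add(start)
        use_a = nbr_a[start] is not None  # begin with whichever edge exists
        cur = start
        while True:
            nxt = (nbr_a if use_a else nbr_b)[cur]
            if nxt is None:
                break
            n_vertices += 1
            seen.add(nxt)
            cur = nxt
            use_a = not use_a
        if n_vertices % 2 == 1:
            odd_paths += 1
    for start in nbr_a:
        if start in seen:
            continue
        cur, use_a = start, True
        while True:
            seen.add(cur)
            cur = (nbr_a if use_a else nbr_b)[cur]
            use_a = not use_a
            if cur == start and use_a:
                break
        cycles += 1
    d = n - (cycles + odd_paths // 2)
    return DcjResult(
        d=d,
        n_markers=n,
        cycles=cycles,
        odd_paths=odd_paths,
        dropped_a=len(counts_a) - n,
        dropped_b=len(counts_b) - n,
    )


def relative_rates(
    dcj: DcjResult, protein_distance: float, divergence_time_myr: float | None = None
) -> tuple[float, float | None]:
    """(relative rate r = rho/protein distance, per-time rate rho/Myr)."""
    if protein_distance <= 0:
        raise ValueError("protein distance must be > 0")
    rho = dcj.per_marker_rate
    r = rho / protein_distance
    per_time = None
    if divergence_time_myr is not None:
        if divergence_time_myr <= 0:
            raise ValueError("divergence time must be > 0")
        per_time = rho / divergence_time_myr
    return r, per_time


def plant_inversions(
    n_markers: int, k: int, rng: np.random.Generator
) -> GeneOrder:
    """A single linear chromosome of ``n_markers`` identity-ordered markers
    with ``k`` random segment inversions applied, each operation cutting at
    positions not cut before (so the k operations are independent and the
    true DCJ distance from the identity order is k with high probability)."""
    perm: list[SignedMarker] = [(i + 1, 1) for i in range(n_markers)]
    used: set[int] = set()
    for _ in range(k):
        while True:
            i = int(rng.integers(0, n_markers))
            j = int(rng.integers(i + 1, n_markers + 1))
            if i in used or j in used or (i == 0 and j == n_markers):
                continue
            used.update((i, j))
            break
        perm[i:j] = [(m, -s) for m, s in reversed(perm[i:j])]
    return GeneOrder([("linear", perm)])


# ---------------------------------------------------------------------------
# Genome aliquoting
# ---------------------------------------------------------------------------

def _chromosomes_from_adjacencies(adjacencies: frozenset) -> GeneOrder:
    """Rebuild a GeneOrder from an adjacency set (inverse of adjacency_set)."""
    nbr: dict[Extremity, Extremity | None] = {}
    for adj in adjacencies:
        items = list(adj)
        if len(items) == 2:
            nbr[items[0]], nbr[items[1]] = items[1], items[0]
        else:
            nbr[items[0]] = None

    def other(e: Extremity) -> Extremity:
        return (e[0], "h" if e[1] == "t" else "t")

    seen: set[Marker] = set()
    chroms: list[tuple[str, list]] = []
    telomeres = sorted((e for e, v in nbr.items() if v is None), key=repr)
    for start in telomeres:
        if start[0] in seen:
            continue
        markers: list[SignedMarker] = []
        e = start
        while True:
            mid = e[0]
            sign = 1 if e[1] == "t" else -1
            markers.append((mid, sign))
            seen.add(mid)
            nxt = nbr.get(other(e))
            if nxt is None:
                break
            e = nxt
        chroms.append(("linear", markers))
    for e in sorted(nbr, key=repr):
        if e[0] in seen:
            continue
        markers = []
        cur = e if e[1] == "t" else other(e)
        first = cur
        while True:
            markers.append((cur[0], 1 if cur[1] == "t" else -1))
            seen.add(cur[0])
            nxt = nbr[other(cur)]
            assert nxt is not None
            if nxt == first:
                break
            cur = nxt
        chroms.append(("circular", markers))
    return GeneOrder(chroms)


def doubled(genome: GeneOrder) -> GeneOrder:
    """Perfectly 2-plicated genome: every chromosome duplicated; copies
    labelled (id, 0) and (id, 1)."""
    chroms = []
    for copy in (0, 1):
        for shape, markers in genome.chromosomes:
            chroms.append((shape, [((mid, copy), sign) for mid, sign in markers]))
    return GeneOrder(chroms)


def _label_copies(genome: GeneOrder) -> GeneOrder:
    """Label the two occurrences of each marker (id,0)/(id,1) in reading order."""
    seen: dict[Marker, int] = {}
    chroms = []
    for shape, markers in genome.chromosomes:
        lab = []
        for mid, sign in markers:
            k = seen.get(mid, 0)
            seen[mid] = k + 1
            lab.append(((mid, k), sign))
        chroms.append((shape, lab))
    return GeneOrder(chroms)


def _swap_labels(genome: GeneOrder, flip: set[Marker]) -> GeneOrder:
    chroms = []
    for shape, markers in genome.chromosomes:
        chroms.append(
            (
                shape,
                [
                    (((mid, 1 - copy) if mid in flip else (mid, copy)), sign)
                    for (mid, copy), sign in markers
                ],
            )
        )
    return GeneOrder(chroms)


def _all_partial_matchings(extremities: list[Extremity]):
    """All genomes over the given extremities, as adjacency sets."""
    if not extremities:
        yield frozenset()
        return
    first, rest = extremities[0], extremities[1:]
    for sub in _all_partial_matchings(rest):
        yield sub | {frozenset({first})}
    for i, partner in enumerate(rest):
        remaining = rest[:i] + rest[i + 1:]
        for sub in _all_partial_matchings(remaining):
            yield sub | {frozenset({first, partner})}


@dataclass
class AliquotResult:
    d: int
    ancestor: GeneOrder
    mode: str


def aliquot_distance(genome: GeneOrder, mode: str = "greedy") -> AliquotResult:
    """Estimate the DCJ distance to a perfectly duplicated ancestor (m=2).

    exact  -- enumerate all candidate ancestors and all copy labelings
              (only feasible for <= 8 distinct markers);
    greedy -- reconstruct ancestor adjacencies by copy support, label copies
              in reading order, then hill-climb label swaps to reduce d.
    """
    counts = genome.marker_counts()
    bad = sorted(str(m) for m, c in counts.items() if c != 2)
    if bad:
        raise ValueError(f"aliquoting requires uniform multiplicity 2; offending: {bad[:5]}")
    distinct = sorted(counts, key=repr)
    labelled = _label_copies(genome)

    if mode == "exact":
        if len(distinct) > 8:
            raise ValueError("exact aliquoting supports at most 8 distinct markers")
        extremities = [(m, e) for m in distinct for e in ("t", "h")]
        best_d, best_anc = None, None
        for adjacencies in _all_partial_matchings(extremities):
            ancestor = _chromosomes_from_adjacencies(adjacencies)
            dbl = doubled(ancestor)
            for flips in itertools.chain.from_iterable(
                itertools.combinations(distinct, k) for k in range(len(distinct) + 1)
            ):
                cand = _swap_labels(labelled, set(flips))
                d = dcj_distance(dbl, cand).d
                if best_d is None or d < best_d:
                    best_d, best_anc = d, ancestor
                if best_d == 0:
                    return AliquotResult(0, best_anc, "exact")
        return AliquotResult(best_d, best_anc, "exact")

    if mode != "greedy":
        raise ValueError(f"unknown aliquoting mode {mode!r}")

    # Support counting: project each observed adjacency to distinct extremities.
    support: dict[frozenset, int] = {}
    for adj in labelled.adjacency_set():
        items = list(adj)
        if len(items) != 2:
            continue
        (m1, c1), e1 = items[0]
        (m2, c2), e2 = items[1]
        key = frozenset({(m1, e1), (m2, e2)})
        if len(key) == 2:
            support[key] = support.get(key, 0) + 1
    used: set[Extremity] = set()
    chosen: set[frozenset] = set()
    for key, _sup in sorted(support.items(), key=lambda kv: (-kv[1], repr(sorted(kv[0], key=repr)))):
        x, y = sorted(key, key=repr)
        if x in used or y in used:
            continue
        chosen.add(key)
        used.update((x, y))
    all_ext = {(m, e) for m in distinct for e in ("t", "h")}
    adjacencies = frozenset(chosen) | frozenset(
        frozenset({e}) for e in all_ext - used
    )
    ancestor = _chromosomes_from_adjacencies(adjacencies)
    dbl = doubled(ancestor)

    cand = labelled

    def label_climb(anc_doubled, start: GeneOrder) -> tuple[int, GeneOrder]:
        cur = start
        best_d = dcj_distance(anc_doubled, cur).d
        for _ in range(8):
            moved = False
            for m in distinct:
                trial = _swap_labels(cur, {m})
                d = dcj_distance(anc_doubled, trial).d
                if d < best_d:
                    best_d, cur, moved = d, trial, True
            if not moved:
                break
        return best_d, cur

    best, cand = label_climb(dbl, cand)

    # local search on the ancestor: DCJ moves among low-support adjacencies
    input_adjacencies = labelled.adjacency_set()

    def adjacency_support(anc_adjacencies: frozenset) -> dict[frozenset, int]:
        sup = {}
        for adj in anc_adjacencies:
            items = list(adj)
            count = 0
            for copy_pair in _doubled_copies(items):
                if copy_pair in input_adjacencies:
                    count += 1
            sup[adj] = count
        return sup

    def _doubled_copies(items):
        if len(items) == 1:
            (m, e) = items[0]
            return [frozenset({((m, 0), e)}), frozenset({((m, 1), e)})]
        (m1, e1), (m2, e2) = items
        return [
            frozenset({((m1, c1), e1), ((m2, c2), e2)})
            for c1 in (0, 1)
            for c2 in (0, 1)
        ]

    anc_adj = set(ancestor.adjacency_set())
    for _ in range(64):
        sup = adjacency_support(frozenset(anc_adj))
        weak = [a for a in anc_adj if sup[a] < 2]
        moved = False
        for x, y in itertools.combinations(sorted(weak, key=repr), 2):
            ex, ey = sorted(x, key=repr), sorted(y, key=repr)
            variants = []
            pool = ex + ey
            if len(pool) >= 2:
                for grouping in _regroupings(ex, ey):
                    variants.append(grouping)
            for new_adjs in variants:
                trial_adj = (anc_adj - {x, y}) | set(new_adjs)
                trial_anc = _chromosomes_from_adjacencies(frozenset(trial_adj))
                trial_dbl = doubled(trial_anc)
                # evaluate with current labels; relabel only on acceptance
                d = dcj_distance(trial_dbl, cand).d
                if d < best:
                    best = d
                    anc_adj = set(trial_adj)
                    ancestor, dbl = trial_anc, trial_dbl
                    moved = True
                    break
            if moved:
                break
        if not moved:
            break
    best, cand = label_climb(dbl, cand)
    return AliquotResult(best, ancestor, "greedy")


def _regroupings(ex: list, ey: list):
    """Alternative adjacency pairings of the extremities in two adjacencies
    (the possible DCJ rejoinings, telomeres included)."""
    outs = []
    if len(ex) == 2 and len(ey) == 2:
        a, b = ex
        c, d = ey
        outs.append([frozenset({a, c}), frozenset({b, d})])
        outs.append([frozenset({a, d}), frozenset({b, c})])
        outs.append([frozenset({a}), frozenset({b}), frozenset({c, d})])
        outs.append([frozenset({c}), frozenset({d}), frozenset({a, b})])
    elif len(ex) == 2 and len(ey) == 1:
        a, b = ex
        (c,) = ey
        outs.append([frozenset({a, c}), frozenset({b})])
        outs.append([frozenset({b, c}), frozenset({a})])
    elif len(ex) == 1 and len(ey) == 2:
        return _regroupings(ey, ex)
    else:
        (a,) = ex
        (c,) = ey
        outs.append([frozenset({a, c})])
    return outs


# ---------------------------------------------------------------------------
# Synteny scaffold clustering and dot plots
# ---------------------------------------------------------------------------

def synteny_clusters(orthology, scaffold_a: dict, scaffold_b: dict):
    """Bidirectional hierarchical scaffold ordering from orthologue sharing.

    For each scaffold pair (one from each assembly) a 2x2 table of shared
    1:1 orthologues (on both scaffolds vs elsewhere) is scored by a
    two-sided Fisher exact test; dissimilarity = -log(P) (natural log).
    Average-linkage clustering is applied independently to each side, using
    each scaffold's profile of -log(P) against the other side's scaffolds.

    Returns (order_a, order_b, dissim DataFrame indexed scaffolds_a x scaffolds_b).
    """
    pairs = [(a, b) for a, b, *_ in orthology.pairs]
    scafs_a = sorted({scaffold_a[g] for g, _ in pairs} | set(scaffold_a.values()))
    scafs_b = sorted({scaffold_b[g] for _, g in pairs} | set(scaffold_b.values()))
    if len(scafs_a) < 2 or len(scafs_b) < 2:
        raise ValueError("need at least 2 scaffolds per side")
    total = len(pairs)
    counts = pd.DataFrame(0, index=scafs_a, columns=scafs_b)
    for ga, gb in pairs:
        counts.loc[scaffold_a[ga], scaffold_b[gb]] += 1
    dissim = pd.DataFrame(np.inf, index=scafs_a, columns=scafs_b)
    for sa in scafs_a:
        row_tot = counts.loc[sa].sum()
        for sb in scafs_b:
            both = counts.loc[sa, sb]
            col_tot = counts[sb].sum()
            table = [
                [both, row_tot - both],
                [col_tot - both, total - row_tot - col_tot + both],
            ]
            if row_tot == 0 or col_tot == 0:
                continue  # zero-orthologue scaffold: infinite dissimilarity
            p = fisher_exact(table, alternative="two-sided")[1]
            dissim.loc[sa, sb] = -math.log(max(p, 1e-300))

    def order(mat: pd.DataFrame) -> list:
        finite = mat.replace(np.inf, np.nan)
        filled = finite.fillna(finite.max().max() if np.isfinite(finite.max().max()) else 1.0)
        profiles = filled.to_numpy()
        labels = list(mat.index)
        with_orth = [i for i, lab in enumerate(labels) if np.isfinite(mat.loc[lab]).any()]
        without = [i for i in range(len(labels)) if i not in with_orth]
        if len(with_orth) < 2:
            ordered = with_orth
        else:
            sub = profiles[with_orth]
            # similarity profiles: cluster scaffolds by euclidean distance of
            # their -log(P) profiles, average linkage
            dist = squareform(
                np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)), checks=False
            )
            ordered = [with_orth[i] for i in leaves_list(average(dist))]
        return [labels[i] for i in ordered + without]

    return order(dissim), order(dissim.T), dissim


def dotplot_export(orthology, order_a, order_b, scaffold_a, scaffold_b, positions_a, positions_b, path, plot_path=None):
    """Write a TSV of orthologue positions in the clustered scaffold order.

    One row per 1:1 pair: cumulative rank coordinates along each axis.
    Optionally renders a PNG scatter when plot_path is given.
    """
    rank_a = {}
    offset = 0
    per_scaf_a: dict = {}
    for s in order_a:
        per_scaf_a[s] = offset
        offset += sum(1 for g, sc in scaffold_a.items() if sc == s)
    per_scaf_b: dict = {}
    offset = 0
    for s in order_b:
        per_scaf_b[s] = offset
        offset += sum(1 for g, sc in scaffold_b.items() if sc == s)
    rows = []
    for ga, gb, *_ in orthology.pairs:
        xa = per_scaf_a[scaffold_a[ga]] + positions_a[ga]
        yb = per_scaf_b[scaffold_b[gb]] + positions_b[gb]
        rows.append((ga, gb, xa, yb))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "x", "y"])
    df.to_csv(path, sep="\t", index=False)
    if plot_path:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(df.x, df.y, s=4)
        ax.set_xlabel("assembly A (clustered gene rank)")
        ax.set_ylabel("assembly B (clustered gene rank)")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
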