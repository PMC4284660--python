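"""Region-class partition of the genome and transcription/methylation
profiles by class.

The genome is partitioned exactly (disjoint cover) into five classes with
precedence cds > intron > upstream/downstream > intergenic. Flanks default
to 1 kb; where flanks of adjacent genes would overlap, the space is split
at the midpoint.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .models import GenomeAnnotation

CLASS_NAMES = ["intergenic", "upstream", "downstream", "intron", "cds"]


@dataclass
class RegionPartition:
    labels: dict[str, np.ndarray]  # per-sequence uint8 codes into class_names
    class_names: list[str]
    flank: int

    def class_lengths(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for arr in self.labels.values():
            counts = np.bincount(arr, minlength=len(self.class_names))
            for i, c in enumerate(self.class_names):
                out[c] += int(counts[i])
        return out

    @property
    def genome_size(self) -> int:
        return sum(len(a) for a in self.labels.values())

    def class_at(self, seq: str, pos: int) -> str:
        return self.class_names[self.labels[seq][pos]]

    def intervals(self, cls: str) -> list[tuple[str, int, int]]:
        code = self.class_names.index(cls)
        out = []
        for seq, arr in self.labels.items():
            mask = arr == code
            if not mask.any():
                continue
            diff = np.diff(mask.astype(np.int8))
            starts = list(np.nonzero(diff == 1)[0] + 1)
            ends = list(np.nonzero(diff == -1)[0] + 1)
            if mask[0]:
                starts.insert(0, 0)
            if mask[-1]:
                ends.append(len(arr))
            out.extend((seq, int(a), int(b)) for a, b in zip(starts, ends))
        return out


def partition_regions(annotation: GenomeAnnotation, flank: int = 1000) -> RegionPartition:
    """Exact disjoint partition into cds/intron/upstream/downstream/intergenic.

    Flanks are painted over intergenic space only; where the upstream and
    downstream claims of neighbouring genes overlap, the overlap is split at
    its midpoint.
    """
    code = {c: i for i, c in enumerate(CLASS_NAMES)}
    labels = {
        name: np.zeros(length, dtype=np.uint8)
        for name, length in annotation.sequences.items()
    }
    # claims on intergenic space: (priority position) handled by midpoint rule
    claims: dict[str, list[tuple[int, int, str]]] = {n: [] for n in labels}
    for g in annotation.genes:
        lo, hi = g.span
        up_cls, down_cls = ("upstream", "downstream") if g.strand == "+" else ("downstream", "upstream")
        claims[g.seq_name].append((max(0, lo - flank), lo, up_cls))
        claims[g.seq_name].append((hi, min(len(labels[g.seq_name]), hi + flank), down_cls))
    # paint flanks; overlapping claims split at the midpoint of their overlap
    for seq, cl in claims.items():
        arr = labels[seq]
        cl.sort()
        painted: list[tuple[int, int, str]] = []
        for a, b, cls in cl:
            if painted:
                pa, pb, pcls = painted[-1]
                if a < pb:  # overlap with previous claim: split at midpoint
                    mid = (a + pb) // 2
                    painted[-1] = (pa, mid, pcls)
                    a = mid
            if b > a:
                painted.append((a, b, cls))
        for a, b, cls in painted:
            arr[a:b] = code[cls]
    # gene bodies: intron then cds on top
    for g in annotation.genes:
        arr = labels[g.seq_name]
        lo, hi = g.span
        arr[lo:hi] = code["intron"]
    for g in annotation.genes:
        arr = labels[g.seq_name]
        for a, b in g.cds:
            arr[a:b] = code["cds"]
    return RegionPartition(labels=labels, class_names=CLASS_NAMES, flank=flank)


def transcription_fractions(
    reads: list[tuple[str, int, int]], partition: RegionPartition
) -> tuple[dict[str, float], float]:
    """Per-class read fractions (%) by majority-overlap assignment, plus
    genome coverage (%) of the read set."""
    counts = {c: 0 for c in partition.class_names}
    covered = {seq: np.zeros(len(arr), dtype=bool) for seq, arr in partition.labels.items()}
    for read in reads:
        seq, start, end = read[0], read[1], read[2]
        if seq not in partition.labels:
            raise ValueError(f"read on unknown sequence {seq!r}")
        arr = partition.labels[seq]
        if end > len(arr) or start < 0:
            raise ValueError(f"read off the end of {seq}: [{start},{end})")
        sub = arr[start:end]
        cls = partition.class_names[int(np.bincount(sub).argmax())]
        counts[cls] += 1
        covered[seq][start:end] = True
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads")
    fractions = {c: 100.0 * n / total for c, n in counts.items()}
    cov = 100.0 * sum(int(m.sum()) for m in covered.values()) / partition.genome_size
    return fractions, cov


@dataclass
class MethylationProfile:
    mean_level: dict[str, float]  # percent per class
    n_sites: dict[str, int]
    high_fraction: dict[str, float]  # fraction of sites >= 80% methylated
    t_tests: pd.DataFrame


def methylation_by_region(
    methyl: pd.DataFrame,
    partition: RegionPartition,
    te_intervals: list[tuple[str, int, int]] | None = None,
    high_threshold: float = 0.8,
    weighted: bool = False,
) -> MethylationProfile:
    """Mean CG methylation per region class (unweighted over sites by
    default; ``weighted=True`` pools reads instead), the fraction of sites
    methylated at >= 80%, and Student's t-tests between classes."""
    levels: dict[str, list[float]] = {c: [] for c in partition.class_names}
    weights: dict[str, list[int]] = {c: [] for c in partition.class_names}
    te_mask: dict[str, np.ndarray] = {}
    if te_intervals:
        te_mask = {seq: np.zeros(len(arr), dtype=bool) for seq, arr in partition.labels.items()}
        for seq, a, b in te_intervals:
            if seq in te_mask:
                te_mask[seq][a:b] = True
        levels["te"] = []
        weights["te"] = []
    for _, row in methyl.iterrows():
        if row.total_reads == 0:
            continue
        level = row.methylated_reads / row.total_reads
        cls = partition.class_at(row.seq, int(row.pos0))
        levels[cls].append(level)
        weights[cls].append(int(row.total_reads))
        if te_mask and te_mask.get(row.seq, np.zeros(0))[int(row.pos0)]:
            levels["te"].append(level)
            weights["te"].append(int(row.total_reads))
    mean_level, n_sites, high = {}, {}, {}
    for cls, vals in levels.items():
        n_sites[cls] = len(vals)
        if not vals:
            mean_level[cls] = float("nan")
            high[cls] = float("nan")
            continue
        v = np.asarray(vals)
        if weighted:
            w = np.asarray(weights[cls], dtype=float)
            mean_level[cls] = 100.0 * float(np.average(v, weights=w))
        else:
            mean_level[cls] = 100.0 * float(v.mean())
        high[cls] = float((v >= high_threshold).mean())
    rows = []
    for a, b in combinations([c for c in levels if levels[c]], 2):
        t, p = stats.ttest_ind(levels[a], levels[b], equal_var=False)
        rows.append((a, b, float(t), float(p)))
    tests = pd.DataFrame(rows, columns=["class_a", "class_b", "t", "p_value"])
    return MethylationProfile(mean_level=mean_level, n_sites=n_sites, high_fraction=high, t_tests=tests)
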