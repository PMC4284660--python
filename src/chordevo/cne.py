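"""Conserved non-coding elements: extraction from pairwise alignment blocks,
the refinement filter chain, summary statistics, enrichment windows and
multi-set intersection.

Coarse candidates are alignment blocks split at annotated coding sequence
and at long gap runs; refinement removes, in fixed order, candidates that
are too short, adjacent to CDS, homologous to known proteins/structural
RNAs, or below the identity cutoff, reporting the total length removed by
each filter class so the accounting balances exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import AlignmentBlockSet, GenomeAnnotation

FILTER_ORDER = ["short", "cds_adjacent", "homology", "low_identity"]


@dataclass
class CneCandidate:
    ref_seq: str
    ref_start: int
    ref_end: int
    query_seq: str
    query_start: int
    query_end: int
    identity: float  # percent; gap columns count as mismatches
    filter_flags: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def cne_id(self) -> str:
        return f"{self.ref_seq}:{self.ref_start}-{self.ref_end}"


@dataclass
class CneSummary:
    genome_size: int
    coarse_length: int
    removed_lengths: dict[str, int]
    refined_length: int
    refined_count: int

    @property
    def refined_percent(self) -> float:
        return 100.0 * self.refined_length / self.genome_size

    @property
    def average_length(self) -> float:
        if self.refined_count == 0:
            return float("nan")
        return self.refined_length / self.refined_count

    def to_series(self) -> pd.Series:
        data = {
            "genome_size": self.genome_size,
            "coarse_length": self.coarse_length,
            **{f"removed_{k}": v for k, v in self.removed_lengths.items()},
            "refined_length": self.refined_length,
            "refined_percent": round(self.refined_percent, 2),
            "refined_count": self.refined_count,
            "average_length": round(self.average_length, 1) if self.refined_count else np.nan,
        }
        return pd.Series(data)


def _coding_intervals(annotation: GenomeAnnotation, use_all_exons: bool) -> dict[str, list]:
    out: dict[str, list] = {name: [] for name in annotation.sequences}
    for g in annotation.genes:
        for iv in (g.exons if use_all_exons else g.cds):
            out[g.seq_name].append(iv)
    for name in out:
        merged: list[list[int]] = []
        for a, b in sorted(out[name]):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out[name] = [(a, b) for a, b in merged]
    return out


def coarse_cnes(
    blocks: AlignmentBlockSet,
    annotation: GenomeAnnotation,
    split_all_exons: bool = False,
    gap_break: int = 10,
    merge_distance: int = 10,
) -> list[CneCandidate]:
    """Split alignment blocks at coding sequence and at gap runs >=
    ``gap_break`` columns; candidates closer than ``merge_distance`` on both
    genomes are merged. Per-candidate identity counts gap columns as
    mismatches.
    """
    ivs = sorted((b.ref_seq, b.ref_start, b.ref_end) for b in blocks)
    for (s1, a1, b1), (s2, a2, b2) in zip(ivs, ivs[1:]):
        if s1 == s2 and a2 < b1:
            raise ValueError(
                f"blocks overlap on reference {s1}:{a2}<{b1}; input is not reciprocal-best"
            )
    coding = _coding_intervals(annotation, split_all_exons)
    candidates: list[CneCandidate] = []
    for block in blocks:
        cds_here = coding.get(block.ref_seq, [])
        ref_pos = block.ref_start
        q_step = 1 if block.query_strand == "+" else -1
        q_pos = block.query_start if block.query_strand == "+" else block.query_end
        run_cols: list[tuple[int, int, bool]] = []  # (ref_pos or -1, q_pos or -1, match)
        segments: list[list] = [[]]
        gap_run = 0
        cols = []
        for rc, qc in zip(block.ref_text, block.query_text):
            r_here = ref_pos if rc != "-" else None
            if block.query_strand == "+":
                q_here = q_pos if qc != "-" else None
            else:
                q_here = (q_pos - 1) if qc != "-" else None
            in_cds = r_here is not None and any(a <= r_here < b for a, b in cds_here)
            cols.append((r_here, q_here, rc, qc, in_cds))
            if rc != "-":
                ref_pos += 1
            if qc != "-":
                q_pos += q_step
        # break points: CDS columns and gap runs >= gap_break
        breaks = [False] * len(cols)
        i = 0
        while i < len(cols):
            if cols[i][4]:
                breaks[i] = True
                i += 1
                continue
            if cols[i][2] == "-" or cols[i][3] == "-":
                j = i
                while j < len(cols) and (cols[j][2] == "-" or cols[j][3] == "-"):
                    j += 1
                if j - i >= gap_break:
                    for k in range(i, j):
                        breaks[k] = True
                i = j
                continue
            i += 1
        seg: list = []
        raw_segments = []
        for col, br in zip(cols, breaks):
            if br:
                if seg:
                    raw_segments.append(seg)
                    seg = []
            else:
                seg.append(col)
        if seg:
            raw_segments.append(seg)
        block_cands = []
        for seg in raw_segments:
            ref_cols = [c[0] for c in seg if c[0] is not None]
            q_cols = [c[1] for c in seg if c[1] is not None]
            if not ref_cols or not q_cols:
                continue
            matches = sum(
                1 for c in seg if c[2].upper() == c[3].upper() and c[2] != "-"
            )
            identity = 100.0 * matches / len(seg)
            block_cands.append(
                CneCandidate(
                    ref_seq=block.ref_seq,
                    ref_start=min(ref_cols),
                    ref_end=max(ref_cols) + 1,
                    query_seq=block.query_seq,
                    query_start=min(q_cols),
                    query_end=max(q_cols) + 1,
                    identity=identity,
                )
            )
        # merge close candidates within the block
        block_cands.sort(key=lambda c: c.ref_start)
        merged: list[CneCandidate] = []
        for cand in block_cands:
            if merged:
                prev = merged[-1]
                ref_gap = cand.ref_start - prev.ref_end
                q_gap = (
                    cand.query_start - prev.query_end
                    if block.query_strand == "+"
                    else prev.query_start - cand.query_end
                )
                if 0 <= ref_gap < merge_distance and abs(q_gap) < merge_distance:
                    total = prev.length + cand.length
                    ident = (
                        prev.identity * prev.length + cand.identity * cand.length
                    ) / total
                    merged[-1] = CneCandidate(
                        prev.ref_seq,
                        prev.ref_start,
                        cand.ref_end,
                        prev.query_seq,
                        min(prev.query_start, cand.query_start),
                        max(prev.query_end, cand.query_end),
                        ident,
                    )
                    continue
            merged.append(cand)
        candidates.extend(merged)
    candidates.sort(key=lambda c: (c.ref_seq, c.ref_start))
    return candidates


def refine_cnes(
    candidates: Sequence[CneCandidate],
    annotation: GenomeAnnotation,
    hits: pd.DataFrame | None = None,
    min_len: int = 75,
    min_identity: float = 70.0,
    cds_flank_bp: int = 20,
    max_evalue: float = 1e-5,
    genome_size: int | None = None,
) -> tuple[list[CneCandidate], CneSummary]:
    """Apply the refinement filters in fixed order (short, CDS-adjacent,
    homology, low identity); each candidate is attributed to the first
    filter that removes it, so per-class removed lengths plus the refined
    length equal the coarse length exactly.
    """
    if min_len < 0 or min_identity < 0 or cds_flank_bp < 0:
        raise ValueError("thresholds must be non-negative")
    coding = _coding_intervals(annotation, use_all_exons=False)
    hit_ids: set[str] = set()
    if hits is not None and len(hits):
        ok = hits[hits.e_value <= max_evalue]
        hit_ids = set(ok.query_id)
    removed = {k: 0 for k in FILTER_ORDER}
    refined: list[CneCandidate] = []
    for cand in candidates:
        flags = cand.filter_flags
        if cand.length < min_len:
            flags.add("short")
        near_cds = any(
            a - cds_flank_bp <= cand.ref_end and cand.ref_start <= b + cds_flank_bp
            for a, b in coding.get(cand.ref_seq, [])
        )
        if near_cds:
            flags.add("cds_adjacent")
        if cand.cne_id in hit_ids:
            flags.add("homology")
        if cand.identity < min_identity:
            flags.add("low_identity")
        for f in FILTER_ORDER:
            if f in flags:
                removed[f] += cand.length
                break
        else:
            refined.append(cand)
    gsize = genome_size if genome_size is not None else annotation.genome_size
    summary = CneSummary(
        genome_size=gsize,
        coarse_length=sum(c.length for c in candidates),
        removed_lengths=removed,
        refined_length=sum(c.length for c in refined),
        refined_count=len(refined),
    )
    return refined, summary


def cne_stats(
    refined_length, refined_count: int | None = None, genome_size: int = 0,
    coarse_length: int | None = None,
) -> CneSummary:
    """Summary statistics from a refined CNE list, or from printed totals
    (refined length in bp plus element count)."""
    if not isinstance(refined_length, (int, float, np.integer)):
        cands = list(refined_length)
        refined_count = len(cands)
        refined_length = sum(c.length for c in cands)
    if genome_size <= 0:
        raise ValueError("genome size must be > 0")
    return CneSummary(
        genome_size=genome_size,
        coarse_length=coarse_length if coarse_length is not None else refined_length,
        removed_lengths={},
        refined_length=refined_length,
        refined_count=refined_count,
    )


def enrichment_windows(
    refined: Sequence[CneCandidate],
    annotation: GenomeAnnotation,
    window: int = 500_000,
    step: int = 100_000,
    top_k: int = 30,
) -> pd.DataFrame:
    """Rank sliding windows by CNE bp, merge overlapping top windows and
    report per-region CNE bp, CNE count and gene count."""
    if window < step:
        raise ValueError("window must be >= step")
    windows = []
    for seq, length in annotation.sequences.items():
        start = 0
        while start < length:
            end = min(start + window, length)
            bp = sum(
                max(0, min(c.ref_end, end) - max(c.ref_start, start))
                for c in refined
                if c.ref_seq == seq
            )
            windows.append((seq, start, end, bp))
            if end == length:
                break
            start += step
    windows.sort(key=lambda w: (-w[3], w[0], w[1]))
    top = windows[:top_k]
    # merge overlapping top windows
    top.sort(key=lambda w: (w[0], w[1]))
    regions: list[list] = []
    for seq, start, end, _bp in top:
        if regions and regions[-1][0] == seq and start <= regions[-1][2]:
            regions[-1][2] = max(regions[-1][2], end)
        else:
            regions.append([seq, start, end])
    rows = []
    for seq, start, end in regions:
        bp = sum(
            max(0, min(c.ref_end, end) - max(c.ref_start, start))
            for c in refined
            if c.ref_seq == seq
        )
        n_cne = sum(1 for c in refined if c.ref_seq == seq and c.ref_start < end and start < c.ref_end)
        n_genes = sum(
            1
            for g in annotation.genes
            if g.seq_name == seq and g.span[0] < end and start < g.span[1]
        )
        rows.append((seq, start, end, bp, n_cne, n_genes))
    df = pd.DataFrame(rows, columns=["seq", "start", "end", "cne_bp", "n_cnes", "n_genes"])
    return df.sort_values("cne_bp", ascending=False).reset_index(drop=True)


def intersect_cne_sets(
    set1: Iterable[tuple[str, int, int]],
    set2: Iterable[tuple[str, int, int]],
    min_len: int = 30,
    reference1: str = "",
    reference2: str = "",
) -> list[tuple[str, int, int]]:
    """Intersection of two CNE interval sets on a shared reference; only
    intersections >= ``min_len`` bp are kept."""
    if reference1 and reference2 and reference1 != reference2:
        raise ValueError(
            f"CNE sets on different references: {reference1!r} vs {reference2!r}"
        )
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq, a, b in set2:
        by_seq.setdefault(seq, []).append((a, b))
    for seq in by_seq:
        by_seq[seq].sort()
    out = []
    for seq, a, b in sorted(set1):
        for c, d in by_seq.get(seq, []):
            lo, hi = max(a, c), min(b, d)
            if hi - lo >= min_len:
                out.append((seq, lo, hi))
    return out
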