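"""Shared data model for the comparative-genomics pipeline.

All coordinates are 0-based half-open on the forward strand. Conversions
from 1-based closed conventions (GFF3, axt) happen only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A protein-coding gene: exon/CDS structure on one sequence.

    ``exons`` and ``cds`` are sorted in genomic order and non-overlapping;
    translation order is genomic order for '+' genes and reversed for '-'.
    """

    gene_id: str
    seq_name: str
    strand: str  # '+' or '-'
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    protein_id: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        for name in ("exons", "cds"):
            ivs = getattr(self, name)
            if ivs != sorted(ivs):
                raise ValueError(f"gene {self.gene_id}: {name} not sorted")
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"gene {self.gene_id}: overlapping {name}")
            for a, b in ivs:
                if b <= a:
                    raise ValueError(f"gene {self.gene_id}: empty {name} interval")

    @property
    def span(self) -> Interval:
        ivs = self.exons or self.cds
        return ivs[0][0], ivs[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    def cds_in_translation_order(self) -> list[Interval]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))


@dataclass
class GenomeAnnotation:
    """Annotation of one assembly: sequence lengths plus gene models."""

    sequences: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    assembly_name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.seq_name not in self.sequences:
                raise ValueError(f"gene {g.gene_id}: unknown sequence {g.seq_name}")
            length = self.sequences[g.seq_name]
            lo, hi = g.span
            if lo < 0 or hi > length:
                raise ValueError(
                    f"gene {g.gene_id}: interval [{lo},{hi}) outside "
                    f"{g.seq_name} of length {length}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def genome_size(self) -> int:
        return sum(self.sequences.values())


@dataclass
class AlignmentBlock:
    """One pairwise alignment block; ref coordinates always ascend.

    ``query_strand`` '-' means the query text is the reverse complement of
    the forward-strand interval [query_start, query_end).
    """

    ref_seq: str
    ref_start: int
    ref_end: int
    query_seq: str
    query_start: int
    query_end: int
    query_strand: str
    ref_text: str
    query_text: str

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.query_text):
            raise ValueError("ragged aligned texts")
        if self.query_strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.query_strand!r}")
        n_ref = sum(1 for c in self.ref_text if c != "-")
        n_qry = sum(1 for c in self.query_text if c != "-")
        if n_ref != self.ref_end - self.ref_start:
            raise ValueError("ref text length does not match ref interval")
        if n_qry != self.query_end - self.query_start:
            raise ValueError("query text length does not match query interval")

    @property
    def n_columns(self) -> int:
        return len(self.ref_text)

    def identity(self) -> float:
        """Percent identity over all columns; gap columns count as mismatches."""
        m = sum(
            1
            for a, b in zip(self.ref_text.upper(), self.query_text.upper())
            if a == b and a != "-"
        )
        return 100.0 * m / self.n_columns if self.n_columns else 0.0


@dataclass
class AlignmentBlockSet:
    blocks: list[AlignmentBlock]
    source_pair: tuple[str, str] = ("ref", "query")

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


def check_intervals(intervals: Iterable[Interval]) -> None:
    for a, b in intervals:
        if b < a:
            raise ValueError(f"interval end {b} < start {a}")
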