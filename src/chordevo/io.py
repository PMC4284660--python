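"""Readers and writers for the standard formats consumed by the pipeline.

GFF3 (1-based closed) and axt (1-based closed) are converted to the internal
0-based half-open convention here and nowhere else. Readers validate
coordinate invariants and raise rather than clamp.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentBlock, AlignmentBlockSet, GeneModel, GenomeAnnotation

# Column schemas for the tabular inputs (TSV, no header unless stated).
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bitscore",
]
DOMAIN_COLUMNS = ["protein_id", "domain_type", "env_start", "env_end", "e_value"]
METHYL_COLUMNS = ["seq", "pos0", "strand", "context", "methylated_reads", "total_reads"]

_SCHEMAS = {"hits": HIT_COLUMNS, "domains": DOMAIN_COLUMNS, "methylation": METHYL_COLUMNS}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str) -> GenomeAnnotation:
    """Read a GFF3 file with gene/mRNA/exon/CDS features (via gffutils).

    Coordinates are converted from 1-based closed to 0-based half-open.
    Sequence lengths come from ``##sequence-region`` pragmas when present,
    otherwise from the maximal feature end per sequence.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="error", keep_order=True, force=True
        )
    except EmptyInputError:
        return GenomeAnnotation(sequences={}, genes=[], assembly_name=os.path.basename(path))
    sequences: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            sequences[parts[1]] = int(parts[3])

    known_ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        if f.featuretype in ("mRNA", "exon", "CDS"):
            for parent in f.attributes.get("Parent", []):
                if parent not in known_ids:
                    raise ValueError(
                        f"{f.featuretype} {f.id or f.start}: parent link {parent!r} unresolvable"
                    )
        if f.featuretype in ("gene", "mRNA", "exon", "CDS") and f.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {f.strand!r} on {f.featuretype} {f.id}")

    models = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        protein_id = ""
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        if mrnas:
            protein_id = mrnas[0].id
        for parent in parents[:1]:  # one transcript per gene in this pipeline
            for ex in db.children(parent, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))
            for c in db.children(parent, featuretype="CDS", order_by="start"):
                cds.append((c.start - 1, c.end))
        models.append(
            GeneModel(
                gene_id=gene.id,
                seq_name=gene.seqid,
                strand=gene.strand,
                exons=sorted(exons),
                cds=sorted(cds),
                protein_id=protein_id or gene.id,
            )
        )
    models.sort(key=lambda m: (m.seq_name, m.span))
    if not sequences:
        for m in models:
            sequences[m.seq_name] = max(sequences.get(m.seq_name, 0), m.span[1])
    return GenomeAnnotation(sequences=sequences, genes=models, assembly_name=os.path.basename(path))


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.sequences.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            lo, hi = g.span
            fh.write(
                f"{g.seq_name}\tchordevo\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = g.protein_id or f"{g.gene_id}.t1"
            fh.write(
                f"{g.seq_name}\tchordevo\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.seq_name}\tchordevo\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={mid}\n"
                )
            for a, b in g.cds:
                fh.write(
                    f"{g.seq_name}\tchordevo\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={mid}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# Pairwise alignments: MAF and axt
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def read_pairwise_alignment(path: str, format: str = "maf") -> AlignmentBlockSet:
    """Read pairwise alignment blocks from MAF or axt.

    Blocks are normalised so that reference coordinates ascend; a query on
    the minus strand keeps forward-strand coordinates and strand '-'.
    """
    if format == "maf":
        return _read_maf(path)
    if format == "axt":
        return _read_axt(path)
    raise ValueError(f"unknown pairwise alignment format {format!r}")


def _read_maf(path: str) -> AlignmentBlockSet:
    blocks = []
    ref_name = qry_name = ""
    for aln in AlignIO.parse(path, "maf"):
        if len(aln) != 2:
            raise ValueError(f"MAF block with {len(aln)} species; expected pairwise")
        ref, qry = aln[0], aln[1]

        def forward(rec):
            start = rec.annotations["start"]
            size = rec.annotations["size"]
            strand = "+" if rec.annotations["strand"] == 1 else "-"
            src_size = rec.annotations["srcSize"]
            if strand == "-":
                start = src_size - start - size
            return rec.id.split(".")[0], start, start + size, strand

        r_seq, r_start, r_end, r_strand = forward(ref)
        q_seq, q_start, q_end, q_strand = forward(qry)
        r_text, q_text = str(ref.seq), str(qry.seq)
        if r_strand == "-":  # flip both so ref ascends
            r_text, q_text = _revcomp(r_text), _revcomp(q_text)
            q_strand = "+" if q_strand == "-" else "-"
        ref_name, qry_name = r_seq, q_seq
        blocks.append(
            AlignmentBlock(r_seq, r_start, r_end, q_seq, q_start, q_end, q_strand, r_text, q_text)
        )
    return AlignmentBlockSet(blocks=blocks, source_pair=(ref_name, qry_name))


def write_maf(blocks: AlignmentBlockSet, path: str, src_sizes: dict[str, int] | None = None) -> None:
    sizes = src_sizes or {}
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            r_size = sizes.get(b.ref_seq, b.ref_end)
            q_size = sizes.get(b.query_seq, b.query_end)
            fh.write(
                f"s {b.ref_seq} {b.ref_start} {b.ref_end - b.ref_start} + {r_size} {b.ref_text}\n"
            )
            if b.query_strand == "+":
                q_start, q_text = b.query_start, b.query_text
            else:
                q_start = q_size - b.query_end
                q_text = b.query_text
            fh.write(
                f"s {b.query_seq} {q_start} {b.query_end - b.query_start} "
                f"{b.query_strand} {q_size} {q_text}\n"
            )
            fh.write("\n")


def _read_axt(path: str) -> AlignmentBlockSet:
    blocks = []
    ref_name = qry_name = ""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        if len(header) < 9:
            raise ValueError(f"malformed axt header: {lines[i]!r}")
        _, r_seq, r_start, r_end, q_seq, q_start, q_end, q_strand, _score = header[:9]
        r_text, q_text = lines[i + 1], lines[i + 2]
        i += 3
        r_s, r_e, q_s, q_e = int(r_start) - 1, int(r_end), int(q_start) - 1, int(q_end)
        # axt minus-strand query coordinates refer to the reverse strand;
        # without srcSize in the file they cannot be projected, so axt inputs
        # must carry forward coordinates in a trailing column (size) if '-'.
        if q_strand == "-" and len(header) >= 10:
            q_size = int(header[9])
            q_s, q_e = q_size - q_e, q_size - q_s
        ref_name, qry_name = r_seq, q_seq
        blocks.append(AlignmentBlock(r_seq, r_s, r_e, q_seq, q_s, q_e, q_strand, r_text, q_text))
    return AlignmentBlockSet(blocks=blocks, source_pair=(ref_name, qry_name))


# ---------------------------------------------------------------------------
# BED / newick / tables
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED4 as (seq, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            seq, start, end = cols[0], int(cols[1]), int(cols[2])
            if end < start:
                raise ValueError(f"BED interval end {end} < start {start} on {seq}")
            name = cols[3] if len(cols) > 3 else ""
            out.append((seq, start, end, name))
    return out


def write_bed(intervals: Sequence[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            seq, start, end = iv[0], iv[1], iv[2]
            if end < start:
                raise ValueError(f"BED interval end {end} < start {start} on {seq}")
            name = iv[3] if len(iv) > 3 else ""
            fh.write(f"{seq}\t{start}\t{end}" + (f"\t{name}" if name != "" else "") + "\n")


def read_newick(path: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    tree.is_rooted = True
    return tree


def read_table(path: str, schema: str) -> pd.DataFrame:
    """Read a TSV with one of the known schemas: hits, domains, methylation."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}; known: {sorted(_SCHEMAS)}")
    columns = _SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(columns):
        missing = columns[df.shape[1]:]
        raise ValueError(f"table {path} missing columns: {missing}")
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    if schema == "hits":
        bad = df[(df.percent_identity < 0) | (df.percent_identity > 100)]
        if len(bad):
            raise ValueError("percent_identity outside [0,100]")
        if (df.e_value < 0).any():
            raise ValueError("negative e_value")
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
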