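"""Synthetic genome evolution: ancestor construction, lineage evolution,
diploid individuals, and truth tables for every estimator in the pipeline.

The simulator builds an ancestral annotated genome (multi-exon genes with
domain architectures, planted intergenic conserved elements) and evolves
descendant lineages with the event classes the pipeline measures:
Jukes-Cantor substitutions, inversions, translocations, exon shuffles with a
tunable 1-1 intron-phase preference, domain-pair gain/loss, optional
whole-genome duplication, and conserved-element decay. Every stochastic
choice is driven by a single seed; identical seeds give identical bundles,
and replaying the emitted event log on the ancestor reproduces the
descendant exactly.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .models import AlignmentBlock, AlignmentBlockSet, GeneModel, GenomeAnnotation
from .io import DOMAIN_COLUMNS, HIT_COLUMNS

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
MAX_EXONS = 30  # truncation point of the exon-count geometric


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Ancestor-genome parameters.

    Length distributions are lognormal, given as (mean, sigma) of log-length.
    Defaults give exon medians ~150 bp, introns ~300 bp, intergenic ~1 kb --
    compact invertebrate-genome scale.
    """

    n_genes: int = 100
    exons_per_gene: float = 5.0  # mean of the truncated geometric
    exon_len: tuple[float, float] = (5.0, 0.4)
    intron_len: tuple[float, float] = (5.7, 0.5)
    intergenic_len: tuple[float, float] = (6.9, 0.6)
    n_chromosomes: int = 4
    n_cne_planted: int = 50
    cne_len_range: tuple[int, int] = (80, 400)
    domain_vocab_size: int = 40
    mean_domains_per_gene: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cne_planted, self.domain_vocab_size) < 0:
            raise ValueError("counts must be >= 0")
        if self.exons_per_gene < 1:
            raise ValueError("exons_per_gene must be >= 1")


@dataclass
class LineageParams:
    subst_rate: float = 0.05
    n_inversions: int = 0
    n_translocations: int = 0
    n_exon_shuffles: int = 0
    phase11_preference: float = 0.0  # beta: P(shuffle uses a 1-1 exon)
    domain_pair_gain: int = 0
    domain_pair_loss: int = 0
    wgd: bool = False
    cne_decay: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase11_preference <= 1.0:
            raise ValueError("phase11_preference must be in [0,1]")
        if self.subst_rate < 0 or self.cne_decay < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class DiploidParams:
    snp_rate: float = 0.0439
    small_indel_rate: float = 0.0098
    small_indel_mean: float = 8.0  # geometric mean, truncated at 300 bp
    large_indel_count: int = 0
    large_indel_range: tuple[int, int] = (301, 10000)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.snp_rate, self.small_indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")


# ---------------------------------------------------------------------------
# Genome representation
# ---------------------------------------------------------------------------

@dataclass
class SimExon:
    exon_id: str
    seq: str  # coding-strand CDS sequence


@dataclass
class SimCne:
    cne_id: str
    offset: int
    length: int


@dataclass
class SimGene:
    gene_id: str
    strand: int  # +1 / -1 relative to the chromosome forward strand
    exons: list[SimExon]
    introns: list[str]  # coding-strand, between consecutive exons
    domains: list[tuple[str, int, int]] = field(default_factory=list)  # aa coords
    phases_truth: list[int] = field(default_factory=list)  # boundary phases 5'->3'
    modified: bool = False  # structure touched by a shuffle

    @property
    def cds_length(self) -> int:
        return sum(len(e.seq) for e in self.exons)

    def coding_strand_seq(self) -> str:
        parts = [self.exons[0].seq]
        for intron, exon in zip(self.introns, self.exons[1:]):
            parts.append(intron)
            parts.append(exon.seq)
        return "".join(parts)

    def protein(self) -> str:
        from Bio.Seq import Seq

        cds = "".join(e.seq for e in self.exons)
        return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


@dataclass
class Intergenic:
    unit_id: str
    seq: str
    cnes: list[SimCne] = field(default_factory=list)
    flipped: bool = False


Unit = object  # SimGene | Intergenic


@dataclass
class SimGenome:
    chromosomes: list[tuple[str, list]]  # (name, [units])
    name: str = "ancestor"

    def genes(self) -> list[SimGene]:
        return [u for _, units in self.chromosomes for u in units if isinstance(u, SimGene)]

    def gene(self, gene_id: str) -> SimGene:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def find_unit(self, unit_id: str):
        for ci, (_, units) in enumerate(self.chromosomes):
            for ui, u in enumerate(units):
                uid = u.gene_id if isinstance(u, SimGene) else u.unit_id
                if uid == unit_id:
                    return ci, ui, u
        raise KeyError(unit_id)

    # -- rendering to standard data structures ------------------------------

    def render(self):
        """Render to (GenomeAnnotation, sequences, domain table, CNE list).

        CNE list entries are (seq_name, start, end, cne_id).
        """
        sequences: dict[str, str] = {}
        genes: list[GeneModel] = []
        cnes: list[tuple[str, int, int, str]] = []
        domain_rows = []
        for chrom_name, units in self.chromosomes:
            pos = 0
            parts: list[str] = []
            for u in units:
                if isinstance(u, Intergenic):
                    parts.append(u.seq)
                    for c in u.cnes:
                        cnes.append((chrom_name, pos + c.offset, pos + c.offset + c.length, c.cne_id))
                    pos += len(u.seq)
                else:
                    gseq = u.coding_strand_seq()
                    out_seq = gseq if u.strand > 0 else _revcomp(gseq)
                    # exon intervals in coding-strand coordinates
                    ivs = []
                    off = 0
                    for i, ex in enumerate(u.exons):
                        ivs.append((off, off + len(ex.seq)))
                        off += len(ex.seq)
                        if i < len(u.introns):
                            off += len(u.introns[i])
                    glen = len(gseq)
                    if u.strand > 0:
                        abs_ivs = [(pos + a, pos + b) for a, b in ivs]
                    else:
                        abs_ivs = sorted((pos + glen - b, pos + glen - a) for a, b in ivs)
                    genes.append(
                        GeneModel(
                            gene_id=u.gene_id,
                            seq_name=chrom_name,
                            strand="+" if u.strand > 0 else "-",
                            exons=abs_ivs,
                            cds=abs_ivs,
                            protein_id=u.gene_id + ".p1",
                            complete=(u.cds_length % 3 == 0),
                        )
                    )
                    for dtype, a, b in u.domains:
                        domain_rows.append((u.gene_id + ".p1", dtype, a, b, 1e-10))
                    parts.append(out_seq)
                    pos += glen
            sequences[chrom_name] = "".join(parts)
        annotation = GenomeAnnotation(
            sequences={k: len(v) for k, v in sequences.items()},
            genes=genes,
            assembly_name=self.name,
        )
        domain_table = pd.DataFrame(domain_rows, columns=DOMAIN_COLUMNS)
        return annotation, sequences, domain_table, cnes

    def proteins(self) -> dict[str, str]:
        return {g.gene_id + ".p1": g.protein() for g in self.genes()}

    def gene_order(self):
        """Signed gene order per chromosome, for DCJ computations."""
        from .rearrangement import GeneOrder

        chroms = []
        for name, units in self.chromosomes:
            markers = [
                (u.gene_id, u.strand) for u in units if isinstance(u, SimGene)
            ]
            if markers:
                chroms.append(("linear", markers))
        return GeneOrder(chroms)

    def exon_order(self):
        """Signed CDS-exon order per chromosome (exons as markers)."""
        from .rearrangement import GeneOrder

        chroms = []
        for name, units in self.chromosomes:
            markers = []
            for u in units:
                if not isinstance(u, SimGene):
                    continue
                exons = u.exons if u.strand > 0 else list(reversed(u.exons))
                markers.extend((ex.exon_id, u.strand) for ex in exons)
            if markers:
                chroms.append(("linear", markers))
        return GeneOrder(chroms)

    def exon_sequences(self) -> dict[str, str]:
        return {ex.exon_id: ex.seq for g in self.genes() for ex in g.exons}

    def exon_to_gene(self) -> dict[str, str]:
        return {ex.exon_id: g.gene_id for g in self.genes() for ex in g.exons}

    def exon_positions(self) -> dict[str, tuple[str, int, int]]:
        """Genomic interval of each CDS exon."""
        out = {}
        for chrom_name, units in self.chromosomes:
            pos = 0
            for u in units:
                if isinstance(u, Intergenic):
                    pos += len(u.seq)
                    continue
                glen = len(u.coding_strand_seq())
                off = 0
                for i, ex in enumerate(u.exons):
                    a, b = off, off + len(ex.seq)
                    if u.strand > 0:
                        out[ex.exon_id] = (chrom_name, pos + a, pos + b)
                    else:
                        out[ex.exon_id] = (chrom_name, pos + glen - b, pos + glen - a)
                    off += len(ex.seq)
                    if i < len(u.introns):
                        off += len(u.introns[i])
                pos += glen
        return out


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, mean: float) -> int:
    p = 1.0 / mean
    while True:
        k = rng.geometric(p)
        if k <= MAX_EXONS:
            return int(k)


def _lognormal_len(rng: np.random.Generator, mu_sigma: tuple[float, float], minimum: int) -> int:
    mu, sigma = mu_sigma
    return max(minimum, int(round(float(rng.lognormal(mu, sigma)))))


def _make_gene(rng: np.random.Generator, params: SimulationParams, gene_id: str) -> SimGene:
    n_exons = _truncated_geometric(rng, params.exons_per_gene)
    phases = [int(rng.integers(0, 3)) for _ in range(n_exons - 1)]
    lengths = []
    cum = 0
    for i in range(n_exons):
        want = _lognormal_len(rng, params.exon_len, 12)
        if i < n_exons - 1:
            target = phases[i]
        else:
            target = 0  # total CDS divisible by 3
        adjust = (target - (cum + want)) % 3
        length = want + adjust
        lengths.append(length)
        cum += length
    total_codons = cum // 3
    cds = _random_codons(rng, total_codons)
    exons, off = [], 0
    for i, length in enumerate(lengths):
        exons.append(SimExon(exon_id=f"{gene_id}.e{i + 1}", seq=cds[off: off + length]))
        off += length
    introns = [
        _random_seq(rng, _lognormal_len(rng, params.intron_len, 30))
        for _ in range(n_exons - 1)
    ]
    # domain architecture over the protein
    n_aa = cum // 3
    n_domains = min(int(rng.poisson(params.mean_domains_per_gene)), 3)
    domains: list[tuple[str, int, int]] = []
    cursor = 1
    for _ in range(n_domains):
        if n_aa - cursor < 25:
            break
        dlen = int(rng.integers(20, min(100, n_aa - cursor)))
        start = cursor + int(rng.integers(0, max(1, (n_aa - cursor - dlen) // max(1, n_domains))))
        dtype = f"D{int(rng.integers(0, params.domain_vocab_size)):03d}"
        domains.append((dtype, start, start + dlen))
        cursor = start + dlen + 2
    return SimGene(
        gene_id=gene_id,
        strand=1 if rng.random() < 0.5 else -1,
        exons=exons,
        introns=introns,
        domains=domains,
        phases_truth=phases,
    )


def build_ancestor(params: SimulationParams) -> SimGenome:
    """Build the ancestral genome; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n_chrom = max(1, params.n_chromosomes)
    chrom_units: list[list] = [[] for _ in range(n_chrom)]
    ig_counter = 0

    def new_intergenic() -> Intergenic:
        nonlocal ig_counter
        ig_counter += 1
        return Intergenic(
            unit_id=f"ig{ig_counter:05d}",
            seq=_random_seq(rng, _lognormal_len(rng, params.intergenic_len, 200)),
        )

    for c in range(n_chrom):
        chrom_units[c].append(new_intergenic())
    for i in range(params.n_genes):
        c = i % n_chrom
        chrom_units[c].append(_make_gene(rng, params, f"g{i + 1:05d}"))
        chrom_units[c].append(new_intergenic())

    genome = SimGenome(
        chromosomes=[(f"chr{c + 1}", units) for c, units in enumerate(chrom_units)],
        name="ancestor",
    )
    # plant CNEs in intergenic units, outside each other
    intergenics = [u for _, units in genome.chromosomes for u in units if isinstance(u, Intergenic)]
    planted = 0
    attempts = 0
    while planted < params.n_cne_planted:
        attempts += 1
        if attempts > 100 * max(1, params.n_cne_planted):
            raise ValueError("cannot place requested CNEs: intergenic space too small")
        u = intergenics[int(rng.integers(0, len(intergenics)))]
        lo, hi = params.cne_len_range
        length = int(rng.integers(lo, hi + 1))
        margin = 50  # keep planted elements clear of flanking coding sequence
        if len(u.seq) < length + 2 * margin + 1:
            continue
        offset = int(rng.integers(margin, len(u.seq) - length - margin))
        if any(offset < c.offset + c.length and c.offset < offset + length for c in u.cnes):
            continue
        planted += 1
        u.cnes.append(SimCne(cne_id=f"cne{planted:05d}", offset=offset, length=length))
    return genome


# ---------------------------------------------------------------------------
# Events and lineage evolution
# ---------------------------------------------------------------------------

@dataclass
class Event:
    kind: str
    data: dict

    def to_json(self) -> dict:
        return {"kind": self.kind, **self.data}


class EventLog(list):
    """Ordered event records; replaying them on the ancestor reproduces the
    descendant exactly."""

    def count(self, kind: str) -> int:  # type: ignore[override]
        return sum(1 for e in self if e.kind == kind)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([e.to_json() for e in self], fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "EventLog":
        with open(path) as fh:
            raw = json.load(fh)
        log = cls()
        for item in raw:
            kind = item.pop("kind")
            log.append(Event(kind, item))
        return log


def apply_event(genome: SimGenome, event: Event) -> None:
    """Apply one event in place. Used both by evolve_lineage and by replay."""
    d = event.data
    if event.kind == "wgd":
        new_chroms = []
        for copy_idx in (1, 2):
            for name, units in genome.chromosomes:
                dup = []
                for u in copy.deepcopy(units):
                    if isinstance(u, SimGene):
                        u.gene_id = f"{u.gene_id}~{copy_idx}"
                        for ex in u.exons:
                            ex.exon_id = f"{ex.exon_id}~{copy_idx}"
                    else:
                        u.unit_id = f"{u.unit_id}~{copy_idx}"
                        for c in u.cnes:
                            c.cne_id = f"{c.cne_id}~{copy_idx}"
                    dup.append(u)
                new_chroms.append((f"{name}~{copy_idx}", dup))
        genome.chromosomes = new_chroms
    elif event.kind == "inversion":
        name, units = genome.chromosomes[d["chrom"]]
        i, j = d["start"], d["end"]
        seg = units[i:j][::-1]
        for u in seg:
            if isinstance(u, SimGene):
                u.strand = -u.strand
            else:
                n = len(u.seq)
                u.seq = _revcomp(u.seq)
                u.cnes = [
                    SimCne(c.cne_id, n - c.offset - c.length, c.length) for c in u.cnes
                ]
                u.flipped = not u.flipped
        units[i:j] = seg
    elif event.kind == "translocation":
        src_name, src_units = genome.chromosomes[d["src_chrom"]]
        seg = src_units[d["start"]: d["end"]]
        del src_units[d["start"]: d["end"]]
        _, dst_units = genome.chromosomes[d["dst_chrom"]]
        at = d["insert_at"]
        dst_units[at:at] = seg
    elif event.kind == "exon_shuffle":
        donor = genome.gene(d["donor_gene"])
        k = d["exon_index"]  # internal index, 0-based into exons
        exon = donor.exons.pop(k)
        merged = donor.introns[k - 1] + donor.introns[k]
        donor.introns[k - 1: k + 1] = [merged]
        donor.phases_truth = []  # constructed phases no longer hold downstream
        donor.modified = True
        recipient = genome.gene(d["recipient_gene"])
        intron_idx = d["intron_index"]
        split_at = d["split_at"]
        intron = recipient.introns[intron_idx]
        recipient.introns[intron_idx: intron_idx + 1] = [
            intron[:split_at],
            intron[split_at:],
        ]
        recipient.exons.insert(intron_idx + 1, exon)
        recipient.phases_truth = []  # no longer the constructed phases
        recipient.modified = True
    elif event.kind == "domain_gain":
        gene = genome.gene(d["gene"])
        gene.domains.append((d["domain_type"], d["aa_start"], d["aa_end"]))
        gene.domains.sort(key=lambda t: t[1])
    elif event.kind == "domain_loss":
        gene = genome.gene(d["gene"])
        gene.domains = [
            dom for dom in gene.domains if list(dom) != [d["domain_type"], d["aa_start"], d["aa_end"]]
        ]
    elif event.kind == "cne_loss":
        _, _, u = genome.find_unit(d["unit"])
        for c in u.cnes:
            if c.cne_id == d["cne_id"]:
                u.seq = u.seq[: c.offset] + d["replacement"] + u.seq[c.offset + c.length:]
                u.cnes.remove(c)
                break
    elif event.kind == "substitutions":
        rng = np.random.default_rng(d["seed"])
        rate = d["rate"]
        for _, units in genome.chromosomes:
            for u in units:
                if isinstance(u, SimGene):
                    for ex in u.exons:
                        ex.seq = _substitute(rng, ex.seq, rate)
                    u.introns = [_substitute(rng, s, rate) for s in u.introns]
                else:
                    u.seq = _substitute(rng, u.seq, rate)
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if not seq or rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return seq
    # uniform choice among the three alternative bases (Jukes-Cantor)
    base_index = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    shifts = rng.integers(1, 4, len(idx))
    lut = np.array([b"A", b"C", b"G", b"T"])
    for j, i in enumerate(idx):
        cur = base_index.get(arr[i].upper(), 0)
        arr[i] = lut[(cur + shifts[j]) % 4]
    return arr.tobytes().decode()


def evolve_lineage(
    ancestor: SimGenome, params: LineageParams, seed: int, name: str = "descendant"
) -> tuple[SimGenome, EventLog]:
    """Evolve a copy of the ancestor; returns (descendant, event log)."""
    rng = np.random.default_rng(seed)
    genome = copy.deepcopy(ancestor)
    genome.name = name
    log = EventLog()

    def emit(kind: str, **data) -> None:
        ev = Event(kind, data)
        apply_event(genome, ev)
        log.append(ev)

    if params.wgd:
        emit("wgd")

    for _ in range(params.n_inversions):
        eligible = [ci for ci, (_, units) in enumerate(genome.chromosomes) if len(units) >= 2]
        ci = eligible[int(rng.integers(0, len(eligible)))]
        n = len(genome.chromosomes[ci][1])
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n + 1))
        emit("inversion", chrom=ci, start=i, end=j)

    for _ in range(params.n_translocations):
        if len(genome.chromosomes) < 2:
            raise ValueError("translocations need >= 2 chromosomes")
        src = int(rng.integers(0, len(genome.chromosomes)))
        while len(genome.chromosomes[src][1]) == 0:
            src = int(rng.integers(0, len(genome.chromosomes)))
        n = len(genome.chromosomes[src][1])
        i = int(rng.integers(0, n))
        j = int(rng.integers(i + 1, min(n, i + 5) + 1))
        dst = int(rng.integers(0, len(genome.chromosomes)))
        while dst == src:
            dst = int(rng.integers(0, len(genome.chromosomes)))
        at = int(rng.integers(0, len(genome.chromosomes[dst][1]) + 1))
        emit("translocation", src_chrom=src, start=i, end=j, dst_chrom=dst, insert_at=at)

    for _ in range(params.n_exon_shuffles):
        donors = [g for g in genome.genes() if len(g.exons) >= 3]
        if not donors:
            raise ValueError("exon shuffles requested but no gene has internal exons")
        use_11 = rng.random() < params.phase11_preference
        choice = None
        if use_11:
            cands = []
            for g in donors:
                cum = 0
                lens = [len(e.seq) for e in g.exons]
                for k in range(1, len(g.exons) - 1):
                    p5 = sum(lens[:k]) % 3
                    p3 = sum(lens[: k + 1]) % 3
                    if p5 == 1 and p3 == 1:
                        cands.append((g, k))
            if cands:
                choice = cands[int(rng.integers(0, len(cands)))]
        if choice is None:
            g = donors[int(rng.integers(0, len(donors)))]
            k = int(rng.integers(1, len(g.exons) - 1))
            choice = (g, k)
        donor, k = choice
        lens = [len(e.seq) for e in donor.exons]
        p5, p3 = sum(lens[:k]) % 3, sum(lens[: k + 1]) % 3
        recipients = [
            g for g in genome.genes() if g.gene_id != donor.gene_id and len(g.exons) >= 2
        ]
        recipient = recipients[int(rng.integers(0, len(recipients)))]
        intron_idx = int(rng.integers(0, len(recipient.introns)))
        intron_len = len(recipient.introns[intron_idx])
        split_at = int(rng.integers(1, max(2, intron_len)))
        emit(
            "exon_shuffle",
            donor_gene=donor.gene_id,
            exon_index=k,
            exon_id=donor.exons[k].exon_id,
            donor_phases=[int(p5), int(p3)],
            recipient_gene=recipient.gene_id,
            intron_index=intron_idx,
            split_at=split_at,
        )

    for _ in range(params.domain_pair_gain):
        with_dom = [g for g in genome.genes() if g.domains]
        g = with_dom[int(rng.integers(0, len(with_dom)))]
        new_type = f"D{int(rng.integers(0, 10_000)):05d}n"
        # append after the architecture's last domain so the insertion never
        # collides with an existing interval
        anchor = max(g.domains, key=lambda d: d[2])
        emit(
            "domain_gain",
            gene=g.gene_id,
            domain_type=new_type,
            aa_start=anchor[2] + 2,
            aa_end=anchor[2] + 2 + max(10, anchor[2] - anchor[1]),
        )

    for _ in range(params.domain_pair_loss):
        with_multi = [g for g in genome.genes() if len(g.domains) >= 2]
        if not with_multi:
            break
        g = with_multi[int(rng.integers(0, len(with_multi)))]
        dom = g.domains[int(rng.integers(0, len(g.domains)))]
        emit("domain_loss", gene=g.gene_id, domain_type=dom[0], aa_start=dom[1], aa_end=dom[2])

    if params.cne_decay > 0:
        for _, units in list(genome.chromosomes):
            for u in units:
                if isinstance(u, Intergenic):
                    for c in list(u.cnes):
                        if rng.random() < params.cne_decay:
                            emit(
                                "cne_loss",
                                unit=u.unit_id,
                                cne_id=c.cne_id,
                                replacement=_random_seq(rng, c.length),
                            )

    if params.subst_rate > 0:
        emit("substitutions", rate=params.subst_rate, seed=int(rng.integers(0, 2**31 - 1)))

    return genome, log


def replay(ancestor: SimGenome, log: EventLog, name: str = "replayed") -> SimGenome:
    genome = copy.deepcopy(ancestor)
    genome.name = name
    for ev in log:
        apply_event(genome, ev)
    return genome


def orthology_truth(desc_a: SimGenome, desc_b: SimGenome) -> list[tuple[str, str]]:
    """Truth 1:1 pairs between two descendants, matched by ancestral gene id.

    After a whole-genome duplication on one side, each ancestral gene maps
    to two copies; the first copy (by id) is taken as the 1:1 representative.
    """

    def base_map(genome: SimGenome) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in sorted(genome.genes(), key=lambda g: g.gene_id):
            base = g.gene_id.split("~")[0]
            out.setdefault(base, g.gene_id)
        return out

    ma, mb = base_map(desc_a), base_map(desc_b)
    return [(ma[k], mb[k]) for k in sorted(set(ma) & set(mb))]


# ---------------------------------------------------------------------------
# Truth-derived pairwise alignment between two descendants
# ---------------------------------------------------------------------------

def truth_alignment(desc_a: SimGenome, desc_b: SimGenome) -> AlignmentBlockSet:
    """Gap-free alignment blocks between two descendants derived from shared
    ancestry, emulating what a reciprocal-best whole-genome aligner retains:
    one block per conserved element shared by both lineages, plus per-exon
    and per-intron blocks of genes structurally untouched in both lineages.
    Neutral intergenic background is treated as having diverged beyond
    alignability and is not emitted.
    """

    def unit_index(genome: SimGenome):
        ann, seqs, _, _ = genome.render()
        idx = {}
        for chrom_name, units in genome.chromosomes:
            pos = 0
            for u in units:
                if isinstance(u, Intergenic):
                    base = u.unit_id.split("~")[0]
                    entry = ("ig", chrom_name, pos, len(u.seq), u.flipped, u)
                    idx.setdefault(base, entry)
                    pos += len(u.seq)
                else:
                    base = u.gene_id.split("~")[0]
                    glen = len(u.coding_strand_seq())
                    idx.setdefault(base, ("gene", chrom_name, pos, glen, u.strand < 0, u))
                    pos += glen
        return idx, seqs

    idx_a, seqs_a = unit_index(desc_a)
    idx_b, seqs_b = unit_index(desc_b)
    blocks: list[AlignmentBlock] = []

    def emit(chrom_a, a0, a1, chrom_b, b0, b1, strand):
        ref_text = seqs_a[chrom_a][a0:a1]
        q_fwd = seqs_b[chrom_b][b0:b1]
        blocks.append(
            AlignmentBlock(
                chrom_a, a0, a1, chrom_b, b0, b1, strand,
                ref_text, q_fwd if strand == "+" else _revcomp(q_fwd),
            )
        )

    for base in sorted(set(idx_a) & set(idx_b)):
        kind_a, chrom_a, pos_a, len_a, flip_a, ua = idx_a[base]
        kind_b, chrom_b, pos_b, len_b, flip_b, ub = idx_b[base]
        if kind_a != kind_b or len_a != len_b:
            continue
        strand = "+" if flip_a == flip_b else "-"
        if kind_a == "gene":
            if ua.modified or ub.modified:
                continue
            emit(chrom_a, pos_a, pos_a + len_a, chrom_b, pos_b, pos_b + len_b, strand)
        else:
            # conserved elements shared by both lineages (matched by id)
            cnes_b = {c.cne_id.split("~")[0]: c for c in ub.cnes}
            for ca in sorted(ua.cnes, key=lambda c: c.offset):
                cb = cnes_b.get(ca.cne_id.split("~")[0])
                if cb is None or cb.length != ca.length:
                    continue
                a0, a1 = pos_a + ca.offset, pos_a + ca.offset + ca.length
                b0, b1 = pos_b + cb.offset, pos_b + cb.offset + cb.length
                emit(chrom_a, a0, a1, chrom_b, b0, b1, strand)
    return AlignmentBlockSet(blocks=blocks, source_pair=(desc_a.name, desc_b.name))


# ---------------------------------------------------------------------------
# Diploid individual
# ---------------------------------------------------------------------------

def make_diploid(sequences: dict[str, str], params: DiploidParams):
    """Plant SNPs and indels onto a second haplotype.

    Returns (haplotype_a, haplotype_b, truth variant DataFrame, alignment).
    Haplotype A is the input; B carries the planted variants. The alignment
    between the haplotypes is exact by construction.
    """
    rng = np.random.default_rng(params.seed)
    total_len = sum(len(s) for s in sequences.values())
    expected = total_len * (params.snp_rate + params.small_indel_rate)
    if params.snp_rate + params.small_indel_rate > 0.5:
        raise ValueError("requested variant density impossible to place")

    hap_b: dict[str, str] = {}
    rows = []
    blocks = []
    for chrom, seq in sequences.items():
        n = len(seq)
        # pre-place large indels, non-overlapping by rejection sampling
        large: dict[int, tuple[str, int]] = {}
        share = round(params.large_indel_count * n / total_len) if total_len else 0
        taken: list[tuple[int, int]] = []
        tries = 0
        while len(large) < share:
            tries += 1
            if tries > 1000 * max(1, share):
                raise ValueError("cannot place requested large indels")
            size = int(rng.integers(params.large_indel_range[0], params.large_indel_range[1] + 1))
            pos = int(rng.integers(0, max(1, n - size)))
            if any(pos < e and s < pos + size for s, e in taken):
                continue
            kind = "del" if rng.random() < 0.5 else "ins"
            large[pos] = (kind, size)
            taken.append((pos, pos + size if kind == "del" else pos + 1))

        a_parts: list[str] = []
        b_parts: list[str] = []
        b_seq_parts: list[str] = []
        i = 0
        b_pos = 0
        while i < n:
            if i in large:
                kind, size = large.pop(i)
                if kind == "del":
                    a_parts.append(seq[i: i + size])
                    b_parts.append("-" * size)
                    rows.append(("large_indel", chrom, i, i + size, size, "del"))
                    i += size
                else:
                    ins = _random_seq(rng, size)
                    a_parts.append("-" * size)
                    b_parts.append(ins)
                    b_seq_parts.append(ins)
                    rows.append(("large_indel", chrom, i, i, size, "ins"))
                    b_pos += size
                continue
            r = rng.random()
            if r < params.small_indel_rate:
                size = _small_indel_size(rng, params)
                if rng.random() < 0.5 and i + size <= n:  # deletion in B
                    a_parts.append(seq[i: i + size])
                    b_parts.append("-" * size)
                    rows.append(("small_indel", chrom, i, i + size, size, "del"))
                    i += size
                else:  # insertion in B
                    ins = _random_seq(rng, size)
                    a_parts.append("-" * size)
                    b_parts.append(ins)
                    b_seq_parts.append(ins)
                    rows.append(("small_indel", chrom, i, i, size, "ins"))
                    b_pos += size
                continue
            base = seq[i]
            if r < params.small_indel_rate + params.snp_rate:
                alt = "ACGT"[("ACGT".index(base) + int(rng.integers(1, 4))) % 4]
                rows.append(("snp", chrom, i, i + 1, 1, f"{base}>{alt}"))
                b_parts.append(alt)
                b_seq_parts.append(alt)
            else:
                b_parts.append(base)
                b_seq_parts.append(base)
            a_parts.append(base)
            b_pos += 1
            i += 1
        a_text = "".join(a_parts)
        b_text = "".join(b_parts)
        hap_b[chrom] = "".join(b_seq_parts)
        blocks.append(
            AlignmentBlock(
                chrom, 0, n, chrom, 0, len(hap_b[chrom]), "+", a_text, b_text
            )
        )
    truth = pd.DataFrame(
        rows, columns=["type", "seq", "ref_start", "ref_end", "length", "change"]
    )
    return dict(sequences), hap_b, truth, AlignmentBlockSet(blocks, ("hapA", "hapB"))


def _small_indel_size(rng: np.random.Generator, params: DiploidParams) -> int:
    while True:
        size = int(rng.geometric(1.0 / params.small_indel_mean))
        if size <= 300:
            return size


# ---------------------------------------------------------------------------
# Similarity tables (emulating consumed BLAST tabular input)
# ---------------------------------------------------------------------------

def _kmer_set(s: str, k: int) -> set[str]:
    return {s[i: i + k] for i in range(0, len(s) - k + 1)}


def hit_table(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    min_identity: float = 30.0,
    kmer_prefilter: int | None = None,
) -> pd.DataFrame:
    """All-against-all similarity table (blast outfmt-6 columns) computed by
    global alignment (edlib). A shared-k-mer prefilter skips clearly unrelated
    pairs; ``kmer_prefilter=None`` disables it.
    """
    import edlib

    rows = []
    kmers_b = (
        {name: _kmer_set(s, kmer_prefilter) for name, s in seqs_b.items()}
        if kmer_prefilter
        else None
    )
    for qa, sa in seqs_a.items():
        ka = _kmer_set(sa, kmer_prefilter) if kmer_prefilter else None
        for qb, sb in seqs_b.items():
            if not sa or not sb:
                continue
            # prefilter only informative for reasonably long sequences
            if (
                kmers_b is not None
                and min(len(sa), len(sb)) >= 8 * kmer_prefilter
                and not (ka & kmers_b[qb])
            ):
                continue
            res = edlib.align(sa, sb, mode="NW", task="distance")
            dist = res["editDistance"]
            aln_len = max(len(sa), len(sb))
            matches = aln_len - dist
            identity = 100.0 * matches / aln_len
            if identity < min_identity:
                continue
            bitscore = 2.0 * matches
            rows.append(
                (
                    qa, qb, round(identity, 2), aln_len, dist, 0,
                    1, len(sa), 1, len(sb), 1e-180, bitscore,
                )
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# Read and methylation simulators for the profiling module
# ---------------------------------------------------------------------------

def simulate_reads(
    partition, class_fractions: dict[str, float], n_reads: int, read_len: int = 80, seed: int = 0
):
    """Sample read intervals whose class composition matches the requested
    fractions: each read is placed fully inside a run of its class."""
    rng = np.random.default_rng(seed)
    runs = {cls: [] for cls in class_fractions}
    for seq_name, labels in partition.labels.items():
        arr = labels
        start = 0
        for i in range(1, len(arr) + 1):
            if i == len(arr) or arr[i] != arr[start]:
                cls = partition.class_names[arr[start]]
                if cls in runs and i - start >= read_len:
                    runs[cls].append((seq_name, start, i))
                start = i
    classes = sorted(class_fractions)
    probs = np.array([class_fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    reads = []
    for _ in range(n_reads):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if not runs[cls]:
            raise ValueError(f"no run of class {cls!r} long enough for reads")
        seq_name, a, b = runs[cls][int(rng.integers(0, len(runs[cls])))]
        start = int(rng.integers(a, b - read_len + 1))
        reads.append((seq_name, start, start + read_len, cls))
    return reads


def simulate_methylation(
    partition, class_means: dict[str, float], n_sites: int, coverage: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Per-site CG methylation calls with planted per-class mean levels."""
    rng = np.random.default_rng(seed)
    positions = {cls: [] for cls in class_means}
    for seq_name, labels in partition.labels.items():
        for cls in class_means:
            code = partition.class_names.index(cls)
            idx = np.nonzero(labels == code)[0]
            if len(idx):
                positions[cls].append((seq_name, idx))
    rows = []
    classes = sorted(class_means)
    for i in range(n_sites):
        cls = classes[i % len(classes)]
        if not positions[cls]:
            continue
        seq_name, idx = positions[cls][int(rng.integers(0, len(positions[cls])))]
        pos = int(idx[int(rng.integers(0, len(idx)))])
        meth = int(rng.binomial(coverage, class_means[cls]))
        rows.append((seq_name, pos, "+", "CG", meth, coverage))
    return pd.DataFrame(rows, columns=["seq", "pos0", "strand", "context", "methylated_reads", "total_reads"])
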