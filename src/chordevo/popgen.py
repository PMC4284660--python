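"""Polymorphism from haplotype alignments: variant calling, rates, spacing
geometry, Nei-Gojobori dN/dS, and effective population size.

The neutral identity theta = 4*Ne*mu links per-site heterozygosity pi to the
effective population size Ne given a per-year mutation rate and generation
time. Inter-variant spacing under random mating is geometric; a chi-square
goodness-of-fit test against the fitted geometric detects clustering.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .models import AlignmentBlockSet

SMALL_INDEL_MAX = 300
LARGE_INDEL_MAX = 10_000

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


# ---------------------------------------------------------------------------
# Variant calling and summaries
# ---------------------------------------------------------------------------

def call_variants(blocks: AlignmentBlockSet) -> pd.DataFrame:
    """Call SNPs and indels column-wise from pairwise alignment blocks.

    SNP = single-column mismatch (adjacent SNPs are not merged); indel =
    maximal gap run, classed small (<=300 bp) or large (300-10,000 bp).
    Block order/orientation breaks are reported as rearrangements.
    """
    ivs = sorted((b.ref_seq, b.ref_start, b.ref_end) for b in blocks)
    for (s1, a1, e1), (s2, a2, e2) in zip(ivs, ivs[1:]):
        if s1 == s2 and a2 < e1:
            raise ValueError(f"overlapping reference blocks at {s1}:{a2}")
    rows = []
    for block in blocks:
        ref_pos = block.ref_start
        i = 0
        r_text, q_text = block.ref_text.upper(), block.query_text.upper()
        n = len(r_text)
        while i < n:
            rc, qc = r_text[i], q_text[i]
            if rc == "-":  # maximal insertion run relative to the reference
                j = i
                while j < n and r_text[j] == "-":
                    j += 1
                size = j - i
                kind = "small_indel" if size <= SMALL_INDEL_MAX else "large_indel"
                rows.append((kind, block.ref_seq, ref_pos, ref_pos, size, "ins"))
                i = j
                continue
            if qc == "-":  # maximal deletion run
                j = i
                while j < n and q_text[j] == "-" and r_text[j] != "-":
                    j += 1
                size = j - i
                kind = "small_indel" if size <= SMALL_INDEL_MAX else "large_indel"
                rows.append((kind, block.ref_seq, ref_pos, ref_pos + size, size, "del"))
                ref_pos += size
                i = j
                continue
            if rc != qc:
                rows.append(("snp", block.ref_seq, ref_pos, ref_pos + 1, 1, f"{rc}>{qc}"))
            ref_pos += 1
            i += 1
    # rearrangements: blocks out of query order or inverted orientation
    by_ref = sorted(blocks, key=lambda b: (b.ref_seq, b.ref_start))
    prev = None
    for b in by_ref:
        if b.query_strand == "-":
            rows.append(("inversion", b.ref_seq, b.ref_start, b.ref_end, b.ref_end - b.ref_start, "strand"))
        if prev is not None and prev.ref_seq == b.ref_seq and prev.query_seq == b.query_seq:
            if b.query_strand == "+" and prev.query_strand == "+" and b.query_start < prev.query_end:
                rows.append(("translocation", b.ref_seq, b.ref_start, b.ref_end, b.ref_end - b.ref_start, "order"))
        prev = b
    return pd.DataFrame(
        rows, columns=["type", "seq", "ref_start", "ref_end", "length", "change"]
    )


@dataclass
class PolymorphismSummary:
    snp_rate: float  # % of aligned (gap-free) columns
    small_indel_event_rate: float  # % events per aligned column
    small_indel_length_fraction: float  # % of genome length
    large_indel_count: int
    large_indel_genome_fraction: float  # % of genome length
    rearranged_fraction: float  # % of genome length


def summarize_polymorphism(
    variants: pd.DataFrame, aligned_length: int, genome_length: int
) -> PolymorphismSummary:
    """Polymorphism rates: SNP and indel-event denominators are aligned
    (gap-free) columns; indel length fractions use genome length."""
    if aligned_length <= 0:
        raise ValueError("aligned length must be > 0")
    snps = variants[variants.type == "snp"]
    small = variants[variants.type == "small_indel"]
    large = variants[variants.type == "large_indel"]
    rearr = variants[variants.type.isin(["inversion", "translocation"])]
    return PolymorphismSummary(
        snp_rate=100.0 * len(snps) / aligned_length,
        small_indel_event_rate=100.0 * len(small) / aligned_length,
        small_indel_length_fraction=100.0 * small.length.sum() / genome_length,
        large_indel_count=len(large),
        large_indel_genome_fraction=100.0 * large.length.sum() / genome_length,
        rearranged_fraction=100.0 * rearr.length.sum() / genome_length,
    )


# ---------------------------------------------------------------------------
# Geometric spacing
# ---------------------------------------------------------------------------

@dataclass
class SpacingFit:
    p_hat: float
    support: str
    statistic: float
    df: int
    p_value: float
    n: int


def variant_spacings(variants: pd.DataFrame) -> np.ndarray:
    """Non-variant run lengths between consecutive variant start positions,
    per sequence."""
    gaps = []
    for _seq, sub in variants.sort_values(["seq", "ref_start"]).groupby("seq"):
        pos = sub.ref_start.to_numpy()
        if len(pos) > 1:
            gaps.append(np.diff(pos) - 1)
    if not gaps:
        return np.array([], dtype=int)
    return np.concatenate(gaps)


def spacing_fit(
    gaps: np.ndarray, support: str = "zero_based", min_expected: float = 5.0
) -> SpacingFit:
    """Geometric MLE and chi-square goodness of fit with tail pooling.

    zero_based: gaps of 0 allowed, p_hat = n/(n + sum g);
    one_based:  support starts at 1, p_hat = 1/mean.
    """
    gaps = np.asarray(gaps, dtype=int)
    n = len(gaps)
    if n < 100:
        raise ValueError("need >= 100 spacing observations")
    if support == "zero_based":
        p_hat = n / (n + gaps.sum())
        pmf = lambda k: p_hat * (1 - p_hat) ** k
        kmin = 0
    elif support == "one_based":
        if (gaps < 1).any():
            raise ValueError("one_based support requires gaps >= 1")
        p_hat = 1.0 / gaps.mean()
        pmf = lambda k: p_hat * (1 - p_hat) ** (k - 1)
        kmin = 1
    else:
        raise ValueError(f"unknown support convention {support!r}")
    if p_hat >= 1.0:
        return SpacingFit(1.0, support, 0.0, 0, 1.0, n)
    # bins: individual k until expected < min_expected, then pooled tail
    edges = []
    k = kmin
    cum = 0.0
    while True:
        e = n * pmf(k)
        if e < min_expected or cum > 0.9999:
            break
        edges.append(k)
        cum += pmf(k)
        k += 1
    if len(edges) < 2:
        raise ValueError("fewer than 3 bins after pooling; spacing too concentrated")
    observed = np.array([np.sum(gaps == k) for k in edges] + [np.sum(gaps > edges[-1])])
    expected = np.array([n * pmf(k) for k in edges] + [n * (1 - p_hat) ** (edges[-1] + 1 - kmin)])
    expected = expected * n / expected.sum() if abs(expected.sum() - n) > 1e-9 else expected
    df = len(observed) - 2  # one estimated parameter
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df))
    return SpacingFit(float(p_hat), support, stat, df, p, n)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) dN/dS
# ---------------------------------------------------------------------------

def _syn_fraction(codon: str, pos: int, table: dict[str, str]) -> float:
    aa = table[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if table[alt] == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str, table: dict[str, str]) -> tuple[float, float]:
    s = sum(_syn_fraction(codon, i, table) for i in range(3))
    return s, 3.0 - s


def _codon_differences(c1: str, c2: str, table: dict[str, str]) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all mutational
    pathways between two codons (equal weighting; pathways through stop
    codons excluded when alternatives exist)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*" and nxt != c2:
                through_stop = True
            if table[cur] == table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, t in paths if not t]
    use = clean if clean else [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


@dataclass
class DnDsResult:
    dn: float
    ds: float
    omega: float | None  # dN/dS; None when dS == 0
    n_codons: int
    pn: float
    ps: float


def dnds_ng86(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei-Gojobori (1986) dN and dS with Jukes-Cantor correction.

    Inputs are in-frame, gap-free codon-aligned CDS of equal length.
    Raises on internal stop codons (callers should skip such pairs).
    """
    table = _codon_table()
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("sequences must be codon-aligned and equal length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    n_codons = len(cds_a) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        c1, c2 = cds_a[3 * i: 3 * i + 3], cds_b[3 * i: 3 * i + 3]
        if table[c1] == "*" or table[c2] == "*":
            if i < n_codons - 1:
                raise ValueError(f"internal stop codon at codon {i + 1}")
            continue
        s1, n1 = _codon_sites(c1, table)
        s2, n2 = _codon_sites(c2, table)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_differences(c1, c2, table)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0

    def jc(p: float) -> float:
        # the correction diverges at p = 3/4; report +inf (saturated)
        if p >= 0.75:
            return float("inf")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ds, dn = jc(ps), jc(pn)
    omega = (dn / ds) if ds > 0 else None
    if math.isinf(ds) and not math.isinf(dn):
        omega = 0.0 if dn == 0 else dn / ds
    return DnDsResult(dn=dn, ds=ds, omega=omega, n_codons=n_codons, pn=pn, ps=ps)


def mean_dnds(pairs) -> tuple[float, float, float]:
    """Genome-wide mean dN, dS and their ratio over codon-aligned pairs;
    pairs raising (stops, saturation) are skipped with a warning."""
    dns, dss = [], []
    for a, b in pairs:
        try:
            r = dnds_ng86(a, b)
        except ValueError as exc:
            warnings.warn(f"pair skipped: {exc}")
            continue
        dns.append(r.dn)
        dss.append(r.ds)
    dn, ds = float(np.mean(dns)), float(np.mean(dss))
    return dn, ds, dn / ds if ds else float("nan")


# ---------------------------------------------------------------------------
# Effective population size and TE attribution
# ---------------------------------------------------------------------------

def effective_population_size(
    pi: float, mu_per_year: float, generation_years: float = 1.0
) -> float:
    """Ne = pi / (4 * mu * g) from theta = 4*Ne*mu per generation."""
    if pi <= 0 or mu_per_year <= 0 or generation_years <= 0:
        raise ValueError("pi, mu and generation time must all be > 0")
    return pi / (4.0 * mu_per_year * generation_years)


def te_attribution(
    variants: pd.DataFrame,
    te_intervals: list[tuple[str, int, int]],
    min_overlap_fraction: float = 0.5,
) -> float:
    """Fraction of large-indel events attributable to transposable elements:
    an event counts as TE-derived when >= ``min_overlap_fraction`` of its
    length overlaps TE intervals."""
    large = variants[variants.type == "large_indel"]
    if len(large) == 0:
        return 0.0
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq, a, b in te_intervals:
        by_seq.setdefault(seq, []).append((a, b))
    n_te = 0
    for _, row in large.iterrows():
        start, end = int(row.ref_start), int(row.ref_end)
        if end == start:  # insertion: judge by insertion point inside a TE
            inside = any(a <= start < b for a, b in by_seq.get(row.seq, []))
            if inside:
                n_te += 1
            continue
        ov = sum(
            max(0, min(end, b) - max(start, a)) for a, b in by_seq.get(row.seq, [])
        )
        if ov >= min_overlap_fraction * (end - start):
            n_te += 1
    return n_te / len(large)
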