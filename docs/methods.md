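# Methods

This note documents the models and procedures implemented in `chordevo`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducing results.

## DCJ distance and rearrangement rates

Genomes are signed gene orders over linear or circular chromosomes. The
double-cut-and-join (DCJ) distance between two genomes restricted to their
shared single-copy markers is computed from the adjacency graph over marker
extremities as `d = N − (C + I/2)`, where `N` is the shared marker count,
`C` the number of cycles and `I` the number of odd paths
(Bergeron–Mixtacki–Stoye). Markers absent from either genome are dropped
before the computation and their counts reported, so rates can be
recomputed under other conventions. The implementation is checked in the
test suite against an independent breadth-first search over the full DCJ
operation set, exhaustively for all signed one-chromosome genomes of up to
five markers.

Rates derived from `d`:

* per-marker rate `ρ = d/N` — this normalisation (rather than marker-pair
  counting) is forced by the worked example `120/269 = 0.45`;
* relative rate `r = ρ / protein distance`, which removes the age of the
  species pair from the comparison;
* per-time rate `ρ / divergence time` in events per marker per Myr.

### Genome aliquoting

For a genome whose markers each occur `m = 2` times (post-WGD), the
aliquoting distance is the minimum DCJ distance from a perfectly doubled
ancestor to the observed genome. The exact mode enumerates every candidate
ancestor (all partial matchings of marker extremities) and every copy
labelling; it is the correctness anchor and is restricted to ≤ 8 distinct
markers. The greedy mode reconstructs ancestor adjacencies by copy support
(adjacencies observed twice are taken first, ties broken by marker id for
determinism), labels copies in reading order, and then improves the
solution by hill-climbing over copy-label swaps and DCJ moves among
low-support ancestor adjacencies. Greedy never undershoots exact, since any
concrete ancestor and labelling upper-bounds the minimum; on doubled
100–200-marker genomes with ≤ 10 planted operations it recovers the planted
count. An integer-programming formulation is out of scope.

### Synteny clustering

For draft assemblies, scaffolds are ordered by shared-orthologue evidence:
each scaffold pair gets a 2×2 table (1:1 orthologues on both scaffolds vs
elsewhere), scored by a two-sided Fisher exact test; the dissimilarity is
−log P with the natural logarithm (the test-sidedness and log base are not
forced by anything upstream; two-sided and natural log are this package's
documented choice). Average-linkage hierarchical clustering of the
−log P profiles, applied independently to each assembly, yields the leaf
orders used for dot plots. Scaffolds with no orthologues have infinite
dissimilarity and are placed last.

## Orthology and protein distances

Gene-level reciprocal best hits: all isoforms are searched; the
best-scoring isoform pair (by summed bitscore) represents a gene pair;
alignment segments between the two genes are concatenated with overlaps on
the query resolved best-bitscore-first, giving a length-weighted mean
identity (the weighting rule is this package's choice; plain concatenation
is underdetermined). Coverage is the concatenated aligned length over the
aligned isoform's length. A pair is accepted iff each gene is the other's
best gene-level hit and both directions pass the cutoffs, defaults 60%
identity and 40% coverage; requiring both directions makes the operation
symmetric under swapping the inputs. Ties break by bitscore then
lexicographic subject id, for determinism.

Protein distance uses gap-free columns only (`p` = mismatches / comparable
sites) with the Poisson correction `−ln(1−p)`. A column mask can restrict
the comparison to externally defined conserved sites, so either a
gap-free-columns or a curated-columns convention can be applied.

Diversity clustering is single linkage over edges that pass identity and
coverage thresholds in both orientations; diversity is the number of
connected components.

## Exon phases and shuffling

The phase of an intron is the cumulative CDS length modulo 3 at the exon
boundary, computed in translation order (minus-strand genes are reversed
first). Genes flagged complete whose CDS length is not a multiple of 3 are
excluded with a warning rather than silently phased. Spectra count internal
exons longer than 100 bp by default and report binomial 95% CIs for the
symmetric classes.

A shuffled exon is one whose reciprocal-best exon counterpart (≥ 60%
identity at the exon level by default; the exon-level threshold is
configurable because only gene-level cutoffs are standard) lies in a gene
that is not the orthologue of its own gene, or in an unpaired gene. The
`chainnet` mode additionally requires the counterpart to fall outside the
aligned block chain covering the exon's gene; it reports fewer,
higher-confidence calls. "Domain exon" means the exon overlaps ≥ 1 bp of a
domain interval projected codon-exactly from protein to CDS coordinates.

Subgenic rearrangement is measured as `d_exon − d_gene` (exon-level minus
gene-level DCJ distance), floored at zero because the two marker
restrictions can differ; the raw difference is also reported. The 1–1
phase-bias contrast between shuffled and background exons uses a 2×2
chi-square with continuity correction, switching to Fisher's exact test
when an expected cell is below 5.

## Domain combinations

A domain pair is an unordered pair of domain types in one protein
architecture. The default mode counts consecutive types only ("adjacent"),
the stricter, shuffling-relevant reading; a co-occurrence mode is retained
for sensitivity analysis. Tandem self-pairs are excluded by default.
Overlapping domain hits are resolved greedily by e-value before
extraction. Under Dollo parsimony each observed pair is gained exactly once,
on the branch above the LCA of the species possessing it, with losses
placed parsimoniously below; the test suite verifies this equals the
brute-force minimum over all single-gain scenarios on 4- and 5-leaf trees.
Gain rates are gains per branch divided by branch duration in Myr.
Presence/absence trees are neighbour-joined from Jaccard distances.
Lineage-specific domain types are an input list; deriving them from domain
database taxonomy is out of scope.

## Conserved non-coding elements

Coarse candidates are pairwise alignment blocks split at annotated CDS
(optionally at all exons) and at gap runs of ≥ 10 columns; candidates
separated by < 10 bp on both genomes are merged; identity counts gap
columns as mismatches (the merge distance, gap-break threshold and
gap-column convention are package defaults, configurable). Refinement
applies filters in a fixed order — shorter than 75 bp, within 20 bp of a
CDS ("adjacent"; the adjacency distance is a package default), homologous
to known proteins/structural RNAs at e ≤ 1e−5, identity < 70% — and
attributes each removed candidate to the first filter that catches it, so
per-class removed lengths plus the refined length always equal the coarse
length exactly. Only listed homology classes are removed, leaving
unannotated conserved sequence (candidate regulatory elements, microRNAs,
lncRNAs) in the refined set. Enrichment regions are top-k sliding windows
ranked by CNE bp and merged when overlapping.

## Polymorphism and population size

Variants are called column-wise from haplotype alignments: a SNP per
mismatching column (adjacent SNPs not merged), an indel per maximal gap
run, classed small (≤ 300 bp) or large (300–10,000 bp); inversions and
translocations come from block orientation/order breaks. SNP and
indel-event rates use aligned (gap-free) columns as the denominator; indel
length fractions use genome length — the two denominators follow the units
in which such rates are conventionally printed.

Inter-variant spacing under random mating is geometric. The fit uses the
zero-based MLE `p̂ = n/(n + Σg)` by default (a gap of 0 between adjacent
variant sites is allowed; a one-based `1/mean` convention is also
implemented), with a chi-square goodness-of-fit whose bins pool the tail to
expected counts ≥ 5 and lose one degree of freedom to the estimated
parameter.

dN/dS follows Nei–Gojobori (1986): synonymous site fractions per codon
position, differences averaged over all mutational pathways with equal
weights (pathways through stop codons excluded when alternatives exist),
Jukes–Cantor correction `d = −3/4 ln(1 − 4p/3)`. The correction diverges at
`p = 3/4`; saturated proportions are reported as infinite distances rather
than errors so that tiny worked examples and genome-wide means both behave.
This counting estimator was chosen over ML codon models as a reproducible,
dependency-free approximation; on neutral simulations its ratio converges
to 1 with bias below 0.05 at 10⁴ codons (tested).

Effective population size is `N_e = π / (4 μ g)` with `π` per-site
heterozygosity, `μ` the per-year mutation rate and `g` the generation time
in years (default 1). With `π = 0.0439 + 0.0098` and `μ = 10⁻⁸`,
`N_e ≈ 1.3` million; `μ = 10⁻⁹` gives 13 million — the sensitivity of the
estimate is entirely in `μ`. Large-indel TE attribution counts an event as
TE-derived when ≥ 50% of its length overlaps TE intervals (threshold
configurable).

## Region profiles

The genome is partitioned exactly (disjoint, length-conserving) with
precedence cds > intron > upstream/downstream > intergenic. Flanks default
to 1 kb — "up/downstream of a gene" needs a concrete width and 1 kb is the
conventional promoter-scale choice — and are painted over intergenic space
only; where claims of neighbouring genes overlap, the overlap is split at
its midpoint. Reads are assigned to the class holding the majority of
their bases. Methylation per site is methylated/total reads; class levels
are unweighted means over sites by default, with a read-weighted
alternative, since the site-weighting convention is genuinely open; both
are one flag apart. The fraction of sites methylated at ≥ 80% and Welch
t-tests between classes are reported.

## The synthetic-data generator

`build_ancestor` constructs chromosomes as alternating intergenic spacers
and genes. Exon counts per gene follow a geometric distribution truncated
at 30 (default mean 5); exon, intron and intergenic lengths are lognormal
with medians near 150 bp, 300 bp and 1 kb — compact invertebrate-genome
scale, chosen so that test-sized simulations (tens to hundreds of genes,
0.2–1 Mb) exercise every code path in seconds. Intron boundary phases are
drawn uniformly from {0,1,2}, so each of the nine phase combinations has
prior probability 1/9 — the reference point for the shuffle-preference
arithmetic (a planted 1–1 preference β yields an expected shuffled 1–1
proportion of β + (1−β)/9). CDS sequence is drawn from the 61 sense
codons; planted conserved elements (default 80–400 bp) sit in intergenic
sequence at least 50 bp from coding ends so that recovery is not confounded
by the CDS-adjacency filter.

Lineage evolution applies, in order: optional WGD (exact doubling of all
chromosomes), inversions and translocations (unit-level, strand- and
orientation-aware), exon shuffles (excise an internal exon, merge its
flanking introns, insert into a random intron of another gene — with
probability β the donor is drawn from 1–1 exons; asymmetric insertions are
allowed and recorded, so phase bias arises from the planted preference,
i.e. selection, not mechanism), domain-pair gains/losses, conserved-element
decay, and finally i.i.d. Jukes–Cantor substitutions (each substituted site
takes one of the three alternative bases uniformly — the simplest model
consistent with the distances the pipeline estimates). Every event is
logged; the substitution stage logs its own sub-seed so the log replays
byte-exactly. `make_diploid` plants SNPs and indels (small-indel sizes
geometric with mean 8 bp truncated at 300 bp — only the class boundary is
standard, the mean is a package default chosen to respect the observed
dominance of short indels) while building the exact haplotype alignment.

The derived pairwise alignment between two descendants emits blocks only
where homology would be detectable by a reciprocal-best aligner: per
exon/intron of structurally untouched genes and per conserved element
shared by both lineages. Neutral intergenic background is treated as
having diverged beyond alignability — which is also why passing CNE tests
here says nothing about aligner sensitivity on real genomes.

What the generator does **not** emulate: realistic transposable-element
sequence evolution, selection on coding sequence (substitutions are
neutral, so simulated dN/dS ≈ 1 by design), recombination, gene loss and
duplication outside WGD, assembly error, and alignment error. Estimator
tests on this generator therefore demonstrate correctness of the
computations, not robustness to real-data noise.

## Problem sizes and determinism

Default test and acceptance runs use 40–200 genes (0.1–1 Mb), 100
replicates for the planted-DCJ recovery rate, 300–400 single-shuffle
replicates for the phase-preference estimate, 10⁴ observations for the
spacing MLE and ~10⁴ codons for neutral dN/dS — sizes at which every
statistical check has comfortable power while the whole suite stays fast.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical simulation
bundles, reports carry a checksum over their content, and ties throughout
(best hits, greedy choices, window ranking) break lexicographically so that
no result depends on iteration order.

## Known limitations

* The greedy aliquoting solver has no approximation guarantee; it is
  validated empirically against the exact solver on small instances.
* NG86 underestimates dS relative to ML codon models when transition bias
  is strong; the package applies no transition/transversion correction.
* The chainnet-style shuffled-exon mode uses the derived block chain, not a
  full chain/net construction.
* CNE identity treats gap columns as mismatches; pipelines that exclude
  gap columns will report slightly higher identities.
* Fisher-based scaffold clustering assumes 1:1 orthologues; paralogy
  inflates the shared counts.
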