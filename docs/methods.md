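# Methods

This note documents the models, parameter choices and numerical
behaviour of `foramdelim`, and what the synthetic validation does and
does not demonstrate.

## Read preparation

Reads are expected to start with an 8-nt sample tag followed by the
forward primer S15rF (`GTGCATGGCCGTTCTTAGTTC`). Demultiplexing requires
an exact tag by default (`tolerance=0`); with a tolerance > 0 a read is
assigned only when a unique tag is within that Hamming distance, which
is safe because tag sets are designed with pairwise distance ≥ 2.
Retention requires the *exact* forward primer (it contains no degenerate
base, so no IUPAC expansion is needed) and a read alphabet of
{A, C, G, T}. The reverse primer S19F (`GTACRAGGCATTCCTRGTT`) carries
degenerate R positions and is searched reverse-complemented in the 3'
half of each read with IUPAC expansion and ≤1 mismatch; the fraction of
retained reads containing it is reported because it determines how much
of the dataset can contribute full-length representative sequences.

Retained reads are trimmed to the 300 bp immediately 3' of the forward
primer. Reads with fewer than 300 bp after the primer are dropped and
counted: downstream clustering and distance computations assume
equal-length, coordinate-homologous fragments, and ragged lengths would
conflate read length with divergence. Trimming an already-trimmed read
is a no-op.

## Chimera screen

Dereplicated amplicons are screened in decreasing-abundance order. For
each query, candidate parents are amplicons at least `abskew = 2` times
more abundant. The best two-parent model maximises positional matches
of `parentA[:breakpoint] + parentB[breakpoint:]` over all breakpoints;
because the amplicons share one coordinate system (equal-length trimmed
reads), this maximisation is separable per breakpoint and runs in
O(candidates × length) per query. A query is flagged when

* the model beats the best single parent by ≥ `min_div` = 0.8
  percentage points of identity,
* the UCHIME-style vote score reaches `min_score` = 0.28, with
  published default weights (no-vote weight `xn` = 8, abstain weight
  `xa` = 1, pseudo-count `dn` = 1.4). Votes are tallied separately on
  each side of the breakpoint and the weaker side decides; the
  pseudo-count is a prior on the model's total no-votes, so each side
  carries `dn/2`,
* the two parents are themselves ≥ `min_parent_div` = 1 % divergent by
  edit distance — a sequence and its own homopolymer-indel variant are
  positionally very different but one edit apart and cannot form a
  meaningful chimera,
* the query is not explained by its best single parent within
  `max_noise_edits` = 5 edits when its positional (Hamming) distance is
  larger than its edit distance. This "frame-shift guard" removes the
  dominant false-positive class of pyrosequencing data: a read with a
  single homopolymer indel whose shifted 3' tail drifts toward an
  arbitrary second parent.

Above 200 amplicons the candidate set is narrowed to the 64 most
similar by shared 4-mers, ranked *per query quarter* rather than
globally — a parent that contributes only a short 3' segment would
otherwise be crowded out by whole-length near-matches of the other
parent. Below 200 amplicons the search is exhaustive, which is the
regime the brute-force oracle tests exercise.

Evaluation against simulation ground truth counts a chimeric read as a
detectable positive only when its breakpoint leaves ≥ 50 bp of each
parent inside the 300 bp analysis window: a chimera whose joint lies
outside the window is, within the analysed fragment, a faithful copy of
one parent, and neither flagging nor passing it is an error of the
detector. The 50 bp margin corresponds to the divergence needed for the
minor parent to contribute at least the `min_div` identity gain at the
within-genus divergence tier.

## Clustering

MOTUs are connected components of the graph joining amplicon pairs at
most *d* = 2 differences apart, where a difference is one unit of
Levenshtein edit distance (substitutions and indels both count).
Components are grown breadth-first from the most abundant unassigned
amplicon, which fixes the seed and the output order; the partition
itself is provably independent of exploration order, and a
permutation-invariance test asserts it. All tie-breaks are abundance
descending, then lexicographic sequence order, making every stage
deterministic. No refinement or cluster-breaking phase is applied: the
target behaviour is pure single-linkage chaining at a local threshold.

The occurrence/abundance filter keeps MOTUs present in ≥ 3 samples with
≥ 10 total reads; the rare remainder re-enters at the reassignment
stage. Each retained MOTU receives a representative sequence: among
untrimmed reads whose post-primer prefix equals the MOTU's 300 bp seed,
the longest are selected and, among those, the most abundant (ties
lexicographic); if no longer read exists the seed itself serves.

## Taxonomic assignment

Percent identity is computed from a global-global Needleman-Wunsch
alignment (match +5, mismatch −4, gap open −12, gap extend −4) as
matches over *all* alignment columns, terminal gaps included. A fast
path handles equal-length pairs whose Levenshtein-optimal alignment
needs no indels (edit distance equals Hamming distance): the ungapped
alignment is then also optimal under the heavy gap penalties and the
identity is (L − d)/L. An optional shared-4-mer prescreen restricts
alignment to the top-k references per query.

Ties at equal identity are unambiguous when all best hits agree at the
morphospecies rank; hits agreeing at morphospecies but differing at
genetic type assign to the morphospecies with genetic type
"unresolved"; conflicts at morphospecies mark the assignment ambiguous.
The deciding rank is a design choice: it preserves unambiguous-
attribution semantics without discarding cases that are resolvable at
the rank that matters ecologically.

MOTUs whose best PR²-style hit is not foraminiferan (rank level 3 of
the reference path) are discarded before delimitation. The
meta-reference merges curated references with the delineated
environmental representatives; entries sharing a 4-rank path are
legitimate (the unique-path count is reported), and same-path sequences
mutually < 95 % identical trigger a warning but are both kept.
Reassignment of the full MOTU set retains MOTUs *strictly* above the
95 % identity threshold ("greater than 95 %"; an `inclusive` switch
implements ≥), merges retained MOTUs by path, and reports excluded
MOTUs with reasons and their read total, so read conservation
(table + excluded = input) is checkable.

## Delimitation

Pairwise distances use the Kimura (1980) two-parameter model,
`d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]`, with pairwise deletion of columns
containing gaps or ambiguity codes; pairs sharing < 100 comparable
sites are flagged unreliable, and saturated pairs (non-positive log
argument) raise rather than returning a fiction. The module consumes
aligned or coordinate-homologous sequences and never aligns.

The barcode-gap sweep evaluates 100 priors log-spaced on
[0.001, 0.2] (the ABGD program defaults). At each prior *P* the sorted
pairwise distance list is scanned for the first interval whose upper
end exceeds *P* and whose width exceeds 0.5 × the running mean of the
distances below it (the relative-gap criterion); sequences are
clustered by single linkage below the gap — the threshold is taken at
the gap midpoint, which keeps pairs sitting exactly at the gap's lower
endpoint connected, an immaterial choice because the open interval
contains no observed distances — and gap detection recurses inside each
group until no further significant gap appears. Groups of < 3
sequences are never re-split and recursion is capped at depth 10.
Identical partitions at consecutive priors form plateaus.

Rank selection is anchored to references: the genetic-type level is the
admissible plateau with the *fewest groups* whose partition never
co-clusters references of distinct genetic types of the same
morphospecies, and the morphospecies level likewise for distinct
morphospecies. "Coarsest admissible" is the only non-vacuous reading
of taking the lowest such plateau — the finest partition never merges
anything and would always qualify — and a `plateau_rule` switch offers
`longest_span_admissible` as the alternative. The genetic-type
partition is refined by the morphospecies partition before labelling,
so nesting holds by construction and is asserted. Genetic-type labels
are qualified by their morphospecies ("sp1 TypeII") because bare type
names recur across species; environmental groups without references
get new labels ("<clade> A", "<clade> B", … at the species level,
"<species>-1", … below). Delimitation runs per crown-group clade
(morphogroup): pooling distant clades would put most of the distance
mass at saturation and hide within-clade gaps. A per-clade policy hook
can collapse genetic types to the morphospecies level — the
conservative treatment for clades whose sub-species signal may be
intragenomic variation rather than diversity.

Patristic validation consumes a user-supplied newick tree, partitions
tip-pair path lengths into intra-type / inter-type-intra-species /
inter-species classes and compares consecutive classes with two-sample
Kolmogorov-Smirnov and Mann-Whitney tests.

## Ecology

Rarefaction is analytic (individual-based hypergeometric expectation),
computed with log-gamma to avoid overflow, and is exact — Monte-Carlo
agreement within 3 standard errors and exact agreement with exhaustive
enumeration on small cases are asserted. Composition summaries report
per-sample clade proportions grouped by size fraction, optionally
alongside user-supplied sediment-count proportions. Display abundances
for occurrence plots use log10(count + 1).

## Synthetic data

The generator emulates the survey design: a full factorial of stations
× depths (SUR, DCM) × size fractions ([20–180 µm], [180–2000 µm],
[>0.8 µm]); tags designed by rejection sampling under the published
constraints (pairwise distance ≥ 2, no run of > 2 identical bases);
reads `tag + forward primer + insert (+ reverse-complemented reverse
primer when full length)`. Degenerate reverse-primer positions are
realised as concrete bases per read, as a synthesised oligo would be.

References evolve down the taxonomy under K80 (κ = 2, matching the
distance model downstream) with branch lengths chosen top-down so the
*expected pairwise* distances equal the configured tiers: 0.2 % within
a genetic type (realised as a per-read branch), 5 % between types of a
morphospecies, 15 % between morphospecies; genera sit at ~1.5× the
species tier and morphogroups at ≥ 30 %. "Long-branch" morphogroups
multiply every branch within them (default ×3). The tiers are the
generator's definition of a consistent barcode gap and a property test
asserts the three distance classes are disjoint at their 1st/99th
percentiles.

Noise follows the pyrosequencing error profile in stylised form:
uniform substitutions (0.3 %/base), ambiguous bases (0.05 %/base), and
indels only within homopolymers of length ≥ 3 (0.15 %/base,
insertion/deletion equiprobable). Chimeras (default 5 % of foram
reads) take two abundance-weighted parents from the read's sample and a
single breakpoint uniform in the middle 60 % of the insert — chimeras
form during PCR, so truncation to sequencing length happens after
joining. 10 % of reads come from divergent non-foraminiferan
outgroups to exercise the screening stage. Whether a read is full
length is an independent Bernoulli draw (default p = 0.3222), so the
observed fraction is binomial around the configured value.

Per-sample communities draw lognormal type abundances (σ = 1.2) with
morphogroup-specific multipliers per size fraction (microperforate and
basal lineages favoured ×4 in the small fractions, spinose and
non-spinose ×4 in the large one), emulating the observed size
partitioning of the community. Default depth is 5,000 reads per
sample, the survey's order of magnitude; tests and the acceptance
script run reduced designs (2–4 stations, 250–500 reads/sample), which
already yield hundreds of MOTUs and stable recovery statistics — the
quantities reported are ratios and indices that are insensitive to the
exact depth.

What passing on synthetic data does *not* show: real 454 flowgram error
structure (only its stylised substitution/homopolymer profile),
intragenomic rDNA variability, PCR amplification bias between lineages,
reference databases with wrong or missing annotations, and chimeras
with more than two parents. Results on real surveys therefore depend
on curation steps the package exposes but cannot automate (e.g. a
user-supplied exclusion list for representatives judged chimeric on
inspection, and the per-clade collapse policy).

## Known limitations

* The chimera detector assumes one shared coordinate system
  (equal-length amplicons); it screens trimmed reads, not full-length
  representatives.
* The barcode-gap criterion is the running-mean relative-gap rule; the
  original ABGD's slope-based gap inference can select slightly
  different gaps on irregular distance distributions.
* `select_ranks` inherits labels through co-clustering with references;
  a reference-free clade receives stable but arbitrary new labels, so
  cross-run label identity is only meaningful within a fixed input.
* Patristic validation requires the user's tree to cover all assigned
  sequences; no tree inference is performed.
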