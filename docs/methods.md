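# Methods

This note documents the models, parameter choices and numerical decisions
behind gvlineage, and what the simulation-based tests do and do not
establish.

## Alignment engine

All similarity computations run on an affine-gap Smith–Waterman
implemented as a numba kernel over int8-encoded sequences
(alphabet: 20 standard residues plus X, scored 0). Defaults are the
standard gapped BLASTp parameters: BLOSUM62, gap existence 11, gap
extension 1 (a gap of length k costs 11 + k), Karlin–Altschul λ = 0.267
and K = 0.041, so bitscore S′ = (0.267·S − ln 0.041)/ln 2 and
E = mn·2^(−S′) with n the total subject letters of the search. Identity is
matches over aligned columns including gap columns, and coverage is the
aligned span over each sequence's full length — both the BLAST
conventions. The traceback breaks ties deterministically
(diagonal > up > left); note that co-optimal alignments mean identity is
only defined up to that convention, and only the optimal *score* is
symmetric under swapping the sequences. The kernel is validated against a
naive textbook DP and against biopython's `PairwiseAligner` in the tests.

**k-mer prefilter.** All-vs-all comparisons first index subjects by exact
4-mers and align only pairs sharing ≥ 2 words (≥ 1 for clustering). This
is a heuristic: no exact-word filter can be loss-free at a 30% identity
threshold. Its observed behaviour, pinned by tests, is that (i) at
family-level divergence (≥ ~56% identity between orthologs) no qualifying
hit is lost, and (ii) reciprocal best hits and AAI are identical with and
without the filter even in the presence of paralogs, because the weak
cross-copy hits it may skip are never best hits. Oracle-equivalence tests
for the clustering algorithm therefore run the exact (unfiltered) path.

## Orthology and paralogy

RBH requires both partners to be each other's best *qualifying* hit
(E ≤ 10⁻⁵, identity ≥ 30%, coverage ≥ 50% of query and of subject —
the strict both-sequences reading). Best-hit ties break by higher
identity, then lexicographic subject id. Within-genome paralogous
families are connected components of the thresholded self-hit graph
refined by a Markov-style clustering step (expansion/inflation on the
column-stochastic bitscore matrix, inflation 1.5 by default); singletons
are not families. Cross-genome ortholog clusters are connected components
of the union graph (RBH edges plus paralog edges); a cluster counts as
present in a lineage if any member genome of that lineage contributes a
protein.

The synteny index is a lightweight stand-in for whole-genome alignment:
the fraction of ortholog adjacencies in one circular gene order (by CDS
start) that are adjacent in the partner genome with consistent relative
orientation (both strands preserved or both flipped). It is 1.0 for an
identical or fully reversed gene order and decreases with inversion count.

## AAI and the lineage rule

AAI is the unweighted mean (with median and SD reported) of RBH alignment
identities; one-way AAI uses per-query best hits under the same
thresholds. Pairs with zero qualifying orthologs are reported missing,
never as 0%. Lineages are single-linkage components at two-way
AAI ≥ 95% — a threshold placed inside the empirical gap between ~97%
within-lineage and <73% between-lineage identity, exposed as
`--aai-threshold`. Single linkage makes the partition invariant to input
order and monotone in the threshold.

The evidence report scores five lines against the partition — synteny,
AAI separation, amino-acid usage (Spearman rank correlation of usage
vectors; report-only, never partition-determining), shared ortholog
clusters, and pan-genome increments (every first genome of a new lineage
should add strictly more clusters than any same-lineage addition). Lines
without the needed contrast (e.g. a single-lineage family has no
between-lineage pairs) are marked uninformative; the overall verdict is
the majority of informative lines, and conflicts are flagged, not
overridden.

## Pan-genome clustering

Clustering is centroid-greedy in the CD-HIT/BLASTclust style: proteins
sorted by descending length (ties by id), each joining the oldest cluster
whose representative it matches at 30% identity and 50% mutual coverage,
else founding a cluster. This is deterministic and pinned against an
independent replay oracle on small instances. Cluster granularity is
engine-dependent; single-genome clusters (including ORFans) count toward
the pan-genome. Pan/core curves follow from cluster–genome incidence, so
monotonicity and final-size order-invariance are structural and are
asserted on every simulated family.

## Trees

*Phyletics.* Pearson distance d = 1 − r on 0/1 profiles (d ∈ [0, 2];
zero-variance profiles are an error, not a silent NaN), UPGMA with
average linkage (single/complete selectable) and lexicographic
tie-breaking; heights are half the merge distance. Cross-checked against
scipy's linkage.

*Core-gene phylogeny.* Marker genes are found by best qualifying hit to a
seed sequence (duplicates resolved by bitscore, then length, then id).
The progressive aligner builds a k-mer-distance UPGMA guide tree and
merges profiles with an affine-gap global DP on column-frequency score
matrices — a deliberately small MSA engine, adequate for the mostly
indel-free marker sets it serves here. Distances are Kimura-corrected
protein p-distances, d = −ln(1 − p − p²/5), over mutually ungapped
columns; genomes missing a marker enter the concatenation as all-gap
blocks. Trees come from canonical neighbor joining (negative branch
lengths clamped to zero, Q-ties broken lexicographically), which is exact
on additive matrices and cross-checked against scikit-bio. An approximate
maximum-likelihood engine was deliberately not used: topology, not branch
support, is the object of interest downstream.

*SPR machinery.* Topologies are encoded as sets of split bitmasks, and
SPR neighborhoods are enumerated by pure integer arithmetic on these keys
(prune a side, project the remaining splits, re-attach on each remaining
edge, keep the pruned side's internal splits). SPR distance is an exact
bidirectional BFS over this graph for ≤ 8 leaves — every tree this
project produces. Beyond 8 leaves an admissible bound pair is returned:
lower ⌈(RF/2)/(n−3)⌉ (one move changes at most n−3 splits), upper the
greedy RF-descent move count or the constructive n−3 leaf-relocation
bound, whichever is smaller — a simpler device than a full
maximum-agreement-forest computation, and documented as such.

*Supertree.* The supertree minimises the total SPR distance from the
candidate (restricted to each input's leaf set by split projection) to
the inputs. With ≤ 7 leaves the full topology space — reachable by BFS
since the SPR graph is connected — is scanned, which is globally optimal.
Beyond that, hill-climbing starts from every full-leaf-set input tree, a
caterpillar, and seeded random topologies; the climb is guided by
per-input BFS distance maps truncated at distance 2 (deeper distances
scored as 3), and final scores are recomputed exactly, so the returned
score is never worse than the best input tree evaluated as a candidate.
Ties break on the sorted split masks, making the result deterministic.

## The simulator

The generator emulates a family of circular dsDNA virus genomes evolving
along a lineage tree with branch lengths in expected substitutions per
site: a site on a branch of length L is substituted with probability
1 − e^(−L), the replacement drawn from fixed BLOSUM62-derived
exchangeability weights (f_b·2^(S(a,b)/2), never the original residue) —
an identity-calibrated scheme, not a full rate-matrix exponentiation.
Defaults describe the study family: four lineages with 4+1+2+1 genomes,
~480 ancestral genes (lognormal lengths, mean 240 aa, clipped to
34–1553), within-lineage identity target 97%, between-lineage band
56–73%, 30 paralogous families expanded in the ancestor (one of 14
copies, then 6/5/4 and pairs, copies seeded at 88% identity), 29 ORFans
per genome (random sequences drawn from the background amino-acid
frequencies: realistic composition, no homologs), ~53% of genes on the
minus strand, Poisson gene birth (120/unit length), death (80/unit) and
segment-inversion (15/unit) processes, and codon choice tuned so realized
G+C lands on the 43.5% target (the synonymous-choice knob is rescaled
because amino-acid composition pins most of coding G+C).

When no lineage tree is supplied, branch lengths are solved from the
identity targets so sister lineages meet near the top of the between band
and non-sisters near the bottom. Within a lineage, genomes hang off a
short caterpillar backbone below the lineage ancestor (adjacent genomes
at the within-lineage target, the most distant pair ~1.5 points below
it): a star would leave within-lineage resolution to noise and make
lineage monophyly in distance trees a coin flip, which real families do
not exhibit. Every protein is tracked to an ancestral family and copy, so
ortholog recovery, cluster composition, pan increments and tree topology
can all be scored against truth. The same configuration and seed
reproduce byte-identical GenBank output.

Two adversarial toggles exist for stress tests: `indel_rate` layers
length-changing insertions/deletions on every branch (off by default, so
orthologous copies keep their ancestral length), and `hgt_burst` makes
the last lineage's genome import ~30% of its shared gene repertoire from
the first lineage's ancestor, putting sequence similarity in conflict
with vertical history; both are recorded in the truth tables.

What the simulator does *not* emulate — and what passing tests therefore
do not establish for real data: nucleotide-level selection and codon
usage evolution (codon draws are i.i.d. given the target G+C), horizontal
transfer from outside the family, annotation error, low-complexity
sequence, and genuine rate-matrix heterogeneity across sites and
lineages.

## Problem sizes

The simulator's full-scale defaults (eight genomes of 346–387 kb,
450–550 genes) are used for single-genome structural checks. Repeated
end-to-end runs — twenty families for lineage recovery, AAI calibration
and the pan/core laws, in both the test suite and
`scripts/acceptance.py` — use the `desk_scale` preset: identical lineage
structure, identity targets and rates, with ~110 ancestral genes of mean
150 aa. The recovered quantities (adjusted Rand index of the partition,
realized identity levels, increment orderings) are properties of the
divergence structure, not of genome size, and the preset keeps a
twenty-family batch to a few minutes.

## Known limitations

* Identity from one co-optimal alignment (tie-break dependent) is what
  enters AAI, as in BLAST-based practice; sub-percent AAI differences are
  therefore not meaningful.
* The MSA engine has no iterative refinement; for indel-rich real marker
  sets a dedicated aligner would be preferable upstream of the distance
  step.
* The paralog-family refinement is a light Markov-process heuristic, not
  a faithful OrthoMCL reimplementation; behaviour is pinned on toys only.
* Accession-based reproduction of published genome statistics requires
  network access (`gvlineage fetch`) and is not exercised by the test
  suite.
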