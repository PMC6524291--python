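# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic data do and do not emulate, and the
known limitations.

## Sequence primitives

Nucleotide sequences are normalized to uppercase `ACGTN` (`U` → `T`);
anything else is a parse error naming the offending position. Coordinates
are 0-based half-open internally and converted to 1-based inclusive in GFF3
output.

**Translation** uses the bacterial/archaeal genetic code (table 11),
authored as an explicit codon table; stops render as `*`, codons containing
`N` as `X`, and trailing partial codons are ignored.

**Gene calling** is a six-frame stop-to-stop ORF scan with `ATG/GTG/TTG`
starts and a default 80-aa minimum; only complete ORFs (terminal stop) are
reported. This is deliberately not a trained gene finder: it is
deterministic, dependency-free and adequate for proteome-based
classification. Six-frame calling necessarily reports shadow ORFs antisense
or off-frame to real genes, so wherever a "proteome" is needed
(`contig_proteome`, panel construction) calls pass a greedy longest-first
overlap filter that drops an ORF more than 50% covered by an already kept
longer one. The filter occasionally prefers a long shadow ORF over a short
real gene — the same failure mode real gene finders have — which is why
truth-recovery assertions on filtered proteomes use a 95% floor while the
raw caller is held to exact coordinates.

**Pairwise alignment** (`seqcore.align`) is affine-gap dynamic programming
(biopython's `PairwiseAligner`): nucleotides at match +1 / mismatch −1 /
gap open −5 / extend −2, proteins with BLOSUM62 at open −11 / extend −1.
Identity is percent identical positions over alignment columns; columns
containing `N` are excluded from the denominator (an ambiguity code is
neither match nor mismatch); gap columns count. These scores are declared
defaults — the workflow's conclusions are driven by identity/coverage
thresholds, not by absolute scores.

**Genome-scale nucleotide comparison** (`mapping.py`) avoids quadratic
dynamic programming: exact 15-mers (2-bit packed, numpy-sorted) seed a
candidate window on the subject via the densest seed diagonal, and edlib
aligns the query inside that window (semi-global). Identity is read off the
extended cigar with the same column convention. The 15-mer seed length
keeps seeding sensitive to ≥ ~20% divergence (expected intact 15-mer rate
at 12% divergence ≈ 0.88¹⁵ ≈ 0.15, i.e. dozens of seeds per kb), which
covers the divergence range the screen must discriminate.

## Reference panel and protein search

The panel holds labeled genomes (genus/species/strain), their proteomes
(auto-predicted when not supplied), optional ITS references, a GH reference
set and mobile-element (phage/plasmid) markers. Protein search uses an
exact 5-mer prefilter (candidates must share ≥ 2 distinct 5-mers) before
alignment; on random 150-aa proteins this retains every pair at ≥ 70%
identity over ≥ 100 residues (property-tested against exhaustive
alignment) while keeping all-vs-all search linear in practice. Best hits
require ≥ 30% identity over ≥ 50% of the query by default — loose,
genus-level sensitivity — and ties break by higher identity then
lexicographically smallest genome id, making results order-independent.

The packaged GH and mobile-marker FASTAs are **synthetic placeholder
exemplars**: generated sequences carrying the family/subfamily labels the
pipeline consumes (GH3/GH10/GH11/GH13/GH43/GH53; capsid, terminase,
integrase, relaxase, mobilization). They exercise the machinery; production
use substitutes curated databases via configuration.

## Genus binning

A contig's genes vote for the genus of their best-hit genome, weighted by
alignment score; support is the fraction of hit-bearing genes that voted
for the winner. Two guards matter:

* records shorter than 300 nt — and longer contigs on which no gene could
  be called — are classified by direct nucleotide mapping against the panel
  genomes (≥ 80% identity over ≥ 50% of the record), since ORF calling is
  unreliable there;
* a contig is only assigned when ≥ 30% of its genes found any panel hit.
  Under the loose per-gene thresholds, unrelated proteins occasionally
  produce a single ~30%-identity local hit; without the evidence floor one
  such hit claims an entire contig. Genuinely related contigs (even at 12%
  nucleotide divergence from their nearest relative) place nearly all of
  their genes, so the floor costs no sensitivity.

Abundance profiles are bp-weighted fractions per genus including
`unclassified`; the machine-readable profile keeps every genus exactly,
while the rendered view folds genera below a 0.2% reporting floor into
`other`.

## Novelty screen

Contigs must exceed 5000 bp (strict: a 5000-bp contig is `too_short`).
The decision order is:

1. **Mobile-element test** — fraction of genes whose best mobile-marker hit
   outscores their best panel hit; ≥ 0.5 ⇒ `mobile_element`. This
   automates what is otherwise manual phage/plasmid curation; contigs in
   the 0.3–0.5 band are flagged for review in the evidence trail.
2. **Known-species tests**, against each panel genome; any pass ⇒
   `known_species` with that genome's species:
   * *nucleotide*: ~1 kb fragments seed-mapped to the genome; fragments at
     ≥ 95% identity must cover ≥ 75% of the contig;
   * *protein*: mean best-hit identity restricted to one genome ≥ 96%,
     with hits for ≥ half the genes;
   * *chromosomal*: the longest collinear (subject-monotone, either
     orientation) chain of mapped fragments at known-species identity must
     cover ≥ 75% of the contig — a lightweight whole-genome alignment.
3. Everything else ⇒ `novel_candidate`. A contig with no genes and no
   nucleotide hits is retained as a novel candidate with a `no_evidence`
   flag (conservative retention) rather than silently dropped.

The 95%/96%/75% defaults are declared, configurable, and echoed in every
output header; the nucleotide threshold is deliberately aligned with the
ANI species boundary so the contig-level and genome-level notions of
"known species" agree. Lowering the nucleotide identity threshold can only
move contigs from novel to known (monotone by construction).

## Glycobiome and substrate rules

Genes are assigned to GH families by best hit against the GH reference at
≥ 40% identity over ≥ 70% coverage (cross-genus GH conservation sits well
above 40%). The substrate map is a TSV rule table: each rule is a
conjunction of clauses, each clause a disjunction of `family` or
`family:subfamily` terms. Defaults:

| pattern | substrate |
|---|---|
| `GH13:pullulanase` | pullulan |
| `GH13:amylase` | starch |
| `GH10\|GH11 & GH43\|GH3:beta-xylosidase` | xylan |
| `GH53` | arabinogalactan |

A fired rule scores `weight × Σ relative abundance of supporting families`
(weights default to 1), so rankings are invariant to multiplying all counts
by a constant. Every recommendation lists its supporting gene ids. The rule
table acts on GH evidence only; transport and regulatory context is out of
scope.

## ANI and species boundary

The query genome is cut into consecutive non-overlapping 1020-nt fragments
(the standard fragment-based convention); each is seed-mapped and aligned
to the subject, kept if identity ≥ 30% and aligned query coverage ≥ 70%,
and the one-way ANI is the mean identity of kept fragments. Reciprocal ANI
averages the two directions; the matrix is symmetric by construction.
Trailing partial fragments are dropped, so self-ANI is exactly 100. If no
fragment passes in either direction the result is an explicit no-homology
value (never 0), which propagates as an `undefined` boundary call. The
species rule is strict: `distinct_species` iff reciprocal ANI < 95;
exactly 95.0 is `same_species`. Indels depress fragment coverage before
identity, so indel-rich pairs lose fragments rather than accumulating
artificially low identities.

On 1 Mb simulated pairs the estimator recovers 100·(1−d) within 0.1 point
across d = 1–10% (≈ 980 fragments per direction), and fragment length
1020 vs 1000 moves the estimate by < 0.2.

## Pan-genome and phylogeny

Ortholog clusters are connected components of a bidirectional-hit graph
(local alignment ≥ 50% identity covering ≥ 50% of *both* proteins).
Connected components rather than MCL keeps clustering deterministic and
dependency-free; cluster ids are assigned over sorted member lists. The
core genome is the set of clusters present in every genome; single-copy
core clusters (exactly one member per genome) feed the distances, and
multi-copy core clusters are counted as paralogous and excluded. Cluster
counts are sensitive to the thresholds and to proteome quality, so they are
reported, not promised.

**Distances.** Rather than building a concatenated multiple alignment,
each single-copy core gene contributes a pairwise p-distance matrix
(1 − identity/100 from global protein alignments) and genes combine by
length-weighted averaging. For distance-based tree building this is the
same signal a concatenated alignment provides (each column family weighted
by its length), without an MSA dependency — a deliberate method
substitution, noted here because likelihood methods could not reuse these
distances.

**Neighbor joining** is the canonical agglomeration: minimize
Q(i,j) = (n−2)d(i,j) − r_i − r_j, ties broken by the smallest index pair in
the current working order; branch lengths from the standard formulas, with
negative estimates clamped to zero and the deficit moved to the sibling
branch. The final unrooted tree is rooted at the midpoint of the outgroup's
pendant edge. On additive matrices the implementation recovers the
generating topology exactly and path lengths to < 1e−9 (up to 12 taxa), and
matches the least-squares-optimal topology over all 15 enumerated 5-taxon
trees.

**Bootstrap** resamples core *genes* with replacement (the pipeline never
builds a site-level supermatrix, so a site bootstrap is not available —
a documented divergence from concatenation-based practice; gene-level
resampling is the coarser but standard alternative). Per replicate the
weighted distance matrix and NJ tree are rebuilt; an internal edge's
support is the percentage of replicates containing the same bipartition.
The method default is 1000 replicates; the orchestrated `confirm` workflow
defaults to 100 at desk scale (configurable). Supports are reproducible
under a fixed seed and invariant to taxon input order.

## ITS triage

Isolate ITS sequences are globally aligned against every reference;
`assigned` requires ≥ 98% identity over ≥ 90% coverage, anything aligning
below that is `putative_novel`, nothing aligning is `no_hit`. Queries under
50 nt are rejected. The 98%/90% defaults are declared (the threshold used
by the original ITS database is external to this package) and the verdict
is monotone in the threshold.

## Synthetic data: what it emulates, what it does not

Genomes are i.i.d. background at a target GC plus implanted protein-coding
ORFs (300–1500 nt, both strands, ≥ 60% coding density); each ORF carries an
immediately preceding in-frame stop so the caller recovers recorded
coordinates exactly. The codon sampler's base composition is analytically
corrected for stop-codon rejection so realized GC lands within ±0.5 pp of
target. Divergent genomes apply per-site substitutions with a uniform
alternative base (expected identity 100·(1−rate)), optionally short indels.
Reverse translation of implanted proteins uses uniform synonymous codons.
Fragmentation draws contig lengths around a target N50 (realized within
20%, total bp conserved exactly, provenance logged). Spike-in titrations
mix target contigs into a background at exact bp fractions, trimming the
last piece.

Not emulated: sequencing error and read-level chimeras, codon usage bias,
operon structure, horizontal transfer, repeat content, real GH/mobile
sequence families (placeholders stand in), and real inter-species protein
divergence patterns (divergence is uniform per site). Consequently,
passing tests demonstrate that the algorithms do what they claim under
controlled divergence and composition — they do not certify recall on real
metagenomes, where assembly artifacts and uneven conservation dominate.

## Numerical conventions and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical spec + seed gives byte-identical
  outputs, and workflow reports contain no timestamps.
* Empty inputs fail loudly (`empty contig set`, `zero proteins`, empty ITS
  reference) except where the contract says otherwise (empty query list →
  empty result; all-N contig → no ORFs).
* Distance matrices must be symmetric and NaN-free before NJ; ANI pairs
  need both genomes ≥ 10 fragment lengths.
* Abundance fractions and GH relative abundances sum to 1 within 1e−9 by
  construction.

## Problem sizes used in validation

The shipped validation suite runs on one CPU: 100 kb panel genomes (four
genomes, three genera), 1 Mb genome pairs for ANI recovery, a 6-genome
pan-genome with 50 core families, ~20-contig screening samples, 2 Mb
spike-in backgrounds, and 25–200 bootstrap replicates. These sizes were
chosen as the smallest at which the estimators' sampling noise is well
inside the asserted tolerances; all stages accept real-scale inputs
through the same interfaces.

## Known limitations

* The ORF caller has no model of translation initiation context; very
  short genes and genes without in-frame upstream stops may shift or drop.
* The whole-genome-alignment test chains ~1 kb fragments, so rearrangement
  breakpoints below that granularity are invisible to it (the nucleotide
  and protein tests still apply).
* Ortholog clustering by connected components can chain distinct families
  through promiscuous domains on real proteomes; MCL-style splitting is out
  of scope.
* ANI is exact alignment-based; no MinHash approximation is provided, so
  all-vs-all matrices over hundreds of genomes are compute-bound.
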