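# Methods

## Scope and data model

`harbormine` operates on gene-level annotation. Coordinates are read from
GFF3 as written (1-based inclusive) and converted once, at the parser
boundary, to 0-based half-open intervals; every downstream module and all
BED output use the half-open convention. The "start codon" of a gene is
approximated by the 5′ end of its gene feature (`start` on +, `end` on −);
CDS sub-features are not resolved, so a long 5′ UTR will shift an upstream
window away from the true start codon. The feature type (`gene`) and ID
attribute are configurable because RefSeq GFF3 dialects differ.

## Intergenic extraction

Genes of a chromosome are swept in (start, end, id) order while tracking
the running maximum covered end. A region is emitted only where coverage
truly breaks, so overlapping and nested genes extend a single covered
block rather than creating spurious gaps. The left flank of a region is
the gene achieving the running maximum end (ties broken by gene id
ascending); the right flank is the next gene to start. Terminal gaps
before the first and after the last gene are not regions, because the
score requires two flanking genes. Strand is ignored for adjacency.
Abutting genes (zero-length break) are *adjacent* for promoter-pair
purposes but produce no intergenic region. The sweep is verified in the
test suite against a per-base coverage oracle on random annotations with
overlaps and nesting.

## Neutral-locus selection

Per library, the score of a region is the arithmetic mean of its two
flanking genes' raw read counts. Raw counts are used (not RPKM) because
only within-library order matters: the funnel takes the top `top_k`
regions of each library (descending score, ties by region id) and
intersects across all libraries, so a survivor's flanks are highly
expressed in every condition. Defaults are `top_k = 500` and a strict
`> 4800 bp` length filter, the values appropriate for a full fungal genome
with ~11,000 intergenic regions; the synthetic study scales `top_k` to 50
(~1/8 of its ~400 regions, the same fraction of the funnel) via
`SimulationConfig.selection_config()`. The strictness of the length
comparison at exactly 4800 bp is configurable but strict by default.
Survivors are ranked by mean per-library score; the final manual step of
choosing a handful of loci spread across chromosomes is not automated —
the report includes the chromosome so users can apply that spread
themselves. Monotonicity (growing `top_k` never shrinks the consensus,
growing the length threshold never grows the final set) and equivalence
with a brute-force full-sort-plus-set-ops oracle are asserted in tests.

## Promoter mining

Divergent pairs reuse the coverage-sweep adjacency, so a third gene nested
between two genes blocks a pair — an interval containing another gene is
not a clean bidirectional promoter. The expression criterion "highly
expressed in most conditions" has no canonical threshold, so it is
operationalised as: both genes rank within the top `q` quantile
(`rank ≤ ceil(q·G)`, default q = 0.10) in at least `m` libraries (default
a strict majority), counting only libraries where both genes pass
together. Both knobs are exposed; the filter is monotone in `q` and
anti-monotone in `m` by construction. The promoter record is the
plus-strand interval between the left gene's end and the right gene's
start; abutting genes raise an error rather than emitting an empty record.

Core promoters default to RPKM ranking (raw-count mode available) with the
library total taken as the column sum over genes present in the matrix —
self-contained and reproducible. Ties in every ranking are broken
lexicographically by gene id for cross-platform determinism. The top `n`
unique genes are taken; a gene whose upstream window would cross a
chromosome end is skipped with a logged warning and replaced by the
next-ranked gene, and the output is partial (with a warning) if the
ranking runs out. Windows are never silently truncated.

## Construct simulation

The donor layout is `5′arm | payload | repeat | marker | 3′arm` with the
repeat duplicating the *start of the 3′ flank*. Which side is duplicated
is not constrained by the architecture, so 5′-side duplication is
available via `repeat_side="five_prime"`. The repeat is taken from the
genomic flank rather than from the arm itself: with short arms (down to
25 bp) the arm is shorter than the 300-bp repeat, but the post-integration
chromosome still carries the native flank, so the two repeat copies exist
regardless of arm length. Integration requires exact arm matches
(mismatch tolerance is out of scope; the contract is deterministic and
testable). Loop-out searches outward from the marker edges for the
nearest pair of identical `repeat_len_min`-mers and excises everything
between the left copy's start and the right copy's start; for the
designed construct this reproduces the wild-type locus with the payload
seamlessly inserted, bit-exact, which the tests assert for 100 random
locus/payload/arm-length combinations. A marker without flanking repeats
raises `LoopOutImpossibleError`, modelling death under 5-FOA. Note that a
full template inserted ectopically *does* physically carry both repeat
copies under this layout; whether such a configuration can loop out in
vivo is biologically doubtful but not mechanistically settled, so the
simulator exposes both configurations (construct `IntegratedChromosome`
directly to model ectopic events) instead of resolving the question.

## Synthetic data generator

The generator emulates the real inputs — a multi-chromosome stranded
annotation and 6–18 libraries of overdispersed counts — with planted
truth. Defaults: 2 chromosomes × 200 genes; gene lengths uniform
500–3000 bp; background gaps 200–2000 bp; planted/long gaps 5000–8000 bp
(strictly above the 4800 bp filter by construction); 6 libraries (an
18-library profile, matching the real study design's library count, ships
for fidelity runs); 8 planted neutral loci, 4 planted divergent pairs, 3
decoys per class. Counts are negative binomial (gamma–Poisson, size
r = 10) rather than Poisson to emulate RNA-seq overdispersion, with
per-library depth factors uniform in 0.6–1.4; constitutive-high genes
draw means from 6,000–12,000, background genes 5–300. These values put
roughly 1.5 orders of magnitude between flank classes — comparable to the
spread between housekeeping-level and median expression in real fungal
RNA-seq — so that recovery is a property of the algorithm, not of a
knife-edge threshold; tests also verify that recovery degrades as the
separation is collapsed. Planted features are assigned to intergenic
slots at pairwise distance ≥ 3 so no two planted features share or
neighbour a flanking gene, and non-divergent planted flanks are forced
convergent, so no unplanned head-to-head pair of constitutive-high genes
can arise. Decoys each violate exactly one predicate: short gap,
background flanks, or flanks high in only a strict minority (2 of 6) of
libraries.

What the generator does **not** emulate: repeats and low-complexity
sequence (chromosomes are i.i.d. random ACGT), tRNA/rRNA and other
non-gene features, correlated expression between conditions, GC/length
biases, and multi-mapping artifacts. Passing tests therefore demonstrate
algorithmic correctness under the stated model, not robustness to every
property of real libraries.

## Problem sizes and determinism

The default study (400 genes, 6 libraries) runs the full funnel in well
under a second; oracle comparisons use 200 random annotations (≤ 50
genes, ≤ 100 kb chromosomes) and 100 random score tables, and the
construct round trip uses 100 random 5–10 kb loci — sizes at which the
brute-force oracles are exact and fast. All randomness flows from a
single integer seed through `numpy.random.Generator`; identical seeds
give byte-identical emitted files, which the tests check by hash.

## Known limitations

* Gene-level windows only; no TSS/UTR inference, so "upstream of the
  start codon" is approximate where annotation lacks CDS resolution.
* No masking of tRNA/rRNA or repeat overlap when nominating loci.
* The expression filter thresholds (q, m) are conventions, not fitted
  values; results should be reported together with them.
* HDR simulation is exact-string; it cannot model partial-homology or
  mutation-carrying integration events.
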