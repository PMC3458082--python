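# Methods

## The classification problem

The positive class is the genomic neighborhood of a miRNA precursor: a
200-nt window whose dominant hairpin's terminal-loop center sits at a
fixed reference position. The negative class is the same construction
applied to pseudohairpins — hairpin-shaped folds of mRNA fragments,
tRNAs, rRNAs, sno/snRNAs and SINEs. Fixing the loop center normalizes
away variation in precursor length, loop size and mature-arm placement,
so that a feature at a given window offset means the same thing in every
instance.

## Coordinate and centering conventions

All internal coordinates are 0-based half-open on the forward strand;
BED is consumed natively and the 1-based TSV dialect is converted at the
file boundary. A 200-nt window has no exact center: the reference base
is placed at index 99 (99 nt to its left, 100 to its right), which makes
the left and right flanks each exactly 100 nt and yields the 80/80
left/right sliding-window decomposition. Even-length loops take the
left of the two middle bases as their center. When a structure has
several hairpins, the one whose enclosing stem carries the most base
pairs wins, ties going leftmost; these tie-breaks are package
conventions chosen for determinism.

## Folding

The default engine is the ViennaRNA MFE folder at 37 °C through its
Python bindings, which also supplies the minimum free energy. A
Nussinov-style maximum-pairing fallback (minimum loop 3, lone pairs
removed so only stems of ≥ 2 stacked pairs remain) keeps the package
functional without the bindings; its structures are marked
`method="nussinov"` and are coarser than thermodynamic folds — tests
that depend on fold quality use the MFE engine when present.

## Feature vector (6,622 values)

Layout: `[80 left windows × 40][1 fixed window × 40][80 right windows ×
40][180 hydrogen-bond][CPB][profile score]`. Windows are 21 nt, step
1 nt; left windows tile [0, 100), right windows [100, 200), and the
fixed window spans [89, 110) so its center is the reference base.

Per window the 40 densities are 4 mononucleotide (counts/21), 16
dinucleotide (counts/20) and 20 structural-triplet densities. The
triplet states are the 20 length-3 dot-bracket strings in which no `)`
precedes a `(` — the only triplets a single hairpin can realize.
Windows that straddle the junction between two hairpins can contain
unrealizable triplets; triplet densities are therefore normalized over
the realizable slots in the window (identical to /19 for any
single-hairpin window), which keeps each density block a probability
simplex — an invariant the test suite asserts for every block.

The 180-value block gives, for each full-sequence window, the mean
per-position hydrogen-bond weight with G·C = 3 and A·U = G·U = 2; the
partner of each base is read from the global structure. The weights
and the /21 normalization are package choices (any monotone
re-weighting would serve); they encode pairing strength rather than a
thermodynamic quantity. CPB is the longest run of non-dot characters.

## Mature-anchored structural profiles

Precursor structures with a known mature interval are re-encoded over
six letters — `( . )` → `M O N` inside the mature interval, `L D R`
outside — so that alignment can distinguish the structurally conserved
mature arm from the flanks. Pairwise alignment is global
Needleman–Wunsch in three anchored pieces (mature vs mature, then each
flank) with match +1, mismatch 0, linear gap −1; no column ever mixes
mature and flank characters. The diagonal-first traceback pushes tie
gaps to a string's start, which is the outer end of a left flank; right
flanks are reversed before alignment so their tie gaps also fall
outward. Identity is matches over aligned columns, gap columns counting
as mismatches.

Encodings are clustered by single linkage at ≥ 80% identity; each
cluster is progressively multiple-aligned (members joining in
decreasing order of mean pairwise identity, each aligned blockwise to
the growing consensus so the mature anchor column is shared by all
rows) and condensed into a per-column probability matrix over the seven
states (six letters + gap). Columns are trimmed to the range covered by
every member — the shortest member extent on each side of the anchor —
so only fully-aligning positions contribute.

Scanning collapses each profile to the three plain dot-bracket states
(gap mass dropped, columns renormalized; all-gap columns contribute
zero): candidates at scan time carry no mature annotation, and the
3-state alphabet is the only one shared with them. A placement's score
is the mean per-column probability of the observed character; the
candidate's profile score is the maximum over all profiles and
placements, so it lives in [0, 1], equals 1 for a self-match against a
one-hot profile, and never decreases when the library grows. The
alignment scoring scheme and the mean-probability window score are
declared package choices; both are configurable at the module surface.

## Classifier

`bag_train` draws K seeded bootstrap resamples (with replacement, size
N = training-set size by default, K = 10) and fits three learners per
resample: an RBF-kernel SVM (C = 1, kernel width 1/n_features,
features z-scored per resample), Gaussian Naive Bayes and an
unrestricted Gini decision tree on raw values. A fully grown Gini tree
is invariant to expansion order, so depth-first growth reproduces
best-first expansion. Prediction is the majority of the 3K votes; the
positive-vote fraction is the reported confidence and exact ties are
called negative, since in genome-wide scanning false positives are the
costlier error. All randomness (bootstraps, CV folds) flows from one
seed. The per-feature F-score used for ranking is
`((m⁺−m)² + (m⁻−m)²) / (s⁺ + s⁻)` with unbiased within-class scatters;
it is affine-invariant and zero for identical classes.

## NGS discovery

Reads are collapsed to unique sequences with counts (ids assigned in
decreasing-count order), then filtered against externally produced
alignment hit sets in fixed order mRNA → other ncRNA → known
precursors, with a per-stage survivor report; counts are conserved at
every stage. Surviving placements cluster at a 250-nt gap; within a
cluster, coverage peaks (plateau-merged local maxima with ≥ `min_reads`
support, default 1) are paired when their summits are ≤ 75 bp apart —
the two-arm signature of Drosha/Dicer processing. One 250-nt region is
extracted per disjoint qualifying pair, centered on the pair's summit
midpoint (pairs chosen by combined height). Centering on the mapped
reads rather than on the cluster midpoint matters in practice: sparse
background reads chain clusters across loci, and a cluster-midpoint
window can miss the read stacks entirely. Regions are re-centered on
their terminal loop to a 200-nt candidate and classified; abundance is
reads-per-million mapped reads (no length term — the classical RPKM
length correction is meaningless for fixed-length regions).

## Synthetic data

`gen_hairpin_set` designs stem-loops — a random 5′ arm (default 25–35
nt, GC 0.55), a loop of 6–15 nt, and the arm's reverse complement
mutated at rate 0.05 — with a 21-nt "mature" interval on the 5′ arm
(flag for 3′), each embedded in a random toy genome with ~600-nt
spacers so loci are separated beyond the read-cluster merge gap and
every loop center has its 100-nt flanks. `gen_pseudohairpins` draws
GC-skewed random sequences (320–420 nt, GC 0.6) and keeps those folding
into a usable hairpin, tagging them with negative-source categories.
`gen_reads` stacks reads (16–36 nt) on the two arms of each planted
locus with ±2 nt jitter plus a 10% uniform background. All generators
are pure functions of (parameters, seed).

What passing on these fixtures shows — and does not. The positives have
designed near-perfect stems and the negatives are random-sequence
folds, so class separation is far cleaner than between real precursors
and genomic pseudohairpins; accuracy and AUC on fixtures are upper
bounds, not estimates of field performance. The fixtures do exercise
every contract end-to-end: coordinate bookkeeping, loop centering, the
profile pipeline, vote aggregation, region calling and the file
formats. Real-data features the generators do not emulate include
miRBase-like family structure (clusters larger than singletons),
bulged/asymmetric stems, expression-dependent read-length
distributions, sequencing errors and multi-mapping reads.

## Problem sizes and numerical choices

The test suite and acceptance checks run at 50 instances per class
(profile library of ~50 singleton profiles, toy genome ~35 kb), sizes
at which the full pipeline — folding included — completes in a couple
of minutes on one core. Simplex sums are asserted at 1e-9; profile
columns must sum to 1 within 1e-9; alignment ties, loop ties and vote
ties are all broken deterministically as described above, so every
pipeline stage is bit-reproducible for a fixed seed.

## Known limitations

* Clustering computes all pairwise anchored alignments (O(n²)); fine at
  library sizes of a few hundred, not tuned for tens of thousands.
* The scanner folds a window and then refolds the re-centered window;
  folding dominates runtime on large genomes. Windows map
  independently, so contig- or window-level parallelism preserves
  byte-identical output, but no built-in multiprocessing is provided.
* Profiles built from 200-nt window structures are dominated by the
  precursor region only insofar as the flanks fold heterogeneously;
  with real families, building profiles from precursor-length
  structures would give sharper cluster structure.
* The Nussinov fallback maximizes pairing, not free energy; MFE-derived
  quantities (e.g. recorded `mfe`) are absent under the fallback.
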