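# Methods

This note documents the models and procedures implemented in
`motifclust`, the parameters that matter, the numerical choices made
where several readings were possible, and the limits of what the test
suite demonstrates.

## Matrix preprocessing

A raw PFM is either a count matrix (columns summing to the number of
aligned binding sites) or a frequency matrix (columns summing to ~1);
the two are distinguished by the column sums (tolerance 0.02). Count
matrices receive a pseudocount of 1 in every cell before column
normalization. Frequency matrices are renormalized with a floor: every
probability is at least 10⁻³, entries below the floor are raised to
exactly 10⁻³ and the excess mass is removed proportionally from the
above-floor entries (so (1,0,0,0) becomes exactly
(0.997, 0.001, 0.001, 0.001)). The floor-then-rebalance order was
chosen over floor-then-global-renormalize because the latter leaves the
raised entries slightly *below* the guaranteed minimum
(0.001/1.003 < 10⁻³); the chosen scheme preserves the guarantee
exactly. Both branches end with the floor applied, so every normalized
column satisfies p(b) ≥ 10⁻³ and Σ p(b) = 1.

Flank trimming removes columns from each end, inward, while
max_b p(b) − min_b p(b) < 0.25; interior columns are never removed. A
matrix whose every column fails the test is flagged empty and rejected
by the aligner. `n_sites` for count matrices defaults to the maximum
column sum; frequency matrices have no site count unless annotated.

## Alignment and information coverage

The aligner exhaustively enumerates all ungapped windows
(s_x, s_y, w ≥ min(5, L_x, L_y)) on both orientations of the second
motif and maximizes the *final* score (raw × IC multiplier), not the
raw score. Ties are broken deterministically: smaller s_x, then smaller
s_y, then forward orientation, then larger width. Both orientations are
scored because motif databases store either strand; coordinates of
reverse-complement alignments refer to the reverse-complemented matrix.

Per-column information is 2 − H in bits (log base 2; the natural choice
for a 4-letter alphabet, maximum 2 bits). Information coverage is
computed on the trimmed matrices, so "total information" excludes
trimmed flanks; a motif with zero total information is defined as fully
covered (ic = 1). The *ave* composite multiplies the raw score by the
arithmetic mean of the two per-motif coverages and *sqr* by their
geometric mean; both multipliers lie in [0,1], and the minimum-width
rule uses trimmed lengths.

Column scores: the α parameter enters ED and SSD as a subtractive
offset (score = α − distance), converting a distance in [0, √2] (ED) or
[0, 2] (SSD) into a local-alignment contribution that is positive
exactly when the columns are closer than α. Defaults are the optimized
values 0.55/0.5 (ED without/with IC) and 0.3/0.25 (SSD). PCC of a
zero-variance 4-vector is defined as 0. LSO uses the natural logarithm
and a uniform background by default; LSO.KL subtracts the symmetrized
Kullback–Leibler divergence (KL(p‖q)+KL(q‖p))/2 from the LSO term, a
reading locked by a regression test.

## Score adjustment

Best local alignment scores grow with the number of candidate windows,
which is proportional to the alignment space a = L_a·L_b. The
adjustment model estimates μ(a) and σ(a) from background score triples
(raw, L_a, L_b) by Nadaraya–Watson regression with a Gaussian kernel on
t = log a, bandwidth by Silverman's rule 0.9·min(sd, IQR/1.34)·n^(−1/5);
σ² is the same regression applied to squared residuals, floored at
σ ≥ 10⁻⁶. Curves are tabulated on a 101-point grid spanning the
training range and evaluated by linear interpolation with constant
extrapolation. At least 50 background pairs are required. Lengths
L_a, L_b are the *trimmed* lengths, consistently with the alignment
engine that produced the scores. Background pairs should be
between-class pairs — pairs certain to be unrelated — rather than
between-family pairs, because same-class pairs may share residual
similarity.

## Family classifier

P(F=1|S_adj) = logistic(β₀ + β₁·S_adj). The shipped defaults
(β₁ = 5.294, β₀ = −3.3296) were estimated for adjusted ED.sqr scores on
a large curated collection and cross the 50% decision threshold at
S_adj ≈ 0.629. Training (`train_classifier`) is a maximum-likelihood
logistic fit (IRLS via statsmodels) with intra-family scores as
positives and between-class scores as negatives; perfectly separable
inputs — common on small, clean collections — fall back to a weak ridge
penalty with a warning.

An important caveat: β coefficients are only meaningful together with
the adjustment model whose scale they were trained on. Applying the
shipped β to a *freshly fitted* adjustment model standardizes the
background to sd ≈ 1, where the 0.629σ crossing admits a substantial
fraction of background pairs and the FBP clustering over-merges. The
FBP pipeline therefore keeps model and classifier paired: with a
supplied model it applies the shipped (or supplied) β; when it fits the
adjustment itself on a class-labeled collection it also retrains β on
that collection, deriving the positive (intra-family) pairs from
per-class network analysis — the same two-stage procedure used to
obtain the shipped coefficients in the first place. Unlabeled input
with no model gets the shipped β with an explicit warning.

## Network clustering

For each class, motif m's edge threshold t(m) is its highest score
against any motif outside the class; edges go to class members scoring
strictly above t(m) (a tie with the first non-class member does not
connect). Because the rule is per-motif it can fire in one direction
only; the undirected network keeps an edge if the rule fires from
either endpoint (union semantics; an intersection mode exists behind a
flag). Classes with fewer than 5 motifs are built but flagged below the
analysis threshold. All edges have weight 1.

MCL is implemented directly: self-loops of weight 1, column
normalization, then alternating expansion (matrix squaring) and
inflation (entrywise power r = 2.0 with column renormalization;
entries < 10⁻¹² pruned) until the maximum entrywise change falls below
10⁻⁸ or 200 iterations. Clusters are read from attractor rows
(diagonal mass > 10⁻⁶), overlapping attractor systems are merged, and
disconnected nodes become singletons. The procedure is deterministic.

## FBP clustering

Initial FBPs are the input motifs with per-column weight
√min(n_sites, 200); the cap keeps matrices built from thousands of
ChIP-derived sites from dominating a consensus. Frequency-only matrices
without a site annotation get weight 1 per column. Merging two FBPs
along their best alignment takes weight-weighted averages of aligned
columns (weights add); overhanging columns are averaged against a
uniform partner column of weight 1. Merged profiles are not re-trimmed;
members are stored with their strand resolved at merge time.

The merge *order* comes from classic average-linkage clustering of the
fixed initial distance matrix 1 − P(F=1|S_adj); distances are never
recomputed from merged FBPs. Merge *acceptance* ignores the linkage
height entirely and applies two checks at the probability threshold
(default 0.5): the FBP–FBP alignment probability must exceed it, and
the candidate merged FBP must re-detect every original member above it.
On failure the proposed cluster is invalid and both children are frozen
— they are reported as final clusters of their own and take no further
part in valid merges (in a fixed dendrogram any later merge would
involve the invalid parent). A `freeze_on_reject=False` mode implements
the alternative reading in which the children of a failed merge may
still merge with other partners at higher tree nodes (pairs attempted
in deterministic lexicographic order, greedily while the validity rules
pass). Input order does not affect the result: motifs are sorted by id
before the linkage, and ties resolve by that order.

## Evaluation statistics

Best hit and class depth are leave-one-out rank statistics; score ties
are broken pessimistically by default (a tied non-class motif counts
against the method), with an optimistic mode for sensitivity analysis.
Class depth divides by class size − 1, since the held-out motif cannot
retrieve itself. Per-class summaries use linear-interpolation (type-7)
quantiles. Catch-all classes can be excluded from the hold-out set
while remaining available as false-positive material. Class subsets
(Top5/Min20/Min10) are computed from the supplied class map. The Rand
index is (#C + #S)/(n choose 2) over item pairs.

## Synthetic collections

The generator emulates how families of related PFMs arise: a family
seed profile with informative columns drawn from a peaked Dirichlet
(concentration 0.3) and background columns from a flat one
(concentration 5), members produced by multinomial resampling of
`n_sites` = 50 binding sites per column, positional shifts within ±2,
0–2 random background flank columns per side, and reverse
complementation with probability 0.25. Default geometry: 4 families ×
6 motifs, cores of 8–12 columns, 80% informative. These defaults
produce collections where related motifs are clearly but not trivially
similar (within-family raw ED.sqr scores separate from background with
overlap in the adjusted tails).

By default every family carries its own class label. The per-class edge
rule thresholds each motif on its best out-of-class score — a maximum
over hundreds of outsiders in a real database, but over only a dozen
motifs at fixture scale, where chance similarity between two same-class
families makes multi-family classes unreliable to split. Multi-family
classes can be planted with `families_per_class > 1`; the rule's
splitting behavior itself is pinned by unit tests on constructed score
tables. `FamilySpec.noisy()` provides a deliberately harder regime
(6 families × 5 motifs, 12 sites, weaker cores, longer flanks) used for
α-sweep experiments, because at the default settings retrieval
saturates and all α values perform equally.

What passing tests on synthetic data do *not* show: real collections
contain dimeric motifs with variable spacers, overlapping half-site
specificities across classes, and heterogeneous matrix-derivation
protocols; none of these are modeled, so recovery rates here are upper
bounds on real-data behavior.

## Problem sizes and limitations

The test suite and the acceptance script run collections of 24–30
motifs (hundreds of pairwise alignments) and simulations of n = 5000;
these sizes make the statistical checks stable while keeping runs in
seconds to minutes. The aligner is exhaustive (O(L_x·L_y·min(L)) per
pair) and intended for motif lengths up to a few tens of columns, not
for gapped or multi-motif alignment. Reproducing published results on
the commercial TRANSFAC collection or on JASPAR CORE requires those
databases: the `cluster` and `evaluate` commands accept user-supplied
files in either dialect, but no database content ships with the
package, and clustering a external collection with the shipped
classifier inherits the cross-collection caveat described above.
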