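# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `codechron`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Character coding of abundance censuses

A census is a domains × proteomes matrix of nonnegative integer
abundances *g*.  Each proteome column is treated as one linearly ordered
multistate character: values are optionally transformed by ln(*g* + 1)
(useful because abundance distributions are heavy-tailed), rescaled to
[0, 1] by the column maximum, and discretized into *S* equal-width bins
with edges at *i*/*S*.  Bins are half-open from below and the top bin is
closed, so a rescaled value of exactly 1 maps to state *S* − 1 and a
value at a bin edge falls in the upper bin (0.5 with *S* = 2 gives state
1).  All-zero columns map every taxon to state 0.  The default *S* = 24
matches the 0–9A–N character alphabet used for published abundance
matrices.  Normalization is per proteome column by default — characters
are proteome-wise abundance profiles — with global normalization
available as a flag; whether the original analyses normalized per
proteome or globally is not stated in the source material, so both are
provided.

Within a column the coding is monotone (larger abundance never maps to a
lower state) and invariant to positive rescaling of the column; both
properties are pinned by tests.

## Wagner parsimony engine

Characters are linearly ordered and reversible: changing state *i* to
*j* costs |i − j| steps.  Tree length is computed by the Sankoff
recursion with the |i − j| cost specialized to an O(*S*) two-pass
distance transform per node, so scoring is exact on binary and
multifurcating trees and costs O(*S* · characters) per node.  The length
of a tree is invariant to root placement (the cost is symmetric), so
search operates on unrooted topologies.

Search strategies:

* **exhaustive** — enumerates all (2*n* − 5)!! unrooted binary
  topologies; guaranteed optimal, allowed up to 9 taxa (10,395 trees at
  *n* = 8; 135,135 at *n* = 9).
* **hillclimb** — greedy stepwise addition (each taxon inserted on the
  edge minimizing length) followed by nearest-neighbor-interchange moves
  to a local optimum, with subtree-prune–regraft moves added when NNI
  stalls on taxon sets of ≤ 12 (the SPR neighborhood grows roughly
  quadratically, so it is disabled on large matrices where NNI suffices
  in practice).  Five stepwise-addition starts (input order plus four
  seeded random orders) are used on small taxon sets, one on large ones.
* **ratchet** — the parsimony ratchet: iteratively reweight a random 25%
  of characters to weight 2, hill-climb on the reweighted matrix, then on
  the original, accepting improvements; stops after 10 idle iterations.
  These are the canonical ratchet settings; the source analyses cite the
  method without parameterizing it.

All co-optimal trees found are returned, keyed by their bipartition sets;
consensus summarization is left to the caller.  Tie-breaks everywhere are
deterministic (lowest index), so a fixed seed reproduces results exactly.

**Rooting.**  The Lundberg method attaches a hypothetical ancestor to the
edge minimizing total length (lowest-indexed edge on ties); the root is
placed at the attachment point and the ancestor itself is not retained.
For domain trees the natural ancestor is "all characters at the maximum
state", per the polarization assumption that abundance grows with age;
for tRNA matrices the ancestor is the all-zero vector (minimal
conformational order) and is carried by the matrix.

**Constraint statistic.**  *S*(group) = length of the best tree with the
group constrained monophyletic minus the unconstrained optimum.  The
hypothetical ancestor is included as an additional terminal so monophyly
is defined on the rooted tree.  Exhaustive enumeration is used through 9
terminals (including the ancestor); above that, stepwise addition
restricted to constraint-legal placements plus constraint-filtered NNI.

**Bootstrap.**  Characters are resampled with replacement to the original
count; support of a reference-tree split is the percentage of replicate
best trees containing it.  The reference tree is the best full-matrix
tree, Lundberg-rooted when an ancestor is available.

**Tree statistics.**  CI = Σ per-character minima / length, with the
ordered-character minimum equal to the leaf state range; RI uses the
star-tree maximum, Σ|x<sub>i</sub> − median|.  When no character varies,
CI and RI are reported as missing.  g1 is the sample skewness of the
length distribution of topologies drawn uniformly at random (sequential
random edge insertion is uniform over labeled topologies); 1,000 draws by
default.

## Timelines and clocks

The node distance of a leaf is (depth − min depth)/(max depth − min
depth), where depth counts nodes on the root-to-leaf path; the
earliest-diverging lineage anchors at *nd* = 0, matching the convention
that the oldest structures sit near zero.  Perfectly balanced trees carry
no relative-age signal; all *nd* are set to 0 with a warning.

Clock calibrations (Gy before present): fold level
*t* = −3.802·*nd* + 3.814; fold-superfamily level
*t* = −3.831·*nd* + 3.628.  Ages that would be negative (the FSF clock
crosses zero at *nd* ≈ 0.947) are clamped to 0 with a warning, since
negative geological ages are meaningless.

Coevolution regressions of tRNA age *S* on domain age *nd* are offered
in two forms and both are reported: through-origin (slope = Σxy/Σx²,
uncentered R², F = (n−1)R²/(1−R²) on (1, n−1) df) — matching a model in
which a domain of age zero pairs with the oldest tRNA — and ordinary
simple regression on (1, n−2) df.  The printed statistics of the original
coevolution plots are mutually inconsistent for any integer df under
standard OLS, so neither variant is asserted to reproduce them; the
underlying (nd, S) pairs were never published.

Amino-acid group partitions: age groups 1 = {Y, S, L},
2 = {K, F, P, T, A, M, I, V}, 3 = {E, Q, R, C, G, W, N, D, H}; expansion
stages A = {P, A, T, G, H}, B = {V, M, I, C, Q, R, L},
C = {D, N, K, S, E, Y, F, W}.  Each partition is validated to cover the
20 residues exactly at load.

## Dipeptide analyses

A protein of length L contains L − 1 overlapping dipeptides.  The
dipeptide universe is the 400 ordered pairs of the 20 standard residues;
pairs containing X or Z are tallied separately and excluded, so the
standard plus ambiguous tallies always sum to L − 1.  (No combinatorial
count over the standard-plus-ambiguous alphabet equals the "408" quoted
in the source description; the ordered-400 universe is the defensible
core and the separate ambiguous tally preserves the information.)

Culling mimics a redundancy-removal server with a lightweight greedy
procedure: sequences outside 40–10,000 residues, with more than one fold
family, or with an unassigned stretch over 30 residues are dropped; the
survivors are processed by descending length and rejected at ≥ 25%
identity to any retained sequence, identity being matches/overlap under
the best ungapped sliding alignment (overlaps under 10 residues ignored).
Only the thresholds matter downstream; this is not a reimplementation of
any external server.

Enrichment of item *i* in the ancient set (*nd* ≤ 0.2 by default; a
strict-< variant is a flag) is tested only when its ancient share
strictly exceeds the background share (k/n > M/N); the p-value is the
upper tail P(X ≥ k) of Hypergeom(N, M, n), the standard enrichment
convention (the point-mass form appears in some write-ups; the inclusive
tail is used here).  The fixed α = 0.01 with no multiplicity correction
is the default; Benjamini–Hochberg re-flagging is available but off.

The group-set contrast maps each counted dipeptide to the (group of
residue 1, group of residue 2) cell of a partition (9 cells for the age
groups) and compares observed counts to a free-permutation expectation:
residues of the concatenated sequences are shuffled and dipeptides
recounted, proportions averaged over permutations (the expectation
converges to the product of group marginal frequencies, which the tests
verify).  Cells with zero permutation expectation are dropped with a
warning and the chi-square df reduced accordingly.

Kyte–Doolittle means: residue sets are averaged unweighted; dipeptide
collections contribute both residue slots (occurrence-weighted).  The
scale means −0.49 over the full alphabet.

## Secondary structure

DSSP letters collapse to four region classes: H = {h, g, i},
E = {e, b}, T = {t, s}, and loop Ω for everything else (blank, and the
'-'/'C' coil conventions of simplified annotations).  DSSP 'S' (bend) is
mapped to class T: the turn/bend class definition controls, and "bend"
is the DSSP S state.  A dipeptide's class is the pair of its residues'
classes; mixed pairs are unordered boundary classes (T–Ω ≡ Ω–T), merged
because boundary categories are symmetric.

Region-bias tests use the sequence as the observation unit: per sequence,
the frequency of enriched-dipeptide occurrences in each class is compared
with the frequency of all dipeptides in that class across sequences by a
two-sided Mann–Whitney test — exact when both samples have ≤ 8
observations and no ties, otherwise the normal approximation with tie
correction.  Direction is reported only at p < α.

The loop-rigidity ratio *r* counts enriched-dipeptide occurrences
spanning a T/Ω boundary against enriched occurrences touching Ω in any
other configuration; a zero denominator is reported as undefined with a
flag rather than infinity.

Exchange groups H = {L, K, F, E, Q}, T = {S, P, T, A, R, C, G, W},
E = {Y, M, I, V, N, D, H} partition the alphabet (asserted at load).
Group frequencies are computed per sequence within each structure class —
helix subclasses are pooled into classes before per-sequence averaging
(pinned by a flag, as the alternative ordering is equally defensible) —
then compared by one-way ANOVA with Tukey HSD pairwise tests summarized
as a compact letter display at α = 0.05.

## The vis-à-vis code map

Complementation is the reverse complement over the RNA alphabet, so
codon position 1 pairs with position 3; the map is involutive and
fixed-point free (the middle base would have to be self-complementary),
giving exactly 32 unordered pairs.  Groove modes default to the
synthetase class of the encoded amino acid — class II (major groove) for
{G, A, P, S, T, H, D, N, K, F}, class I (minor) otherwise — and are
caller-overridable, since the known behavioral exceptions are
annotations, not pairing rules.  Code-expansion stages are labels
supplied by the caller; the historical binary decision tree is
represented as stage labels on cells, not as an executable classifier,
because its split criteria come from curated inputs.  Acceptor-stem
summaries count N2 (first base of the 2:71 pair) and N73 per group and
tally, over complementary codon pairs with data on both sides, whether
the N2 bases are Watson–Crick coordinated.

## Synthetic data

The generators emulate the statistical structure the analyses assume;
their defaults are the study conditions of the test suite.

**Census** (`simulate_census`; defaults 50 domains × 20 proteomes, noise
0.3).  Proteomes evolve on a random Yule topology (uniform random
splitting).  Domain *k* (birth rank *k*) is born at relative time
*k*/*n* and spreads to the proteomes of a tree clade whose size tracks
the fraction of lineages alive at its birth; occupancy is kept
non-increasing in birth rank so the noiseless construction has strictly
decreasing row sums.  Abundance per occupied proteome is
100·(1 − birth time) under multiplicative log-normal noise of scale
`noise_sd`.  The abundance model is the simplest monotone-accumulation
process consistent with the assumption that domain abundance grows with
age; no specific noise model is prescribed by the source analyses, and
any monotone-in-age model is admissible.  Row order is shuffled; the
ground truth records the birth order.

**Sequences** (`simulate_sequences`; defaults 240 sequences over 10
fold families with evenly spaced ages — a ten-fold scale-down of a
~2,400-sequence culled structural set with a ~20% ancient fraction).
Sequences come from first-order residue chains.  The enriched chain used
by ancient families (*nd* ≤ 0.2) is built from the uniform joint
dipeptide matrix plus, per planted pair (a, b), a rank-one perturbation
δ·(e<sub>a</sub> − u)(e<sub>b</sub> − u)ᵀ with zero row and column sums,
with δ set so the planted pair probability is the enrichment factor
times 1/400.  Because the perturbation leaves both residue marginals
uniform, the enrichment cannot leak into single-residue composition:
only the planted pairs are genuinely over-represented (the remaining
pairs are uniformly slightly depleted), which keeps the planted list a
well-defined ground truth for sensitivity/FDR measurement.  A literal
"multiply the transition weight and renormalize the row" construction
was rejected because row renormalization shifts the stationary residue
composition of the enriched set, making every dipeptide containing the
affected residues genuinely (if weakly) enriched and the notion of a
false positive ill-defined.  The default planted set has 30 pairs
(mirroring the scale of a 33-dipeptide enriched set) arranged so no
residue occupies either slot more than twice, which keeps the
perturbed matrix elementwise positive.  Secondary-structure strings come
from a segment process — helix/strand/turn/coil runs with
class-specific geometric lengths and one DSSP letter drawn per segment —
because only region-class statistics are consumed downstream.

**tRNA matrices** (`simulate_trna_matrix`; defaults 8 taxa, 40
characters, 24 states).  Characters are dealt round-robin to the
branches of a random rooted binary tree; each branch raises each of its
dedicated characters by Poisson(2) states from the all-zero ancestor — a
gains-only drift toward higher conformational order in which every
character changes on one branch only, so internal branches carry clean
synapomorphies and the generating tree is a most-parsimonious tree.
This is deliberate: under i.i.d. Poisson drift on all characters the
optimal trees become ladder-like (states track total path length) and
clades planted near the base resolve as paraphyletic grades, defeating
the generator's purpose of providing groups with known *S* = 0.  A
`loss_rate` parameter adds Poisson state losses on every character of
every branch for homoplasy-robustness experiments (default 0).  Planted
groups are non-overlapping clades of the generating tree (up to three,
shallowest first); their age ranks follow clade depth.

All generators are deterministic under a fixed seed.

**What the synthetic data does not capture.**  Real censuses have
lineage-specific losses, horizontal transfer and correlated proteome
sizes; real sequence sets have family-specific length and composition
structure, and real secondary structure is constrained by the sequence
itself (here the two are independent).  Passing recovery tests therefore
demonstrates the correctness and calibration of the inference machinery
under the stated generative assumptions, not the validity of those
assumptions for real genomes and structures.

## Problem sizes in the standard suites

Exhaustive-search cross-checks use 6–7 taxa (105 and 945 topologies);
heuristic-vs-exhaustive equality is measured over 100 random 7-taxon
matrices; the census recovery pipeline runs 50 domains × 20 proteomes;
enrichment calibration uses 20 generator seeds of 240 sequences each.
These sizes make every oracle comparison exact while keeping the default
test run fast.

## Known limitations

* Exhaustive search is capped at 9 taxa; heuristic optimality beyond
  that is measured, not guaranteed.
* The heuristic constrained search can in principle overestimate *S*
  on large matrices (both optima are local); exhaustive mode is exact.
* The identity-culling routine is a greedy ungapped approximation, not
  an alignment-based server.
* Region-bias testing treats sequences as independent observations;
  within-family correlation is not modeled.
* The genome-scale census tree (hundreds of proteomes, thousands of
  families) and snapshot-specific results (the published 33-dipeptide
  list, printed regression statistics) are out of desk-scale reach and
  are not reproduced.
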