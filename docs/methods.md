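# Methods

## Model

Profiles are modeled as i.i.d. draws from the pairwise maximum-entropy
distribution over binary presence vectors,

    P(n) ∝ exp( Σ_{i<j} J_ij n_i n_j + Σ_i h_i n_i ),   n_i ∈ {0, 1},

whose one- and two-column marginals reproduce the empirical frequencies
f_i and f_ij of the profile matrix. The {0,1} encoding is used throughout
(not ±1 spins); couplings quoted from Ising-convention literature must be
rescaled before comparison (J^{01} = 4·J^{±1} for the pair term, with
corresponding field shifts). The partition function is never computed:
inference goes through the mean-field or pseudo-likelihood
approximations, both deterministic, so all results are bit-reproducible
for a given input ordering.

### Profile construction

Presence means "at least one copy"; copy numbers are discarded at build
time. Domains never observed in any genome are dropped (they are
unobservable, carrying no statistics). Rows and columns are sorted
lexicographically so serialization and downstream rankings are
deterministic. Duplicate or near-duplicate species rows are retained as
given: phylogenetic redundancy is a property of real panels, not an input
error.

The frequency filter keeps a domain iff its presence count lies in
[ceil(f_min·M), floor(f_max·M)]. The ceil/floor convention is chosen so
that fractional bounds translate to the sharpest integer bounds
containing them; at M = 1041 with the default 5%/95% band this gives
counts in [53, 988].

### Mean-field inference

With pseudocount λ (default 0.01), frequencies are shrunk towards the
independent-uniform prior, f'_i = (1−λ)f_i + λ/2 and
f'_ij = (1−λ)f_ij + λ/4 (i ≠ j), the connected-correlation matrix
C_ij = f'_ij − f'_i f'_j is inverted, and J_ij = −(C⁻¹)_ij off-diagonal
(diagonal forced to zero, matrix symmetrized against round-off). Biases
follow from mean-field self-consistency,
h_i = logit(f'_i) − Σ_j J_ij f'_j. The pseudocount guards against
singular C (duplicated or nearly-duplicated columns); a singular matrix
raises an error asking for a larger λ rather than returning garbage.

### Pseudo-likelihood inference

Each domain i is fit by L2-regularized logistic regression of its column
on all others (penalties l2_J·Σ_j J_ij² and l2_h·h_i² on the
weight-normalized conditional log-likelihood; defaults l2_J = l2_h =
0.01, the customary magnitude for plmDCA-style inference). Optimization
is L-BFGS with analytic gradients, iteration cap 500; convergence is
declared at gradient norm ≤ 1e-6 and failure raises an error naming the
node. The two asymmetric estimates are symmetrized by arithmetic mean.
Row weights are supported so that an exhaustively enumerated state table
weighted by exact model probabilities can be fit directly — the
sampling-noise-free limit used by the recovery oracle.

### APC and ranking

The average product correction S'_ij = J_ij − (mean_i J)(mean_j J)/(mean
J), means over off-diagonal entries, removes rank-one background from
heterogeneous domain conservation. It is applied to the signed couplings.
Default rankings use the *uncorrected* couplings with APC as an opt-in,
since on phyletic profiles the correction's effect is limited and raw
couplings are the primary quantity; both columns are always written to
the couplings TSV. A subtlety worth recording: for a coupling matrix with
a single nonzero pair, APC removes about half of the spike (exactly
N/(2(N−1)) of it) — the correction's rank-one background estimate does
not vanish for arbitrarily sparse matrices, it vanishes only relative to
a dense heterogeneous background.

Positive and negative coupling tails are ranked separately (descending
and ascending respectively); zero couplings belong to neither. Baseline
rankings (Hamming, Pearson, Fisher) rank by relatedness in the positive
direction only — negative Pearson correlation is *not* folded into
relatedness, mirroring how positive relations are benchmarked.

## Positive relation sets

Five evidence classes; a pair may carry several labels but counts once.
The metabolic class removes currency metabolites (those participating in
more than 50 reactions, substrate or product side) *before* detecting
common-substrate / common-product / chain relations, because ATP, water
and the like would otherwise connect essentially all enzymes. Reaction
reversibility is not modeled; chains are detected in both directions,
which subsumes reversible cases. Domain pairs are emitted across reaction
pairs only, not within a single multi-enzyme reaction. The structural
class is a pass-through pair list, as it originates from a database
export rather than a computation.

## Evaluation

PPV(k) is the fraction of known positives among the top k ranked pairs.
The significance threshold is an operationalization of reading histogram
overlays by eye: couplings are ranked descending, the local PPV is
computed in a sliding window of 100 ranked pairs (window size exposed),
and the threshold is the coupling value at the deepest rank down to which
the local PPV has stayed ≥ 0.5. For a ranking whose top block is entirely
positive, this returns exactly the coupling at the block boundary.

The signed network keeps pairs with |J| above a user threshold. In the
triangle census, "frustrated" denotes the ++− sign pattern — one
mutual-exclusion link between two domains that share a positive partner —
following the usage in this analysis context rather than the physics
convention (odd number of negative edges). The census is exhaustive over
triangles via neighbor-set intersection; a cubic brute-force scan is kept
as the test oracle. The correlation-versus-distance profile uses
unweighted shortest paths (signs and weights ignored) over all profile
domain pairs; pairs disconnected from — or absent from — the network form
the baseline class, and pairs beyond d_max are dropped from the
per-distance classes.

## Synthetic data

The generator plants a sparse symmetric coupling matrix (edges uniform
without replacement, weights ±J_scale with optional ±20% jitter, biases
uniform in an interval) and samples genomes by single-site Gibbs with
fixed sweep order, burn-in 1000 sweeps and thinning 10 sweeps from a
single chain — settings validated against exhaustive enumeration of the
Boltzmann distribution at N ≤ 4. For N ≤ 20 exact state enumeration is
available and serves as the oracle for both the sampler and the
inference routes.

Default study conditions for the recovery harness, chosen to represent a
sparse, moderately coupled system at a realistic panel size (a few
thousand genomes, as in bacterial profile panels):

* recovery AUC: N = 30 domains, 8 edges (6 positive, 2 negative),
  |J| = 1, h ∈ [−1, 0], M = 5000 genomes;
* MF/PLM concordance: N = 50, 25 edges (20 positive, 5 negative),
  M = 2000;
* couplings-versus-correlations: a chain of 16 domains with repeating
  strong/strong/weak couplings (2.5, 2.5, 0.8; h = −1.5). The
  heterogeneity is the point: indirect correlation transmitted through
  two strong links exceeds the profile correlation of a weak *direct*
  link, so a local measure misranks those pairs while the global model
  attributes the indirect correlation to the strong links and still
  isolates the weak direct coupling.

Genomes are i.i.d. from the model, which real panels are not: related
species share gain/loss history, so real profile correlations contain a
phylogenetic component that i.i.d. sampling cannot produce. An optional
tree-correlated mode (genomes evolved along a random binary tree by
per-branch conditional re-equilibration of a fraction of domains,
default off) emulates that confound qualitatively, but passing recovery
tests on i.i.d. data demonstrates correctness of the inference, not
robustness to phylogenetic bias.

## Numerical choices and edge cases

* Fisher's exact test is two-sided by the standard "probability at most
  that of the observed table" rule (with the customary 1 + 1e−7 relative
  tolerance when comparing table probabilities), matching hypergeometric
  enumeration; mid-p is not used.
* Hamming distance is normalized by M; normalization does not affect
  ranking but makes scores panel-size comparable.
* Ranking ties always break lexicographically by (domain_i, domain_j).
* Filtering away all domains, or a disjoint reference set, yields a
  valid 0-column matrix plus a logged warning, not an error; a constant
  column reaching Pearson or PLM is an error naming the offending domain.
* The Gibbs sampler emits from a single chain; with thinning of 10
  sweeps its pair-frequency deviations from exact marginals are
  consistent with independent-sample Monte-Carlo error at the default
  coupling strengths (checked against enumeration), so 3·SE bounds with
  binomial SE are used in calibration checks.

## Limitations

* i.i.d. sampling understates the correlations of real panels (above);
  no gain/loss-rate or HGT model is provided.
* MF and PLM are approximations; at strong couplings both shrink
  estimates relative to planted values (ranking is far more robust than
  magnitude — see the recovery report's RMSE vs AUC).
* Dense N×N inference: memory and the pair scan are O(N²), adequate for
  domain-repertoire scales (thousands of families), not for millions of
  variables.
* Exact enumeration (and thus the oracle) stops at N = 20.
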