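# Methods

## Model

A secondary structure over a sequence of length *n* is a set of base pairs
(i, j), 1 ≤ i < j ≤ n, each position pairing at most once. Stored structures
may cross (the binary-matrix view permits pseudoknots), but every structure
*inferred* here is pseudoknot-free: no two pairs (i, j), (k, l) with
i < k < j < l. All public coordinates are 1-based, matching the CT file
convention.

Given predictions from k components for one sequence, the consensus matrix is
P(w)ᵢⱼ = Σₗ wₗ · BP(S(Aₗ,s))ᵢⱼ with weights on the probability simplex;
entries lie in [0, 1] and are interpreted as consensus pairing probabilities.
Uniform weights reduce to the plain vote tally, and the implementation makes
this an exact identity (the uniform weighted sum is computed by the same code
path, so the matrices are bit-identical).

### Structure inference

Two extractors operate on the thresholded candidate set
C(θ) = {(i, j) : P(w)ᵢⱼ ≥ θ} (the comparison is inclusive):

* **Greedy**: scan candidates in decreasing score order, accepting each pair
  iff it neither reuses a base nor crosses an accepted pair. The selection at
  a higher threshold processes a prefix of the same ranked list, which gives
  the monotonicity property: raising θ can only shrink the selected set, so
  predicted pair counts and sensitivity are non-increasing in θ.
* **Exact MEA**: the dynamic program
  M[i][j] = max( M[i+1][j], max over l with (i,l) ∈ C(θ) of
  score(i,l) + M[i+1][l−1] + M[l+1][j] ) in O(n³) time / O(n²) space,
  maximising the summed score of the selected pairs. The objective is the
  summed pair score over the thresholded candidates — there is no
  unpaired-base term, since the vote matrix defines pair entries only. This
  makes greedy and exact inference directly comparable: greedy's total score
  is bounded by the DP optimum, which in turn equals an exhaustive
  enumeration oracle on every small instance tested.

**Tie-breaking.** Ranking ties are broken lexicographically by (i, j). The DP
traceback prefers leaving position i unpaired on ties, then the smallest
pairing partner; the traceback recomputes candidate sums with the same
floating-point grouping used in the fill, so it is exact and deterministic
across platforms. Equal-score optima may therefore differ between the greedy,
DP and brute-force extractors in *which* pairs they return, but never in
total score, which is the quantity the oracle tests compare.

### Accuracy measures

A predicted pair is correct only if exactly identical to a reference pair —
no credit for one-position slips. Sensitivity = correct / |reference pairs|,
PPV = correct / |predicted pairs|, F = harmonic mean. Conventions for empty
structures: both empty → sensitivity = PPV = 1; exactly one empty → 0 (the
only reading that avoids division by zero in both ratios); F = 0 when both
inputs are 0. These conventions give the duality ppv(X, Y) = sensitivity(Y, X)
for all structure pairs.

## Resampling statistics

* **Bootstrap percentile CI** for the mean of an accuracy vector f: B means
  of with-replacement resamples of size |f|; the (1−level)/2 and
  1−(1−level)/2 empirical quantiles (linear interpolation between order
  statistics) are the bounds. Default B = 10⁴, level 0.95.
* **Paired permutation test** for mean accuracy of A vs B: the statistic is
  mean(f_A) − mean(f_B); each permutation swaps the two values at every index
  independently with probability 1/2 (equivalently, flips the sign of the
  per-index difference). The default p-value is one-sided — the fraction of
  permuted statistics ≥ the observed one — matching the percentile
  construction the test is based on; a two-sided mode
  (2·min(p≥, p≤), capped at 1) is available. Counting is inclusive with the
  add-one convention, so p ≥ 1/(B+1) and identical vectors give p = 1
  exactly. Default B = 10⁴, α = 0.05. With B = 1000 the add-one convention
  makes the realised type-I error slightly below α (≈ 0.049 nominal), which
  the calibration checks account for.
* **Spearman correlation** is Pearson on average ranks (scipy), raising on
  zero rank variance rather than returning NaN.
* The pairwise comparison report derives a per-pair seed from the master seed
  and the pair indices via `numpy.random.SeedSequence`, so the full matrix is
  reproducible. No multiple-testing correction is applied across the matrix;
  cells are raw pairwise p-values.

All randomness in the package flows from explicit seeds; no global random
state is touched.

## Parameter fitting

The training objective is the mean F-measure of the consensus prediction
over a set of (prediction-set, reference) records; greedy inference is the
default during fitting because it is orders of magnitude cheaper than the
O(n³) DP at equal final accuracy in our experiments.

The search space is (k weights, θ). Raw search variables live in [0, 1]^(k+1);
weight coordinates are clipped to be non-negative and normalised to sum 1
(uniform if all zero), θ is clipped to [0, 1]. The backend is a seeded,
iteration-bounded run of scipy's differential evolution with polishing
disabled, keeping the whole search gradient-free; the optimizer contract is
deliberately backend-agnostic (any gradient-free stochastic search honouring
the iteration budget and seed fits). The uniform-weight, θ = 0.5 baseline is
always evaluated alongside the search result and the better of the two is
returned, so fitting can never regress below the plain vote. With k = 1 the
single weight is fixed at 1 and only θ is searched. A per-record cache of
the union of proposed pairs and their predictor-membership matrix reduces
each objective evaluation to one matrix product plus inference.

Defaults: max_iterations 100, population size 15. The test suite and the
acceptance study use reduced budgets (25–40 iterations, population 10–12),
which already drive the synthetic recovery problems to mean F ≥ 0.99.

## Ablation

At each step, for every remaining predictor l the reduced ensemble without l
is re-optimized (with the current parameters, renormalised over the remaining
components, injected as a warm-start candidate) and scored on the training
set; the predictor whose reduced ensemble scores **lowest** is removed and
train/test accuracy recorded. Note the direction: this removes the *most
valuable* component first — the trace ranks components by how catastrophic
their loss is, and the weakest component is the last survivor. This matches
the procedure's defining rule ("remove the A_l for which the ensemble without
A_l performs worst"); a consequence worth spelling out is that a perfect
predictor among weak decoys is eliminated at the first step, since its
absence hurts most. The loop runs to a single survivor by default;
`stop_at_two=True` stops while two components remain. Removal ties are
broken by label order for determinism.

## Synthetic data generator

The generator emulates the study conditions every test runs under: an
ensemble of imperfect, optionally correlated predictors over random valid
references.

* **References**: pairs inserted one at a time, uniformly over the pairs
  still compatible with the current nested set and spanning j − i ≥ 4, so
  every hairpin-closing pair encloses ≥ 3 unpaired bases; insertion stops at
  the target paired fraction (`pairing_density`, default 0.5) or when no
  candidate remains (densities above ≈ 0.55 saturate; the shortfall is
  logged, not raised). Sequences are uniform over {A, C, G, U}; base identity
  is irrelevant to every computation but required by the file formats.
* **Predictors**: each true pair is kept with probability 1 − `drop_rate`
  (default 0.3); `decoy_rate` (default 3.0) spurious pairs per structure are
  drawn Poisson and added only where compatible, so outputs are always valid.
* **Correlation**: with `correlation_share` ∈ [0, 1], each predictor adopts a
  shared per-pair keep decision with that probability (else draws its own),
  and adopts each shared decoy proposal with that probability while adding
  independent extras at rate decoy_rate·(1 − share). share = 1 with identical
  noise models yields identical predictor outputs; share = 0 yields fully
  independent errors.

What the generator does **not** model: thermodynamics (no energy model, no
sequence-dependent pairing), any real predictor's error profile (real methods
make systematically structured errors, e.g. helix-register shifts, not
independent per-pair drops), unpaired-base statistics, or length/family
composition of curated benchmarks. Passing tests therefore demonstrate the
correctness and calibration of the machinery and the reality of the consensus
gain under independent-noise conditions — not the accuracy any particular
real predictor ensemble would achieve.

## Numerical and design notes

* Weights are stored normalised to sum 1 (tolerance 1e−9); parameter files on
  a percentage scale are divided by their sum on load, and θ > 1 in a file is
  treated as a percentage and divided by 100.
* A prediction missing for some sequence from some predictor is a hard error
  by default; an explicit permissive mode renormalises the remaining weights
  for that sequence and logs it, because silent renormalisation changes the
  estimator.
* Dot-bracket parsing accepts only `(`, `)`, `.` — extended bracket families
  are rejected since all in-scope structures are pseudoknot-free. `T` is read
  as `U`; unknown residues map to `N` with a warning. No minimum hairpin-loop
  constraint is imposed on *parsed* structures (component predictors enforce
  their own); only the synthetic generator enforces the ≥ 3 gap.
* CT records must be pairing-symmetric; asymmetry is an error, not silently
  repaired.
* The brute-force MEA oracle enumerates only valid (nested, one-pair-per-base)
  candidate subsets by pruned depth-first search and is guarded to ≤ 20
  candidates; it exists purely as an independent test oracle for the DP.
* CLI outputs carry a provenance header (version, command, seed, config
  hash) and identical invocations are byte-identical; exit codes are
  0 (success), 2 (input/validation error), 3 (internal invariant violation).

## Problem sizes

The shipped tests and the acceptance study use 30–100 sequences of 40–80 nt
with 3–5 predictors, 200+ random instances for the inference oracle checks,
and 1000 replicates for the bootstrap-coverage and permutation-calibration
studies — sizes at which every documented phenomenon (consensus gain,
parameter recovery, statistical calibration) is already stable and the whole
suite runs in well under a minute of compute per study.

## Known limitations

* The exact MEA objective has no unpaired-base term; methods that reward
  correctly unpaired bases would need a different recurrence.
* Pseudoknots are detected but never produced; no multi-family dot-bracket.
* Base-pair probability (dot-plot) inputs are not supported — components
  contribute a single structure each, not a distribution.
* The optimizer returns a local optimum of a non-convex objective; the
  baseline guarantee bounds it below but global optimality is not claimed.
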