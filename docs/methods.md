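# Methods

## Problem and data model

The package addresses two-group differential protein abundance from
label-free LC-MS peptide quantification at very small sample sizes
(typically five samples per group). Input is a peptide × sample matrix of
MS1 peak areas with a unique peptide→protein assignment (shared peptides
must be resolved upstream; ambiguous rows are rejected), an optional pair
of identification-confidence columns (protein-level posterior probability
and MS1 isotope dot product, both filtered at ≥ 0.9 by default, inclusive),
and a design table coding the two groups 0/1. Missing cells mean "not
detected" and are distinct from measured zeros; they are never imputed —
every center, scale and average simply ignores them.

## Preprocessing

**Log2 transform.** Non-positive linear intensities cannot be logged; the
policy is configurable (reject with an error naming the cell, or mask to
missing; the pipeline default masks).

**Central-tendency normalization.** One additive offset per sample on the
log2 scale equalizes a per-sample center statistic. Default: the *median*,
shifted to the grand median of the table — the median is robust to the
heavy right tail of peptide intensities, and grand-center targeting keeps
the table on its original scale. The fitted offsets are recorded
(`NormalizationParams`) so a run can be audited and replayed. Note that
per-sample shifts injected into the data are absorbed exactly, but the
normalized table is only defined up to one global constant (the grand
center moves with the data); the constant is irrelevant downstream because
the rollup removes location entirely.

**ZRollup.** Each peptide's profile across samples is scaled
`z = (x − center(x)) / sd(x)` with center = median by default (mean
available) and sd using the n−1 denominator; a protein's abundance per
sample is the mean of its peptides' scaled values over present cells.
Peptides with zero or undefined scale (constant profiles, or fewer than two
present values) carry no relative information and are excluded with a
warning; a protein losing all peptides is dropped; a protein/sample cell
with fewer than `min_samples_present` contributing peptides (default 1)
becomes missing. Median centering is the default because it leaves group
means free to sit off zero (mean centering forces every protein's row mean
to zero, which visibly distorts reported group means). The rollup is exactly
invariant to per-peptide additive offsets and positive rescalings — the
ionization-efficiency nuisance it exists to remove.

**Peptide-count filter.** Proteins need ≥ 2 supporting peptides (single-
peptide identifications are too fragile to quantify). The filter runs on
the peptide table before rollup, which retains exactly the proteins that
would show ≥ 2 peptides after it.

## Sparse PLS-DA

The group code is regressed on the protein matrix by the
surrogate-direction / active-set-refit sparse PLS construction: at each of
K components, the cross-covariance between the standardized predictors and
the current response residual is soft-thresholded at a fraction η of its
largest magnitude, the surviving variables join the accumulated active set,
and a plain univariate-response PLS with (up to) k components is refit on
the active set. η = 0 reduces the procedure to ordinary PLS1 (verified in
the tests against scikit-learn's NIPALS implementation to 1e-8); η → 1
keeps only the single best variable. The univariate-y PLS core is computed
directly (weight = deflated Xᵀy normalized, score/loading/deflation per
component, β = W(PᵀW)⁻¹q); no iterative inner loop is needed for a scalar
response.

Predictors are autoscaled (unit variance, n−1 denominator) by default;
constant columns are left unscaled and can never be selected. The response
is centered only. Classification thresholds the fitted linear score at 0.5
on the 0/1 code rather than wrapping a separate discriminant classifier:
the significance test operates on the regression coefficients β, so β must
be the object that defines the predictor.

**Tuning.** η ∈ {0.1, …, 0.9} × K ∈ {1, …, 5} by stratified shuffled
4-fold cross-validation (seeded; with 5+5 samples the folds are 3/3/2/2
with both classes everywhere) on mean misclassification. Ties are broken
toward larger η, then smaller K — at equal error, prefer the sparser,
simpler model. K is capped at n_train − 1 inside folds. The loss and the
fold seed are configuration, not science: with ten samples the error grid
is coarse (steps of 1/10th) and ties are common, which is why the tie-break
is normative.

## Stability and significance validation

With (η, K) frozen at the full-data tuning (retuning under every resample
is available via `retune_per_resample` but disproportionate by default —
the procedure's reference description tunes once):

* the observed leave-one-out selection frequency `f_orig` of each protein
  is computed over the n single-drop refits;
* B label permutations (default 1000) are drawn uniformly *with
  replacement*; with balanced 5+5 groups only 252 distinct arrangements
  exist, so duplicates — and occasionally the identity arrangement — are
  inevitable and deliberately kept: discarding them would bias the null;
* each permutation record holds the full-data β vector and the LOO
  selection-frequency vector computed on the permuted labels
  (like-for-like null for both tests);
* P_st = (1 + #{f_perm ≥ f_orig}) / (B + 1), with P_st = 1 by convention
  when f_orig = 0; P_si = (1 + #{|β_perm| ≥ |β_obs|}) / (B + 1).

The add-one estimator is used because it is a valid permutation P value
(never anti-conservative); its floor is 1/(B+1). Proteins with β = 0 are
flagged as carrying no weight in the classification; their P_si is 1 by the
formula (|β_perm| ≥ 0 always) and they can never be declared differential.
No multiplicity correction is applied across proteins; the two P values and
the sign constraint are jointly already conservative, and the procedure is
a screening tool, not a family-wise error guarantee.

## Decision rule and report

FC = 2^(mean₀ − mean₁) from the group means of the rolled-up abundances.
Differential ⇔ P_st ≤ α ∧ P_si ≤ α ∧ β ≠ 0 ∧ sign consistency (FC < 1,
i.e. group 1 up, requires β > 0 under the 0/1 coding; FC > 1 requires
β < 0). The threshold is inclusive (≤). FC exactly 1 is flagged
indeterminate and never declared. The report is sorted ascending by FC,
ties broken by protein id; FC is printed to two decimals, so comparisons
against printed tables use a ±0.01 envelope (the printed group means are
themselves rounded to two decimals, which limits exact agreement on a few
rows).

## Synthetic data generator

`log2 intensity = μ_g + δ_g·group(s) + o_p + c_s + ε` with protein
baselines μ_g ~ N(20, 2²) (2²⁰ ≈ 10⁶, a typical MS1 area), signed protein-
level effects δ_g (± `effect_size_log2`, default 2.0, on a random 12.5% of
proteins), peptide ionization offsets o_p ~ N(0, 2²), sample shifts
c_s ~ N(0, 0.5²), and cell noise ε ~ N(0, 0.5²); cells are masked missing
completely at random at rate 0.05. Peptide counts per protein are
2 + Poisson(3.2) (mean 5.2, minimum 2, ~1,040 peptides over 200 proteins,
the depth of the retained dataset in the study design this emulates).
Defaults: 2 groups × 5 samples, 200 proteins.

What it does *not* emulate: intensity-dependent (MNAR) missingness,
peptide-specific differential behavior (effects are inherited identically
by all of a protein's peptides), correlated proteins beyond the group
effect, retention-time or spectral artifacts, and mis-assigned peptides.
Passing the recovery tests therefore demonstrates correctness of the
statistical machinery under the generative model, not robustness to every
pathology of real label-free data.

## Problem sizes in the test and acceptance runs

The test suite exercises the full pipeline at the study's shape (200
proteins, 2 × 5 samples) with B = 199 permutations for the power check
(10 replicate generators) and B = 99 for the null-calibration check (50
replicates at 40 proteins); the acceptance script runs one complete
pipeline at B = 1000, the reference procedure's permutation count. These
sizes give Monte-Carlo errors comfortably inside the asserted margins while
keeping a full run in seconds.

## Numerical choices

* sd denominators are n−1 throughout (scaling, rollup, autoscaling).
* PLS deflation stops early when the residual weight or score norm falls
  below 1e-12 (signal exhausted); fitted components may then be fewer than
  K.
* Soft-thresholding with an all-zero cross-covariance returns the zero
  direction (nothing to select) rather than erroring; a constant response
  errors.
* All randomness flows through seeded `numpy` generators: fold assignment
  (`fold_seed`), permutations (`perm_seed`), simulation (`seed`); the CLI
  derives fold_seed = seed and perm_seed = seed + 1 and echoes all three in
  the run manifest. Repeated runs are byte-identical.

## Known limitations

* Exactly two groups; no multiclass or continuous response.
* No imputation, batch correction, or alternative rollups (reference- or
  quantile-based) in this version.
* The stability test's null statistic is the permuted-data LOO selection
  *frequency* (protein-matched); selection counts or indicators are
  equivalent up to the fixed denominator but other published variants of
  the LOO-permutation combination exist.
* With n = 10 the permutation floor at B = 1000 is ~0.001 and the
  arrangement space holds only 252 distinct balanced labelings; P values
  below ~0.004 should be read as "at the resolution floor".
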