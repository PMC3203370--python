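# Methods

## Problem setting

The package analyzes a genes × samples expression matrix `X` (n genes, m
samples, n ≫ m) annotated with exactly two phenotype groups. The goal is a
list of genes whose expression tracks the phenotype, obtained not by
per-gene testing but by unsupervised decomposition: latent components are
estimated first, the components that discriminate the groups are identified
from their sample-side weights, and the genes that load those components
strongly are reported. Two factorization models are run side by side because
they impose different — and complementary — structure.

## Preprocessing

Two normalized forms are derived from the same loaded matrix:

* **Sample standardization (ICA input).** Every sample profile is scaled to
  mean 0 and standard deviation 1 across genes, using the n−1 denominator
  (the common statistical convention; the choice is stated here because
  either denominator would be defensible). A constant sample is rejected
  rather than silently dropped.
* **Nonnegativity (NMF input).** Each gene row containing a negative value
  is shifted up by −min(row). An already-nonnegative matrix passes through
  unchanged. The per-gene shift preserves within-gene contrasts exactly,
  which is what metagene loadings summarize; a global shift would distort
  relative profiles and clipping would destroy them. Standardized data are
  never fed to the NMF track — standardization and nonnegativity are
  mutually exclusive.

Missing values are rejected at load time, not imputed: no imputation rule is
part of the method, and the simulator produces complete matrices.

## Track 1: consensus FastICA

Model: `Xᵀ = A S` with statistically independent rows of `S` (expression
modes) and square mixing `A`. Estimation steps:

1. **Whitening.** Row-center the samples × genes matrix and eigendecompose
   the (n−1)-denominator covariance of the sample profiles. All components
   with singular value above 1e−10 × the largest are retained; a
   rank-deficient input is reduced to its numerical rank with a warning, a
   zero-variance row is an error.
2. **Symmetric fixed-point iteration.** All unmixing rows are updated in
   parallel with the contrast derivative `g(u) = tanh(a₁u)` (default
   a₁ = 1.0) followed by symmetric decorrelation `W ← (WWᵀ)^{-1/2}W`.
   Symmetric rather than deflation-based estimation avoids the error
   accumulation of one-at-a-time extraction and matches how the whole
   mixing matrix is used downstream. Convergence: every component direction
   unchanged up to sign within `tol` (default 1e−6).
3. **Stall handling.** When the retained dimension exceeds the number of
   truly non-Gaussian modes — the expected regime for real expression data —
   the directions spanning the near-Gaussian remainder cycle indefinitely
   and the strict criterion is never met (the independent reference
   implementation behaves identically). Each run therefore tracks the
   iterate with the smallest fixed-point residual and stops early once the
   residual has not improved by ≥5% for 100 consecutive iterations,
   returning that best iterate flagged as non-converged.
4. **Restart consensus.** `ica_n_restarts` seeded runs (default 100) are
   pooled. Components are matched across runs pairwise by greedy absolute
   Pearson correlation of their source rows; each component's stability is
   its mean |r| to matched partners, and the run with the highest mean
   stability is returned. If no restart met the strict tolerance the
   consensus pools all runs and emits a warning rather than failing: the
   non-Gaussian components of interest stabilize long before the Gaussian
   remainder, and the stability scores make the distinction measurable.
5. **Conventions.** Source rows are scaled to unit (n−1) variance with the
   scale absorbed into `A`, and each mode's sign is fixed so its skewness is
   nonnegative. ICA is only identified up to permutation and sign; these
   conventions, plus the phenotype-anchored orientation used at selection
   time, absorb the indeterminacy completely.

## Track 2: non-smooth NMF

Model: `V ≈ W S_θ H` with `S_θ = (1−θ)I + (θ/k)11ᵀ`, θ ∈ [0, 1]. The
smoothing matrix is symmetric, doubly stochastic, and interpolates between
no smoothing (θ = 0, classical NMF) and full averaging (θ = 1). Because the
reconstruction passes through `S_θ`, the multiplicative updates compensate
by concentrating mass in `W` and `H` — the sparseness mechanism that makes
metagenes module-like.

Updates are the Lee–Seung divergence-form rules with the smoothed partner:
`W S_θ` is treated as the fixed basis when updating `H`, and `S_θ H` as the
fixed encoding when updating `W`. Each half-step monotonically decreases the
generalized KL divergence `D(V ‖ W S_θ H)`, which is recorded after every
iteration. Numerical choices:

* Factors are initialized from a seeded uniform(ε, 1] draw and floored at
  `epsilon_floor` (default 1e−9) after every update so the multiplicative
  rules cannot absorb exact zeros.
* The iteration budget is fixed (default 2000); an optional relative-change
  early stop (`rel_tol`) is available but off by default.
* Columns of `W` are rescaled to unit ℓ1 norm **after the final iteration**,
  with the inverse scale absorbed into `H`, so loadings are comparable
  across metagenes. Rescaling inside the loop would change `W S_θ H` for
  θ > 0 (the smoothing matrix does not commute with a diagonal rescaling)
  and void the monotone-objective guarantee, so it is deliberately deferred.
* An all-zero row or column of `V` triggers a warning; its factor entries
  remain at the floor.

`nsnmf_multistart` runs `nsnmf_n_restarts` seeded fits (default 40, rank
k = 2, 2000 iterations) and keeps the lowest final objective; all final
objectives are retained as diagnostics. θ defaults to 0.5 — a middle value
that demonstrably sparsifies without flattening the reconstruction; the
appropriate θ is data-dependent and exposed in the config. Hoyer sparseness
`(√d − ‖v‖₁/‖v‖₂)/(√d − 1)` is reported for every factor so the effect of θ
is visible.

## Component scoring and gene selection

* **Discrimination score.** For each mixing column, a Welch two-sample t
  statistic between the group entries plus a *sign separation*: the best
  fraction, over the two ways of assigning a sign to each group, of samples
  whose entry sign matches their group's sign. Components are ranked by |t|
  (a perfectly separated zero-variance column yields t = ±∞ and ranks
  first; an identical-groups column yields t = 0 and ranks last), with ties
  broken by sign separation then index. The pipeline auto-selects every
  component with sign separation 1.0, falling back to the top-ranked one —
  a formalization of reading a Hinton diagram of `A` by eye.
* **ICA gene calls.** The chosen mode's loadings are standardized to
  z-scores across genes and thresholded at |z| ≥ 2.5 (inclusive).
  Standardized rather than raw loadings make one threshold meaningful
  across modes of different scale. The mode is first oriented so the
  disease group (first group in the annotation's order) has positive mean
  mixing weight; z > 0 is then "up in disease".
* **NMF gene calls.** `W` is nonnegative, so selection is one-sided:
  z ≥ 2.5 on the standardized column. Direction comes from the raw data
  (mean expression in disease vs. control); an exact tie resolves to
  "down" — arbitrary but fixed and tested.
* **Classification and biclustering.** Samples are assigned to their argmax
  metagene (ties to the lowest index). Factor sorting orders genes by
  descending metagene loading and samples by descending encoding weight,
  ties keeping input order; it is a pure permutation.
* **Integration.** The two gene lists are compared as sets (intersection,
  union, Jaccard) with per-gene provenance and direction-conflict flags.

## Synthetic data

The generators plant exactly the structure each model assumes, at the
motivating study's design (5 + 8 samples; 6398 genes at full scale):

* **ICA-style.** Modes are standard-normal over genes with a sparse subset
  (default 2%) spiked to |value| = `signal_z` (default 4) — sparse spikes
  both create the heavy tails the tanh contrast targets and serve as the
  ground-truth significant genes. The mixing matrix is standard normal
  except the phenotype mode's column, which is +1 for one group and −1 for
  the other (perfect sign separation before noise). Gaussian noise
  (default SD 0.5) is added to the mixed data. Significant sets are
  disjoint across modes so sensitivity/false-positive bookkeeping is
  unambiguous.
* **NMF-style.** `W_true` holds k disjoint modules (default 50 genes) at
  loading 1.0 over a 0.05 background; `H_true` gives each group weight 10
  on its own metagene and 2 elsewhere; noise is zero-truncated Gaussian so
  the output stays nonnegative. The defaults put module genes at roughly
  4× the between-group contrast of background genes, a clearly detectable
  but noise-perturbed signal.

What the simulators do **not** model: probe-level microarray artifacts
(PM/MM, saturation), batch effects, correlated gene-gene noise, non-Gaussian
heavy-tailed technical noise, and any overlap between modules or modes.
Passing recovery tests therefore demonstrates that the estimation machinery
works when the model's assumptions hold; it does not certify performance on
real data, where modes are neither exactly independent nor exactly sparse.
Default effect sizes and noise levels are calibration choices for the
simulator, not measurements of any dataset.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at reduced scale so the whole suite completes
quickly on one CPU: recovery tests use 500–3000 genes (full 6398-gene runs
are exercised once for shape conformance and once in the acceptance
script's end-to-end pipeline), ICA recovery batches use 25 restarts rather
than the 100 of the default config (restart count affects only consensus
stability, which is already saturated at 25 on planted data), and
multi-seed rates use 10–20 seeds. The acceptance script prints each
quantity together with the problem size it was measured at.

## Known limitations

* The consensus is a lightweight stability selection (best run + pairwise
  matching), not full centrotype clustering of all restart components.
* No rank-selection procedure for k; the default k = 2 mirrors the
  two-group design and other values must be chosen by the user.
* Monotonicity of the KL objective under the smoothed updates is a
  guarantee of the update theory at θ = 0 and an empirically verified
  property (to 1e−9 per step) for θ > 0 here; no convergence proof for the
  smoothed case is claimed.
* The sample-exclusion step of the motivating study ("samples with
  significant noise") has no stated rule and is not implemented; inputs are
  taken as given. Expression scale (raw vs. log) is likewise taken as
  given.
* With only two groups and small m, the Welch t statistic on 5 + 8 samples
  is coarse; the permutation-null test in the suite quantifies how rarely a
  noise component outranks a genuinely separated one.
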