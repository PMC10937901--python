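# Methods

## Model and assumptions

Expression profiles Y₁,…,Yₙ ∈ ℝᵖ are modeled as i.i.d. with mean μ and
covariance Σ; edges of the network are the nonzero entries of the
partial-correlation matrix ρ = −Ω/√(diag Ω · diag Ωᵀ), Ω = Σ⁻¹.  The
inferential guarantees assume (i) approximately Gaussian data (rounded
counts with a moderate mean behave like Gaussian data in practice;
heavy-tailed raw counts should be transformed first), (ii) a sparse
precision matrix — each gene has conditional associations with a number
of partners that is small relative to √n, and (iii) a prior edge set
per gene of bounded size.  Under the null ρ_{j₁j₂} = 0 the de-biased
statistic √n·ρ̂_{j₁j₂} is asymptotically standard normal, which is the
basis of the thresholding procedure; the test suite verifies this
calibration empirically (KS comparison at p = 20, n = 200).

The estimator is intentionally a *testing* device: under alternatives
the de-biased ρ̂ can overshoot the population value at moderate n
(occasionally |ρ̂| > 1, which the output flags per edge), because the
de-biasing removes shrinkage bias without re-normalizing the residual
variances of fully-penalized fits.  Overshoot inflates true-edge
statistics and costs nothing for error control, which depends on the
null distribution only.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `lam` | 2√(log p / n) | node-wise lasso penalty, the standard rate for neighborhood selection; applied to unit-variance genes. Always user-overridable (`--lambda`), and per-node vectors are accepted. |
| `standardize` | `True` | scale genes to unit variance before regression so one global λ weighs all genes equally. Partial correlations are invariant to per-gene scaling, so the estimand is unchanged. With heterogeneous gene variances and standardization off, the effective per-gene penalty varies and the null statistics of structured networks become over-dispersed (empirically ~3× FDR inflation at p=100, n=80); standardization restores calibration. |
| `alpha` | 0.05 | nominal FDR level of the discovered edge set. |
| `prior` | empty | unordered gene pairs exempt from the penalty. Only well-established connections should be supplied: false prior edges inflate the realized FDR because their coefficients escape shrinkage. |
| `tol`, `max_iter` | 1e−8, 10 000 | coordinate-descent stop: largest coefficient change per full sweep. |

Simulation engine defaults mirror the validation study conditions:
compound-symmetric blocks with diagonal ~ U(1, 1.25) and off-diagonal
~ U(0.3, 0.5); Erdős–Rényi edge probability η and Barabási–Albert
attachment count e as supplied; nonzero precision entries uniform on
(0.2, 0.5) with a fair sign coin; diagonal set to the absolute row sum
plus 0.1; count data rounded from N(10, Σ) and floored at zero.  Priors
are parameterized by PIS (fraction of true edges included) and PA
(fraction of prior edges that are true); false prior edges are sampled
uniformly from non-edges so that true/total = PA.

## Numerical choices

* **Penalized solver.**  Cyclic coordinate descent on the shared Gram
  matrix ("covariance updates"), one batched solve for all p node-wise
  regressions; the prior-exempt solve warm-starts from the
  fully-penalized solution.  The univariate update is the closed-form
  soft threshold, verified against sklearn's Lasso to 1e−7.  Intercepts
  are handled by mean-centering.  Constant (zero-variance) genes get
  zero coefficients everywhere, a logged warning, and ρ̂ entries of 0.
* **Diagonal rule in the simulator** uses *absolute* row sums + 0.1:
  with mixed-sign entries a signed row sum need not dominate, and
  strict diagonal dominance is what guarantees positive definiteness
  (every eigenvalue ≥ 0.1 up to rounding, by Gershgorin).
* **Threshold selection** computes the exact infimum of the FDR
  criterion over τ ∈ (0, 2].  Between consecutive observed values of
  |T|/√(log p) the discovery set is constant while B(τ) decreases
  continuously, so the first feasible interval is found by scanning the
  sorted candidate values and the crossing point inside it is solved in
  closed form through the normal quantile.  This matches a dense
  brute-force grid scan at the grid's resolution (asserted at step
  1e−4).  When no τ satisfies the criterion the most conservative value
  τ̂ = 2 is returned and flagged (`fallback_used`); the infimum of an
  empty set is otherwise undefined.
* **Counting convention.**  |D(τ)| counts ordered pairs (twice the
  unordered count) so that it is on the same scale as the worst-case
  null count m₀ = p² − p; halving both leaves the criterion unchanged.
  m₀ is used as-is (no estimated-null fraction), making the procedure
  operate like a Benjamini–Hochberg rule asymptotically.
* **No clipping.**  ρ̂ is not clipped to [−1, 1] before forming √n·ρ̂ —
  clipping would distort the tail the calibration relies on.  Output
  tables carry an `abs_rho_gt_1` indicator instead.
* **Ties** in ROC/PR sweeps enter together (strictly-greater threshold
  rule, matching the discovery rule); equal-statistic edge groups are
  atomic, and a fully tied matrix yields AUC 0.5.
* **Excess power** (TP − TP_prior)/(m₁ − TP_prior) is reported as
  missing when the prior covers every true edge (m₁ = TP_prior), not
  coerced to 0.
* **Reproducibility.**  One root seed per experiment; per-replicate
  generators are spawned as `default_rng([seed, rep])` so any replicate
  can be regenerated in isolation.  Inference itself is deterministic
  given (Y, prior, λ, α).

## Pseudogene supplementation

Appending Z ~ N(0,1) and setting Ỹ = Y + aZ gives supplemented data
with covariance [[Σ + aaᵀ, a], [aᵀ, 1]], whose precision matrix has Ω
as its upper p×p block — the original network is untouched (verified
exactly over random SPD draws).  The pseudogene's partial correlations
are proportional to (Ωa)ⱼ.  Note this is nonzero not only on the
support of a but also for network *neighbors* of supplemented genes; the
support of a equals the pseudogene's true edge set only when the
supplemented genes have no other connections.  The bundled recovery
experiment therefore attaches the pseudogene to genes that are
conditionally independent of the rest (the remaining genes carry an
Erdős–Rényi network, whose discoveries realistically lower the
selection threshold), making the false-positive count well-defined.
Coefficient magnitudes default to |aⱼ| = 2 with random signs — strong
enough that, with ~10 connections sharing the pseudogene's unit
variance, each true edge sits near the per-edge ceiling
|ρ| ≈ 1/√(#connections); weaker choices probe the power curve rather
than the calibration.

## What the simulations do and do not show

The generator reproduces the structural features the method is
sensitive to — sparsity patterns (clustered, homogeneous-random,
hub-dominated), signal magnitudes on the scale of real co-expression
partial correlations, p ≫ n regimes, and integer-valued data — under
exact i.i.d. multivariate normality with a precision matrix fixed
across replicates.  It does not emulate library-size variation,
negative-binomial overdispersion, batch effects, or temporal dependence
(time-course samples are treated as i.i.d.).  Passing tests therefore
demonstrate correctness of the procedure and its calibration under the
model, not robustness to real-data artifacts; group-centering
(`center_by_group`) removes known treatment/genotype effects before
analysis, and raw counts should be variance-stabilized upstream.

## Validation problem sizes

The bundled checks run at deliberately modest scale so the whole suite
completes in minutes on one core: the FDR/power study uses one fixed
scale-free precision matrix (p = 100, n = 80) with 100 replicates
(Monte-Carlo SE of the mean FDP ≈ 0.008); null calibration pools 1 900
statistics over 10 replicates; the pseudogene experiment uses 50
replicates at p = 50, n = 200.  The `n_reps` and grid parameters of
`SimulationConfig` scale every study up (e.g. to 500 replicates or the
full 12-setting structure × sparsity × dimension grid) without code
changes.

## Known limitations

* Dense-matrix implementation: intended for p up to a few thousand.
* λ is not selected by cross-validation; the default rate is the
  analysis-friendly choice and can be overridden.
* Prior accuracy is trusted as given — there is no internal screening
  of prior edges; inaccurate priors inflate realized FDR.
* The strict-inequality discovery rule makes edges with statistics
  exactly at the threshold (measure-zero for continuous data)
  non-discoveries.
* With an accurate but small prior (≈30% of edges) on strong-signal
  scale-free networks, the no-prior procedure already detects most
  edges and the measured power gain from the prior, while nonnegative
  on average, need not be strictly positive in most individual
  replicates; the gain grows with prior size and with structures whose
  edges are individually harder to detect (e.g. compound-symmetric
  blocks, where we observe power 0.62 with a 70% prior vs 0.16
  without).
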