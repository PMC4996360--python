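# Methods

## Normalization

**MHMN.** Given an `M × N` matrix of finite expression values, the pooled
sort of all `M·N` values is split into `M` consecutive bins of `N` values
(`pool_and_bin`); each column is stably sorted (`column_sort`); rank row `i`
of the sorted matrix is mapped linearly onto `[min B(i), max B(i)]`
(`scale_row`); and the values are returned to their original within-column
positions. Consequences that the test suite pins down: the rank-`i` value of
every column lies inside bin `i`; the global minimum and maximum of the
matrix are unchanged; within-column order is preserved in the weak sense
(values can merge when a rank row or a bin is degenerate, but never reorder);
and when each rank row's multiset equals its bin, MHMN is the identity.

**QN.** Stable sort per column, replace each rank row by its cross-column
mean, un-sort. No tie-averaging adjustment is applied (tied values receive
the value of their stable rank, so results differ from tie-averaged QN
variants only on tied inputs). After QN the sorted values of every column are
identical as a sequence — the property that makes QN safe for rank-based
analysis and lossy for continuous models. One useful corollary, exploited in
a test: adding a constant to one column adds `δ/N` to *every* QN output
entry, so gene–gene Pearson correlations after QN are exactly invariant to a
single-column additive artifact.

**Numerical choices.** All computation is double precision with no rounding.
In `scale_row`, entries equal to the row extremes are pinned bit-exactly to
the bin endpoints (the affine formula can be off by one ulp); a degenerate
row (zero spread, where the scaling is 0/0) maps to the bin midpoint, which
reduces to the correct constant when the bin is also degenerate. All sorts
are stable and un-sorting uses the inverse of the stable permutation, so tied
values return to their exact original positions. Missing values are rejected
rather than imputed: the binning step needs exactly `M·N` observations.

## Time-series simulator

Each simulated dataset has three patterned genes — increasing ramp,
decreasing ramp (`baseline ± amplitude·t/(N−1)`), and a sinusoid
(`baseline + amplitude·sin(2πt/period + phase)`, default period `N/2`, i.e.
two cycles) — plus random-level genes whose constant baseline is drawn
`Uniform(1, 10)` per gene. Defaults: amplitude 5, baseline 5, Gaussian
observation noise with sd = 10% of amplitude (0.5 for the random genes).
The time grid is the integer indices `0 … N−1`. The plate effect draws one
column (uniformly, or a fixed index) and one magnitude
`Uniform(magnitude_range)` — default `(0.5, 2)` — and applies it to the whole
column, additively or multiplicatively: an array-level artifact is a shared
shift/scale, not per-entry noise.

The generator emulates the structure of small designed time-course
experiments (a few genes with clear temporal signal among genes without). It
does *not* model intensity-dependent variance, probe effects, or correlated
noise, so benchmark results speak to array-level artifacts only.

`large_matrix_standin` is the genome-wide analogue used by the
subset-correlation benchmark: every gene gets a smooth temporal pattern with
per-gene random kind, amplitude `Uniform(0.5, 5)`, baseline `Uniform(1, 10)`,
period and phase. This reflects the feature of real transcriptome time
courses that the large-data regime depends on: gene–gene correlations are
dominated by temporal signal, not by observation noise. A stand-in made of
flat noise-only genes lacks that property — its correlations are pure noise
artifacts, and the two normalizations then behave measurably differently at
any matrix size.

## Linear ODE networks

Networks are binary adjacency matrices with weights `Uniform(−1, 1)`
(exact zeros redrawn) on `n_edges` positions drawn uniformly without
replacement among all `n²` ordered pairs, self-loops included (they are the
decay/self-regulation terms). `dx/dt = W x` is integrated with DOP853 at
rtol 1e-10 / atol 1e-12 and evaluated on a regular grid of `n_samples`
points including `t = 0`; sampled states are cross-checked against the
matrix-exponential solution in the tests. Trajectories exceeding `1e12` in
magnitude raise an instability error; `sample_stable_system` rejects and
redraws (up to 50 attempts) any network whose sampled trajectory exceeds
`10³ × max|x0|`, keeping dynamics in a reasonable range without biasing
toward a particular spectrum. Initial values are `Uniform(1, 10)` per
component; the default horizon is `t_end = 3` with 16 samples.

## Parameter inference

Derivatives are estimated by finite differences on the sampling grid
(central at interior points, one-sided at the ends), followed by ordinary
least squares of `dx/dt` on `x`, solved by SVD with a relative
singular-value cutoff (`rcond`). The full `n × n` matrix is estimated by
default; a boolean support mask restricts the regression to a known edge set.

Identifiability matters here: a *single* trajectory only excites part of
state space. The extreme case is uniform decay `W = −I`, whose trajectory
`x(t) = e^{−t}x0` spans a rank-1 subspace — the full-matrix problem then has
infinitely many solutions and the minimum-norm one is `−x0x0ᵀ/‖x0‖²`, not
`−I`; recovery of `−I` requires the support mask (a test documents both
facts). Generic networks with distinct eigenvalues are identifiable but often
badly conditioned (`σ_min/σ_max ∼ 1e−5` at 16 samples), and with
machine-precision `rcond` the finite-difference noise is amplified
catastrophically. The benchmark therefore uses `rcond = 1e−2`, chosen by a
convergence study on clean unnormalized data: the cutoff sits at the relative
noise floor of the finite-difference derivatives (discrepancy principle),
minimizing clean-data error (median log10 edge-weight error ≈ −0.7 versus
≈ +0.7 uncut). The cost is a bias plateau: with the cutoff active,
refinement of the sampling grid stops improving the estimate once truncation
bias dominates, so the convergence tests use `rcond=None` on well-conditioned
systems. A tolerance of 1.5 relative Frobenius error for 16-sample inference
on random sparse 4-node systems comes from the same study (observed maximum
1.43 over 100 systems).

Parameter errors are reported as `log10(|ŵ − w| + 1e−12)` per entry; the
floor keeps exact recoveries finite (at −12). Log base 10 is a display
convention — KS comparisons are invariant to it.

## Benchmarks

All three experiments are pure functions of `(config, seed)`; replicate
seeds are drawn from one master generator, and results serialize to JSON
(config echo, seed, per-replicate errors, KS summary).

**Correlation benchmark** (default 500 replicates; the acceptance run uses
100): simulate 8×16, record the Pearson correlation matrix of the clean
data, apply additive plate noise, normalize with each method, and score
`log10` of the Frobenius norm of the difference between the normalized and
the clean correlation matrices (exact zeros floored at 1e−12). The ground
truth is deliberately the pre-noise, pre-normalization data. Zero-variance
gene rows have undefined correlations; they are masked and excluded from the
Frobenius sum.

**Subset benchmark**: normalize one large matrix once per method (after the
optional plate effect), then score the same correlation error on random
gene subsets (default 1000 subsets of 10) against the clean data's subset
correlations. On the 20,000×5 stand-in the QN and MHMN error distributions
are statistically indistinguishable — with `M ≫ N` the bins shrink to
near-points and both methods converge to mapping each column onto the pooled
histogram.

**ODE benchmark** (default 100 experiments): node count uniform on {4, 5},
edge count uniform on `[n, 2n]` (sparse, like real regulatory networks —
and necessary: dense random networks make single-trajectory identification
ill-conditioned for *every* method, drowning the normalization effect in
estimator error), multiplicative plate noise on one sampled time point
(additive selectable), methods raw/QN/MHMN, full-matrix inference, pooled
per-parameter log errors, two-sample KS (asymptotic p; sample sizes are in
the thousands) between the QN and MHMN pools.

## Known limitations

- MHMN requires the complete matrix; no missing-value handling.
- The simulators model array-level artifacts only; nothing is claimed about
  intensity-dependent or probe-level error structure.
- Inference is restricted to the linear model with plain least squares; the
  estimator interface accepts alternative implementations (e.g. a transition
  -matrix logarithm) behind the same contract, but none is provided.
- With the SVD cutoff active, inferred matrices are biased toward zero in
  poorly excited directions; comparisons between normalization methods are
  unaffected (all methods share the estimator), but absolute error levels
  should not be quoted as the estimator's best achievable accuracy.
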