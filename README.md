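# mhmnorm

Inter-array normalization for time-series expression matrices, built around
**modified histogram matching normalization (MHMN)** with classical
**quantile normalization (QN)** as the reference comparator, plus the
simulation benchmarks that show where the two methods differ.

## The problem

In a microarray (or bulk expression) time course, each array is one time
point, so any array-level technical bias — a "plate effect" that shifts or
scales every measurement of one array — masquerades as a temporal change.
Inter-array normalization removes such bias, but the popular choice, QN, does
so by force: it replaces the rank-*r* value in every column by the mean of
the rank-*r* values across columns, so after QN **every time point contains
exactly the same set of numbers**. Rank information survives; the *amount* by
which a gene rises or falls between arrays does not. That loss is harmless
for rank-based analyses but damaging when the downstream model is
continuous — e.g. a correlation network, or a linear ODE model
`dx/dt = W x` whose interaction matrix `W` is inferred from the sampled
trajectories.

## The method

For an `M × N` matrix (M genes, N time points), MHMN:

1. sorts all `M·N` values of the matrix by magnitude;
2. partitions the sorted pool into `M` consecutive bins `B(i)` of exactly
   `N` values;
3. sorts each column, giving the rank matrix `S` with entries `s_ij`;
4. rescales row `i` of `S` linearly into the range of bin `i`:

   `f(s_ij) = (max B(i) − min B(i)) · (s_ij − min S(i)) / (max S(i) − min S(i)) + min B(i)`

5. returns each scaled value to its original position within its column.

Every column then follows the pooled histogram of the whole dataset (like
QN, this removes array-level bias), but within each rank the *contrast*
between arrays is preserved up to a linear map — exactly the information a
continuous-time model needs. A degenerate rank row (all `N` values equal)
maps to its bin midpoint; all sorting is stable, so tied values return to
their original positions.

## Worked example

The 2×2 matrix `[[1, 10], [2, 3]]` (two genes, two time points), as a TSV:

```
gene	t0	t1
g0	1.0	10.0
g1	2.0	3.0
```

```bash
$ mhmnorm normalize --method mhmn --input toy.tsv --output toy_mhmn.tsv
$ cat toy_mhmn.tsv
gene	t0	t1
g0	1.0	10.0
g1	3.0	2.0

$ mhmnorm normalize --method qn --input toy.tsv --output toy_qn.tsv
$ cat toy_qn.tsv
gene	t0	t1
g0	2.0	6.0
g1	6.0	2.0
```

Hand-checking MHMN: the pooled sort is `1,2,3,10`, so the bins are `{1,2}`
and `{3,10}`. Column-sorting gives rank rows `[1,3]` and `[2,10]`; scaling
maps `[1,3] → [1,2]` and `[2,10] → [3,10]`; un-sorting restores the original
column order. Note both columns now hold one value from each bin, yet column
t1 keeps its large spread (`10` vs `2`). After QN, both columns consist of
the identical values `{2, 6}` — the between-array contrast is gone.

The benchmarks (library functions `run_correlation_benchmark`,
`run_subset_correlation_benchmark`, `run_ode_benchmark`, or the CLI):

```bash
$ mhmnorm benchmark correlation --reps 100 --seed 1 --out corr.json
median log10 error [qn]: 0.5272
median log10 error [mhmn]: 0.4644
KS (qn vs mhmn): D=0.3800, p=5.33e-07
```

Each replicate simulates an 8-gene × 16-time-point dataset (increasing,
decreasing and sinusoidal genes plus random-level genes), perturbs one random
time point with additive plate noise, normalizes, and reports the log10
Frobenius distance between the normalized and the original correlation
matrices — MHMN preserves the correlation structure better, and the KS test
confirms the two error distributions differ.

```bash
$ mhmnorm benchmark ode --experiments 100 --nodes 4 5 --seed 1 --out ode.json
median log10 error [raw]: -0.7390
median log10 error [qn]: -0.2519
median log10 error [mhmn]: -0.4029
KS (qn vs mhmn): D=0.1287, p=2.47e-15
```

Here each experiment draws a random sparse 4–5-node network, simulates
`dx/dt = W x`, samples 16 time points, multiplies one random time point by a
random factor (plate effect), normalizes, and re-infers `W` by least squares
on finite-difference derivatives; the numbers are median log10 absolute
errors of the inferred parameters. Without noise the raw data is best, but
once an array-level artifact is present, normalization is needed — and MHMN
loses far less of the dynamics than QN.

Other entry points: `mhmnorm simulate timeseries`, `mhmnorm simulate ode`,
`mhmnorm infer ode`, `mhmnorm benchmark subset`. See `docs/methods.md` for
models, parameters, and numerical choices.

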