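# Methods

## The problem and the model

A sample x₁, …, xₙ is drawn from a normal population, except that at
most one observation — the *contaminant* — may come from a slipped
distribution: N(δ, 1) under slippage of central tendency, or N(0, ε²)
(standard deviation |ε|) under slippage of dispersion. A discordancy
test looks at the sample's extreme observation and decides, at a chosen
confidence level, whether it is consistent with the normal model. The
package measures, by Monte Carlo simulation, how often four classical
tests make the right call as a function of n, δ or ε.

The *outlier* (the observed extreme) and the *contaminant* (the
observation generated from the slipped distribution) need not coincide:
with small slippage the contaminant often lands at an inner position of
the ordered array, and the extreme under evaluation is then a perfectly
legitimate observation.

## Test statistics

All four statistics are location/scale invariant and are listed in
`stats.py`: Grubbs's extreme studentized deviate N2, Dixon's gap/range
ratio N8, the absolute sample skewness N14, and the sample kurtosis
N15. The standard deviation uses the n − 1 denominator; since the same
convention is used when simulating critical values, verdicts are
insensitive to the choice, but it is fixed and documented. Degenerate
samples (zero spread) raise an error rather than returning 0 or ∞.

Each statistic has upper, lower and two-sided application modes. The
two-sided mode — the max-form for N2/N8, the absolute value for N14,
and the plain value for N15 — is the form used both for the null
simulation of critical values and for every test application in the
Monte Carlo experiments. The *tested rank* reported with a result says
which extreme the application evaluated: the side of the larger
one-sided form for N2/N8, the sign of the skewness for N14, the extreme
farther from the mean for N15. Exact ties (possible only on crafted
symmetric inputs; a probability-zero event under continuous sampling)
resolve to the highest observation so results are deterministic.

## Critical values

Critical values are empirical quantiles of the simulated null
distribution: the two-sided statistic evaluated on R independent
N(0, 1) samples of size n, with the quantile taken by linear
interpolation between order statistics (the "type 7" rule). Each table
entry records its replication count, derived seed and quantile method,
so tables regenerate bit-identically from one base seed (per-entry
seeds are SeedSequence hashes of (base seed, test code, n), masked to
31 bits).

For N2 the exact two-sided critical value is known in closed form,
cv = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t
quantile on n − 2 degrees of freedom; the test suite checks the
simulated quantile against it within three Monte Carlo standard errors
at every n in 5..20 (the standard error of an empirical quantile is
estimated as √(q(1−q)/R) divided by a finite-difference density
estimate). Shipped defaults: confidence 0.99; R = 2×10⁷ for production
tables, smaller counts for interactive use.

## Simulation protocol

One replication draws n − 1 base observations from one generator
stream, one contaminant observation from a second stream, and an
insertion position from a third, so chunked and unchunked generation
consume the value streams identically. Streams are PCG64 generators
seeded by SeedSequence mixing of (base seed, experiment id, role), one
triple per experiment — every experiment in a grid has its own streams
and the whole campaign reproduces from a single integer.

Each test is applied **two-sided** against its critical value;
significance requires a strict exceedance, TN > CV (a tie counts as not
significant). A contaminated replication is classified as a **C event**
when the contaminant is the observation under evaluation — the array's
outlier in the deviation sense, i.e. the extreme farther from the
sample mean — and a **C̄ event** otherwise. The classification is a
property of the sample, shared by all tests applied to it, and is
resolved by tracking the contaminant's index through the ordering
(never by comparing floating-point values). The four contaminated
outcome probabilities are conditional rates within the C and C̄
classes:

    π_D̄C̄ = #(not significant, C̄)/#C̄     π_DC̄ = #(significant, C̄)/#C̄
    π_D̄C  = #(not significant, C)/#C      π_DC  = #(significant, C)/#C

so each pair partitions to 1 exactly (counts stay integers until the
final division). With this structure the near-null conditional
significant rates both calibrate to 1 − confidence (≈ 0.01), and the
two criteria are

    Ω     = π_DC̄ + π_DC           (Power of Test)
    π_D|C = π_DC/(π_DC + π_D̄C)    (conditional power, P5; equals π_DC).

At large slippage no C̄ events occur in finite M; the spurious rates
are then reported as 0, so Ω reduces to π_DC = π_D|C. When no C events
occur (tiny M edge case) the conditional power is returned as an
explicit undefined marker (None) rather than 0 or NaN, so aggregation
can skip it. These application and classification conventions were
fixed by validating the pipeline's output against independently
published values of all four probabilities across location and scale
slippage at n = 5–20; alternatives (one-sided forced application,
per-test classification sides, joint rather than conditional rates)
fail that validation and are not offered.

Uncontaminated cells (δ = 0 or ε = ±1) still draw one observation from
the second stream — with no slippage — and report the plain true
negative and type I fractions of M.

Because the slipped-contaminant construction is mirror symmetric, −δ
(or ε < −1) cells are distribution-identical to +δ (or +|ε|) cells;
grids simulate the positive branch once and report it as the pooled ±
row. The symmetry itself is asserted in the test suite by simulating
both signs.

## Experiments, uncertainties, comparisons

A *cell* of the design is one (n, contamination) combination. Within a
cell all requested tests are evaluated on the same M replications
(paired design): between-test comparisons are within-sample, which
reduces the variance of percent differences and cannot bias the means.
E independent experiments per cell give, for every quantity, a mean and
a u99 half-width t_{0.995, E−1}·sd/√E — Student t rather than normal,
which matters at small E. The worst-case single-experiment binomial
error is 2·√(0.5·0.5/M) (0.00022 at M = 2×10⁷). Percent differences use
Grubbs N2 as the reference: Δx̄ = 100·(x̄_test − x̄_N2)/x̄_N2.

Desk-scale defaults (grid runner: E = 10, M = 10⁶; acceptance script:
M = 2×10⁶ per cell with 10⁷-replication critical values; test suite:
cells of 2×10⁵–5×10⁵ × 5–8 experiments, critical-value sweeps at
10⁶–10⁷) were chosen from binomial power calculations so that every
assertion's tolerance exceeds its sampling uncertainty severalfold; a
full production campaign (M = 2×10⁷, E ≈ 100, all cells) uses the same
code paths and is a matter of compute time only.

## What the generator emulates — and what it does not

The synthetic data are exactly the model under study: i.i.d. normal
samples with at most one slipped observation. Real laboratory data
depart from this in ways the simulation deliberately excludes —
multiple outliers (and the masking/swamping interactions between them),
non-normal parent distributions, serial correlation, rounding and
detection limits. Passing results therefore quantify the tests'
behaviour *under the normal single-contaminant model*, not their
robustness beyond it; the multiple-outlier problem in particular is out
of scope (consecutive application of single-outlier tests is not
simulated).

## Numerical choices

* Verdicts use strict inequality TN > CV; TN = CV is not significant.
* Quantiles: numpy's linear (type 7) rule, frozen and recorded.
* Conditional rates for an empty conditioning class are 0 (Ω) or an
  undefined marker (π_D|C).
* Vectorized kernels (`bulk_statistics*`) process replications in
  chunks of 5×10⁵ rows; results are independent of the chunk size.
* Results CSVs print floats at 17 significant digits and are re-read
  with round-trip parsing, so write/read is bit-exact; the decimal
  point is locale-independent.

## Known limitations

* Only the four two-sided single-outlier statistics are implemented; no
  one-sided-only Dixon variants, no multiple-outlier tests, no robust
  estimators.
* Critical values for N14/N15 have heavier-tailed null distributions,
  so their empirical quantiles carry larger Monte Carlo errors at equal
  R; near half-power, a critical-value error propagates into Ω with a
  gain of order the alternative density (up to ~10 for N2 at n = 5).
  Use R ≥ 10⁷ where third-decimal accuracy of power values matters.
* The runner is single-process; cells are embarrassingly parallel and
  deterministic per (base seed, experiment id), so external
  parallelization is safe, but none is built in.
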