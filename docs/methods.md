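# Methods

## Model

Each transcript is treated as a well-mixed pool with first-order
degradation:

    dRA/dt = TR(t) − k_D(t) · RA(t)

with RA the mRNA amount (arbitrary units after normalization) and TR the
synthesis rate (units/min). Two assumptions discretize the problem onto
the sampling grid (default 0, 4, 11, 16, 26, 40 min, the heat-shock
design):

1. **Steady state at time 0.** The pre-shift culture is in balanced
   growth, so RA is constant and k_D(0) = TR(0)/RA(0). This anchors all
   relative k_D values; genes with TR(0) = 0 or RA(0) ≤ 0 are excluded
   from inversion and listed in the run summary.
2. **Piecewise structure within intervals.** TR varies linearly between
   consecutive samples and k_D is constant within each interval — the
   finest structure the data can support, since each interval contributes
   a single equation.

Under these assumptions the balance integrates in closed form. With
TR(s) = TR₁ + m·s, m = (TR₂−TR₁)/Δt, s ∈ [0, Δt]:

    RA₂ = RA₁·e^(−kΔt) + TR₁·(1−e^(−kΔt))/k + m·(kΔt−1+e^(−kΔt))/k²

whose k→0 limit is RA₁ plus the trapezoidal integral of TR. For
kΔt < 10⁻² the two non-homogeneous coefficients are evaluated by series
truncated after the x⁴ term (truncation ~x⁵): the exact expressions lose
roughly eps/x² relative accuracy to cancellation there, which would cap
the accuracy of the inversion for slowly decaying transcripts. The
closed form is validated against a fixed-step RK4 integration (an
independent oracle kept in the tests) to 10⁻⁶ relative over 1000 random
parameter draws.

## Interval inversion

RA₂ is strictly decreasing in k_D at fixed endpoints, so the
interval-mean k_D solving the equation is unique whenever RA₂ lies below
the zero-decay bound RA₁ + (TR₁+TR₂)Δt/2. The root is found by bisection
on [0, 10] min⁻¹ (10 min⁻¹ ≈ 4 s half-life, beyond any plausible mRNA),
expanding the bracket tenfold when needed (flag `bracket_expanded`,
capped at 10³). Bisection runs to an absolute k_D tolerance of 10⁻¹²
with no residual-based early exit — an early exit at a relative RA
residual of 10⁻⁸ was found to limit recovery to ~10⁻⁵ relative for
k_D ≈ 10⁻⁴ min⁻¹, short of the 10⁻⁶ recovery the pipeline guarantees on
noiseless data. An observed RA₂ at or above the zero-decay bound is
unreachable for any non-negative k_D and is reported as k_D = 0 with
flag `no_positive_root` (`at_zero_bound` when within tolerance of the
bound) rather than allowing unphysical negative decay; cluster averaging
includes such genes as 0 and counts the flags. Estimates are assigned to
interval midpoints, and relative values are k_D/k_D(0).

Replicates (triplicate by default) are averaged per gene and time before
inversion, so one inversion is performed on the mean curves.

## Temperature correction of TR

Run-on incorporation measures polymerase density, not flux; when the
temperature jumps 25→37 °C the elongation rate rises, so post-shift TR
under-reports synthesis. Assuming Arrhenius dependence of the catalytic
constant, the fold change is exp[(Ea/R)(1/T₁ − 1/T₂)] with
R = 1.987×10⁻³ kcal/(mol·K). For the two available activation energies
of the bacterial elongation step, 13 and 9.7 kcal/mol, the factors are
2.34 and 1.88 (mean ≈ 2.1), supporting the conventional fixed factor 2
applied to all post-shift TR values — the default
(`temperature.mode: fixed_factor`, `temperature.factor: 2`);
`arrhenius` mode derives the factor from configurable Ea/T₁/T₂. The
correction records itself on the data and refuses re-application.
Simulated datasets carry true synthesis rates and should be analyzed
with the correction off.

## Stability classification

The theoretical RA trajectory propagates the measured TR forward from
RA(0) with k_D frozen at k_D(0). Per gene, over the post-shift points:
mean log₂(RA/RA_theo) calls the gene stabilized (> +0.3), destabilized
(< −0.3) or unchanged; the Pearson correlation between the two curves is
reported as a goodness-of-prediction statistic. The 0.3 log₂ threshold
(≈1.23-fold) is a configurable screening default
(`stability.log2_threshold`); no published quantitative criterion exists
for it. TR direction uses the same threshold on mean log₂(TR/TR(0)), and
genes are tallied homodirectional (TR up & stabilized, or TR down &
destabilized), antagonistic (the opposite pairings) or neutral. Both the
per-gene tallies and cluster-level mean curves are reported, since
genome-wide percentages depend on which of the two views is taken.

## Profile clustering

Each gene's ten-point profile is log₂ TR(tᵢ)/TR(t₀) at the five
post-shift times concatenated with the same for RA (time 0 is implicitly
0 on the log scale). Clustering is a self-organizing tree (SOTA): a
binary tree of centroids grown from one cell; each growth cycle runs
presentation epochs (winner updated with rate 0.01, its leaf sibling
0.005, parent 0.001; epoch error tolerance 10⁻⁶, at most 200 epochs),
then splits the leaf with the highest heterogeneity (mean member
distance to centroid), stopping at `max_clusters` (default 16) or below
a heterogeneity threshold. Two implementation choices sharpen the
classical scheme while preserving its tree structure: split children are
initialized on either side of the leaf's principal axis (deterministic
differentiation of the two cells), and after each growth step members
are batch-reassigned to their nearest leaf with centroids reset to
member means until stable, so converged leaves always satisfy
centroid = member mean. The procedure is deterministic given the input
order.

The default distance is 1 − Pearson correlation, the customary choice
for expression shapes. Internally correlation mode operates on
row-standardized profiles (centered, unit norm), where 1 − r equals half
the squared Euclidean distance; this makes mean centroids geometrically
correct and the assignments exactly invariant to per-gene affine
transforms a·x + b (a > 0). Squared-Euclidean on raw profiles
(`clustering.distance: euclidean`) is available when overall magnitude
should separate clusters. Per-cluster summaries are the mean relative
k_D per interval midpoint (flag-filtered, with standard errors) and mean
experimental vs theoretical RA curves relative to their time-0 means.

## Set enrichment

The binomial screen treats the n genes of a cluster as draws with
success probability equal to the target set's share of the universe and
reports the exact upper tail P(X ≥ k); the default report threshold is
p < 10⁻⁶ on raw p-values (a Bonferroni column is emitted for reference
but does not drive the `significant` flag). Which side constitutes the
"draws" is a modeling choice; this implementation fixes draws = cluster
genes. The hypergeometric tail is available as an option and underlies
the Monte-Carlo mode, which draws `n_sims` (default 1000) random
same-size clusters and adjusts each set's p family-wise as
(b+1)/(n_sims+1), b = number of null draws whose *best* per-set p is at
least as extreme. The minimum adjusted p across sets is uniform under
the null (verified by KS test over 200 seeded repetitions); any single
set's adjusted p is conservative by construction when other sets are
tested alongside.

## Half-life fitting from shutoff series

Band intensities are background-subtracted (local background region per
band), divided by the loading-control signal, and referred to the time-0
sample. Corrected values driven non-positive by background subtraction
are floored at 10⁻⁶ of the time-0 value, flagged, and excluded from
window selection. First-order decay makes ln(value) linear in time with
slope −k_D; because late points flatten (detection floor, stable
sub-populations), the fit uses the longest initial prefix (≥3 points)
with r² ≥ 0.95 — a reproducible surrogate for the by-eye "initial linear
range" — falling back to the 3-point prefix with flag `low_r2`. A
non-negative slope flags `fit_failed`. Replicates are fitted separately
and reported as mean t½ ± SD. Conditions are compared by tie-corrected
Kruskal-Wallis; for ≤12 total observations the p-value is exact by full
enumeration of group assignments, otherwise the χ² approximation is
used.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
steady-state initialization RA(0) = TR(0)/k_D0 (exact before noise),
piecewise-linear TR programs, piecewise-constant k_D programs, and
independent multiplicative lognormal observation noise with unit mean
and configurable CV applied per replicate (noise never feeds back into
the dynamics). Defaults: grid (0, 4, 11, 16, 26, 40) min, 3 replicates,
noise CV 0.15 (a declared choice — replicate variance is not published),
k_D0 log-uniform on 0.05–0.15 min⁻¹ (half-lives ≈ 4.6–14 min,
bracketing directly measured stress-period transcripts at 6.4 and
9.5 min), TR(0) uniform on 0.5–5 units/min.

The shipped 16-archetype library encodes the qualitative cluster
behaviors of the heat-shock response — a repressed branch with varied
repression timing and mostly destabilization, a transiently induced but
destabilized branch with flat or falling RA, and an induced branch with
mostly stabilization, including purely post-transcriptional classes.
Fold values were designed once under three constraints: faithfulness to
those descriptions; decisive ground-truth calls (every archetype's
designed stability and TR-direction label holds at the 0.3 log₂
threshold across the entire k_D0 range, so noiseless classification is
exact by construction); and mutual separability in profile space
(pairwise centroid correlations ≤ ~0.9; timing signatures — step, ramp,
pulse, dip-recover, delayed — deliberately varied). Archetype recovery
tests add Gaussian noise of 0.15 log₂ units per profile element, the
profile-space equivalent of the observation noise.

What the simulator does **not** emulate: run-on labeling efficiency,
spot-level array artifacts, gene-length effects, cell-cycle structure,
correlated (batch) noise, or model mismatch — real TR is not piecewise
linear and real k_D not piecewise constant. Passing recovery tests
therefore demonstrate correctness of the inference given the model, not
robustness to violations of it.

## Problem sizes and determinism

Default verification sizes are desk-scale and chosen as the package's
own test design: 1600 genes (16 × 100) for the noiseless inversion and
clustering-recovery checks; 1000 random draws for solver equivalence;
200 seeded repetitions × 200 simulations for the Monte-Carlo
calibration; 3 replicates × 6 time points for half-life recovery. All
randomness flows through seeded numpy Generators; identical seed, config
and input order give identical outputs (serialized floats are written at
6 significant digits).

## Known limitations

- Per-gene k_D estimates inherit the full noise of both TR and RA and
  are best interpreted through cluster averages; the pipeline reports
  per-interval solver flags so degenerate inversions are visible.
- The genome-wide stability percentages depend on the per-gene threshold
  (or, alternatively, on the clustering); there is no single canonical
  value and both views are reported.
- The binomial enrichment model samples with replacement and slightly
  overstates tails for large target sets; the hypergeometric option is
  exact for sampling without replacement.
- Interval inversion assumes strictly positive RA throughout; genes with
  missing or zero values are excluded rather than imputed.
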