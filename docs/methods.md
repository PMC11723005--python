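# Methods

## Scope and data model

The package analyses long-format clonal progeny-trial measurement
tables: one row per tree per year with clone id, cross type (direct
`DxM` or reciprocal `MxD`), block, tree id, age (years since
planting), DBH (cm) and height (m). Units follow forestry-table
convention: HDR is height in metres over DBH in centimetres (mature
poplar values ≈ 0.6–0.8), and the volume equation converts DBH to
metres internally. Rows with non-positive or missing DBH/height are
rejected (counted and logged, never imputed); a duplicate
(clone, block, tree, age) key is a hard error; age gaps inside a
clone's measured span are recorded in the table metadata and left as
gaps in every downstream computation.

Group means are always means of per-tree derived values. Applying
the volume formula to group-mean DBH and height instead would
systematically overshoot the mean of per-tree volumes (the formula is
convex in DBH), which is why published group volume rows cannot be
recovered from the published group DBH/height means; the package does
not attempt to force that agreement.

## Derived traits

* `HDR = H / DBH` — slenderness; lower is a stockier, more
  wind-stable stem, so selection flags treat *below*-mean HDR as
  favourable.
* `G = π·(DBH/100)²/4` m² — breast-height basal area.
* `V = G · H · F` m³ with form factor `F = 0.44` (default,
  configurable) — a fixed-form-factor stem-volume equation; no
  allometric fitting is in scope.

## Increments and quantitative maturity

For a clone's mean-volume series on integer ages, `MAI(t) = V(t)/t`
and `PAI(t) = V(t) − V(t−1)`, with PAI indexed to the later age of
its one-year interval and undefined at the first age and after gaps.
QMA is the smallest age with `PAI ≤ MAI` that is preceded by at least
one age with `PAI > MAI`. The prior-exceedance requirement prevents a
concave, already-declining series from receiving a spurious maturity
age at its first measurement; such series are flagged
`IMMEDIATE_DECLINE`, while series whose PAI never returns to MAI in
range are `NOT_REACHED` (reported as an empty age plus flag,
mirroring the dash convention of published maturity tables). Exact
ties count as crossings. Integer ages are reported (matching how such
tables are printed); the bracketing ages and a linearly interpolated
real-valued crossing are emitted as diagnostics. An optional 3-point
moving-average smoother on PAI exists but is off by default.

QMA is invariant to uniform positive rescaling of the volume series
(MAI and PAI scale identically); this is property-tested.

## Path analysis

Predictors DBH, H and HDR; response volume; tree×year observations
pooled within age windows (default 2–3, 4–6, 7–9, 10–12, 13–15,
16–18) per cross type. Ordinary least squares with intercept
(statsmodels) gives partial regression coefficients `B_i`; the direct
path coefficient is the standardized coefficient
`DPC_i = B_i·S_i/S_y`, and indirect effects are
`IPC_ij = r_ij·DPC_j`, reported as the total over mediators with the
per-mediator terms kept as diagnostics. The path identity
`DPC_i + Σ_{j≠i} IPC_ij = r(x_i, y)` holds on any finite sample and
is asserted at 1e-10 throughout the tests. Significance of a trait's
path uses the OLS coefficient t-test; stars follow the two-level
convention (`*` p<0.05, `**` p<0.01; a three-level convention is
collapsed to `**`). Tree-level observations are the analysis unit
(maximizing n within windows); pairwise deletion handles missing
values; an exactly collinear predictor set raises an error naming the
collinear pair. Note that DPC/IPC are standardized regression
quantities, not correlations, and can legitimately exceed 1 in
magnitude when predictors are strongly intercorrelated — as DBH, H
and HDR inevitably are.

One-way ANOVA between the two cross types at a single age uses
tree-level values (scipy); for two groups F equals the square of the
pooled t statistic, asserted at 1e-10. Zero within-group variance
with distinct means is reported as F = ∞, p = 0 with a `DEGENERATE`
flag.

## Age–age correlation and early selection

`Rp` is the Pearson correlation of the trait (default DBH) at early
age `t_l` against the mature reference age `t_e`, computed across
clone means by default (stable against tree-level mortality;
tree-level pairing available). The p-value uses
`t = r√(n−2)/√(1−r²)` with n−2 df. `ESE = Rp·t_e/t_l`; the late/early
ratio direction follows the published worked values (e.g.
0.88·14/7 = 1.76). The default reference age is 14 — late
quantitative maturity in the reference trial — for both the
correlation and the ESE multiplier; both are parameters, since usage
varies between "final measurement year" and "maturity year"
conventions.

The optimal window is the earliest maximal run of consecutive early
ages with `Rp ≥ 0.50` and p < 0.05. In joint mode (default) both
populations must qualify at an age — this is what excludes an age
where one population's correlation sits in the moderate band
(0.30–0.50) even though the other's is strong.

## Selection pipeline

Survival filtering keeps clones with `100·surviving/planted ≥ 60 %`
— inclusive, because the reference trial's own retained set includes
a clone at exactly 60 %. Duplicate (clone, cross) keys in a survival
table are surfaced in the result rather than merged. Ranking is by
clone-mean volume at the reference age (default: final measured age);
`floor(rate·n)` clones are selected with a minimum of one
(floor, not ceiling, reproduces 17 → 4 at 25 %); ties break on higher
DBH, then lexicographic clone id, making selection deterministic and
idempotent. CV uses the sample standard deviation (n−1) and is
rounded to whole percent for display only.

## The simulator: what it emulates and what it does not

Design: 10 direct-cross and 7 reciprocal-cross clones, 3+3+2 ramets
over three blocks, ages 2–18 — the reference trial's layout. Each
cross type has mean logistic curves `L(t) = K/(1+e^{−r(t−t0)})` for
DBH and height; per-clone effects are a multiplicative log-normal
factor on `K` (CV 12 % for DBH, 6 % for height) and a shared additive
normal shift on `t0` (sd 0.8 y); measurement noise is additive
Gaussian (sd 0.4 cm DBH, 0.3 m height), truncated just above zero;
mortality is Bernoulli at 2 %/tree-year with series truncated at
death. Volume is *derived* through the form-factor equation, never
simulated directly, so the analytic QMA of each clone's noise-free
volume curve (dense 0.01-y grid + bisection) is an exact oracle for
the empirical detector.

Calibration was done once, against the scale of the reference trial,
and frozen: final-age population means ≈ 35 cm / 25.5 m (DxM) and
32 cm / 24.5 m (MxD); noise-free QMA at 13.4 y (DxM) and 14.4 y
(MxD), inside the reference 12–16-y band; the reciprocal cross has
the higher juvenile HDR (faster early height growth); population
volume CVs land near 20–27 %, the scale of published clone-trial
variability. Clone effects constant in time are what make late
age–age correlations approach 1 while early correlations are
moderate — the pattern the ESE analysis exploits.

Not emulated: site/climate effects, block effects (blocks are
homogeneous), genotype×year interaction beyond iid noise,
non-logistic growth phases, and any genetic structure beyond
iid clone effects. Consequently, passing tests show the analysis
chain is correct and well-calibrated for data with stable clone
rankings and sigmoid growth; they do not show robustness to rank
changes over age (true genotype×age interaction), which real trials
can exhibit.

All randomness flows from one root generator; stream order (clone
effects in clone-id order, then per-tree draws in table order) is
fixed, so one integer seed reproduces a byte-identical table.

## Numerical conventions

* Correlations within 1e-12 of ±1 are snapped to exactly ±1 (so
  self-correlation is exactly 1).
* Zero-variance inputs to correlation, and singular predictor sets in
  path analysis, are errors, not NaNs.
* Tie-breaks everywhere are deterministic (documented above), so the
  full pipeline is byte-reproducible for a fixed seed.

## Problem sizes

Tests and the reproduction script run the default 17-clone × 8-tree ×
17-age trial (≈ 2000 rows), 100-sample property sweeps for the path
identity, and 20 simulated replicates for the clone-asymptote
recovery check — sizes at which every statistical contract here is
sharp while the whole suite completes in seconds.
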