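# Methods

`standthin` is a simulation-and-analysis pipeline for stand-density
management in even-aged Chinese fir (*Cunninghamia lanceolata*)
plantations. It reproduces, on synthetic stands, the workflow of a
long-term thinning experiment: plant dense plots, thin from below at a
young age (pre-commercial) or near culmination (commercial), and follow
the consequences for quantitative maturity age, diameter-class and
merchantable-timber composition, structural heterogeneity, and
productivity.

## The experimental design the simulator emulates

Seven treatments on 20 m × 20 m plots (0.04 ha) planted at 5,000
trees/ha, three replicate plots per treatment, measured annually from age
4 to age 32:

| treatment | thinning age | residual density | residual trees/plot |
|-----------|--------------|------------------|---------------------|
| CK        | —            | 5,000/ha         | 200 |
| TE3250 / TE2500 / TE1750 | 9 (pre-commercial) | 3,250 / 2,500 / 1,750/ha | 130 / 100 / 70 |
| TL400 / TL278 / TL156    | 23 (commercial)    | 400 / 278 / 156/ha       | 16 / 11 / 6 |

Per-plot residual counts are `round(density × area)` half away from zero,
so 278 and 156 trees/ha become 11 and 6 trees on 0.04 ha. Each plot is
thinned at most once. Both event kinds are *thinning from below*: trees are
removed in ascending (DBH, height, tree id) order — "cut the small, keep
the big". Field vigour assessments collapse onto DBH because the data model
carries no vigour attribute; DBH is the operational proxy for "poorly
growing". No natural mortality is modelled: all density change is thinning.

Trees are aged as a single cohort (replanted seedlings are not
distinguished), and simulation starts at age 4, the first year all stems
plausibly exceed breast height (1.3 m).

## Growth kernel

Each live tree's annual diameter increment is

    ΔD_i = pot(D_i) · exp(−γ · BAL_i / BA) · max(0, 1 − α · BA_ha / BA_ref) + ε,
    ΔD_i ≥ 0 (truncated),

with the three factors:

* **Potential growth** `pot(D)`: the one-year increment of an open-grown
  tree of size D on a Richards curve `D(t) = a(1 − e^{−bt})^c`
  (equivalently `dD/dt = b·c·D·((a/D)^{1/c} − 1)`). The tree's implied age
  is recovered by inverting the curve at its current D, so potential
  growth is size-dependent, not age-dependent.
* **Size-asymmetric competition** `exp(−γ · BAL_i/BA)`: BAL is the summed
  basal area of strictly larger neighbours, normalized by plot basal area.
  Dominants (BAL → 0) grow near potential; suppressed trees fall further
  behind. This one term generates both the widening basal-area inequality
  and the persistent right skewness of the diameter distribution.
* **Stand-level density dependence** `1 − α·BA_ha/BA_ref`: a linear
  reduction in growth as plot basal area per hectare approaches a site
  carrying capacity near `BA_ref/α`. It saturates the control, drives
  mean-annual-increment culmination, and re-closes thinned stands.

`ε ~ N(0, noise_sd)` is small additive measurement/micro-site noise.
Heights follow the deterministic allometry `H = 1.3 + h_s1 · D^{h_s2}`;
initial diameters are log-normal (median `dbh0_median`, log-sd
`dbh0_sigma`), giving the right-tailed starting distribution the
skewness analysis assumes.

### Default parameters and why

| parameter | default | role |
|-----------|---------|------|
| `dbh0_median` | 2.8 cm | initial median DBH at age 4 |
| `dbh0_sigma`  | 0.13   | initial log-sd; sets initial basal-area Gini ≈ 0.15 |
| `pot_a` | 34 cm  | potential asymptotic DBH on this site |
| `pot_b` | 0.24 /yr | potential-curve rate |
| `pot_c` | 10     | potential-curve shape; per-tree *volume* increment peaks near D ≈ 0.69·`pot_a` ≈ 23 cm |
| `comp_gamma` | 1.02 | competition asymmetry |
| `dens_alpha` | 0.9  | density-dependence strength |
| `ba_ref` | 42 m²/ha | reference basal area (carrying capacity ≈ 47 m²/ha) |
| `noise_sd` | 0.005 cm | increment noise |
| `h_s1`, `h_s2` | 1.1, 0.85 | height allometry |

The defaults were calibrated once, jointly, against the qualitative
behaviour the analysis is meant to exhibit, and then frozen:

* the unthinned control's basal-area Gini grows from ≈0.15 at planting to
  0.30–0.45 by age 32, essentially monotonically;
* diameter-distribution skewness of unthinned stands at age 9 is ≈0.6–0.8
  and stays positive through age 32;
* control volume culminates (MAI = CAI) in the low teens of years, with
  maturity progressively delayed by pre-commercial intensity and delayed
  much further by commercial thinning; the heaviest commercial intensity
  (6 residual trees) never re-culminates within the window;
* post-thinning productivity increases with pre-commercial intensity and
  decreases with commercial intensity;
* merchantable composition at maturity shifts from small-dominated
  (control) to medium-dominated (pre-commercial) to large-dominated
  (commercial).

The high potential shape (`pot_c` = 10) matters for commercial thinning:
released dominants (D ≈ 15–19 cm at age 23) sit below the volume-increment
optimum, so their release produces a multi-year growth surge, while the
basal-area feedback re-closes the 16-tree plots and ends the surge before
age 32.

## Stand measurements

* **Density**: live trees / plot area (trees/ha).
* **Tree volumes** (m³), fixed Chinese fir allometries of the form
  `V = k·DBH^{p_D}·H^{p_H}`:
  * stock volume `V = 5.877042e−5 · DBH^1.9699831 · H^0.89646157` — used
    for stand volume and yield accounting;
  * merchantable volume `V_D = 3.60243758e−5 · DBH^1.94752076 · H^1.00793769`
    — used for the timber size-class tables.
* **Diameter classes**: 2-cm classes; class label c covers DBH in
  (c−1, c+1] (so class 10 spans 9–11 cm exclusive/inclusive). Merchantable
  size classes are defined on the class label: 10–14 small, 16–20 medium,
  ≥22 large, ≤8 sub-merchantable. Sub-merchantable stems are excluded from
  merchantable totals and reported separately. Raw DBH between class-edge
  odd integers (e.g. 15.0) therefore resolves by its 2-cm class, never
  ambiguously.
* **Skewness (SK) and excess kurtosis (ST)** of the live-tree DBH sample:
  the adjusted-moment (bias-corrected) estimators, n ≥ 3 (SK) and n ≥ 4
  (ST), sample sd with ddof = 1. Positive SK means mass at small diameters
  with a long right tail.
* **Gini coefficient (GC)** of individual-tree basal area
  (`ba = π(D/200)²` m²): with areas sorted ascending and ranks j = 1..n,
  `GC = Σ(2j − n − 1)·ba_j / (Σba_j · (n − 1))`, identical to the
  mean-absolute-difference form `Σ|ba_i − ba_j| / (2n(n−1)·mean)`. GC is
  scale-invariant, so stands with very different mean sizes compare
  directly; 0 = all trees equal.
* Per-snapshot metric failures on tiny stands (e.g. kurtosis of a 3-tree
  plot) are flagged fields, not exceptions, so batch reports survive heavy
  commercial thinning.

## Stand volume accounting

The standing (existing) volume is the stock-volume sum of live trees per
hectare. The total yield series adds thinned trees *frozen at their size
at removal* (existing + thinned). The total is continuous across a
thinning event — the event repartitions volume between standing and
removed, never destroys it — and is non-decreasing in age.

## Quantitative maturity age

The Richards model `y(t) = a(1 − e^{−bt})^c` is fitted to volume–age
series by nonlinear least squares on the absolute (volume) scale, with a
27-point multi-start (`a₀ ∈ {1, 1.2, 1.5}·max y`, `b₀ ∈ {0.05, 0.15, 0.3}`,
`c₀ ∈ {1.5, 3, 6}`), keeping the best sum of squares. The printed form of
the growth equation has exponent `r = −b < 0`; the implementation uses
`b > 0` throughout.

The quantitative maturity age (QMA) is the age where mean annual increment
(MAI = y/t) meets current annual increment (CAI = dy/dt) — the harvest age
maximizing sustained mean yield. Analytically, MAI = CAI reduces to
`e^u = 1 + c·u` with `u = b·t`: the asymptote cancels, a positive root
exists only for c > 1, and it is found by bracketed root finding to 1e−10.

For measured (annual) series, CAI is the backward first difference with no
smoothing, MAI is cumulative volume over age, and the empirical QMA is the
first age at which MAI − CAI changes sign from negative to non-negative,
with the fractional crossing interpolated linearly and reported as an
integer year. A series already decelerating at its first evaluable age
never exhibited the accelerating phase inside the window, so its apparent
"crossing" is rejected as spurious and no maturity age is reported.

For a managed stand the crossing is sought on the existing-plus-thinned
volume series restricted to ages at and after the last thinning event
(MAI remains cumulative from planting): maturity of the post-treatment
stand is a property of its post-treatment growth course. An unthinned
stand uses its full series. Under this rule the heaviest commercial
intensity — whose six released stems never push stand CAI back above MAI —
correctly reports "not reached within the window". A single Richards fit
over a thinned stand's full series was considered and rejected: the fit
averages away the post-release growth surge and dates maturity before the
treatment.

## Productivity and the structure–productivity relation

Periodic annual increment `PAI(t) = (SV(t) − SV(t−w))/w` (default window
w = 1, annual measurements) is the productivity measure; windows spanning
a thinning event are flagged. On the existing-plus-thinned basis PAI is
live-tree growth; on the existing basis the event window absorbs the
removal.

The structure–productivity relation is the fixed-effects line
`PAI = β₀ + β₁·GC` with additive group offsets whenever the supplied
points carry more than one group level, and a seeded 1,000-resample case
bootstrap percentile CI on β₁. The pipeline fits each thinning scenario
separately on **one summary point per plot** (mean GC and mean PAI over
the post-treatment ages), so β₁ is identified by the between-intensity
gradient — the comparison the scenario-level claims are about. Feeding
per-age points with per-treatment offsets instead would absorb the
intensity gradient entirely and leave only the within-stand age trend,
which has the opposite interpretation (it tracks ageing, not density
management).

## What the synthetic data do and do not show

The generator reproduces the *mechanistic structure* the analysis assumes:
right-tailed diameter distributions that widen under size-asymmetric
competition, sigmoid volume growth with density-dependent culmination,
release after thinning from below, and the ordering contrasts between
thinning times and intensities. Passing tests therefore demonstrate that
the pipeline's estimators and decision rules recover these patterns from
tree-list data — not that the simulator predicts any particular field
stand. Absolute numbers (maturity at ~12 yr for the simulated control vs
~22 yr in northern-China field stands; stand volumes; a starting Gini of
0.15 rather than 0.10) depend on site quality and calibration and are out
of numeric scope; only directions, orderings and calibration bands are
asserted.

Known limitations:

* Within the commercial scenario, the simulated maturity of the 400/ha
  stand (~31 yr) comes *after* the 278/ha stand (~28 yr), whereas the
  field experiment dates them 31 and 32 yr. With this kernel, stand CAI
  after thinning scales nearly proportionally with retained tree count
  while MAI is shared, so the denser residual stand always re-crosses
  later; reversing that would need a much stronger per-tree release
  gradient (the field data imply roughly 2.5× between 156 and 400
  trees/ha) than a linear basal-area feedback can express. The
  between-scenario orderings are unaffected.
* The control's Gini trajectory is monotone to a resolution of 1e−3
  (asserted as such): in the saturated phase, leaders sit past the
  potential-increment peak and curve convergence offsets competitive
  divergence by ≤1e−4 per year.
* Competition is distance-independent (no spatial coordinates); no
  climate, site-index or understory effects; crown dimensions are carried
  as optional columns but never modelled.

## Numerical choices

* Thinning tie-breaks: ascending (DBH, height, tree id); removal counts
  use round-half-away-from-zero.
* Richards root finding: `brentq` on [log c, expanding upper bracket],
  xtol 1e−10; fit bounds a, b, c > 0 with b ≤ 10, c ≤ 100.
* Degenerate inputs: zero-variance samples and n below the estimator
  minimum raise typed errors at the operation level and become flagged
  fields in batch reports.
* Seeds: each plot's random stream derives from
  `SeedSequence([base_seed, treatment_index, replicate])`; the bootstrap
  seed is the scenario base seed. Identical configuration and seeds give
  byte-identical numeric tables.
* Problem sizes: the shipped analysis uses the full factorial (21 plots,
  ≤200 trees each, 29 annual steps) — a few seconds end to end; the
  noisy-recovery study in the acceptance checks uses 100 seeded
  replicates of a 32-point series.
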