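# Methods

## The simulated experiment

One simulation run mirrors a snapshot morphometry experiment. Two groups
("control", "treatment") of *n* samples are built, each sample holding *m*
spines drawn independently **with replacement** from one base population
(spines are pooled across the population's cells; with-replacement sampling
keeps group construction well defined for any n·m and matches bootstrap
practice — the alternative, exhausting a finite database without
replacement, would cap n·m and couple the samples). The treatment group's
samples are then passed through a change model, one statistical test is run
at level α, and the rejection outcome is recorded.

Monte Carlo repetition of this run yields the false negative rate (with a
real change; 2000 runs by default), the false positive rate (with no change,
or with the per-sample nuisance applied to *both* groups; 10000 runs), and —
by searching over n — the minimal number of samples per group that keeps the
FNR at or below 5%. All rates carry Wilson 95% intervals.

The statistical unit ("datum") follows the test: per-sample means for the t-
and u-tests, all n·m pooled spine values for the Kolmogorov–Smirnov test,
and per-sample subclass fractions for the classification-based tests. The
pooled K-S test deliberately ignores sample membership; that is exactly why
per-sample systematic variation inflates its false positive rate (see below).

## Change models

| kind | parameters (defaults) | action |
|---|---|---|
| `linear_growth` | variable, factor | multiply one variable of every spine |
| `head_swelling` | factor | `linear_growth` restricted to head-width |
| `filopodia_elimination` | threshold 2 μm, p 0.5 | long spines removed with probability p, replaced from the source |
| `small_spine_growth` | threshold 0.8 μm², factor 1.5 | areas below threshold multiplied once (membership on pre-change area) |
| `systematic_perturbation` | variable, σ | one Normal(1, σ²) factor per sample, shared by all its spines |

Two choices deserve emphasis:

* **Elimination refill.** Replacement spines are drawn from the full base
  source and pass through the same elimination rule (redrawn until they
  survive), so the sample keeps exactly m spines while its length spectrum
  shifts toward mature spines. Each output spine is therefore distributed as
  a source draw conditioned on survival, giving a closed-form long-spine
  fraction q(1−p)/(1−pq) that the tests verify against a one-spine-at-a-time
  simulation. A `replacement_pool="below_threshold"` switch restricts
  replacements to sub-threshold spines instead, since either reading of
  "replaced from the database" is defensible.
* **σ is the standard deviation of the per-sample factor.** The nuisance
  factor is Normal with mean 1 and SD σ (swept over 0–15%, i.e. percentages
  of the mean), redrawn until positive; for σ ≤ 0.2 the truncation is
  negligible (factor mean stays ≈ 1 to within 0.5%).

## Statistical engines

* **t-test**: the classic equal-variance two-sample two-tailed form.
  Degenerate inputs follow fixed conventions: zero pooled variance with
  equal means → p = 1; with unequal means → a logged p = 5e-324 sentinel.
* **u-test**: exact two-tailed Mann–Whitney p from the permutation null of
  the rank-sum statistic, enumerated by the Gaussian-binomial
  (partition-count) recurrence whenever the input is tie-free,
  min(n₁,n₂) ≤ 15 and n₁+n₂ ≤ 40; continuity-corrected normal approximation
  with midranks and tie correction otherwise. Two-tailed p is
  2·min(P(U ≤ u), P(U ≥ u)), capped at 1. The switchover constants are fixed
  package constants (u-test results are known to differ across software
  packages that approximate silently; pinning the exact regime makes results
  machine-independent). Counts stay exact in float64 (C(40,20) < 2⁵³).
  Because the null is discrete, the smallest attainable two-tailed p for
  groups of n₁ and n₂ is 2/C(n₁+n₂, n₁): with equal groups of 6 that floor
  is 2/924 ≈ 0.0022, so at α = 0.001 the u-test can never reject below n = 7.
* **K-S test**: two-sided two-sample p via scipy, exact small-sample
  distribution while the effective size n₁n₂/(n₁+n₂) < 35, asymptotic
  Kolmogorov distribution above — again a fixed, documented switchover.
* **Classification**: rules applied in order — filopodium (L > 4 μm,
  strict), stubby (L/N > 2, strict), then mushroom (H/N ≥ 1.3) else thin.
  The H/N = 1.3 boundary is assigned to mushroom to make the rule total; all
  thresholds are configurable. Note the printed stubby criterion L/N > 2 is
  biologically atypical (stubby spines are usually *short* relative to their
  neck); it is implemented as conventionally stated rather than silently
  "fixed", and on the default synthetic population it labels ~80% of spines
  stubby. The binary large/small split uses the *median area of the base
  population computed at run time* (≈ 0.51 μm² for the default synthetic
  population; ≈ 0.65 μm² for the measured culture the simulation emulates) —
  the printed 0.65 value is a property of one data set, not of the method.
* **Fraction tests** compare per-sample subclass fractions between groups
  with the t-test.

## The synthetic population

The generator is hierarchical. Each spine first draws an archetype —
stubby / thin / mushroom / filopodium — then, conditional on it:

    L ~ LogNormal,  N ~ LogNormal,  H = N · r with r ~ LogNormal,
    A = κ · L · H · ε with ε ~ Uniform(1−a, 1+a)

Defaults: κ = 1.3, a = 0.95; archetype medians are textbook values for
dissociated hippocampal cultures (stubby: short, wide neck; thin: long,
narrow; mushroom: H/N ≈ 1.75; filopodium: L ≈ 5.5 μm with nearly all mass
above 4 μm). The hierarchy induces realistic L–H–A correlations; only
marginal shape facts are known for the emulated data, so the correlation
structure is a modelling choice, not a measured fact.

**Calibration.** Three global knobs — the filopodium weight, a common scale
on the length sigmas, and a common scale on the neck/head-ratio sigmas — are
tuned by coordinate descent (grids evaluated on common random numbers,
400 000 draws per candidate) until the large-sample excess kurtosis of
length and head-width match their targets, 7.97 and 2.02, within ±10%. The
resulting parameter set is frozen in `spinesim/data/default_model.json`
(filopodium weight 0.065, length-sigma scale 1.20, head-sigma scale 0.925);
at 10⁶ draws it reads kurtosis ≈ 7.9 (length), ≈ 2.0 (head-width), ≈ 6.6
(area), with ~4.6% of lengths beyond 5 μm. Kurtosis uses the
bias-uncorrected (population-moment) estimator throughout.

**Why uniform area noise.** With lognormal ε, any noise level large enough
to make area the most dispersed variable (relative to its mean) drove the
area kurtosis near 18. The emulated data show the opposite pattern: area is
the *hardest* variable to detect changes in — its coefficient of variation
exceeds length's — yet its kurtosis (7.38) is *below* length's (7.96).
Bounded uniform noise reproduces exactly that: it widens the bulk of the
area distribution (CV 0.91 vs 0.84 for length) without fattening its tail
(kurtosis 6.6). The area kurtosis is a soft target; the generator is only
required to keep it heavy-tailed (> 3).

**What passing tests do and do not show.** The synthetic population
reproduces marginal shapes, the filopodia tail, and plausible cross-variable
coupling — not the raw measured database. Minimal-n values computed on it
are therefore *structurally* comparable to those from real cultures (same
orderings in m, effect size and variable; same test rankings) but their
exact numeric cells are properties of whichever population is supplied.
Real data also contain features the generator omits: between-cell
heterogeneity (unless `sample_effect_sigma` > 0), measurement noise floors
near the optical resolution limit (~0.18 μm), and within-dendrite spatial
correlation of spine shapes.

## Numerical and reproducibility choices

* **Seed scheme.** One master seed; the stand-in database and every run r of
  every grid cell c use `SeedSequence(master, spawn_key=(c, r))` — a
  counter-based scheme that is order-independent, parallel-safe and
  bit-reproducible. The default population reference ("synthetic-default")
  generates a 2499-spine / 34-cell database from the frozen model on a
  reserved sub-stream, mirroring the size of the measured reference culture.
* **Minimal-n search.** The decision uses the FNR point estimate at the full
  run budget (2000 runs by default; the table builders use 500 runs per cell
  as a deliberate scale-down, stated in their output). A stricter
  `criterion="wilson_upper"` mode requires the upper Wilson bound to clear
  the threshold. The default search brackets geometrically and bisects,
  relying on the monotone decay of FNR in n; `search="scan"` checks every n
  in increasing order. Both modes use identical per-n random streams, so
  they agree up to Monte Carlo wiggle at the boundary.
* **Monotonicity audits** on minimal-n tables allow one sample of slack —
  the integer-n analogue of the two-standard-error tolerance used when
  comparing Monte Carlo rates — to avoid flagging boundary jitter.
* **Representative-setting rule.** Where a comparison needs "a setting in
  which the direct test's FNR lies between 1% and 50%" (the binary-fraction
  sensitivity cost), the group size is tuned to bring the direct FNR nearest
  the geometric centre (~7%) of that band: a mid-range, informative regime
  chosen by rule rather than by hand.
* **EM mixture fit** (for parametrising length distributions as a
  superposition of three Gaussians): deterministic quantile initialisation,
  sd floor 10⁻⁶ of the data range, convergence when the log-likelihood gain
  falls below 10⁻⁸ relative, iteration cap 500 with the best-so-far model
  attached to the failure. The per-iteration log-likelihood trajectory is
  recorded so EM's defining monotonicity is testable.
* **K-S false-positive sweep.** Both groups receive independent per-sample
  perturbations — the nuisance affects every sample in the study, and
  perturbing one group only would fake a treatment effect. At the swept
  σ = 0.15 the inflation is strong for m = 60 spines per sample and only
  beginning for m = 15: the critical σ shrinks as m grows, which is the
  counterintuitive but expected behaviour (more spines per sample leave less
  sampling noise for the systematic effect to hide behind).

## Limitations

* Simulated changes are applied to independently resampled spines; temporal
  dynamics (spine motility, longitudinal imaging of the same spines) are out
  of scope, as is any image analysis.
* The equal-variance t-test is intentional (it is the conventional choice in
  this literature); no Welch or permutation variants are provided, and no
  multiple-testing correction is applied across grid cells.
* Sensitivity estimates from simulation are best-case bounds: real
  experiments add preparation, animal and imaging variability on top of
  sampling noise.
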