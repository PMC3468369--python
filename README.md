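# spinesim

Monte Carlo power analysis for dendritic spine morphometry.

Dendritic spines — the micron-scale protrusions that carry most excitatory
synapses — are extraordinarily diverse in shape. When two groups of samples
(cells or animals) are compared on a morphometric variable, that diversity
translates into large sampling noise, and real treatment effects are easily
"buried": the experiment commits a Type II error. Conversely, tests that
compare pooled spine *distributions* can fire on cell-level nuisance
variation that has nothing to do with the treatment, inflating the Type I
error. `spinesim` quantifies both failure modes by simulating the whole
experiment.

It is written for experimentalists planning morphometry studies (how many
cells per group do I need?) and for methodologists comparing statistical
strategies (means vs distributions vs subclass fractions).

## The model

A simulated experiment draws a control and a treatment group of *n* samples
× *m* spines per sample from one spine population, applies a controlled
change to the treatment group, runs one test at level α, and repeats:

- **false negative rate** (FNR, 2000 runs): fraction of runs in which the
  simulated change goes undetected;
- **false positive rate** (FPR, 10000 runs): fraction of runs rejecting when
  both groups come from the same population;
- **minimal n**: smallest number of samples per group with FNR ≤ 5%.

Each spine carries length *L* (μm), head-width *H* (μm), neck-width *N*
(μm) and projected cross-sectional area *A* (μm²). Change models include
uniform linear growth of one variable (×1.1 / ×1.2 / ×1.5), elimination of
long spines (*L* > 2 μm removed with probability 0.5 and replaced, shifting
the spectrum toward mature spines), growth of small spines (*A* < 0.8 μm²
× 1.5), head swelling (head-width growth only), and a per-sample
multiplicative Gaussian nuisance factor (mean 1, SD σ) that models
systematic cell/preparation effects.

Tests: the equal-variance two-tailed Student t-test and the **exact**
two-tailed Mann–Whitney u-test on per-sample means, the two-sample
Kolmogorov–Smirnov test on pooled spine values, and t-tests on per-sample
subclass fractions (filopodium / stubby / mushroom / thin classification:
filopodium if *L* > 4, else stubby if *L/N* > 2, else mushroom/thin by
*H/N* ≷ 1.3; or a binary large/small split at the population median area).
Because the exact u-test null is discrete, its smallest attainable
two-tailed p for equal groups of *n* is 2/C(2n, n) — at α = 0.001 the test
cannot reject at all below *n* = 7.

Populations come from a morphometry CSV or from a built-in synthetic
generator: a hierarchical archetype mixture calibrated by moment matching so
that 10⁶ draws reproduce the heavy-tailed length distribution (excess
kurtosis ≈ 8, with a filopodia tail beyond 4–5 μm), a near-unimodal
head-width distribution (kurtosis ≈ 2) and a heavy-tailed area. See
`docs/methods.md` for the model, its calibration and its limitations.

## Worked example

Estimate the chance of *missing* a 20% head-width enlargement with 4 cells
per group and 60 spines per cell:

```yaml
# exp.yaml
n: 4
m: 60
variable: head_width
change: {kind: linear_growth, variable: head_width, factor: 1.2}
test: {name: t_test, alpha: 0.01}
runs: 2000
seed: 1
```

```
$ spinesim simulate --config exp.yaml
false negative rate: 0.2045 (95% CI 0.1874-0.2227, 2000 runs)
```

With 4 cells per group, one in five such experiments would miss a real 20%
effect. How many cells are enough, and how does the choice of variable
matter?

```
$ spinesim power-table --out table.csv --magnitudes 0.2,0.5 --alphas 0.01 \
      --variables head_width,length,area --m-values 60 --runs 500 --seed 1
$ cat table.csv
magnitude,alpha,variable,m,minimal_n,fnr_at_n,found,runs
0.2000,0.0100,head_width,60,6,0.0080,True,500
0.2000,0.0100,length,60,15,0.0500,True,500
0.2000,0.0100,area,60,16,0.0440,True,500
0.5000,0.0100,head_width,60,3,0.0160,True,500
0.5000,0.0100,length,60,5,0.0380,True,500
0.5000,0.0100,area,60,6,0.0080,True,500
```

`minimal_n` is the number of cells per group needed to keep the FNR below
5%: a 20% head-width change needs ~6 cells, but the same relative change in
area needs ~16 — head-width is consistently the most detectable variable,
because its distribution is the least dispersed relative to its mean.
Other subcommands: `generate-population` (write a synthetic morphometry
CSV), `fpr-sweep` (K-S false-positive inflation versus the per-sample
nuisance σ) and `classify` (shape-class fractions of a CSV).

The same operations are available as a library
(`spinesim.estimate_false_negative_rate`, `spinesim.power_table`,
`spinesim.fpr_sigma_sweep`, ...), fully seeded: every rate is bit-for-bit
reproducible from its config and master seed.

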