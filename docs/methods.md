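# Methods

## The assay and its data

A 384-well ER transactivation screen is retrofitted with hepatic
metabolism by placing enzyme-laden alginate microspheres in the wells:
rows 2–8 carry water-alginate spheres (metabolism-negative, Met Neg) and
rows 9–15 S9-alginate spheres (metabolism-positive, Met Pos); rows 1 and
16 hold no-microsphere baseline wells. Chemicals are acoustically
dispensed as a 9-level series; metabolism proceeds at 2X concentration and
the conditioned medium is added 1:1 to reporter cells, giving final 1X
levels of 2.49 nM–199 µM. Each concentration is a single technical
replicate per plate, with 4 replicate plates per experiment. The readout
is luciferase luminescence (relative light units).

## Dosing arithmetic

A level's final concentration is
`stock × dispensed_volume / (medium + total_dispense) / 2`, where the
total dispense is the DMSO backfill target (400 nL into 100 µL) and the
final ÷2 is the 1:1 transfer to cells. The default per-level dispense
volumes (0.005–400 nL from a 100 mM stock) reproduce the printed 1X
series to within 0.35%. The two lowest volumes are below an acoustic
dispenser's droplet size and are *effective* volumes — a real workflow
reaches them via diluted daughter plates — but only the resulting molarity
matters to the analysis. The backfill is treated as inert: it fixes the
DMSO fraction (0.2%) without affecting test-chemical molarity.

## Normalization and QC

`resp = cval/bval − 1`, with `bval` the per-plate median of
quality-passing DMSO wells and `cval` the raw signal after dropping wells
flagged by the liquid handler. No background subtraction or spatial
correction is applied. The baseline MAD (`bmad`) is computed on DMSO
responses pooled across an experiment's plates; the efficacy cutoff is
`3·bmad`. Control quality uses CV% (`100·sd/|mean|`, sample sd — control
well counts are small) and the Z′-factor
(`1 − 3(σ_pos+σ_neg)/|µ_pos−µ_neg|`), computed on per-well normalized
values pooled across replicate plates, per compound × mode, with the
same-mode DMSO wells as the Z′ negative group. Because DMSO's own `resp`
mean is ~0 by construction, its CV is computed on the fold-change scale
(`1 + resp`). Undefined metrics (zero mean, coincident means) are reported
as "NA". Whether to compute CV on raw or normalized values, and which
negative group Z′ should use, are genuinely open conventions; the pooled
normalized-value/DMSO choice is the package default.

## Concentration-response modeling

Ten model forms (see `models.py`): constant, linear, quadratic, power,
hill, gain-loss, and four exponentials, in the ToxCast curve-fitting
family's parameterization. Two implementation choices matter:

* **Signed amplitudes.** Every form is linear in its amplitude parameter
  (`a`/`tp`), so allowing the amplitude to be negative covers
  response suppression with exactly the parameter space that refitting
  each model with negated sign would give — one bounded fit instead of
  two mirrored ones.
* **Robust likelihood.** Residuals follow a scaled Student-t with 4
  degrees of freedom, scale `e^er` estimated jointly with the curve. AIC
  is `2k − 2·loglik` with `k` counting the error scale.

Optimization is multi-start bounded maximum likelihood: 5 deterministic
starts seeded from data quantiles plus 5 pseudo-random starts from a
configurable seed. Each start's amplitude is first profiled in closed form
(linearity again), the starts are ranked by that SSE, and the best three
run a trust-region least-squares pass with analytic Jacobians; the two
best solutions are then polished by joint (curve + error scale) L-BFGS-B
with an analytic gradient. Bounds: potencies in
[min conc/100, max conc×100], powers in [0.3, 8], |amplitude| ≤ 12 ×
max|resp|, er ≥ log(1e−8); convergence tolerances 1e−8 on the
least-squares pass. The per-series random stream is keyed by (seed,
chemical) — not mode — so identical data fit under either mode label gives
identical results and ΔAUC mode-swap antisymmetry is exact end to end.
AIC ties (within 1e−9) resolve toward fewer parameters, then fixed suite
order. Series with fewer than four distinct concentrations (e.g., after
quality filtering) are reported unfit with hit-call NA.

The continuous hit-call multiplies three probabilities: P1, at least one
concentration's median exceeds the cutoff under the winner's t(4) error
model with the median's standard error `σ/√n`; P2, the winner's |top|
(signed extreme over the tested range) exceeds the cutoff under the same
error scale; P3, the pairwise Akaike weight of the winner against the
constant model. A constant winner is exactly 0. The benchmark response is
`1.349 × bmad` (the ToxCast-family default; the source screen does not
print its factor), and the BMD is the first log-grid bracketing crossing
of |fit| = BMR refined by root finding; no crossing within the tested
range is reported as "> top concentration". Both the BMR factor and the
0.9 positive threshold are configuration options.

## ΔAUC shift statistic

AUC is the trapezoidal integral of the winning curve's predicted response
over 100 points evenly spaced in log10 concentration, over a grid shared
by both modes of a chemical (lowest to highest tested concentration); its
units are fold-change × log10(µM). A constant winner integrates to exactly
0, so "no change = 0" arises only from double-constant fits and no epsilon
band is applied (a tolerance is available in configuration). Direction is
the strict sign of `ΔAUC = AUC_pos − AUC_neg`. Concordance rules:
Bioactivated expects `activated`, Bioinactivated expects `inactivated`;
Agonist expects a positive hit-call in both modes; Agonist-Negative
expects either no Met Neg positive or a metabolic loss of activity. The
directional rules are the screen's operational definition; the agonist
rules are an inference (the source defines concordance numerically only
for directional classes) and are config-exposed. Shift concordance is
scored only on chemicals positive (`hitc ≥ 0.9`) in at least one mode;
equivocal chemicals count as inactive.

## Synthetic data generator

The generator emulates: the row-band plate layout with 21 test columns and
3 control columns (DMSO; an ER agonist reference at 100 µM-scale dosing; a
bioinactivated control; a bioactivated control — default metabolism
effects ×0.220, ×0.208 and ×2.361 on their true responses, matching the
reference chemicals' reported −78%/−79%/+136% shifts); the printed 9-level
dose series along band rows; per-plate scale factors U(0.8, 1.25) around a
10,000 RLU baseline; multiplicative lognormal well noise (default
σ = 0.1, a realistic luminescence CV); and sparse dispense failures
(default 1% low-quality flags). Metabolism acts on a chemical's generating
curve by multiplying its amplitude and/or shifting log10 potency. One
random stream per plate is derived from (seed, plate index), so plates are
independently reproducible and identical seeds give byte-identical tables.

What it does **not** emulate: spatial/edge effects, cytotoxicity bursts at
high dose, plate-to-plate drift beyond a scalar, receptor-level
saturation kinetics, or real metabolite chemistry. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
assay's assumed error structure, not that the assay itself is free of
those artifacts.

Two calibration facts the tests rely on: baseline `resp = e^ε − 1` has
MAD ≈ 0.6745σ (0.0674 at σ = 0.1), and the per-plate baseline median over
~62 DMSO wells has sampling sd ≈ 1.6%, so baseline recovery is asserted as
an RMS over plates (expected ~1.6%, bound 2%) rather than per plate, and
the bmad moment check averages over batches.

## Problem sizes and numerical choices

The test suite uses the 9-level design with 4 replicates (36 points per
series). Stochastic checks: 200 noisy-recovery reps across all ten
generating models, 1000 null series for hit-rate calibration (bound 5%),
and 100 reps per metabolism multiplier {0.25, 0.5, 2, 4} for direction
recovery (bound 90%). `scripts/acceptance.py` re-runs the same checks at
100/400/120 reps so a full from-scratch reproduction stays within a few
minutes on one CPU; sizes are package choices balancing Monte-Carlo error
(~2–5% on the reported rates) against runtime. Degenerate inputs are
handled explicitly: all-flagged plates and nonpositive baselines raise QC
errors; mean-zero CV and equal-mean Z′ return NA sentinels; exact-zero
series fit constant with hit-call 0.

## Known limitations

* Hit-call constituent formulas follow the ToxCast family's published
  approach but the screen prints no equations; P1/P2's use of the fitted
  t(4) scale is the package's own precise rendering of "under the fitted
  error model".
* BMD reporting treats "no crossing in tested range" as censored at the
  top concentration; model extrapolation beyond the tested range is never
  used.
* Concordance for agonist-class chemicals is an inferred rule; the
  packaged fixture carries the original printed flags, which are used
  as-is when re-tallying the published screen.
* No statistical significance testing is attached to ΔAUC; the statistic
  ranks metabolism-dependent effects.
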