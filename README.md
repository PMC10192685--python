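# aimeshift

Analysis pipeline for estrogen-receptor transactivation (ERTA) screens run
with retrofitted hepatic metabolism: 384-well plates carrying
metabolism-negative (water-alginate) microspheres in rows 2–8 and
metabolism-positive (hepatic S9-alginate) microspheres in rows 9–15, so
every chemical is screened with and without biotransformation on the same
plate. The package answers the screening question: *which chemicals become
more estrogenic (bioactivated) or less estrogenic (bioinactivated) once
metabolism is added?*

It is written for screening toxicologists and assay analysts working with
AIME-style (Alginate Immobilization of Metabolic Enzymes) retrofit assays,
and for anyone who needs a tested, reproducible implementation of the
ToxCast-style concentration-response workflow with a ΔAUC shift statistic
on top.

## Method

1. **Normalization.** Raw luminescence is normalized per plate to
   zero-centered fold-change, `resp = cval / bval − 1`, where `bval` is
   the plate-level median of the DMSO solvent-control wells and `cval` is
   the raw signal after removing wells flagged low-quality by the liquid
   handler. The efficacy cutoff is `3 × bmad`, with `bmad` the median
   absolute deviation of the normalized DMSO responses.
2. **Curve fitting.** Each chemical × mode series is fit to ten models
   (constant, linear, quadratic, power, hill, gain-loss, exponential 2–5)
   by bounded maximum likelihood under a Student-t (df = 4) error model;
   the winner minimizes AIC. Activity strength is a continuous hit-call
   `hitc ∈ [0, 1]` — the product of the probabilities that (a) some
   concentration's median response exceeds the cutoff, (b) the winning
   curve's top exceeds the cutoff, and (c) the winner beats the constant
   model on Akaike weight. `hitc = 0` is negative, `hitc ≥ 0.9` positive,
   anything between equivocal. Efficacy is `max_med` (the largest
   per-concentration median, sign retained) and potency is the benchmark
   dose BMD (first concentration where |fit| reaches `1.349 × bmad`).
3. **Metabolism shift.** The winning curve in each mode is integrated by
   the trapezoidal rule over a shared log10-concentration grid;
   `ΔAUC = AUC(Met Pos) − AUC(Met Neg)` classifies each chemical as
   bioinactivated (< 0), unchanged (= 0) or bioactivated (> 0), and
   concordance scores these directions against expected classifications.
4. **Synthetic plates.** A generator emulates the screen — plate layout,
   the printed 9-level dose series (2.49 nM – 199 µM), controls,
   multiplicative lognormal well noise, plate scale effects, sparse
   dispense failures — with full ground truth, so every stage is testable
   without raw instrument data.

## Worked example

```bash
aimeshift simulate --seed 11 --out sim
aimeshift report --wells sim/wells.csv --seed 11 --out rep
```

prints

```
wrote 792 wells to sim/wells.csv
analyzed 12 series, 6 chemicals with both modes
```

and writes `rep/fits.csv` (winning model, hit-call, efficacy, BMD per
chemical × mode), `rep/shifts.csv` (per-chemical AUCs, ΔAUC, direction),
`rep/qc.csv` (control CV% and Z′-factor) and `rep/summary.json`. A typical
shift row:

```
chemical_id  expected_class  delta_auc  direction  hitc_met_neg  hitc_met_pos
chem00       Bioactivated       +9.257  activated          1.00          1.00
```

meaning the fitted Met Pos curve encloses 9.26 fold-change·log10(µM) more
area than the Met Neg curve — the chemical's estrogenic activity increased
with metabolism — and the series is a confident positive in both modes.
The packaged 25-chemical screen summary can be re-tallied with
`aimeshift verify-fixture`, which reports 22/25 chemicals active in at
least one mode and 73.7% overall concordance of observed ΔAUC directions
with expected biotransformations.

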