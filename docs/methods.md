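# Methods

## Scope and data flow

The package models one individual at a time: three bone isotope proxies in,
a posterior over five food-group caloric fractions out, with that
posterior's combined marine fraction feeding mixed-curve radiocarbon
calibration. The packaged inputs are the published per-specimen chemistry
table, AMS dates with a local ΔR of −138 ± 23 ¹⁴C yr, the enamel Sr table,
and an already-aggregated five-group source matrix (C3 plants, C4/CAM
plants, combined freshwater+terrestrial fauna, and two marine groups)
compiled from 611 foodstuffs. The `foodweb` module also exposes the
item-level machinery (Suess correction, fat/carbohydrate offsets,
macronutrient mass balance, group aggregation) for users building their own
source matrices; item-level edible-tissue and digestibility corrections are
per-item configuration fields with identity defaults, since their source
compilations are external.

## Preservation screening

Collagen passes when yield > 0.5 wt%, C > 4.5 wt%, N > 0.9 wt%, and atomic
C:N lies in the inclusive window 2.9–3.6 (the window is treated as
inclusive because a sample printed at 3.6 is conventionally accepted).
A missing required field fails with an explicit "missing" reason rather
than passing vacuously. Apatite yield must fall in 21–63 wt%, with a
configurable soft tolerance (default 2 wt%) above the upper bound that
admits slightly-over-range samples with a warning — such samples are
routinely retained in practice. The preferred 3.5 wt% collagen yield is
flagged informationally, never used as a gate.

Screening gates the likelihood, not just the cohort: an individual enters
diet modelling only with a passing collagen screen, and the apatite δ¹³C
proxy enters the likelihood only with a passing apatite screen. An apatite
value whose extraction yield was never reported cannot be quality-vetted
and is dropped (its absence is recorded on the posterior). In the packaged
cohort this excludes one individual's apatite proxy (the Maruca burial) and
one whole individual (no measurable collagen chemistry).

## Mixing model

Predicted signals are concentration-dependent and macronutrient-routed
(equations in the README): collagen N from dietary protein only; apatite C
a caloric-weighted average of whole-diet carbon; collagen C a routed
f : (1−f) blend of protein and energy carbon with f ~ N(0.74, 0.04)
truncated to (0,1).

Parameters and priors:

| parameter | prior / default | units | why |
|---|---|---|---|
| diet fractions α | iid U(0,1) renormalized (`normalized_uniform`) | — | matches the sampling scheme of the classical food-reconstruction tools whose outputs this model is benchmarked against; `dirichlet` (flat) available |
| macronutrient % (pᵢ, eᵢ) | N(mean, sd) truncated [0,100], pair renormalized to 100 | % calories | source-matrix uncertainty |
| source signatures | N(mean, sd) per group and fraction | ‰ | source-matrix uncertainty; bulk, protein and energy values treated as independent |
| Δ¹⁵N | 3.6 ± 1.2 | ‰ | omnivore feeding-study trophic offset |
| Δ¹³C_ap | 10.1 ± 0.4 | ‰ | diet–carbonate spacing |
| Δ¹³C_co | 4.8 ± 0.5 (tunable, sensible range ≈ 4–6) | ‰ | regression-based diet–collagen offset convention; dataset-specific values differ, so it is an explicit config knob |
| f | 0.74 ± 0.04, truncated (0,1) | — | routed share of collagen C from protein |
| instrumental sd | 0.1 per proxy | ‰ | stipulated measurement uncertainty |

On the diet-fraction prior: independent U(0,1) draws renormalized to the
simplex have density ∝ 1/max(α)ᴷ, which concentrates mass toward even
diets relative to a flat Dirichlet. This package defaults to that prior
deliberately: on the packaged cohort it reproduces the published
per-individual posterior means to a couple of points, whereas a flat
Dirichlet misses the dominant group by 10+ points at any plausible
Δ¹³C_co. Users comparing against Dirichlet-based tools should switch
`FitConfig.prior`.

### Inference

Conditional on (α, macronutrients, f), every source signature and offset is
Gaussian and enters the predicted proxies linearly, so they are integrated
out analytically: each proxy's likelihood is Gaussian with its variance
inflated by the weighted source and offset variances. The sampler therefore
explores only 3K = 15 parameters (softmax-parameterized simplex, raw
macronutrient pairs, f) with emcee's affine-invariant ensemble — the
marginal posterior over α is identical to sampling the full hierarchy, and
mixing is far better. The two carbon proxies are treated as conditionally
independent given the sampled parameters (the whole-diet bulk signal is its
own source value per group, not a recombination of the protein/energy
signals); the recombined variant was implemented and rejected because it
degrades agreement with the benchmark posteriors badly.

Defaults: 64 walkers, 1,200 burn-in ensemble steps, 10,000 retained draws
pooled across walkers, all seeded. Burn-in is a fixed step count rather
than a fraction of retained draws because the integrated autocorrelation
time (tens of ensemble steps) is independent of how many draws one keeps.
The fitter estimates the effective sample size from the chain
autocorrelation and warns (never silently) below a configurable floor.
Degenerate inputs are handled explicitly: zero-sd priors pin their
parameters; a diet with zero total protein is rejected when a
protein-borne proxy is requested; missing proxies drop their likelihood
term and are recorded.

## Calibration

The mixed curve is μ_mix = (1−m)·μ_terr + m·(μ_marine + ΔR), with variance
combined in quadrature and ΔR applied to the marine curve only. Uncertainty
in m (Normal truncated to [0,1]) and ΔR (Normal) is marginalized with 500
seeded Monte Carlo draws, averaging per-draw likelihoods — an explicit
approximation to schemes that integrate the mixture internally. The
posterior is normalized on a 1-cal-yr grid over the curves' common span
(linear interpolation between knots; an error is raised if > 0.1% of mass
sits at the grid edge), condensed to the 95.4% highest-density region, and
reported in cal BC (cal BP − 1950) with segment endpoints rounded outward
to 10 yr (5 yr configurable). Endpoint rounding and mixture handling can
each move a segment bound by about one rounding unit relative to other
calibration software; segment probabilities always total 95.4 ± 0.2.

Curve files use the standard three-column `.14c` format. The published
IntCal20/Marine20 tables are not redistributed; tests and examples run on
synthetic curves (identity, constant +400-yr marine offset, or sinusoidal
wiggles) whose closed-form behaviour is known.

## Synthetic data

`synthetic_data` forward-simulates consumers through the same routing
equations the fitter inverts, at the source-matrix means with N(0, 0.1 ‰)
instrumental noise, storing the generating diets alongside. The default
scenario mirrors the packaged cohort's scale: four consumers with diets
near the published posterior means. QC tables are generated with a known
pass/fail structure (each failing row violates exactly one named
criterion). What the generator does **not** emulate: diagenesis and any
QC-failure correlation with isotope values, inter-individual source-matrix
variation, correlated multi-proxy measurement error, and real calibration
curve structure. Passing recovery tests therefore validates the inference
machinery, not the field validity of the source matrix or offsets.

## Known limitations

- Posterior *means* reproduce the benchmark study closely, but converged
  posterior sds here run several points narrower than that study's printed
  sds for the weakly identified groups (the printed spreads exceed even the
  flat-Dirichlet prior sd, which no converged fit of this likelihood can
  match; they plausibly reflect short, under-mixed chains in the original
  tool). The acceptance-style test comparing sds records this honestly.
- The Maruca individual is fitted without its apatite proxy (unscreenable;
  see Preservation screening). Including it moves that posterior's C3 mean
  down by roughly ten points — proxy admission policy matters at this
  sample size and is therefore an explicit, logged rule.
- Δ¹³C_co is a convention, not a measured constant; conclusions that hinge
  on C3-vs-fauna partitioning should be checked across its documented
  range.
- The diet PCA is provided for cohort comparison but published multi-cohort
  comparisons cannot be reproduced without the comparison cohorts'
  contribution matrices.
- The packaged Sr isoscape envelope is synthetic (the published regional
  isoscape is a map, not a table); locality verdicts on packaged data are
  demonstrations only.
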