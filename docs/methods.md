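# Methods

## Data model

A survey is a pair of delimited tables with fixed schemas —
`individuals(individual_id, species, province, svl_mm, git_weight_g)`
and `particles(particle_id, individual_id, polymer, shape, color,
size_um)`.  Contamination status is always derived (positive iff ≥ 1
linked particle), never stored, so prevalence and the contamination
factor cannot drift out of sync with the particle table.  Validation is
reporting, not raising: `validate_dataset` returns a typed issue list
(orphan particles, duplicate ids, non-positive morphometrics, shapes
outside {fiber, fragment, film}, sizes outside (0, 5000) µm — the 5 mm
bound is the microplastic definition).  Readers accept a decimal-comma
dialect because source tables from decimal-comma locales are common;
outputs always use the point.  `PA` and `NYLON` are kept as distinct
polymer labels even though chemically synonymous: they are reported as
separate categories, and merging them silently would change every
sum-over-polymers quantity (both carry hazard score 47, so PHI is
unaffected; category counts and chi-square are not).

## Risk indices

PHI = Σ Pₙ·Sₙ with Pₙ the *proportion* (0–1) of polymer n in the group
and Sₙ its Lithner-derived hazard score.  Hazard-index write-ups
sometimes word Pₙ as a "percentage"; proportions are the only reading
that places survey mixtures on the published five-level scale (the
reference savignyi mixture gives 167.48 ≈ the published 167.51 — medium;
on a 0–100 scale it would give ≈ 16 748 and everything would be "very
high").  A percentage mode is deliberately not offered.

CF divides the mean particle load per contaminated individual by
C₀ = 1.  PERI = PHI · CF, since CF is constant across polymers within a
group.  Category bins for both indices are implemented as left-closed
half-open intervals [0,150), [150,300), [300,600), [600,1200), [1200,∞):
the published definitions use strict inequalities on both sides, leaving
boundary values unassigned, and half-open bins make the classifier a
total monotone step function.

Published arithmetic truncates decimals rather than rounds (183/113 =
1.6194… is printed 1.61, and 167.51 × 1.61 = 269.69 is only recovered
from the truncated value; full precision would round to 1.62).  The
package computes at full precision by default and offers a
`paper_truncated` CF mode plus a truncating display formatter so printed
values can be matched exactly; truncated values never feed back into
other computations.

Known discrepancies in the reference results, reported as computed:

* the *H. orientalis* PHI: the stated formula on its printed composition
  {PET 7, PE 1, EVA 1} gives 48/9 ≈ 5.33, not the published 10; the
  package reports the formula value (both classify as the lowest level).
* the published savignyi PHI 167.51 versus the recomputed 167.48: the
  residual plausibly stems from intermediate rounding of percentages in
  the original calculation and is within the package's acceptance band.

## Reconstructed reference survey

`reference_survey()` rebuilds an individual-/particle-level dataset from
the published summary counts.  The published tables are internally
inconsistent in four places: (1) overall contaminated individuals are
given as 123 while the species counts sum to 113 + 9 = 122; (2) the
province-level contamination counts sum to 101; (3) the province-level
particle counts split 184/8 by species while the species shape
compositions total 183/9 (the grand total 192 matches either way); and
(4) one province (Adana) lists 3 contaminated individuals but only 2
particles.  No dataset can satisfy all of these simultaneously — with
the printed province particle counts held fixed, at most 109 savignyi
individuals can be contaminated, short of the printed 113.

The reconstruction therefore pins, in priority order: the species-level
totals and compositions (these drive every species-level statistic);
the three province rows whose rates are quoted in the results
(Hatay-Hassa 44/10, Bitlis 24/7, Kilis 28 particles with 10/10
positive); and the remaining provinces at their printed values where
consistent, with a fixed hand-audited adjustment elsewhere (provinces
published as contamination-free stay at zero; the per-province table in
`reference.PROVINCE_TABLE` is the single source of truth).  The overall
prevalence of the reconstruction is 122/276 = 44.20%, not the published
44.57% — the corresponding acceptance test asserts the published figure
and is expected to fail, documenting rather than hiding the source
inconsistency.

The shape-within-polymer joint distribution is fully determined by the
published narrative (128 of 129 PET particles are fibers; PE = 22
fragments + 1 film; PA = 1 fiber + 19 fragments + 2 films; PP = 1
fragment; NYLON/EVA/PAN/PU/PCT all fiber) and is consistent with both
species' marginals, so the fixture uses it exactly.  Colors are assigned
to match the per-species marginals (only marginal color counts were
published).  Within a province, particles are dealt round-robin over the
contaminated individuals in id order, which guarantees every positive
individual at least one particle and makes the dataset byte-identical
across calls.  Individual sizes were never published: the fixture fills
them with deterministic log-spaced values spanning each species'
published min–max, so size-based outputs from the fixture illustrate the
workflow but are not comparable to published size statistics (the
published overall mean 206.56 µm is likewise not recomputable from any
printed data).

## Synthetic generator

`generate_survey(SurveyConfig)` samples, per species × province stratum,
independent Bernoulli contamination at the configured prevalence;
positives draw particle counts from a zero-truncated Poisson.  Because
surveys report the mean load *among contaminated individuals*, the
configured `mean_items` m is the mean of the truncated law: λ solves
λ/(1−e^{−λ}) = m (Brent's method; m = 1 maps to the degenerate all-ones
limit), and sampling is exact inverse-CDF on the conditional
distribution.  Polymer is drawn from the stratum mixture, shape from a
shape-given-polymer table, color independently (no joint polymer–color
table was published), and size from a per-shape log-normal, resampling
the rare draw at or above the 5 mm bound.  All randomness flows from one
`numpy` Generator seeded by `SurveyConfig.seed`.

`default_survey_config()` mirrors the reference survey: one stratum per
province row with its reconciled N, prevalence and mean load; pooled
polymer/shape/color mixtures; per-shape log-normal sizes
moment-matched to the published per-shape means (fiber 219.33 µm,
fragment 142.98 µm, film 496.74 µm) with log-scale SD 0.8, a typical
spread for right-skewed particle-size data.  The generator reproduces
the *statistical structure* the analysis assumes — it does not emulate
spatial autocorrelation, polymer–color dependence, observer effects or
recovery bias, so passing parameter-recovery tests demonstrates the
estimators track the generating model, not that real surveys satisfy it.

## Test battery

Chi-square is uncorrected Pearson Σ(O−E)²/E (the published statistics
0.88, 7.02, 2.83 are uncorrected values); a zero margin is an error,
expected counts below 5 warn but do not fail, since sparse composition
tables are the norm in this setting.  Kruskal–Wallis uses midranks with
the standard tie correction; all-identical inputs return statistic 0
rather than erroring.  Dunn's z uses pooled midranks with tie term
Σ(t³−t)/(12(N−1)); adjustment (none/holm/bonferroni) defaults to none,
as the reference analysis states none.  The rank-sum statistic is the
first sample's U (the R `wilcox.test` W) with tie-corrected normal
p-value and no continuity correction; the t-test is Welch's with
Welch–Satterthwaite df.  The published rank-sum/t/correlation values on
raw morphometrics and the province-level chi-squares are not
reproducible from printed data (raw values and the full province ×
category tables were not published) and are implemented but not
verified against them.

## Problem sizes and numerical choices

Verification jobs are sized for a laptop-class single core: generator
parameter recovery uses 200 replicates of a 2 000-individual stratum
(estimates compared within 3 Monte-Carlo SEs), and test calibration uses
10⁴ null replicates (2×3 multinomial tables of 200 particles; 3 × 15
Kruskal–Wallis samples), giving a ±0.0065 three-SE band around the
nominal 0.05.  Probability vectors must sum to 1 within 1e-9;
classification thresholds are exact floating comparisons; all reported
statistics are computed in double precision with no accumulated
rounding shortcuts.

## Limitations

Polymer identity, shape and color are taken as given (no spectral or
image processing); scores are inputs, not derived from monomer toxicity;
the fixture's per-individual particle split beyond the published
per-province totals is a deterministic convention, so statistics that
depend on the within-province distribution of loads (beyond means) are
not survey-faithful; and the generator's independence assumptions are
documented above.
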