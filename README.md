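# mpsurvey

Analysis toolkit for gastrointestinal-tract microplastic surveys of
wildlife: contamination prevalence and particle-characterization
summaries, the Polymer Hazard Index (PHI) and Potential Ecological Risk
Index (PERI) with their five-level classifications, and the
categorical/nonparametric test battery such surveys report — plus a
seeded synthetic-survey generator and a deterministic reconstruction of
a published two-species tree-frog survey (*Hyla savignyi* and *Hyla
orientalis* across Türkiye) used to verify every stage against printed
results.

It is written for ecotoxicologists and biostatisticians who have a table
of examined individuals and a table of identified particles (polymer,
shape, color, size) and want reproducible prevalence, risk-index and
composition-test outputs.

## The model

A survey is two tables: individuals (species, province, snout–vent
length, gastrointestinal-tract weight) and particles (polymer, shape ∈
{fiber, fragment, film}, color, size in µm, each linked to an
individual).  An individual is *contaminated* iff it carries ≥ 1
particle.  For a group of particles with polymer proportions Pₙ and
Lithner-derived hazard scores Sₙ (packaged defaults: PE 11, PP 1, PET 4,
PA/NYLON 47, PU 7384, PAN 10 599, EVA 9, PCT 4):

```
PHI  = Σₙ Pₙ · Sₙ
CF   = (mean particles per contaminated individual) / C₀,  C₀ = 1
PERI = Σₙ (Pₙ · Sₙ) · CF = PHI · CF
```

Both indices classify into five ordinal levels at thresholds
150 / 300 / 600 / 1200 (PHI: low → very high hazard; PERI: minor →
extreme danger).  Composition differences between groups are tested with
uncorrected Pearson chi-square; size differences across categories with
Kruskal–Wallis plus Dunn's post hoc; morphometrics with Wilcoxon
rank-sum, Welch's t and Pearson correlation.

The synthetic generator draws, per species × province stratum,
independent contamination with a configured prevalence, particle counts
from a zero-truncated Poisson calibrated on the *truncated* mean,
attributes from categorical mixtures (shape conditional on polymer), and
log-normal sizes per shape.

## Worked example

```python
from mpsurvey import reference_survey, risk_report

dataset = reference_survey()
for r in risk_report(dataset, group_by="species", formatting="paper_truncated"):
    print(f"{r.group}: PHI = {r.phi:.2f} ({r.phi_category}), CF = {r.cf:.2f}, "
          f"PERI = {r.peri:.2f} ({r.peri_category})")
```

prints

```
Hyla orientalis: PHI = 5.33 (low), CF = 1.00, PERI = 5.33 (minor)
Hyla savignyi: PHI = 167.48 (medium), CF = 1.61, PERI = 269.64 (medium)
```

*H. savignyi*'s particle mixture (183 particles, PET-dominated with
traces of the high-hazard PAN and PU) scores PHI ≈ 167.48 — medium
hazard — and its exposure (183 particles across 113 contaminated
individuals, mean load 1.61 after the published truncating arithmetic)
lifts this to PERI ≈ 269.64, medium danger.  *H. orientalis* carried one
particle per contaminated individual (CF = 1), so its PERI equals its
PHI.  More walkthroughs live in `examples/` (one script per capability),
and the same operations are exposed on the command line:

```
mpsurvey simulate --seed 3 --out sim/
mpsurvey validate  --individuals sim/individuals.csv --particles sim/particles.csv
mpsurvey risk      --individuals sim/individuals.csv --particles sim/particles.csv --by species
mpsurvey test      --individuals sim/individuals.csv --particles sim/particles.csv \
                   --kind chi2 --row species --col shape
```

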