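"""Generate a synthetic survey under the reference study conditions.

Each stratum (species x province) contaminates individuals independently
at its configured prevalence; positives draw particle counts from a
zero-truncated Poisson calibrated so the *truncated* mean equals the
configured mean items per positive; particle attributes come from the
configured mixtures; sizes are log-normal per shape.
"""

from mpsurvey import default_survey_config, generate_survey, prevalence

config = default_survey_config(seed=42)
dataset = generate_survey(config)
print(f"generated {dataset.n_individuals()} individuals, {dataset.n_particles()} particles")

for s in prevalence(dataset, "species"):
    print(f"{s.group}: {s.rate_pct:.1f}% contaminated, {s.n_particles} particles")
# With seed 42 the empirical rates fluctuate around the configured
# species-level prevalences (56.5% and 11.8%); rerunning with the same
# seed reproduces the dataset byte for byte.

pet = (dataset.particles["polymer"] == "PET").mean()
print(f"PET fraction: {pet:.3f} (configured {config.polymer_mixture['PET']:.3f})")
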