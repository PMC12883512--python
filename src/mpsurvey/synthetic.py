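"""Seeded generator for synthetic multi-province microplastic surveys.

The generator emulates the statistical structure the analysis assumes:

* each stratum (species × province) has ``n_individuals`` animals, each
  independently contaminated with probability ``prevalence``;
* a contaminated individual carries k ≥ 1 particles drawn from a
  zero-truncated Poisson; the configured ``mean_items`` is the mean of
  the *truncated* law, i.e. λ is calibrated so that λ/(1−e^{−λ}) equals
  it (surveys report mean items per contaminated individual, not λ);
* particle polymer is drawn from the stratum's polymer mixture, shape
  from a shape-given-polymer conditional table, color independently
  from a color mixture (published data give only marginal color counts);
* particle size is log-normal per shape (sizes are positive and
  right-skewed, spanning roughly 30–1100 µm in the reference survey),
  resampled in the rare case a draw reaches the 5 mm microplastic bound.

Everything is reproducible from ``SurveyConfig.seed``.
:func:`default_survey_config` mirrors the reference survey's strata and
compositions, so generated surveys are statistically exchangeable with
the reconstructed one.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.stats import poisson

from . import reference
from .io import SHAPE_LABELS, MAX_PARTICLE_SIZE_UM, SurveyDataset

__all__ = [
    "LogNormalSize",
    "StratumConfig",
    "SurveyConfig",
    "generate_survey",
    "default_survey_config",
    "zt_poisson_lambda",
    "zt_poisson_mean",
]

_PROB_TOL = 1e-9


def zt_poisson_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: λ / (1 − e^{−λ}); → 1 as λ → 0."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 1.0
    return lam / (1.0 - math.exp(-lam))


def zt_poisson_lambda(mean: float) -> float:
    """Invert the truncated mean: the λ with λ/(1−e^{−λ}) = mean (mean ≥ 1)."""
    if mean < 1:
        raise ValueError("zero-truncated Poisson mean must be >= 1")
    if mean == 1:
        return 0.0
    return float(brentq(lambda lam: zt_poisson_mean(lam) - mean, 1e-12, mean + 20.0))


def _sample_zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Exact inverse-CDF sampling of k ≥ 1 from Poisson(λ) conditioned on k ≥ 1."""
    if size == 0:
        return np.zeros(0, dtype=int)
    if lam == 0.0:
        return np.ones(size, dtype=int)
    p0 = math.exp(-lam)
    u = rng.uniform(size=size)
    return poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)


class LogNormalSize(BaseModel):
    """Log-normal size model: log-size ~ Normal(mu_log, sigma_log²), µm."""

    mu_log: float
    sigma_log: float = Field(gt=0)


def _check_simplex(probs: dict[str, float], what: str) -> dict[str, float]:
    if not probs:
        raise ValueError(f"{what} must be nonempty")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{what} has negative probabilities")
    total = sum(probs.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"{what} must sum to 1 (got {total!r})")
    return probs


class StratumConfig(BaseModel):
    """One species × province stratum."""

    species: str
    province: str
    n_individuals: int = Field(gt=0)
    prevalence: float = Field(ge=0.0, le=1.0)
    mean_items: float = Field(ge=1.0, description="mean particles per contaminated individual (truncated-Poisson mean)")


class SurveyConfig(BaseModel):
    """Full generator configuration (shared mixtures, per-stratum rates)."""

    strata: list[StratumConfig] = Field(min_length=1)
    polymer_mixture: dict[str, float]
    shape_given_polymer: dict[str, dict[str, float]]
    color_mixture: dict[str, float]
    size_model: dict[str, LogNormalSize]
    seed: int = 0

    @field_validator("polymer_mixture", "color_mixture")
    @classmethod
    def _simplex(cls, v, info):
        return _check_simplex(v, info.field_name)

    @field_validator("shape_given_polymer")
    @classmethod
    def _conditional_simplex(cls, v):
        for poly, probs in v.items():
            _check_simplex(probs, f"shape_given_polymer[{poly!r}]")
            unknown = set(probs) - set(SHAPE_LABELS)
            if unknown:
                raise ValueError(f"unknown shapes {sorted(unknown)} for polymer {poly!r}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self):
        missing = set(self.polymer_mixture) - set(self.shape_given_polymer)
        if missing:
            raise ValueError(f"polymers without a shape distribution: {sorted(missing)}")
        shapes_used = {s for probs in self.shape_given_polymer.values() for s in probs}
        no_size = shapes_used - set(self.size_model)
        if no_size:
            raise ValueError(f"shapes without a size model: {sorted(no_size)}")
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False, allow_unicode=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SurveyConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        return cls.model_validate(data)


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    labels = np.array(sorted(probs))
    p = np.array([probs[l] for l in labels], dtype=float)
    p = p / p.sum()  # renormalise away the <=1e-9 tolerance
    return rng.choice(labels, size=size, p=p)


def _draw_sizes(rng: np.random.Generator, model: LogNormalSize, size: int) -> np.ndarray:
    out = rng.lognormal(model.mu_log, model.sigma_log, size)
    # the 5 mm bound defines a microplastic; resample the rare overshoot
    bad = out >= MAX_PARTICLE_SIZE_UM
    while bad.any():
        out[bad] = rng.lognormal(model.mu_log, model.sigma_log, int(bad.sum()))
        bad = out >= MAX_PARTICLE_SIZE_UM
    return out


def generate_survey(config: SurveyConfig) -> SurveyDataset:
    """Sample one survey dataset from the configured model.

    Fully reproducible given ``config.seed``; the number of particles
    equals the sum of per-contaminated-individual counts by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    lam_cache = {s.mean_items: zt_poisson_lambda(s.mean_items) for s in config.strata}

    ind_rows = []
    hosts: list[str] = []
    host_counts: list[int] = []
    for idx, stratum in enumerate(config.strata):
        code = f"S{idx:02d}"
        contaminated = rng.uniform(size=stratum.n_individuals) < stratum.prevalence
        ks = _sample_zt_poisson(rng, lam_cache[stratum.mean_items], int(contaminated.sum()))
        k_iter: Iterator[int] = iter(ks)
        for i in range(stratum.n_individuals):
            iid = f"{code}-{i + 1:04d}"
            ind_rows.append((iid, stratum.species, stratum.province, np.nan, np.nan))
            if contaminated[i]:
                k = int(next(k_iter))
                hosts.append(iid)
                host_counts.append(k)

    individuals = pd.DataFrame(
        ind_rows, columns=["individual_id", "species", "province", "svl_mm", "git_weight_g"]
    )

    n_particles = int(sum(host_counts))
    owner = np.repeat(np.array(hosts, dtype=object), np.array(host_counts, dtype=int)) if hosts else np.array([], dtype=object)
    polymers = _draw_categorical(rng, config.polymer_mixture, n_particles)
    shapes = np.empty(n_particles, dtype=object)
    sizes = np.empty(n_particles, dtype=float)
    for poly in np.unique(polymers):
        mask = polymers == poly
        shapes[mask] = _draw_categorical(rng, config.shape_given_polymer[str(poly)], int(mask.sum()))
    for shape in np.unique(shapes) if n_particles else []:
        mask = shapes == shape
        sizes[mask] = _draw_sizes(rng, config.size_model[str(shape)], int(mask.sum()))
    colors = _draw_categorical(rng, config.color_mixture, n_particles)

    particles = pd.DataFrame(
        {
            "particle_id": [f"P{i + 1:05d}" for i in range(n_particles)],
            "individual_id": owner,
            "polymer": polymers.astype(object),
            "shape": shapes,
            "color": colors.astype(object),
            "size_um": np.round(sizes, 2),
        }
    )
    return SurveyDataset(individuals, particles)


def default_survey_config(seed: int = 0) -> SurveyConfig:
    """Generator configuration mirroring the reference survey.

    Strata reproduce the reference province table (N, prevalence, mean
    items per contaminated individual); mixtures pool both species'
    particle compositions; per-shape log-normal size models are moment
    matched to the published per-shape mean sizes (fiber 219.33 µm,
    fragment 142.98 µm, film 496.74 µm) with a common log-scale SD of
    0.8, a typical spread for right-skewed particle-size data.
    """
    strata = []
    for province, species, n, n_pos, n_mp, _svl, _git in reference.PROVINCE_TABLE:
        strata.append(
            StratumConfig(
                species=species,
                province=province,
                n_individuals=n,
                prevalence=n_pos / n,
                mean_items=(n_mp / n_pos) if n_pos else 1.0,
            )
        )

    polymer_totals: dict[str, int] = {}
    shape_within: dict[str, dict[str, int]] = {}
    color_totals: dict[str, int] = {}
    for species in reference.SHAPE_WITHIN_POLYMER:
        for poly, shapes in reference.SHAPE_WITHIN_POLYMER[species].items():
            for shape, k in shapes.items():
                polymer_totals[poly] = polymer_totals.get(poly, 0) + k
                shape_within.setdefault(poly, {})
                shape_within[poly][shape] = shape_within[poly].get(shape, 0) + k
        for color, k in reference.COLOR_COUNTS[species].items():
            color_totals[color] = color_totals.get(color, 0) + k

    total = sum(polymer_totals.values())
    polymer_mixture = {p: k / total for p, k in polymer_totals.items()}
    shape_given_polymer = {
        p: {s: k / sum(shapes.values()) for s, k in shapes.items()} for p, shapes in shape_within.items()
    }
    color_mixture = {c: k / total for c, k in color_totals.items()}

    sigma = 0.8
    mean_size = {"fiber": 219.33, "fragment": 142.98, "film": 496.74}
    size_model = {
        shape: LogNormalSize(mu_log=math.log(m) - sigma**2 / 2, sigma_log=sigma)
        for shape, m in mean_size.items()
    }
    return SurveyConfig(
        strata=strata,
        polymer_mixture=polymer_mixture,
        shape_given_polymer=shape_given_polymer,
        color_mixture=color_mixture,
        size_model=size_model,
        seed=seed,
    )
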