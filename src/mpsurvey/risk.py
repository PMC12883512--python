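"""Polymer Hazard Index (PHI) and Potential Ecological Risk Index (PERI).

PHI scores a polymer mixture by chemical hazard:

    PHI = Σₙ Pₙ · Sₙ

where Pₙ is the proportion of particles of polymer n in the group and Sₙ
its hazard score after the Lithner monomer-hazard ranking (packaged
defaults: PE 11, PP 1, PET 4, PA 47, NYLON 47, PU 7384, PAN 10599,
EVA 9, PCT 4).  PERI couples that hazard with exposure magnitude:

    CF   = (mean particles per contaminated individual) / C₀,   C₀ = 1
    PERI = Σₙ (Pₙ · Sₙ) · CF = PHI · CF

since CF is constant across polymers within a group.  Both indices are
mapped onto five-level ordinal categories with thresholds 150, 300, 600
and 1200 (PHI: low → very high hazard; PERI: minor → extreme danger).

Note on Pₙ: hazard-index literature sometimes words Pₙ as a "percentage";
here Pₙ is a *proportion* (0–1).  Only proportions place realistic
amphibian-survey mixtures on the published category scale (e.g. a
PET-dominated mixture with traces of PAN/PU scores ≈167, medium hazard;
on a 0–100 percentage scale the same mixture would score ≈16 748 and
every group would be "very high").  A percentage mode is deliberately
not offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .descriptive import truncate_decimals
from .io import SurveyDataset

__all__ = [
    "HazardScoreTable",
    "PolymerProfile",
    "RiskResult",
    "default_hazard_scores",
    "load_hazard_scores",
    "phi",
    "classify_phi",
    "contamination_factor",
    "peri",
    "classify_peri",
    "risk_report",
    "PHI_CATEGORIES",
    "PERI_CATEGORIES",
]

#: Shared category thresholds; bins are left-closed half-open
#: ([0,150), [150,300), [300,600), [600,1200), [1200,∞)).  The published
#: definitions use strict inequalities on both sides and leave exact
#: boundary values unassigned; half-open intervals make the classifier a
#: total monotone step function.
_THRESHOLDS = (150.0, 300.0, 600.0, 1200.0)
PHI_CATEGORIES = ("low", "medium", "considerable", "high", "very high")
PERI_CATEGORIES = ("minor", "medium", "high", "danger", "extreme danger")


class MissingScoreError(KeyError):
    """A polymer in the profile has no hazard score (never silently zero)."""


@dataclass(frozen=True)
class HazardScoreTable:
    """Mapping polymer label → hazard score Sₙ (dimensionless, ≥ 0)."""

    scores: Mapping[str, float]

    def __post_init__(self):
        for poly, s in self.scores.items():
            if s < 0:
                raise ValueError(f"hazard score for {poly!r} must be >= 0, got {s}")

    def __getitem__(self, polymer: str) -> float:
        try:
            return float(self.scores[polymer])
        except KeyError:
            raise MissingScoreError(f"no hazard score for polymer {polymer!r}") from None

    def __contains__(self, polymer: str) -> bool:
        return polymer in self.scores


def default_hazard_scores() -> HazardScoreTable:
    """The packaged default score table (Lithner-derived ranks)."""
    with resources.files("mpsurvey.data").joinpath("hazard_scores.csv").open("r") as fh:
        return load_hazard_scores(fh)


def load_hazard_scores(source) -> HazardScoreTable:
    """Load a polymer → score CSV with columns ``polymer, score``."""
    df = pd.read_csv(source)
    if not {"polymer", "score"} <= set(df.columns):
        raise ValueError("hazard score table needs columns 'polymer' and 'score'")
    return HazardScoreTable(dict(zip(df["polymer"].str.strip(), df["score"].astype(float))))


@dataclass(frozen=True)
class PolymerProfile:
    """Polymer composition of a particle group, as nonnegative counts."""

    counts: Mapping[str, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("polymer counts must be nonnegative")
        if self.total == 0:
            raise ValueError("polymer profile must contain at least one particle")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def proportions(self) -> dict[str, float]:
        """Pₙ = count / total; sums to 1."""
        tot = self.total
        return {poly: c / tot for poly, c in self.counts.items() if c > 0}

    @classmethod
    def from_particles(cls, particles: pd.DataFrame) -> "PolymerProfile":
        return cls(particles["polymer"].value_counts().to_dict())


@dataclass(frozen=True)
class RiskResult:
    group: str
    n_particles: int
    n_contaminated: int
    phi: float
    phi_category: str
    cf: float
    peri: float
    peri_category: str


def phi(profile: PolymerProfile, scores: HazardScoreTable) -> float:
    """Polymer Hazard Index: Σₙ Pₙ · Sₙ over the profile's polymers.

    Raises :class:`MissingScoreError` if any polymer with a positive
    count lacks a score — an unscored polymer must never contribute a
    silent zero.
    """
    return sum(p * scores[poly] for poly, p in profile.proportions().items())


def _classify(value: float, categories: tuple[str, ...]) -> str:
    if value < 0:
        raise ValueError(f"index value must be >= 0, got {value}")
    for threshold, category in zip(_THRESHOLDS, categories):
        if value < threshold:
            return category
    return categories[-1]


def classify_phi(value: float) -> str:
    """Five-level hazard category for a PHI value."""
    return _classify(value, PHI_CATEGORIES)


def classify_peri(value: float) -> str:
    """Five-level danger category for a PERI value."""
    return _classify(value, PERI_CATEGORIES)


def contamination_factor(
    n_particles: int,
    n_contaminated: int,
    c0: float = 1.0,
    formatting: str = "full",
) -> float:
    """CF = (n_particles / n_contaminated) / c0.

    ``formatting="paper_truncated"`` truncates the mean load to two
    decimals before dividing by c0, reproducing published arithmetic in
    which 183/113 = 1.6194… enters the risk product as 1.61.  Default is
    full precision.
    """
    if n_contaminated <= 0:
        raise ValueError("CF undefined: no contaminated individuals")
    if c0 <= 0:
        raise ValueError("reference level c0 must be positive")
    mean_load = n_particles / n_contaminated
    if formatting == "paper_truncated":
        mean_load = truncate_decimals(mean_load, 2)
    elif formatting != "full":
        raise ValueError(f"formatting must be 'full' or 'paper_truncated', got {formatting!r}")
    return mean_load / c0


def peri(phi_value: float, cf: float) -> float:
    """PERI = PHI · CF (CF is constant across polymers within a group)."""
    if phi_value < 0 or cf < 0:
        raise ValueError("PHI and CF must be >= 0")
    return phi_value * cf


def risk_report(
    dataset: SurveyDataset,
    scores: HazardScoreTable | None = None,
    group_by: str = "species",
    c0: float = 1.0,
    formatting: str = "full",
) -> list[RiskResult]:
    """Per-group PHI, CF and PERI with their categories.

    Groups are species or province; a group enters the report only if it
    has at least one particle and one contaminated individual.  Results
    are independent of particle row order.
    """
    if group_by not in ("species", "province"):
        raise ValueError(f"group_by must be 'species' or 'province', got {group_by!r}")
    if scores is None:
        scores = default_hazard_scores()

    frame = dataset.particles_with_individual_attrs()
    counts = dataset.particle_counts()
    ind = dataset.individuals.assign(k=counts.to_numpy())

    out = []
    for label in sorted(frame[group_by].dropna().unique()):
        particles = frame[frame[group_by] == label]
        n_contaminated = int((ind.loc[ind[group_by] == label, "k"] > 0).sum())
        if len(particles) == 0 or n_contaminated == 0:
            continue
        profile = PolymerProfile.from_particles(particles)
        phi_value = phi(profile, scores)
        cf = contamination_factor(len(particles), n_contaminated, c0, formatting)
        peri_value = peri(phi_value, cf)
        out.append(
            RiskResult(
                group=str(label),
                n_particles=len(particles),
                n_contaminated=n_contaminated,
                phi=phi_value,
                phi_category=classify_phi(phi_value),
                cf=cf,
                peri=peri_value,
                peri_category=classify_peri(peri_value),
            )
        )
    return out


def risk_report_frame(dataset, scores=None, group_by="species", c0=1.0, formatting="full") -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in risk_report(dataset, scores, group_by, c0, formatting)])
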