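"""Grouped contamination and particle-size summaries.

These functions populate the survey-style summary tables: per-group
contamination prevalence (how many individuals carried at least one
particle), mean particle load among contaminated individuals (the
numerator of the contamination factor used by the risk indices), and
particle-size descriptives.

All statistics are computed at full floating precision.  The published
tables truncate decimals rather than round (183/113 = 1.6194… is printed
as 1.61, 24/7 = 3.4285… as 3.42), so :func:`truncate_decimals` /
:func:`format_truncated` are provided to reproduce printed values
exactly; they are display helpers only and never feed back into
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SurveyDataset

__all__ = [
    "PrevalenceSummary",
    "SizeSummary",
    "prevalence",
    "items_per_contaminated",
    "size_summary",
    "truncate_decimals",
    "format_truncated",
]

_GROUP_FIELDS = ("species", "province", "overall")
_SIZE_GROUP_FIELDS = ("species", "province", "polymer", "shape", "color", "overall")


def truncate_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate (round toward zero) to ``ndigits`` decimals: 1.6194 → 1.61."""
    factor = 10**ndigits
    return math.trunc(x * factor) / factor


def format_truncated(x: float, ndigits: int = 2) -> str:
    """Format with truncation, keeping trailing zeros ("3.42", "4.40")."""
    return f"{truncate_decimals(x, ndigits):.{ndigits}f}"


@dataclass(frozen=True)
class PrevalenceSummary:
    """Contamination summary for one group of individuals.

    ``mean_items_per_positive`` is ``n_particles / n_positive`` at full
    precision, or None when the group has no contaminated individual.
    """

    group: str
    n: int
    n_positive: int
    rate_pct: float
    n_particles: int
    mean_items_per_positive: float | None


@dataclass(frozen=True)
class SizeSummary:
    """Particle-size descriptives for one group of particles.

    ``se_um`` is the standard error of the mean (sample SD with n−1
    denominator over √n); it is None for a single particle rather than
    0, since one observation carries no spread information.
    """

    group: str
    n_particles: int
    mean_um: float
    se_um: float | None
    min_um: float
    max_um: float


def _group_individuals(dataset: SurveyDataset, group_by: str) -> pd.core.groupby.DataFrameGroupBy:
    if group_by not in _GROUP_FIELDS:
        raise ValueError(f"group_by must be one of {_GROUP_FIELDS}, got {group_by!r}")
    ind = dataset.individuals.copy()
    key = "overall" if group_by == "overall" else group_by
    if group_by == "overall":
        ind["overall"] = "overall"
    return ind.groupby(key, sort=True)


def prevalence(dataset: SurveyDataset, group_by: str = "species") -> list[PrevalenceSummary]:
    """Per-group contamination prevalence.

    An individual counts as positive iff at least one particle links to
    it.  ``rate_pct`` is 100 · positives / examined.  Groups with zero
    individuals do not occur (grouping is over observed labels).
    """
    counts = dataset.particle_counts()
    by_id = pd.Series(counts.to_numpy(), index=dataset.individuals["individual_id"])
    out = []
    for label, grp in _group_individuals(dataset, group_by):
        k = by_id.loc[grp["individual_id"]]
        n = len(grp)
        n_pos = int((k > 0).sum())
        n_particles = int(k.sum())
        out.append(
            PrevalenceSummary(
                group=str(label),
                n=n,
                n_positive=n_pos,
                rate_pct=100.0 * n_pos / n,
                n_particles=n_particles,
                mean_items_per_positive=(n_particles / n_pos) if n_pos else None,
            )
        )
    return out


def items_per_contaminated(dataset: SurveyDataset, group_by: str = "species") -> dict[str, float | None]:
    """Mean particles per contaminated individual, per group.

    This is the exposure quantity the contamination factor normalises
    (reference C₀ = 1 particle per contaminated individual).  Returned at
    full precision; use :func:`format_truncated` for printed-style values
    ("3.42" for 24/7).  Groups without contaminated individuals map to
    None.
    """
    return {s.group: s.mean_items_per_positive for s in prevalence(dataset, group_by)}


def size_summary(dataset: SurveyDataset, group_by: str = "species") -> list[SizeSummary]:
    """Particle-size mean ± SE and range per group; empty groups are omitted."""
    if group_by not in _SIZE_GROUP_FIELDS:
        raise ValueError(f"group_by must be one of {_SIZE_GROUP_FIELDS}, got {group_by!r}")
    frame = dataset.particles_with_individual_attrs()
    if group_by == "overall":
        frame = frame.assign(overall="overall")
    out = []
    for label, grp in frame.groupby(group_by, sort=True):
        sizes = grp["size_um"].to_numpy(dtype=float)
        n = sizes.size
        se = float(np.std(sizes, ddof=1) / math.sqrt(n)) if n > 1 else None
        out.append(
            SizeSummary(
                group=str(label),
                n_particles=int(n),
                mean_um=float(sizes.mean()),
                se_um=se,
                min_um=float(sizes.min()),
                max_um=float(sizes.max()),
            )
        )
    return out


def prevalence_frame(dataset: SurveyDataset, group_by: str = "species") -> pd.DataFrame:
    """Prevalence summaries as a DataFrame (convenient for CSV output)."""
    return pd.DataFrame([vars(s) for s in prevalence(dataset, group_by)])


def size_summary_frame(dataset: SurveyDataset, group_by: str = "species") -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in size_summary(dataset, group_by)])
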