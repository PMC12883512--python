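"""Survey data model and delimited-table input/output.

A microplastic survey is stored as two flat tables:

``individuals``
    one row per examined animal — ``individual_id, species, province,
    svl_mm, git_weight_g`` (snout–vent length in millimetres and
    gastrointestinal-tract wet weight in grams; both may be missing).

``particles``
    one row per detected microplastic — ``particle_id, individual_id,
    polymer, shape, color, size_um``.  ``shape`` is one of ``fiber``,
    ``fragment``, ``film``; polymer and color are open vocabularies with
    a canonical spelling for the common labels; ``size_um`` must lie in
    (0, 5000) µm, the conventional upper bound for a microplastic.

Contamination status is never stored: an individual is contaminated iff
at least one particle row references it.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "SurveyDataset",
    "ContingencyTable",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "RowParseError",
    "RowValidationError",
    "INDIVIDUAL_COLUMNS",
    "PARTICLE_COLUMNS",
    "SHAPE_LABELS",
    "POLYMER_LABELS",
    "COLOR_LABELS",
    "read_individual_table",
    "read_particle_table",
    "write_individual_table",
    "write_particle_table",
    "validate_dataset",
    "contingency_table",
    "normalize_label",
]

INDIVIDUAL_COLUMNS = ["individual_id", "species", "province", "svl_mm", "git_weight_g"]
PARTICLE_COLUMNS = ["particle_id", "individual_id", "polymer", "shape", "color", "size_um"]

SHAPE_LABELS = ("fiber", "fragment", "film")

#: Canonical spellings for the polymer vocabulary.  PA and NYLON are kept
#: distinct on purpose: they are chemically synonymous but are reported as
#: separate categories, and merging them silently would change every
#: sum-over-polymers quantity downstream.  ``PA_NYLON_ALIASES`` can be
#: passed to :func:`merge_polymer_aliases` to pool them explicitly.
POLYMER_LABELS = ("PET", "PE", "PA", "NYLON", "EVA", "PAN", "PU", "PP", "PCT")

COLOR_LABELS = (
    "navy blue",
    "black",
    "pink",
    "blue",
    "red",
    "gray",
    "green",
    "transparent",
)

#: Microplastic definition: particles strictly smaller than 5 mm.
MAX_PARTICLE_SIZE_UM = 5000.0


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class RowParseError(ValueError):
    """A cell in a data row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class RowValidationError(ValueError):
    """A parsed value violates a domain invariant; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect.

    ``decimal`` exists because survey tables from locales that write
    decimal commas ("36,82" for 36.82 mm) are common; outputs always use
    the point.
    """

    delimiter: str = ","
    decimal: str = "."


_CANONICAL = {lbl.lower(): lbl for lbl in POLYMER_LABELS + COLOR_LABELS + SHAPE_LABELS}
_CANONICAL["grey"] = "gray"


def normalize_label(value: str) -> str:
    """Trim and map case-insensitively onto the canonical vocabulary.

    Unknown labels are kept verbatim (trimmed): polymer and color are open
    vocabularies, so a new label is data, not an error.
    """
    v = str(value).strip()
    return _CANONICAL.get(v.lower(), v)


def _read_raw(source, dialect: Dialect, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing (found {list(df.columns)})")
    return df


def _parse_numeric(series: pd.Series, dialect: Dialect, column: str) -> pd.Series:
    raw = series.str.strip() if series.dtype == object else series
    if dialect.decimal != ".":
        raw = raw.str.replace(dialect.decimal, ".", regex=False)
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.str.len() > 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowParseError(row, f"non-numeric value {series.iloc[row]!r} in column {column!r}")
    return out.astype(float)


def read_individual_table(source, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read an individuals table (one row per examined animal).

    Parameters
    ----------
    source
        Path or text stream of a delimited file with a header row.
    dialect
        Delimiter and decimal-mark options.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`INDIVIDUAL_COLUMNS`; missing morphometrics are NaN.
    """
    df = _read_raw(source, dialect, INDIVIDUAL_COLUMNS)
    out = pd.DataFrame(
        {
            "individual_id": df["individual_id"].str.strip(),
            "species": df["species"].str.strip(),
            "province": df["province"].str.strip(),
            "svl_mm": _parse_numeric(df["svl_mm"], dialect, "svl_mm"),
            "git_weight_g": _parse_numeric(df["git_weight_g"], dialect, "git_weight_g"),
        }
    )
    return out


def read_particle_table(source, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read a particles table (one row per detected microplastic).

    Polymer, shape and color are normalized case-insensitively against the
    canonical vocabulary.  Rows with a shape outside {fiber, fragment,
    film} or a size outside (0, 5000) µm raise :class:`RowValidationError`
    rather than being coerced or dropped.
    """
    df = _read_raw(source, dialect, PARTICLE_COLUMNS)
    size = _parse_numeric(df["size_um"], dialect, "size_um")
    out = pd.DataFrame(
        {
            "particle_id": df["particle_id"].str.strip(),
            "individual_id": df["individual_id"].str.strip(),
            "polymer": df["polymer"].map(normalize_label),
            "shape": df["shape"].map(normalize_label),
            "color": df["color"].map(normalize_label),
            "size_um": size,
        }
    )
    bad_shape = ~out["shape"].isin(SHAPE_LABELS)
    if bad_shape.any():
        row = int(np.flatnonzero(bad_shape.to_numpy())[0])
        raise RowValidationError(row, f"unknown shape {out['shape'].iloc[row]!r}")
    if out["size_um"].isna().any():
        row = int(np.flatnonzero(out["size_um"].isna().to_numpy())[0])
        raise RowValidationError(row, "missing size_um (particles must have a size)")
    out_of_range = (out["size_um"] <= 0) | (out["size_um"] >= MAX_PARTICLE_SIZE_UM)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise RowValidationError(
            row,
            f"size_um {out['size_um'].iloc[row]} outside (0, {MAX_PARTICLE_SIZE_UM}) µm",
        )
    return out


def write_individual_table(individuals: pd.DataFrame, target, delimiter: str = ",") -> None:
    """Write an individuals table; the decimal mark is always '.'."""
    individuals.to_csv(target, sep=delimiter, index=False, columns=INDIVIDUAL_COLUMNS)


def write_particle_table(particles: pd.DataFrame, target, delimiter: str = ",") -> None:
    particles.to_csv(target, sep=delimiter, index=False, columns=PARTICLE_COLUMNS)


@dataclass
class SurveyDataset:
    """A survey: individuals plus the particles recovered from them."""

    individuals: pd.DataFrame
    particles: pd.DataFrame

    @classmethod
    def from_files(cls, individuals_path, particles_path, dialect: Dialect = Dialect()) -> "SurveyDataset":
        return cls(
            read_individual_table(individuals_path, dialect),
            read_particle_table(particles_path, dialect),
        )

    def particle_counts(self) -> pd.Series:
        """Particles per individual, indexed by individual_id (zeros included)."""
        counts = self.particles.groupby("individual_id").size()
        return counts.reindex(self.individuals["individual_id"], fill_value=0)

    def contaminated_mask(self) -> pd.Series:
        """Boolean per individual: contaminated iff ≥ 1 linked particle."""
        return self.particle_counts() > 0

    def n_individuals(self) -> int:
        return len(self.individuals)

    def n_particles(self) -> int:
        return len(self.particles)

    def particles_with_individual_attrs(self) -> pd.DataFrame:
        """Particles joined with species/province of the owning individual."""
        return self.particles.merge(
            self.individuals[["individual_id", "species", "province"]],
            on="individual_id",
            how="left",
            validate="many_to_one",
        )

    def to_files(self, individuals_path, particles_path, delimiter: str = ",") -> None:
        write_individual_table(self.individuals, individuals_path, delimiter)
        write_particle_table(self.particles, particles_path, delimiter)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # orphan_particle | duplicate_id | out_of_range | missing_field
    message: str
    record_id: str

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "record_id": self.record_id, "message": self.message})


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def __iter__(self):
        return iter(self.issues)

    def to_jsonl(self) -> str:
        return "\n".join(issue.to_json() for issue in self.issues)


def validate_dataset(dataset: SurveyDataset) -> ValidationReport:
    """Check referential and domain integrity; report, never raise.

    The report is empty iff every invariant holds: unique ids, particles
    referencing existing individuals, positive morphometrics where
    present, shapes in the closed vocabulary, sizes in (0, 5000) µm.
    """
    issues: list[ValidationIssue] = []
    ind = dataset.individuals
    par = dataset.particles

    for dup in ind.loc[ind["individual_id"].duplicated(), "individual_id"].unique():
        issues.append(ValidationIssue("duplicate_id", "duplicate individual_id", str(dup)))
    for dup in par.loc[par["particle_id"].duplicated(), "particle_id"].unique():
        issues.append(ValidationIssue("duplicate_id", "duplicate particle_id", str(dup)))

    known = set(ind["individual_id"])
    orphans = par.loc[~par["individual_id"].isin(known)]
    for pid, iid in zip(orphans["particle_id"], orphans["individual_id"]):
        issues.append(
            ValidationIssue("orphan_particle", f"particle references absent individual {iid!r}", str(pid))
        )

    for col in ("svl_mm", "git_weight_g"):
        bad = ind.loc[ind[col].notna() & (ind[col] <= 0), "individual_id"]
        for iid in bad:
            issues.append(ValidationIssue("out_of_range", f"{col} must be > 0 when present", str(iid)))

    bad_shape = par.loc[~par["shape"].isin(SHAPE_LABELS), "particle_id"]
    for pid in bad_shape:
        issues.append(ValidationIssue("out_of_range", "shape outside {fiber, fragment, film}", str(pid)))

    bad_size = par.loc[
        par["size_um"].isna() | (par["size_um"] <= 0) | (par["size_um"] >= MAX_PARTICLE_SIZE_UM),
        "particle_id",
    ]
    for pid in bad_size:
        issues.append(
            ValidationIssue("out_of_range", f"size_um outside (0, {MAX_PARTICLE_SIZE_UM}) µm", str(pid))
        )
    return ValidationReport(issues)


@dataclass(frozen=True)
class ContingencyTable:
    """Particle counts cross-classified by two categorical factors."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # (n_rows, n_cols) nonnegative ints

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match label lists")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        if len(set(self.row_labels)) != len(self.row_labels) or len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate row or column labels")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


_INDIVIDUAL_FACTORS = ("species", "province")
_PARTICLE_FACTORS = ("polymer", "shape", "color")


def contingency_table(
    dataset_or_particles,
    row_factor: str,
    col_factor: str,
    *,
    individuals: pd.DataFrame | None = None,
    row_order: Iterable[str] | None = None,
    col_order: Iterable[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate particles by two categorical factors.

    ``species`` and ``province`` are resolved through the owning
    individual; ``polymer``/``shape``/``color`` come from the particle
    itself.  Label order is lexicographic unless an explicit order is
    given.  The grand total always equals the number of input particles.
    """
    if isinstance(dataset_or_particles, SurveyDataset):
        particles = dataset_or_particles.particles
        individuals = dataset_or_particles.individuals
    else:
        particles = dataset_or_particles

    frame = particles
    needs_join = {row_factor, col_factor} & set(_INDIVIDUAL_FACTORS)
    if needs_join:
        if individuals is None:
            raise ValueError(f"factors {sorted(needs_join)} require the individuals table")
        frame = particles.merge(
            individuals[["individual_id", "species", "province"]],
            on="individual_id",
            how="left",
            validate="many_to_one",
        )
        unresolved = frame[list(needs_join)].isna().any(axis=1)
        if unresolved.any():
            pid = frame.loc[unresolved, "particle_id"].iloc[0]
            raise ValueError(f"particle {pid!r}: cannot resolve {sorted(needs_join)} via individual")

    for factor in (row_factor, col_factor):
        if factor not in frame.columns:
            raise ValueError(f"unknown factor {factor!r}")

    table = pd.crosstab(frame[row_factor], frame[col_factor])
    rows = list(row_order) if row_order is not None else sorted(table.index)
    cols = list(col_order) if col_order is not None else sorted(table.columns)
    table = table.reindex(index=rows, columns=cols, fill_value=0)
    return ContingencyTable(tuple(map(str, rows)), tuple(map(str, cols)), table.to_numpy())
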