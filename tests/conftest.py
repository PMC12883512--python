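import io

import pandas as pd
import pytest

from mpsurvey import SurveyDataset, reference_survey


@pytest.fixture(scope="session")
def reference_ds() -> SurveyDataset:
    """The reconstructed published survey (built once per session)."""
    return reference_survey()


def make_dataset(individual_rows, particle_rows) -> SurveyDataset:
    """Build a small in-memory dataset from plain tuples."""
    individuals = pd.DataFrame(
        individual_rows,
        columns=["individual_id", "species", "province", "svl_mm", "git_weight_g"],
    )
    particles = pd.DataFrame(
        particle_rows,
        columns=["particle_id", "individual_id", "polymer", "shape", "color", "size_um"],
    )
    return SurveyDataset(individuals, particles)


@pytest.fixture
def tiny_ds() -> SurveyDataset:
    """Two individuals, one contaminated with three particles."""
    return make_dataset(
        [
            ("i1", "Hyla savignyi", "Adana", 36.5, 0.33),
            ("i2", "Hyla savignyi", "Adana", 35.0, 0.30),
        ],
        [
            ("p1", "i1", "PET", "fiber", "navy blue", 100.0),
            ("p2", "i1", "PE", "fragment", "black", 300.0),
            ("p3", "i1", "PA", "film", "red", 50.0),
        ],
    )


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
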