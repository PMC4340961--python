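import numpy as np
import pandas as pd
import pytest

from skerrydiv import (
    LandscapeParams,
    OccurrenceMatrix,
    SimulationParams,
    SpeciesTrait,
    SquareRecord,
    SurveyDataset,
    generate_survey,
)


def make_square(square_id, x, y, land=500_000.0, shore=800.0, dist=2000.0,
                width=None):
    return SquareRecord(
        square_id=square_id, x=x, y=y, land_area=land, shoreline=shore,
        dist_sea=dist, width=width if width is not None else dist + 3000.0,
    )


def make_dataset(presence: pd.DataFrame, traits=None, grid=None) -> SurveyDataset:
    """Build a SurveyDataset from a presence DataFrame with default plumbing."""
    if traits is None:
        traits = [
            SpeciesTrait(s, "specialist" if i % 2 == 0 else "generalist",
                         "NT" if i % 3 == 0 else "none")
            for i, s in enumerate(presence.columns)
        ]
    if grid is None:
        grid = [
            make_square(sq, x=1000.0 * (i + 0.5), y=500.0)
            for i, sq in enumerate(presence.index)
        ]
    return SurveyDataset(grid=grid, occ=OccurrenceMatrix(presence, traits))


@pytest.fixture
def tiny_ds() -> SurveyDataset:
    """Four squares x three species, hand-checkable."""
    presence = pd.DataFrame(
        [[1, 1, 0], [0, 1, 1], [1, 0, 0], [0, 0, 0]],
        index=["q1", "q2", "q3", "q4"],
        columns=["Common Eider", "Mallard", "Arctic Tern"],
    )
    traits = [
        SpeciesTrait("Common Eider", "specialist", "NT"),
        SpeciesTrait("Mallard", "generalist", "none"),
        SpeciesTrait("Arctic Tern", "specialist", "none"),
    ]
    return make_dataset(presence, traits)


@pytest.fixture(scope="session")
def desk_ds() -> SurveyDataset:
    """A small seeded synthetic survey shared across tests."""
    lp = LandscapeParams(n_cols=12, n_rows=8, n_islands=90)
    sp = SimulationParams()
    return generate_survey(lp, sp, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
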