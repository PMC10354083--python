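"""Shared fixtures: small synthetic worlds and packaged text fixtures."""

from pathlib import Path

import numpy as np
import pytest

import urbantol as ut
from urbantol.hexgrid import HexGrid

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def filter_fixture_path() -> Path:
    return DATA / "filter_fixture.tsv"


@pytest.fixture(scope="session")
def range_square_path() -> Path:
    return DATA / "range_square.geojson"


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared across tests.

    6,000 checklists on a 60x60 km landscape with three cities; one species
    with a positive radiance effect.  Session-scoped because generation
    plus buffer-median extraction is the slow part.
    """
    cfg = ut.SyntheticConfig(
        extent_km=(60.0, 60.0),
        n_cities=3,
        n_checklists=6000,
        seed=42,
    )
    raster = ut.make_alan_raster(cfg)
    checklists = ut.simulate_checklists(cfg, raster)
    truth = ut.SpeciesTruth("sp00", beta0=-0.3, beta_alan=0.4, theta=1.5)
    dataset = ut.simulate_species_counts(checklists, raster, truth, seed=cfg.seed)
    grid = HexGrid(5.0)
    q, r = grid.assign_cells(
        dataset["lon"].to_numpy(), dataset["lat"].to_numpy()
    )
    dataset["cell_q"] = q
    dataset["cell_r"] = r
    return {
        "config": cfg,
        "raster": raster,
        "checklists": checklists,
        "truth": truth,
        "dataset": dataset,
        "grid": grid,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
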