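"""Shared fixtures: seeded RNGs, synthetic frames, and the seed-replicated
aggregation cohorts reused across threshold-recovery and cell-cycle tests."""

from __future__ import annotations

import numpy as np
import pytest

from synclamp.experiment import generate_aggregation_cohort
from synclamp.params import PlantParams
from synclamp.plant import new_cell
from synclamp.render import render_frame

BASE_SEED = 1
N_SEEDS = 20


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_nonoverlapping_frame(rng, n_cells=5, gfp_range=(2.0, 12.0),
                              noise_level=0.5):
    """Render n non-overlapping cells; returns (frame, cells)."""
    params = PlantParams.for_strain("WT")
    cells, pts = [], []
    for i in range(n_cells):
        while True:
            x, y = rng.uniform(35.0, 220.0, 2)
            if all((x - a) ** 2 + (y - b) ** 2 > 45.0 ** 2 for a, b in pts):
                break
        pts.append((x, y))
        c = new_cell(params, rng, i)
        c.position = (float(x), float(y))
        c.gfp = float(rng.uniform(*gfp_range))
        c.volume_proxy = 1.0
        cells.append(c)
    return render_frame(cells, rng=rng, noise_level=noise_level), cells


def _cohorts(strain: str, n_cells: int):
    return [generate_aggregation_cohort(strain, n_cells,
                                        seed=BASE_SEED * 1000 + i)
            for i in range(N_SEEDS)]


@pytest.fixture(scope="session")
def wt_cohorts():
    """20 seeded WT nine-level-ramp cohorts (n=53 aggregated cells each)."""
    return _cohorts("WT", 53)


@pytest.fixture(scope="session")
def a53t_cohorts():
    """20 seeded A53T nine-level-ramp cohorts (n=64 aggregated cells each)."""
    return _cohorts("A53T", 64)
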