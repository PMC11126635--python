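"""Shared fixtures: a small virtual study and the full demo run.

BLAS threads are pinned to one before numpy loads so that results are
bit-reproducible across machines with different core counts.
"""

import os

for _var in (
    "OMP_NUM_THREADS",
    "OPENBLAS_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
from hypothesis import settings

import multisdm as m

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small virtual study for fast functional tests."""
    return m.make_demo_bundle(
        seed=7, n_species=8, size=24, n_obs=20_000, n_sites=80
    )


@pytest.fixture(scope="session")
def demo_bundle():
    """The default virtual study (30 species, 64x64, 100k records)."""
    return m.make_demo_bundle(seed=42)


@pytest.fixture(scope="session")
def demo_run(demo_bundle):
    """Reduced two-member run on the demo bundle.

    Trains a cross-entropy and a ranking-loss member (width 128, two
    blocks, 10 balanced + 20 natural epochs) and predicts the
    spring-summer (phenology) and February-November (dominance) cubes
    for each member and their ensemble.
    """
    b = demo_bundle
    days_spring = np.arange(60, 274)
    days_season = np.arange(32, 335, 3)
    out = {"bundle": b}
    cubes_spring, cubes_season = [], []
    for loss, seed in (("cel", 42), ("ndcg", 43)):
        tc = m.TrainingConfig(
            loss=loss, phase1_epochs=10, phase2_max_epochs=20, seed=seed
        )
        model, partition = m.fit_model(
            b.observations.copy(),
            b.landscape.grid,
            training=tc,
            width=128,
            n_blocks=2,
            seed=seed,
            n_val_per_taxon=0,
        )
        out[f"{loss}_model"] = model
        out[f"{loss}_partition"] = partition
        cubes_spring.append(m.predict_cube(model, b.landscape.grid, days_spring))
        cubes_season.append(m.predict_cube(model, b.landscape.grid, days_season))
    out["cel_cube_spring"] = cubes_spring[0]
    out["ens_cube_spring"] = m.ensemble_predictions(cubes_spring)
    out["ens_cube_season"] = m.ensemble_predictions(cubes_season)
    return out
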