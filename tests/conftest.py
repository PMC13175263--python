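"""Shared fixtures.

The heavy session fixtures run the scaled-down restoration study once
(dataset simulation, OSEM reconstruction, network training) and are shared
by the acceptance tests; unit tests use small throwaway objects instead.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import petrestore as pr
from petrestore import experiments, phantom

# Study conditions of the scaled-down restoration experiments: a compact
# torso grid, 42 projection angles, 2M prompts and 24^3 crops keep the full
# simulate -> reconstruct -> train -> evaluate chain tractable on one CPU
# while preserving the noise, partial-volume and Gibbs phenomenology.
SUITE_CFG = pr.ExperimentConfig(
    experiment=1,
    preset="suite",
    grid_shape=(48, 48, 28),
    voxel_size=(2.09, 2.09, 2.03),
    n_angles=42,
    total_prompts=2e6,
    crop_shape=(24, 24, 24),
    composition={"uniform": 24, "halves": 24, "hollow": 24},
    small_volume_range=(0.8, 5.0),
    large_volume_range=(5.0, 7.0),
    large_fraction=0.5,
    epochs=10,
    batch_size=4,
    master_seed=20,
)


@pytest.fixture(scope="session")
def small_grid() -> pr.VoxelGrid:
    return pr.VoxelGrid((48, 48, 24), (2.09, 2.09, 2.03))


@pytest.fixture(scope="session")
def torso(small_grid):
    return phantom.make_torso_phantom(small_grid)


@pytest.fixture(scope="session")
def exp1_result(tmp_path_factory):
    """Scaled experiment 1: simulate, reconstruct, train, evaluate held-out cases."""
    outdir = tmp_path_factory.mktemp("exp1")
    return experiments.run_experiment(SUITE_CFG, outdir=outdir)


@pytest.fixture(scope="session")
def exp1_model_path(exp1_result, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "model.npz"
    exp1_result.model.save(path)
    return path


@pytest.fixture(scope="session")
def exp2_result(exp1_model_path):
    """Scaled experiment 2: per-case PSFs drawn from N(4.5, 0.2^2) mm."""
    cfg = replace(
        SUITE_CFG,
        experiment=2,
        psf_mode="sampled",
        composition={"uniform": 3, "halves": 3, "hollow": 3},
        large_fraction=1.0,
        master_seed=21,
    )
    return experiments.run_experiment(cfg, model_path=exp1_model_path)


@pytest.fixture(scope="session")
def exp3_result(exp1_model_path):
    """Scaled experiment 3: hollow tumours > 5 ml at 0.5x and 2x prompts."""
    cfg = replace(
        SUITE_CFG,
        experiment=3,
        composition={"hollow": 5},
        large_fraction=1.0,
        master_seed=22,
    )
    return experiments.run_experiment(cfg, model_path=exp1_model_path)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
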