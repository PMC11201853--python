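"""Shared fixtures: default call/directivity models and the desk-scale
trained fields reused across rendering, reconstruction and acceptance tests.

Training fixtures are session-scoped because fitting a field, even reduced,
dominates suite runtime; every consumer treats them as read-only.
"""

import numpy as np
import pytest
from hypothesis import settings

import echofield as ef
from echofield.cli import simulate_ensemble
from echofield.field import FieldConfig
from echofield.render_train import TrainConfig, train
from echofield.spectro import SpectroConfig, make_ensemble_observations

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def call():
    return ef.make_call()


@pytest.fixture(scope="session")
def call_flat():
    # flat-envelope sweep: the clean probe for renderer-vs-simulator checks
    return ef.make_call(taper=0.0)


@pytest.fixture(scope="session")
def ertf():
    return ef.PistonErtf()


def _desk_spectro():
    # coarser range axis (hop 8) keeps desk-scale training tractable
    return SpectroConfig(overlap=1 - 8 / 64)


def make_one_sphere_scene(radius=0.015, n_points=100):
    pts = radius * ef.fibonacci_sphere(n_points)
    return ef.Scene([ef.Scatterer(p) for p in pts], name="one-sphere",
                    bounds=np.array([[-0.03] * 3, [0.03] * 3]))


DESK_FIELD = dict(hidden_widths=(64, 64), skip_at=())
DESK_TRAIN = dict(batch_size=64, lr=0.01, lr_drop=0.97, n_hemisphere=128)


@pytest.fixture(scope="session")
def trained_sphere(call, ertf):
    """One 3 cm sphere, 24 training poses at 0.3 m, reduced 2x64 field,
    20 epochs — plus 4 held-out poses simulated under the same conditions."""
    scene = make_one_sphere_scene()
    sim = ef.SimConfig(max_range=0.42)
    spect = _desk_spectro()
    poses = ef.pose_sphere(24, 0.3, (0, 0, 0), seed=5)
    ens = simulate_ensemble(scene, poses, call, ertf, sim, spect)
    params = train(
        ens,
        FieldConfig(seed=7, **DESK_FIELD),
        TrainConfig(epochs=20, seed=11, **DESK_TRAIN),
        scene_bounds=np.array([[-0.06] * 3, [0.06] * 3]),
    )
    held_poses = ef.pose_sphere(4, 0.3, (0, 0, 0), seed=99)
    held = simulate_ensemble(scene, held_poses, call, ertf, sim, spect)
    return {
        "scene": scene, "sim": sim, "spect": spect, "poses": poses,
        "ensemble": ens, "params": params, "held_poses": held_poses,
        "held": held, "true_center": np.zeros(3), "true_radius": 0.015,
    }


@pytest.fixture(scope="session")
def trained_leaf_pair(call, ertf):
    """Leaf with and without the insect cluster, trained under identical
    seeds and a joint compression reference, plus both Rs volumes."""
    from echofield import integrate_directions, query_grid
    from echofield.echosim import simulate_echo

    sim = ef.SimConfig(max_range=0.42)
    spect = _desk_spectro()
    leaf = ef.build_leaf_scene(False, n_leaf_points=200, seed=1)
    leaf_i = ef.build_leaf_scene(True, n_leaf_points=200, seed=1)
    poses = ef.pose_sphere(24, 0.3, (0, 0, 0), seed=5)
    echoes = [simulate_echo(leaf, p, call, ertf, sim) for p in poses]
    echoes += [simulate_echo(leaf_i, p, call, ertf, sim) for p in poses]
    obs = make_ensemble_observations(echoes, call, spect, sim.v_s, sim.max_range)
    n = len(poses)
    ens_a = ef.TrainingEnsemble(poses, obs[:n], call, meta={"ertf": ertf})
    ens_b = ef.TrainingEnsemble(poses, obs[n:], call, meta={"ertf": ertf})
    bounds = np.array([[-0.06, -0.06, -0.04], [0.06, 0.06, 0.05]])
    grid_bounds = np.array([[-0.05, -0.05, -0.03], [0.05, 0.05, 0.04]])
    vols = []
    for ens in (ens_a, ens_b):
        params = train(
            ens,
            FieldConfig(seed=7, **DESK_FIELD),
            TrainConfig(epochs=20, seed=11, **DESK_TRAIN),
            scene_bounds=bounds,
        )
        grid = query_grid(params, grid_bounds, 0.005, 100, seed=3)
        vols.append(integrate_directions(grid))
    return {"leaf": leaf, "leaf_insect": leaf_i, "vol_leaf": vols[0],
            "vol_insect": vols[1], "insect_center": leaf_i.insect_center}
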