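"""Shared fixtures: synthetic datasets, a trained overfit model, two-view scenes."""

from __future__ import annotations

import numpy as np
import pytest

from voxrecon.decoder import DecoderConfig
from voxrecon.encoder import EncoderConfig
from voxrecon.pipeline import ReconstructionModel, TrainConfig, train
from voxrecon.recurrence import LSTMConfig
from voxrecon.synthetic_data import (
    LightModel,
    build_dataset,
    checkerboard_box,
    make_camera_ring,
    render_view,
)
from voxrecon.voxel_io import load_multiview_dataset

# study conditions of the desk-scale overfit experiment
OVERFIT = dict(n_objects=3, n_views=5, n_v=16, image_size=64, seed=7,
               grid_n=2, hidden=16, epochs=60)


def tiny_model(latent_dim=32, grid_n=2, hidden=8, n_v=8, seed=0) -> ReconstructionModel:
    """A minimal but fully wired model for fast structural tests."""
    return ReconstructionModel(
        EncoderConfig(backbone="compact", latent_dim=latent_dim, seed=seed),
        LSTMConfig(grid_n=grid_n, hidden=hidden, kernel=3, latent_dim=latent_dim,
                   seed=seed + 1),
        DecoderConfig(channels=(hidden, 8, 8, 8, 8), grid_n=grid_n, resolution=n_v,
                      seed=seed + 2),
    )


@pytest.fixture(scope="session")
def small_dataset_root(tmp_path_factory):
    root = tmp_path_factory.mktemp("smallset")
    return build_dataset(
        OVERFIT["n_objects"], OVERFIT["n_views"], OVERFIT["n_v"], root,
        seed=OVERFIT["seed"], width=OVERFIT["image_size"], height=OVERFIT["image_size"],
    )


@pytest.fixture(scope="session")
def small_samples(small_dataset_root):
    return list(load_multiview_dataset(small_dataset_root))


@pytest.fixture(scope="session")
def overfit_result(small_samples):
    """Train the compact model to overfit the 3-shape micro-dataset."""
    model = ReconstructionModel(
        EncoderConfig(backbone="compact", latent_dim=1024, seed=0),
        LSTMConfig(grid_n=OVERFIT["grid_n"], hidden=OVERFIT["hidden"], kernel=3,
                   latent_dim=1024, seed=1),
        DecoderConfig(channels=(OVERFIT["hidden"], 32, 16, 8, 8),
                      grid_n=OVERFIT["grid_n"], resolution=OVERFIT["n_v"], seed=2),
    )
    history = train(small_samples, model, TrainConfig(epochs=OVERFIT["epochs"], seed=0))
    return model, history


@pytest.fixture(scope="session")
def teethnet_root(tmp_path_factory):
    root = tmp_path_factory.mktemp("teethnet")
    return build_dataset(0, 0, 32, root, seed=3, preset="teethnet")


@pytest.fixture(scope="session")
def two_view_scene():
    """Two rendered views of a checker-textured box with known relative pose."""
    mesh, albedo = checkerboard_box(subdiv=10, seed=1)
    cams = make_camera_ring(36, radius=3.0, elevation_deg=25.0, width=256, height=256)
    cam_a, cam_b = cams[0], cams[1]  # 10 degrees apart in azimuth
    light = LightModel(ambient=0.6)
    img_a = render_view(mesh, cam_a, light, face_albedo=albedo)
    img_b = render_view(mesh, cam_b, light, face_albedo=albedo)
    r_rel = cam_b.R @ cam_a.R.T
    t_rel = cam_b.t - r_rel @ cam_a.t
    t_rel = t_rel / np.linalg.norm(t_rel)
    return dict(img_a=img_a, img_b=img_b, K=cam_a.K, R=r_rel, t=t_rel)
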