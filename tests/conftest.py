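"""Shared fixtures: small simulated scenes and hand-built point scenes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from periplaque import PixelCalibration, SceneConfig, sample_scene
from periplaque.simulate import OpticsNoiseModel, SceneGroundTruth
from periplaque.spatial import AxonTrace


NOISELESS = OpticsNoiseModel(poisson_scale=0.0, read_noise_sd=0.0)


def make_point_scene(
    xy_um: np.ndarray,
    field_um: tuple[float, float] = (100.0, 100.0),
    pixel_um: float = 0.2,
    plaque_polygons: list | None = None,
    dystrophy_xy_um: np.ndarray | None = None,
    dystrophy_diameter_um: float = 3.0,
    seed: int = 0,
) -> SceneGroundTruth:
    """A scene with explicitly placed boutons (all kept, all unpaired)."""
    xy = np.atleast_2d(np.asarray(xy_um, dtype=float))
    boutons = pd.DataFrame(
        {
            "bouton_id": np.arange(len(xy)),
            "axon_id": 0,
            "arc_um": np.zeros(len(xy)),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "dist_plaque_um": np.inf,
            "kept": True,
            "paired_post": False,
        }
    )
    polys = plaque_polygons or []
    plaques = pd.DataFrame(
        {
            "plaque_id": np.arange(len(polys)),
            "area_um2": [p.area for p in polys],
            "centroid_x_um": [p.centroid.x for p in polys],
            "centroid_y_um": [p.centroid.y for p in polys],
        }
    )
    if dystrophy_xy_um is None:
        dys = pd.DataFrame(
            columns=["dystrophy_id", "axon_id", "x_um", "y_um", "diameter_um", "plaque_id"]
        )
    else:
        dxy = np.atleast_2d(dystrophy_xy_um)
        dys = pd.DataFrame(
            {
                "dystrophy_id": np.arange(len(dxy)),
                "axon_id": 0,
                "x_um": dxy[:, 0],
                "y_um": dxy[:, 1],
                "diameter_um": dystrophy_diameter_um,
                "plaque_id": 0,
            }
        )
    # a dummy axon along the bottom edge keeps the trace list non-empty
    axon = AxonTrace(axon_id=0, vertices_um=np.array([[1.0, 1.0], [field_um[0] - 1, 1.0]]))
    cfg = SceneConfig(
        field_size_um=field_um,
        pixel_size_um=pixel_um,
        n_plaques=0,
        n_axons=1,
        dystrophy_prob_per_plaque_axon=0.0,
        seed=seed,
    )
    return SceneGroundTruth(
        plaques=plaques,
        plaque_polygons=polys,
        axons=[axon],
        boutons=boutons,
        dystrophies=dys,
        config=cfg,
        seed_used=seed,
    )


def disk(cx: float, cy: float, r: float, n: int = 256):
    return Point(cx, cy).buffer(r, quad_segs=n // 4)


@pytest.fixture(scope="session")
def small_null_scene() -> SceneGroundTruth:
    """100x100 um scene, 2 plaques, 10 axons, no depletion, no dystrophies."""
    cfg = SceneConfig(
        field_size_um=(100.0, 100.0),
        n_plaques=2,
        plaque_radius_um=(5.0, 0.2),
        n_axons=10,
        depletion_prob_inside=0.0,
        depletion_prob_ring=0.0,
        dystrophy_prob_per_plaque_axon=0.0,
        seed=2,
    )
    return sample_scene(cfg)


@pytest.fixture()
def calib_02() -> PixelCalibration:
    return PixelCalibration(um_per_px_x=0.2, um_per_px_y=0.2, width_px=500, height_px=500)
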