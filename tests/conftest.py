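"""Shared fixtures: synthetic scenes and solved fields reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from ptcmorph.io_config import RunConfig
from ptcmorph.morphometry import measure_mask
from ptcmorph.segmentation import segment
from ptcmorph.synthdata import make_scene_2d


def rasterize_disk(radius_px: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius_px + 2 * pad
    yy, xx = np.mgrid[:n, :n] - n // 2
    return (yy**2 + xx**2) <= radius_px**2


def rasterize_ellipse(a_px: float, b_px: float, pad: int = 3) -> np.ndarray:
    n = int(2 * a_px) + 2 * pad
    yy, xx = np.mgrid[:n, :n] - n // 2
    return (xx / a_px) ** 2 + (yy / b_px) ** 2 <= 1.0


@pytest.fixture(scope="session")
def scenes_200():
    """One control-like and one injury-like 200-capillary scene (seed 1)."""
    return {
        cond: make_scene_2d(200, cond, seed=1)
        for cond in ("control_like", "injury_like")
    }


@pytest.fixture(scope="session")
def measured_200(scenes_200):
    """Pipeline measurements (segment + morphometry) of the 200-shape scenes."""
    out = {}
    for cond, scene in scenes_200.items():
        cfg = RunConfig(pixel_size=scene.image.pixel_size)
        mask = segment(scene.image, cfg)
        out[cond] = measure_mask(mask, size_min=cfg.size_min,
                                 size_max=cfg.size_max)
    return out
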