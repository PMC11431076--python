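"""Shared fixtures: a small synthetic scene with precomputed hexification.

The scene geometry (rasters, grid, per-hexagon areas, ranks) is expensive
relative to point generation, so session-scoped fixtures compute it once;
multi-seed tests then redraw only the CD8+ point pattern and recount.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from immunohex import (
    Cd8ProfileParams,
    RankingParams,
    SceneParams,
    build_grid,
    generate_cd8_points,
    generate_scene,
    rank_compartments,
)
from immunohex.hexgrid import count_cells, rasterize_areas

SMALL_SCENE = SceneParams(
    domain_width_um=2400.0,
    domain_height_um=2400.0,
    um_per_pixel=2.0,
    tumor_radius_um=600.0,
    tumor_boundary_roughness=0.1,
    stroma_band_um=350.0,
    seed=11,
)

DISC_SCENE = SceneParams(
    domain_width_um=2400.0,
    domain_height_um=2400.0,
    um_per_pixel=2.0,
    tumor_radius_um=600.0,
    tumor_boundary_roughness=0.0,
    stroma_band_um=350.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SMALL_SCENE)


@pytest.fixture(scope="session")
def disc_scene():
    return generate_scene(DISC_SCENE)


@pytest.fixture(scope="session")
def small_grid(small_scene):
    return build_grid(small_scene.bbox_um)


@pytest.fixture(scope="session")
def small_areas(small_scene, small_grid):
    return rasterize_areas(small_scene, small_grid)


@pytest.fixture(scope="session")
def small_ranked(small_areas):
    """Ranked hexagon skeleton (areas + labels + ranks, no counts)."""
    return rank_compartments(small_areas, RankingParams())


@pytest.fixture(scope="session")
def ranked_with_cells(small_scene, small_grid, small_ranked):
    """Factory: attach a fresh CD8+ draw (by profile params) to the ranked table."""

    def _make(profile: Cd8ProfileParams) -> pd.DataFrame:
        cells = generate_cd8_points(small_scene, profile)
        return count_cells(small_grid, cells, small_ranked)

    return _make


def toy_aggs(rows):
    """Build a minimal aggregate table from (q, r, epi, stroma, bg, compartment)."""
    df = pd.DataFrame(rows, columns=["q", "r", "epithelium_area_um2",
                                     "stroma_area_um2", "background_area_um2",
                                     "compartment"])
    df["cd8_count"] = 0
    df["other_count"] = 0
    df["center_x_um"] = 0.0
    df["center_y_um"] = 0.0
    return df
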