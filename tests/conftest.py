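"""Shared fixtures: synthetic spectra, bilayer frames, and the Voronoi oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

import lipidorder as lo


@pytest.fixture
def liposome_spectrum():
    """Noiseless liposome-like spectrum with S_b = 0.225 plus its truth."""
    cfg = lo.SpectrumGeneratorConfig(target_s_b=0.225, noise_sigma_frac=0.0)
    return lo.generate_spectrum(cfg)


@pytest.fixture
def noisy_spectrum():
    """SNR-50 spectrum at S_b = 0.5, fixed seed."""
    cfg = lo.SpectrumGeneratorConfig(target_s_b=0.5, noise_sigma_frac=0.02, seed=11)
    return lo.generate_spectrum(cfg)


def monolayer_frame(heads2: np.ndarray, box: np.ndarray) -> lo.BilayerFrame:
    """A frame whose upper leaflet holds ``heads2`` (lower is a mirror copy)."""
    n = len(heads2)
    heads = np.vstack(
        [
            np.column_stack([heads2, np.full(n, 0.75 * box[2])]),
            np.column_stack([heads2, np.full(n, 0.25 * box[2])]),
        ]
    )
    return lo.BilayerFrame(
        box=box,
        lipid_ids=np.arange(2 * n),
        heads=heads,
        carbonyls=np.repeat(heads[:, None, :], 4, axis=1),
    )


def periodic_voronoi_areas(points2: np.ndarray, box2: np.ndarray) -> np.ndarray:
    """Exact per-point Voronoi cell areas under 2D periodic boundaries.

    Independent oracle: the points are tiled 3x3, scipy computes the plane
    Voronoi diagram, and the central copies' polygons are measured with
    shapely.  Areas sum to the box area.
    """
    n = len(points2)
    shifts = np.array(
        [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float
    ) * box2
    tiled = np.concatenate([points2 + s for s in shifts])
    vor = Voronoi(tiled)
    k0 = [tuple(s) for s in shifts].index((0.0, 0.0)) * n
    areas = np.empty(n)
    for k in range(n):
        region = vor.regions[vor.point_region[k0 + k]]
        assert -1 not in region, "unbounded central Voronoi cell; tiling too small"
        areas[k] = Polygon(vor.vertices[region]).area
    return areas


def voronoi_perimeters(points2: np.ndarray, box2: np.ndarray) -> np.ndarray:
    """Perimeters of the periodic Voronoi cells (for discretization bounds)."""
    n = len(points2)
    shifts = np.array(
        [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float
    ) * box2
    tiled = np.concatenate([points2 + s for s in shifts])
    vor = Voronoi(tiled)
    k0 = [tuple(s) for s in shifts].index((0.0, 0.0)) * n
    return np.array(
        [
            Polygon(vor.vertices[vor.regions[vor.point_region[k0 + k]]]).length
            for k in range(n)
        ]
    )
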