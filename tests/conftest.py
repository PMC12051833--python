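"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check:
polygon areas come from the shoelace formula or Monte-Carlo rejection
sampling, and point-to-boundary distances from direct point-segment
arithmetic in numpy.
"""

import numpy as np
import pytest
import shapely

from cpindex import LesionShapeSpec, make_lesion
from cpindex.geometry import LesionGeometry


def shoelace_area(coords) -> float:
    """Polygon area by the shoelace formula (exterior ring, no holes)."""
    c = np.asarray(coords, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def monte_carlo_area(region, n=100_000, seed=0):
    """Rejection-sampling area estimate over the bounding box.

    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    box_area = (maxx - minx) * (maxy - miny)
    x = rng.uniform(minx, maxx, n)
    y = rng.uniform(miny, maxy, n)
    p = shapely.contains_xy(region, x, y).mean()
    est = p * box_area
    se = box_area * np.sqrt(p * (1 - p) / n)
    return est, se


def segment_distances(points, ring):
    """Min distance from each point to a closed ring of vertices (pure numpy)."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(ring, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    a = v
    b = np.roll(v, -1, axis=0)
    ab = b - a  # (m, 2)
    ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    denom = (ab**2).sum(axis=1)  # (m,)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return d.min(axis=1)


@pytest.fixture(scope="session")
def disk_lesion():
    """Disk lesion (R = 500 µm, 64 vertices) with its tissue and geometry."""
    shape = LesionShapeSpec(kind="disk", radius=500.0, n_vertices=64, seed=0)
    lesion, tissue = make_lesion(shape)
    lg = LesionGeometry.build(lesion.geometry, tissue.geometry, name="disk")
    return shape, lesion, tissue, lg
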