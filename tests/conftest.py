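"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from disconn import VolumeMap, VoxelGrid, make_grid
from disconn.core_geometry import KIND_DENSITY


@pytest.fixture
def grid16() -> VoxelGrid:
    """Small symmetric grid: 16^3, 2 mm isotropic, origin-centred."""
    return make_grid((16, 16, 16), 2.0)


@pytest.fixture
def grid_default() -> VoxelGrid:
    return make_grid()


def vmap(values, grid, kind=KIND_DENSITY) -> VolumeMap:
    return VolumeMap(np.asarray(values, dtype=float), grid, kind)


# ---------------------------------------------------------------------------
# traversal oracles (independent of the crossing-midpoint implementation)
# ---------------------------------------------------------------------------

def sampling_visited(points: np.ndarray, grid: VoxelGrid,
                     step_factor: float = 0.01) -> set[tuple[int, int, int]]:
    """Dense point-sampling oracle at step ``step_factor * min(voxel_size)``.

    One-sided: it can only miss voxels whose chord inside the cell is
    shorter than the sampling step (corner clips).
    """
    step = step_factor * float(min(grid.voxel_size))
    cells: set[tuple[int, int, int]] = set()
    dims = np.asarray(grid.dims)
    for a, b in zip(points[:-1], points[1:]):
        length = float(np.linalg.norm(b - a))
        n = max(2, int(np.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n)
        u = grid.world_to_voxel(a + t[:, None] * (b - a)) + 0.5
        c = np.floor(u).astype(int)
        ok = np.all((c >= 0) & (c < dims), axis=1)
        cells.update(map(tuple, c[ok].tolist()))
    return cells


def boxclip_visited(points: np.ndarray, grid: VoxelGrid) -> set[tuple[int, int, int]]:
    """Exact segment-box oracle: Liang-Barsky interval clipping per voxel.

    For every voxel in each segment's bounding box, the segment's t-interval
    inside the (half-open) cell is computed from first principles; the cell
    is visited iff the interval is non-degenerate (or degenerate but landing
    in the cell under the larger-index tie rule).
    """
    pts = np.asarray(points, dtype=float)
    u = grid.world_to_voxel(pts) + 0.5
    dims = np.asarray(grid.dims)
    cells: set[tuple[int, int, int]] = set()
    for a, b in zip(u[:-1], u[1:]):
        d = b - a
        lo = np.maximum(np.floor(np.minimum(a, b)).astype(int), 0)
        hi = np.minimum(np.floor(np.maximum(a, b)).astype(int), dims - 1)
        if np.any(lo > hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)),
                                 indexing="ij")
        c = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        t0 = np.zeros(len(c))
        t1 = np.ones(len(c))
        ok = np.ones(len(c), dtype=bool)
        for ax in range(3):
            if d[ax] == 0.0:
                ok &= (c[:, ax] <= a[ax]) & (a[ax] < c[:, ax] + 1)
            else:
                ta = (c[:, ax] - a[ax]) / d[ax]
                tb = (c[:, ax] + 1 - a[ax]) / d[ax]
                lo_t, hi_t = np.minimum(ta, tb), np.maximum(ta, tb)
                t0 = np.maximum(t0, lo_t)
                t1 = np.minimum(t1, hi_t)
        hit = ok & (t1 > t0)
        touch = ok & (t1 == t0)
        if np.any(touch):
            p = a[None, :] + t0[touch, None] * d[None, :]
            hit[np.flatnonzero(touch)[np.all(np.floor(p) == c[touch], axis=1)]] = True
        cells.update(map(tuple, c[hit].astype(int).tolist()))
    return cells


def random_polylines(rng: np.random.Generator, grid: VoxelGrid, n: int,
                     margin_mm: float = 10.0) -> list[np.ndarray]:
    """Random polylines spanning the grid (and a bit beyond, to hit clipping)."""
    lo = grid.voxel_to_world(np.array([[-0.5, -0.5, -0.5]]))[0] - margin_mm
    hi = grid.voxel_to_world(np.array([[d - 0.5 for d in grid.dims]]))[0] + margin_mm
    out = []
    for _ in range(n):
        k = int(rng.integers(2, 8))
        out.append(rng.uniform(lo, hi, size=(k, 3)))
    return out
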