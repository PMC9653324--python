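"""Shared data model, geometry, traversal and file I/O.

Conventions
-----------
* World coordinates are millimetres (RAS+ for on-disk formats).
* Voxel indices are 0-based.  Voxel ``i`` spans the half-open interval
  ``[i - 0.5, i + 0.5)`` in continuous voxel coordinates, i.e. the voxel
  centre sits at the integer index.  A point exactly on a shared face
  belongs to the voxel with the larger index.
* Streamlines are kept in world mm internally.  The TRK voxel-mm on-disk
  convention is converted at load time (nibabel does this for us).
* Streamline portions outside the grid are silently clipped during
  traversal (logged at debug level), never an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: lesion roles
ROLE_T = "T"
ROLE_T_PLUS_O = "T+O"
ROLES = (ROLE_T, ROLE_T_PLUS_O)

#: hemisphere labels for the tumour core
SIDE_LEFT = "left"
SIDE_RIGHT = "right"
SIDE_BILATERAL = "bilateral"
SIDES = (SIDE_LEFT, SIDE_RIGHT, SIDE_BILATERAL)

#: volume-map kinds
KIND_DENSITY = "density"
KIND_SD_DIRECT = "sd_direct"
KIND_SD_INDIRECT = "sd_indirect"
KIND_BINARY = "binary"
KINDS = (KIND_DENSITY, KIND_SD_DIRECT, KIND_SD_INDIRECT, KIND_BINARY)


class GridMismatchError(ValueError):
    """Two objects that must live on the same voxel grid do not."""


class TractogramFormatError(IOError):
    """A streamline file could not be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class VoxelGrid:
    """Geometry of a 3D volume.

    Parameters
    ----------
    dims
        Number of voxels along each axis (all >= 1).
    affine
        4x4 voxel-to-world map (must be invertible).  ``affine @ (i,j,k,1)``
        is the world position of the centre of voxel ``(i,j,k)`` in mm.
    lr_axis
        Index of the voxel axis running left-right.
    midplane
        Continuous voxel coordinate of the midsagittal plane on ``lr_axis``.
        Defaults to the grid centre ``(dims[lr_axis] - 1) / 2``.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray
    lr_axis: int = 0
    midplane: float | None = None

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {dims}")
        aff = np.array(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if not 0 <= int(self.lr_axis) <= 2:
            raise ValueError("lr_axis must be 0, 1 or 2")
        aff.setflags(write=False)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "lr_axis", int(self.lr_axis))
        mid = self.midplane
        if mid is None:
            mid = (dims[self.lr_axis] - 1) / 2.0
        object.__setattr__(self, "midplane", float(mid))
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must all be > 0")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (product of voxel sizes / 1000)."""
        return float(np.prod(self.voxel_size) / 1000.0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel coordinates."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points, dtype=float)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel coordinates (N, 3) to world mm."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_as(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.affine, other.affine, atol=tol)
            and self.lr_axis == other.lr_axis
            and abs(self.midplane - other.midplane) <= tol
        )


def check_same_grid(a: VoxelGrid, b: VoxelGrid, what: str = "objects") -> None:
    if not a.same_as(b):
        raise GridMismatchError(f"{what} do not share a voxel grid")


#: a Streamline is an (n >= 2, 3) float array of world-mm points
Streamline = np.ndarray


@dataclass
class Tractogram:
    """Ordered collection of streamlines (world-mm polylines) tied to a grid."""

    streamlines: list[Streamline]
    grid: VoxelGrid
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        sls = []
        for i, s in enumerate(self.streamlines):
            a = np.asarray(s, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) array")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            sls.append(a)
        self.streamlines = sls

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def subset(self, indices: Sequence[int]) -> "Tractogram":
        """New tractogram containing the given streamlines, order preserved."""
        return Tractogram([self.streamlines[i] for i in indices], self.grid,
                          self.space_tag)


@dataclass
class LesionMask:
    """Binary lesion volume with role (T or T+O) and hemisphere label."""

    voxels: np.ndarray
    grid: VoxelGrid
    role: str
    side: str

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.shape != self.grid.dims:
            raise ValueError("lesion mask shape does not match grid dims")
        self.voxels = v.astype(bool)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def volume_cm3(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_cm3


def check_nested(t: LesionMask, t_plus_o: LesionMask) -> None:
    """Raise if the T mask is not a subset of the T+O mask."""
    check_same_grid(t.grid, t_plus_o.grid, "lesion masks")
    if np.any(t.voxels & ~t_plus_o.voxels):
        raise ValueError("T mask is not contained in the T+O mask")


@dataclass
class VolumeMap:
    """Real-valued volume on a grid (density, SD map or binary mask)."""

    values: np.ndarray
    grid: VoxelGrid
    kind: str = KIND_DENSITY

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.dims:
            raise ValueError("volume shape does not match grid dims")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == KIND_BINARY:
            if not np.all((v == 0) | (v == 1)):
                raise ValueError("binary map values must be 0 or 1")
        elif np.any(v < 0):
            raise ValueError(f"{self.kind} map values must be >= 0")
        self.values = v

    @property
    def mask(self) -> np.ndarray:
        """Boolean support of the map."""
        return self.values > 0

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "VolumeMap":
        return VolumeMap(values, self.grid, kind or self.kind)


# ---------------------------------------------------------------------------
# streamline - voxel traversal
# ---------------------------------------------------------------------------
#
# Exact segment-grid traversal: for every polyline segment we collect the
# parameters t where the segment crosses an integer plane of the (shifted)
# voxel lattice, then identify the cell of each inter-crossing interval by
# its midpoint.  This is equivalent to an Amanatides-Woo walk but fully
# vectorised over all segments of a tractogram, and sampling-independent.
# The half-open cell convention [i, i+1) in shifted coordinates (= voxel
# centre at the integer in unshifted coordinates) makes boundary ties land
# in the larger-index voxel via floor().


def _crossing_params(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment parameters t in [0, 1] at which cells can change.

    A, B : (M, 3) segment endpoints in *shifted* voxel coordinates
    (cell ``i`` spans ``[i, i+1)``).  Returns (segment index, t) including
    the endpoints t=0 and t=1 of every segment.
    """
    M = len(A)
    d = B - A
    segs = [np.arange(M), np.arange(M)]
    ts = [np.zeros(M), np.ones(M)]
    c0 = np.floor(A).astype(np.int64)
    c1 = np.floor(B).astype(np.int64)
    for ax in range(3):
        delta = c1[:, ax] - c0[:, ax]
        m = np.abs(delta)
        total = int(m.sum())
        if total == 0:
            continue
        seg = np.repeat(np.arange(M), m)
        # 1-based crossing counter within each segment
        j = np.arange(total) - np.repeat(np.cumsum(m) - m, m) + 1
        step = np.sign(delta)[seg]
        plane = np.where(step > 0, c0[seg, ax] + j, c0[seg, ax] - j + 1)
        t = (plane - A[seg, ax]) / d[seg, ax]
        segs.append(seg)
        ts.append(t)
    seg_all = np.concatenate(segs)
    t_all = np.clip(np.concatenate(ts), 0.0, 1.0)
    return seg_all, t_all


def _segment_cells(A: np.ndarray, B: np.ndarray,
                   dims: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Exact in-bounds cells intersected by each segment.

    Returns ``(segment_index, cells)`` where ``cells`` is (K, 3) int64 in
    shifted-lattice indices (identical to voxel indices).  Cells may repeat
    within a segment only at degenerate (zero-length) intervals.
    """
    if len(A) == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, 3), dtype=np.int64)
    d = B - A
    seg_all, t_all = _crossing_params(A, B)
    order = np.lexsort((t_all, seg_all))
    seg_s = seg_all[order]
    t_s = t_all[order]
    same = seg_s[:-1] == seg_s[1:]
    sm = seg_s[:-1][same]
    tm = 0.5 * (t_s[:-1][same] + t_s[1:][same])
    P = A[sm] + tm[:, None] * d[sm]
    cells = np.floor(P).astype(np.int64)
    inb = np.all((cells >= 0) & (cells < np.asarray(dims)), axis=1)
    if not np.all(inb):
        log.debug("clipped %d out-of-grid cell intervals", int((~inb).sum()))
    return sm[inb], cells[inb]


def polyline_cells(points: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Unique voxel indices (K, 3) intersected by one polyline, unordered."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    u = grid.world_to_voxel(pts) + 0.5
    _, cells = _segment_cells(u[:-1], u[1:], grid.dims)
    return np.unique(cells, axis=0)


def voxels_visited(streamline: Streamline, grid: VoxelGrid) -> set[tuple[int, int, int]]:
    """Every voxel whose cell is intersected by any segment of the streamline.

    Out-of-grid portions contribute nothing.  Each voxel appears once no
    matter how many segments cross it.
    """
    cells = polyline_cells(streamline, grid)
    return {tuple(c) for c in cells.tolist()}


def tractogram_cells(t: Tractogram) -> tuple[np.ndarray, np.ndarray]:
    """Distinct (streamline id, flat voxel code) pairs of a whole tractogram.

    The flat code is ``np.ravel_multi_index`` over ``t.grid.dims``.  Each
    streamline contributes a voxel at most once (re-entrant streamlines
    included), so the result directly supports track-density counting and
    lesion-overlap selection.
    """
    grid = t.grid
    if len(t) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pts = np.concatenate(t.streamlines)
    u = grid.world_to_voxel(pts) + 0.5
    lens = np.array([len(s) for s in t.streamlines], dtype=np.int64)
    ends = np.cumsum(lens)
    keep = np.ones(len(pts), dtype=bool)
    keep[ends - 1] = False                      # drop inter-streamline joins
    seg_start = np.flatnonzero(keep)
    sid_of_seg = np.repeat(np.arange(len(t), dtype=np.int64), lens - 1)
    seg_idx, cells = _segment_cells(u[seg_start], u[seg_start + 1], grid.dims)
    if len(seg_idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    sid = sid_of_seg[seg_idx]
    codes = np.ravel_multi_index((cells[:, 0], cells[:, 1], cells[:, 2]), grid.dims)
    pair = sid * np.int64(grid.n_voxels) + codes
    uniq = np.unique(pair)
    return uniq // grid.n_voxels, uniq % grid.n_voxels


# ---------------------------------------------------------------------------
# resampling and ROI exclusion
# ---------------------------------------------------------------------------

def resample_mask(obj: "LesionMask | VolumeMap", target: VoxelGrid,
                  transform: np.ndarray | None = None):
    """Resample a mask or map onto a target grid.

    ``transform`` is a 4x4 world-to-world affine mapping the object's world
    frame into the target's world frame (identity when omitted).  Binary
    data are resampled nearest-neighbour, continuous maps trilinearly.
    An identity transform between identical grids returns the input
    unchanged.
    """
    tr = np.eye(4) if transform is None else np.asarray(transform, dtype=float)
    if tr.shape != (4, 4) or abs(np.linalg.det(tr)) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 affine")
    source = obj.grid
    if np.allclose(tr, np.eye(4)) and source.same_as(target):
        return obj
    # output voxel -> output world -> input world -> input voxel
    full = np.linalg.inv(source.affine) @ np.linalg.inv(tr) @ target.affine
    binary = isinstance(obj, LesionMask) or obj.kind == KIND_BINARY
    data = obj.voxels.astype(np.float32) if isinstance(obj, LesionMask) else obj.values
    out = ndimage.affine_transform(
        np.asarray(data, dtype=float), full[:3, :3], offset=full[:3, 3],
        output_shape=target.dims, order=0 if binary else 1, mode="constant", cval=0.0,
    )
    if isinstance(obj, LesionMask):
        return LesionMask(out > 0.5, target, obj.role, obj.side)
    if binary:
        out = (out > 0.5).astype(float)
    return VolumeMap(out, target, obj.kind)


def exclude_rois(vmap: VolumeMap, rois: Iterable) -> VolumeMap:
    """Zero a map inside each ROI (subcortical exclusion); idempotent.

    ``rois`` may contain LesionMask, binary VolumeMap or plain boolean
    arrays on the same grid.
    """
    out = vmap.values.copy()
    for roi in rois:
        if isinstance(roi, LesionMask):
            check_same_grid(vmap.grid, roi.grid, "map and ROI")
            m = roi.voxels
        elif isinstance(roi, VolumeMap):
            check_same_grid(vmap.grid, roi.grid, "map and ROI")
            m = roi.mask
        else:
            m = np.asarray(roi).astype(bool)
            if m.shape != vmap.grid.dims:
                raise GridMismatchError("ROI array shape does not match grid")
        out[m] = 0.0
    return vmap.copy_with(out)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_tractogram(path: str | Path, grid: VoxelGrid,
                    space_tag: str = "subject") -> Tractogram:
    """Load a TCK or TRK file; streamlines come back in world mm (RAS+)."""
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise TractogramFormatError(f"cannot read tractogram {path}: {exc}") from exc
    sls = [np.asarray(s, dtype=float) for s in tf.streamlines]
    return Tractogram(sls, grid, space_tag)


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    """Write TCK or TRK (chosen by extension); coordinates stored as RAS mm."""
    path = str(path)
    tg = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in t.streamlines], affine_to_rasmm=np.eye(4))
    if path.endswith(".trk"):
        header = {
            "voxel_to_rasmm": t.grid.affine.astype(np.float32),
            "voxel_sizes": t.grid.voxel_size.astype(np.float32),
            "dimensions": np.asarray(t.grid.dims, dtype=np.int16),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(tg, path, header=header)
    else:
        nib.streamlines.save(tg, path)


def grid_from_nifti(img: nib.Nifti1Image, lr_axis: int = 0,
                    midplane: float | None = None) -> VoxelGrid:
    return VoxelGrid(tuple(img.shape[:3]), np.asarray(img.affine),
                     lr_axis=lr_axis, midplane=midplane)


def read_volume(path: str | Path, kind: str = KIND_DENSITY,
                grid: VoxelGrid | None = None) -> VolumeMap:
    img = nib.load(str(path))
    g = grid if grid is not None else grid_from_nifti(img)
    return VolumeMap(np.asarray(img.get_fdata(), dtype=float), g, kind)


def write_volume(vmap: VolumeMap, path: str | Path) -> None:
    """Maps are written as 32-bit float NIfTI with the grid's affine."""
    img = nib.Nifti1Image(vmap.values.astype(np.float32),
                          np.asarray(vmap.grid.affine))
    nib.save(img, str(path))


def read_lesion(path: str | Path, role: str, side: str,
                grid: VoxelGrid | None = None) -> LesionMask:
    img = nib.load(str(path))
    g = grid if grid is not None else grid_from_nifti(img)
    return LesionMask(np.asarray(img.get_fdata()) > 0.5, g, role, side)


def write_lesion(mask: LesionMask, path: str | Path) -> None:
    """Masks are written as 8-bit unsigned NIfTI."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          np.asarray(mask.grid.affine))
    nib.save(img, str(path))
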