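"""Synthetic tractogram / lesion phantoms with exported ground truth.

A phantom cohort emulates the data regime the pipeline consumes: bundles
of coherent streamlines on a shared symmetric grid, nested ellipsoidal
lesions (tumour core T inside core+oedema T+O) with a left/right/
bilateral label, a population of intact control tractograms built from
the same bundle anatomy with per-subject jitter, and optional radial
mass-displacement of patient fibres around the tumour core.  Everything
is deterministic given a seed; the ground-truth disconnected-voxel mask
of a patient is the union of visited voxels of the bundles that
intersect the lesion, with the lesion itself excluded.

The default geometry is a 48^3 grid of 2 mm isotropic voxels with 3-6
bundles of 200-1000 streamlines each and 10 controls: small enough that
the full pipeline runs in seconds, large enough that density maps and
majority votes behave like the real quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core_geometry import (
    ROLE_T,
    ROLE_T_PLUS_O,
    SIDE_BILATERAL,
    SIDE_LEFT,
    SIDE_RIGHT,
    LesionMask,
    Tractogram,
    VoxelGrid,
    tractogram_cells,
)

DEFAULT_DIMS = (48, 48, 48)
DEFAULT_VOXEL_MM = 2.0
DEFAULT_N_CONTROLS = 10


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of one streamline bundle (world mm)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    n_streamlines: int = 400
    spread_mm: float = 3.0          # lateral Gaussian offset of streamlines
    curvature_mm: float = 0.0       # sagittal bow of the centerline
    n_points: int = 60


@dataclass(frozen=True)
class PhantomSpec:
    """One patient phantom: grid, bundles, tumour and displacement."""

    bundles: tuple[BundleSpec, ...]
    tumour_center: tuple[float, float, float]
    t_radii: tuple[float, float, float]
    to_radii: tuple[float, float, float]
    grid_dims: tuple[int, int, int] = DEFAULT_DIMS
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    displacement_magnitude: float = 0.0
    displacement_radius: float = 0.0
    jitter_mm: float = 1.5          # per-subject endpoint jitter
    n_controls: int = DEFAULT_N_CONTROLS
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t > o for t, o in zip(self.t_radii, self.to_radii)):
            raise ValueError("T radii must be <= T+O radii componentwise")


@dataclass
class Patient:
    pid: str
    tractogram: Tractogram
    bundles: list[Tractogram]
    lesions: dict[str, LesionMask]           # role -> mask
    side: str
    ground_truth: dict[str, np.ndarray]      # role -> boolean volume
    spec: PhantomSpec


@dataclass
class Cohort:
    grid: VoxelGrid
    patients: list[Patient]
    controls: list[Tractogram]
    seed: int


def make_grid(dims: tuple[int, int, int] = DEFAULT_DIMS,
              voxel_size: float = DEFAULT_VOXEL_MM, lr_axis: int = 0) -> VoxelGrid:
    """Symmetric grid centred on the world origin (RAS-like, lr along x)."""
    dims = tuple(int(d) for d in dims)
    aff = np.eye(4)
    for ax in range(3):
        aff[ax, ax] = voxel_size
        aff[ax, 3] = -voxel_size * (dims[ax] - 1) / 2.0
    return VoxelGrid(dims, aff, lr_axis=lr_axis)


def _world_bounds(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    corners = grid.voxel_to_world(np.array(
        [[i, j, k] for i in (-0.5, grid.dims[0] - 0.5)
         for j in (-0.5, grid.dims[1] - 0.5)
         for k in (-0.5, grid.dims[2] - 0.5)]))
    return corners.min(axis=0), corners.max(axis=0)


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(d)))] = 1.0
    p1 = np.cross(d, helper)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d, p1)
    return p1, p2


def make_bundle(spec: BundleSpec, grid: VoxelGrid,
                rng: np.random.Generator) -> Tractogram:
    """Smooth polylines around the bundle centerline with Gaussian offsets.

    With ``spread_mm == 0`` every streamline equals the centerline.
    Deterministic given the generator state.
    """
    if spec.spread_mm < 0:
        raise ValueError("spread must be >= 0")
    if spec.n_streamlines < 1:
        raise ValueError("need at least one streamline")
    start = np.asarray(spec.start, dtype=float)
    end = np.asarray(spec.end, dtype=float)
    lo, hi = _world_bounds(grid)
    for p in (start, end):
        if np.any(p < lo) or np.any(p >= hi):
            raise ValueError(f"bundle endpoint {p} lies outside the grid")
    tpar = np.linspace(0.0, 1.0, spec.n_points)
    p1, p2 = _perp_basis(end - start)
    centerline = (start[None, :] + tpar[:, None] * (end - start)[None, :]
                  + spec.curvature_mm * np.sin(np.pi * tpar)[:, None] * p1[None, :])
    offsets = rng.normal(size=(spec.n_streamlines, 2)) * spec.spread_mm
    sls = [centerline + offsets[i, 0] * p1 + offsets[i, 1] * p2
           for i in range(spec.n_streamlines)]
    return Tractogram(sls, grid)


def _ellipsoid(grid: VoxelGrid, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    idx = np.indices(grid.dims, dtype=float)
    pts = np.stack([idx[0], idx[1], idx[2]], axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(pts)
    q = ((world - center) / radii) ** 2
    return (q.sum(axis=1) <= 1.0).reshape(grid.dims)


def _side_of(grid: VoxelGrid, center_world: np.ndarray) -> str:
    c_vox = grid.world_to_voxel(center_world[None, :])[0][grid.lr_axis]
    r = int(np.argmax(np.abs(grid.affine[:3, grid.lr_axis])))
    sign = np.sign(grid.affine[r, grid.lr_axis])
    signed = (c_vox - grid.midplane) * sign
    if abs(signed) < 0.5:
        return SIDE_BILATERAL
    return SIDE_LEFT if signed < 0 else SIDE_RIGHT


def make_lesions(spec: PhantomSpec, grid: VoxelGrid) -> tuple[LesionMask, LesionMask]:
    """Nested ellipsoidal T and T+O masks; side label from the core centre."""
    center = np.asarray(spec.tumour_center, dtype=float)
    lo, hi = _world_bounds(grid)
    if np.any(center < lo) or np.any(center >= hi):
        raise ValueError(f"tumour centre {center} lies outside the grid")
    side = _side_of(grid, center)
    t_vox = _ellipsoid(grid, center, np.asarray(spec.t_radii, dtype=float))
    to_vox = _ellipsoid(grid, center, np.asarray(spec.to_radii, dtype=float))
    to_vox |= t_vox                  # guard against discretisation at equal radii
    return (LesionMask(t_vox, grid, ROLE_T, side),
            LesionMask(to_vox, grid, ROLE_T_PLUS_O, side))


def apply_displacement(t: Tractogram, center: Sequence[float],
                       magnitude: float, radius: float) -> Tractogram:
    """Push streamline points radially away from the tumour centre.

    The push decays with a cosine ramp from ``magnitude`` at the centre to
    zero at ``radius`` (smooth, compactly supported), so points beyond the
    influence radius are untouched and connectivity is preserved.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0 or radius <= 0:
        return Tractogram([s.copy() for s in t.streamlines], t.grid, t.space_tag)
    c = np.asarray(center, dtype=float)
    out = [_displace_points(s, c, magnitude, radius) for s in t.streamlines]
    return Tractogram(out, t.grid, t.space_tag)


def _displace_points(points: np.ndarray, center: np.ndarray,
                     magnitude: float, radius: float) -> np.ndarray:
    v = points - center
    r = np.linalg.norm(v, axis=1)
    inside = (r < radius) & (r > 0)
    push = np.zeros_like(r)
    push[inside] = magnitude * 0.5 * (1.0 + np.cos(np.pi * r[inside] / radius))
    return points + np.where(r[:, None] > 0,
                             v / np.maximum(r, 1e-12)[:, None], 0.0) * push[:, None]


def displace_oedema(lesion_to: LesionMask, lesion_t: LesionMask,
                    center: Sequence[float], magnitude: float,
                    radius: float) -> LesionMask:
    """Carry the oedema mask through the tumour's displacement field.

    The oedema is segmented on the patient's displaced anatomy, so the
    peritumoural tissue (and the fibres it contains) that the mass effect
    pushed outward is still part of the T+O mask.  The result is the union
    of the core, the original oedema and the displaced oedema (which keeps
    the T ⊆ T+O nesting and, by radial continuity, leaves no gaps).
    """
    grid = lesion_to.grid
    idx = np.argwhere(lesion_to.voxels).astype(float)
    if idx.size == 0 or magnitude <= 0 or radius <= 0:
        return lesion_to
    # supersample each voxel so the expanded region rasterises without holes
    offs = np.array([[dx, dy, dz] for dx in (-0.25, 0.25)
                     for dy in (-0.25, 0.25) for dz in (-0.25, 0.25)])
    sub = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    world = grid.voxel_to_world(sub)
    moved = _displace_points(world, np.asarray(center, dtype=float),
                             magnitude, radius)
    cells = np.round(grid.world_to_voxel(moved)).astype(np.int64)
    ok = np.all((cells >= 0) & (cells < np.asarray(grid.dims)), axis=1)
    out = lesion_to.voxels.copy()
    out[tuple(cells[ok].T)] = True
    out |= lesion_t.voxels
    return LesionMask(out, grid, lesion_to.role, lesion_to.side)


def _jittered(b: BundleSpec, grid: VoxelGrid, rng: np.random.Generator,
              jitter: float) -> BundleSpec:
    lo, hi = _world_bounds(grid)
    margin = 1.0
    start = np.clip(np.asarray(b.start) + rng.normal(scale=jitter, size=3),
                    lo + margin, hi - margin)
    end = np.clip(np.asarray(b.end) + rng.normal(scale=jitter, size=3),
                  lo + margin, hi - margin)
    return replace(b, start=tuple(start), end=tuple(end))


def _ground_truth(bundles: list[Tractogram], lesion: LesionMask) -> np.ndarray:
    """Union of visited voxels of bundles intersecting the lesion, lesion-excluded."""
    grid = lesion.grid
    gt = np.zeros(grid.n_voxels, dtype=bool)
    les = lesion.voxels.ravel()
    for b in bundles:
        _, codes = tractogram_cells(b)
        if np.any(les[codes]):
            gt[codes] = True
    gt &= ~les
    return gt.reshape(grid.dims)


def build_patient(spec: PhantomSpec, grid: VoxelGrid,
                  rng: np.random.Generator, pid: str = "p00") -> Patient:
    """Instantiate one patient phantom from its spec."""
    bundles = [make_bundle(_jittered(b, grid, rng, spec.jitter_mm), grid, rng)
               for b in spec.bundles]
    lesion_t, lesion_to = make_lesions(spec, grid)
    if spec.displacement_magnitude > 0:
        bundles = [apply_displacement(b, spec.tumour_center,
                                      spec.displacement_magnitude,
                                      spec.displacement_radius)
                   for b in bundles]
        # oedema is segmented on the displaced anatomy
        lesion_to = displace_oedema(lesion_to, lesion_t, spec.tumour_center,
                                    spec.displacement_magnitude,
                                    spec.displacement_radius)
    tract = Tractogram([s for b in bundles for s in b.streamlines], grid)
    gt = {ROLE_T: _ground_truth(bundles, lesion_t),
          ROLE_T_PLUS_O: _ground_truth(bundles, lesion_to)}
    return Patient(pid=pid, tractogram=tract, bundles=bundles,
                   lesions={ROLE_T: lesion_t, ROLE_T_PLUS_O: lesion_to},
                   side=lesion_t.side, ground_truth=gt, spec=spec)


def _default_anatomy(grid: VoxelGrid, rng: np.random.Generator
                     ) -> tuple[BundleSpec, ...]:
    """Shared bundle anatomy: one left-right crossing bundle plus 2-5 others."""
    lo, hi = _world_bounds(grid)
    margin = 8.0
    n_bundles = int(rng.integers(3, 7))
    specs = []
    for b in range(n_bundles):
        axis = 0 if b == 0 else int(rng.integers(1, 3))  # first bundle crosses lr
        start = rng.uniform(lo + margin, hi - margin)
        end = rng.uniform(lo + margin, hi - margin)
        start[axis] = lo[axis] + margin
        end[axis] = hi[axis] - margin
        # keep transverse drift moderate so the bundle stays coherent
        mid = 0.5 * (start + end)
        start = mid + 0.7 * (start - mid)
        end = mid + 0.7 * (end - mid)
        specs.append(BundleSpec(
            start=tuple(start), end=tuple(end),
            n_streamlines=int(rng.integers(200, 1001)),
            spread_mm=float(rng.uniform(2.0, 4.0)),
            curvature_mm=float(rng.uniform(0.0, 6.0))))
    return tuple(specs)


def _default_patient_spec(anatomy: tuple[BundleSpec, ...], grid: VoxelGrid,
                          rng: np.random.Generator, displacement: bool,
                          n_controls: int) -> PhantomSpec:
    """Tumour placed off the core of a random bundle.

    The centre sits 0.5-1.5 core radii away from a random centerline
    point, so the T mask clips part of the bundle and the oedema shell
    recruits additional streamlines — the regime in which including the
    oedema enlarges the detected disconnection.
    """
    lo, hi = _world_bounds(grid)
    b = anatomy[int(rng.integers(len(anatomy)))]
    tpos = rng.uniform(0.25, 0.75)
    on_line = np.asarray(b.start) + tpos * (np.asarray(b.end) - np.asarray(b.start))
    t_radii = rng.uniform(6.0, 12.0, size=3)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    center = on_line + rng.uniform(0.5, 1.5) * float(np.mean(t_radii)) * u
    if rng.random() < 0.1:           # occasional bilateral tumour on the midline
        center[grid.lr_axis] = grid.voxel_to_world(
            np.array([[grid.midplane] * 3]))[0][grid.lr_axis]
    center = np.clip(center, lo + 4.0, hi - 4.0)
    to_radii = t_radii + rng.uniform(4.0, 10.0, size=3)
    mag, rad = 0.0, 0.0
    if displacement:
        mag = float(rng.uniform(4.0, 8.0))
        rad = 2.0 * float(np.max(t_radii))
    return PhantomSpec(
        bundles=anatomy, tumour_center=tuple(center),
        t_radii=tuple(t_radii), to_radii=tuple(to_radii),
        grid_dims=grid.dims, displacement_magnitude=mag,
        displacement_radius=rad, n_controls=n_controls)


def make_cohort(patient_specs: Sequence[PhantomSpec] | None = None,
                n_controls: int = DEFAULT_N_CONTROLS, seed: int = 0,
                n_patients: int = 20, displacement: bool = False,
                grid: VoxelGrid | None = None) -> Cohort:
    """Build a fully reproducible synthetic cohort.

    When ``patient_specs`` is omitted, a shared bundle anatomy is drawn
    and each patient receives a jittered instance of it plus a tumour;
    controls are intact jittered instances of the same anatomy (the
    anatomy of ``patient_specs[0]`` when specs are supplied explicitly).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = make_grid()
    if patient_specs is None:
        if n_patients < 1:
            raise ValueError("need at least one patient")
        anatomy = _default_anatomy(grid, rng)
        patient_specs = [
            _default_patient_spec(anatomy, grid, rng, displacement, n_controls)
            for _ in range(n_patients)]
    else:
        patient_specs = list(patient_specs)
        if not patient_specs:
            raise ValueError("need at least one patient spec")
        anatomy = patient_specs[0].bundles
    patients = [build_patient(spec, grid, rng, pid=f"p{i:02d}")
                for i, spec in enumerate(patient_specs)]
    jitter = patient_specs[0].jitter_mm
    controls = []
    for _ in range(n_controls):
        bundles = [make_bundle(_jittered(b, grid, rng, jitter), grid, rng)
                   for b in anatomy]
        controls.append(Tractogram([s for b in bundles for s in b.streamlines],
                                   grid, space_tag="template"))
    return Cohort(grid=grid, patients=patients, controls=controls, seed=seed)
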