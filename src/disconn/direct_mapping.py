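"""Direct structural disconnection (dSD) mapping.

The direct approach works on the patient's own tractogram: streamlines
with non-null overlap with the tumoral lesion are selected, and the dSD
map counts, per voxel, how many selected streamlines pass through it.
Significance of a voxel is decided by the ratio of its dSD count to a
normative track density (``AvgDensity``): the left-right-symmetrised,
lesion-excluded population average of whole-tractogram density maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_geometry import (
    KIND_BINARY,
    KIND_DENSITY,
    KIND_SD_DIRECT,
    LesionMask,
    Tractogram,
    VolumeMap,
    check_same_grid,
    tractogram_cells,
)

log = logging.getLogger(__name__)

#: default and supported dSD ratio thresholds
DEFAULT_T_DSD = 0.10
T_DSD_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class DirectSDResult:
    """Output bundle of the direct method for one patient and lesion role."""

    dsd: VolumeMap                 # integer streamline counts, kind sd_direct
    selected_count: int            # streamlines with lesion overlap
    lesion_role: str
    threshold_used: float
    significant: VolumeMap         # binary significance mask

    @property
    def sd(self) -> VolumeMap:
        """The continuous SD map (common accessor shared with the indirect result)."""
        return self.dsd


def _selected_sids(t: Tractogram, lesion: LesionMask,
                   cells: tuple[np.ndarray, np.ndarray] | None):
    check_same_grid(t.grid, lesion.grid, "tractogram and lesion")
    sid, codes = cells if cells is not None else tractogram_cells(t)
    hit = lesion.voxels.ravel()[codes]
    return np.unique(sid[hit]), (sid, codes)


def select_intersecting(t: Tractogram, lesion: LesionMask,
                        cells: tuple[np.ndarray, np.ndarray] | None = None) -> Tractogram:
    """Streamlines whose visited-voxel set intersects the lesion, order kept.

    ``cells`` optionally supplies precomputed ``tractogram_cells(t)`` so a
    single traversal can serve several selections.
    """
    sel, _ = _selected_sids(t, lesion, cells)
    return t.subset(sel.tolist())


def density_map(t: Tractogram, grid=None,
                cells: tuple[np.ndarray, np.ndarray] | None = None) -> VolumeMap:
    """Voxel-wise track-density map: distinct-streamline count per voxel."""
    g = grid if grid is not None else t.grid
    if grid is not None:
        check_same_grid(t.grid, g, "tractogram and grid")
    _, codes = cells if cells is not None else tractogram_cells(t)
    counts = np.bincount(codes, minlength=g.n_voxels).astype(float)
    return VolumeMap(counts.reshape(g.dims), g, KIND_DENSITY)


def population_average_density(densities: Sequence[VolumeMap],
                               lesions: Sequence[LesionMask],
                               return_coverage: bool = False):
    """Population average of density maps, lesion-excluded patient-by-patient.

    At each voxel the mean is taken over the subjects whose lesion does not
    cover that voxel (per-voxel denominator).  Voxels lesioned in every
    subject get 0 and are flagged via the debug log (and the optional
    coverage map).
    """
    if len(densities) == 0 or len(densities) != len(lesions):
        raise ValueError("need equal-length, non-empty density and lesion lists")
    grid = densities[0].grid
    total = np.zeros(grid.dims, dtype=float)
    n_contrib = np.zeros(grid.dims, dtype=np.int64)
    for dens, les in zip(densities, lesions):
        check_same_grid(dens.grid, grid, "density maps")
        check_same_grid(les.grid, grid, "lesions and densities")
        keep = ~les.voxels
        total += dens.values * keep
        n_contrib += keep
    uncovered = n_contrib == 0
    if np.any(uncovered):
        log.debug("%d voxels lesioned in all subjects set to 0", int(uncovered.sum()))
    avg = total / np.maximum(n_contrib, 1)
    avg[uncovered] = 0.0
    out = VolumeMap(avg, grid, KIND_DENSITY)
    if return_coverage:
        return out, n_contrib
    return out


def symmetrize(vmap: VolumeMap) -> VolumeMap:
    """Left-right symmetrise a map about the grid midplane.

    ``out(v) = (in(v) + in(mirror(v))) / 2``.  The mirror must map voxel
    indices onto voxel indices (grid symmetric about its midplane),
    otherwise the geometry is rejected.
    """
    grid = vmap.grid
    ax = grid.lr_axis
    n = grid.dims[ax]
    twice = 2.0 * grid.midplane
    if abs(twice - round(twice)) > 1e-9:
        raise ValueError("midplane is not on a symmetric sampling of the grid")
    j = int(round(twice)) - np.arange(n)
    if np.any((j < 0) | (j >= n)):
        raise ValueError("grid is not symmetric about its midplane; cannot flip")
    mirrored = np.take(vmap.values, j, axis=ax)
    return vmap.copy_with(0.5 * (vmap.values + mirrored))


def threshold_dsd(dsd: VolumeMap, avg: VolumeMap,
                  t: float = DEFAULT_T_DSD) -> VolumeMap:
    """Binary significance mask: ``dSD(v) / AvgDensity(v) > t`` (strict).

    Where the normative density is zero, any positive dSD evidence is
    significant (the ratio is treated as +inf); zero over zero is not.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    check_same_grid(dsd.grid, avg.grid, "dSD and AvgDensity")
    a = avg.values
    d = dsd.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a > 0, d / np.where(a > 0, a, 1.0), np.inf)
    sig = np.where(a > 0, ratio > t, d > 0)
    return VolumeMap(sig.astype(float), dsd.grid, KIND_BINARY)


def compute_direct_sd(t: Tractogram, lesion: LesionMask, avg: VolumeMap,
                      threshold: float = DEFAULT_T_DSD,
                      cells: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> DirectSDResult:
    """Full direct pipeline: select -> count -> ratio-threshold.

    Run once with the T mask and once with the T+O mask to obtain the two
    direct disconnection maps of a patient.
    """
    sel, (sid, codes) = _selected_sids(t, lesion, cells)
    grid = t.grid
    member = np.isin(sid, sel)
    counts = np.bincount(codes[member], minlength=grid.n_voxels).astype(float)
    dsd = VolumeMap(counts.reshape(grid.dims), grid, KIND_SD_DIRECT)
    sig = threshold_dsd(dsd, avg, threshold)
    return DirectSDResult(dsd=dsd, selected_count=int(len(sel)),
                          lesion_role=lesion.role, threshold_used=float(threshold),
                          significant=sig)
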