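"""Three-metric comparison framework between structural disconnection maps.

ΔVol (signed volume difference, cm^3) and Dice are computed on the
binarised (significance) maps, the correlation at the intersection
(Corr) on the thresholded continuous maps.  Before any comparison each
map is masked with the lesion that generated it: disconnection is
measured outside the causative lesion, so lesion voxels are zeroed.
Hemisphere decomposition splits a map into ipsilateral / contralateral
components relative to the tumour side; bilateral tumours are excluded
from that decomposition.  Voxels whose centre lies exactly on the
midplane belong to neither hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_geometry import (
    KIND_BINARY,
    SIDE_BILATERAL,
    SIDE_LEFT,
    SIDE_RIGHT,
    LesionMask,
    VoxelGrid,
    VolumeMap,
    check_same_grid,
)

log = logging.getLogger(__name__)

SCOPE_WHOLE = "whole"
SCOPE_IPSI = "ipsilateral"
SCOPE_CONTRA = "contralateral"
SCOPES = (SCOPE_WHOLE, SCOPE_IPSI, SCOPE_CONTRA)


class BilateralExclusionError(ValueError):
    """Hemisphere decomposition requested for a bilateral tumour."""


@dataclass
class ComparisonResult:
    """One (pair, scope) row: ΔVol is antisymmetric in the pair order."""

    pair_label: str
    scope: str
    delta_vol_cm3: float
    dice: float | None
    corr: float | None


def mask_sd_map(vmap: VolumeMap, lesion: LesionMask) -> VolumeMap:
    """Zero an SD map inside its generating lesion (exclusion semantics)."""
    check_same_grid(vmap.grid, lesion.grid, "SD map and lesion")
    out = vmap.values.copy()
    out[lesion.voxels] = 0.0
    return vmap.copy_with(out)


def binary_volume_cm3(mask: VolumeMap | np.ndarray, grid: VoxelGrid | None = None) -> float:
    """Volume of a binary map in cm^3."""
    if isinstance(mask, VolumeMap):
        grid = mask.grid
        m = mask.mask
    else:
        m = np.asarray(mask).astype(bool)
    return float(m.sum()) * grid.voxel_volume_cm3


def delta_vol(a: VolumeMap, b: VolumeMap, grid: VoxelGrid | None = None) -> float:
    """Signed volume difference ``(|A| - |B|) * voxel volume`` in cm^3.

    The argument order is (first-named map, second-named map), so an
    intra-method comparison ``delta_vol(X_T+O, X_T)`` is positive when the
    larger lesion detects a larger disconnection volume.
    """
    check_same_grid(a.grid, b.grid, "compared maps")
    g = grid if grid is not None else a.grid
    return (float(a.mask.sum()) - float(b.mask.sum())) * g.voxel_volume_cm3


def dice(a: VolumeMap, b: VolumeMap) -> float | None:
    """Sorensen-Dice index ``2|A∩B| / (|A| + |B|)``; None when both empty."""
    check_same_grid(a.grid, b.grid, "compared maps")
    am, bm = a.mask, b.mask
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return None
    return 2.0 * int((am & bm).sum()) / denom


def corr_intersection(a: VolumeMap, b: VolumeMap,
                      support_a: np.ndarray | None = None,
                      support_b: np.ndarray | None = None) -> float | None:
    """Pearson correlation of continuous values over the support intersection.

    Supports default to each map's nonzero voxels (the thresholded SD maps
    are zero outside their significance mask).  The value is missing when
    the intersection has fewer than 2 voxels or either side is constant.
    """
    check_same_grid(a.grid, b.grid, "compared maps")
    sa = a.mask if support_a is None else np.asarray(support_a).astype(bool)
    sb = b.mask if support_b is None else np.asarray(support_b).astype(bool)
    inter = sa & sb
    if int(inter.sum()) < 2:
        return None
    x = a.values[inter]
    y = b.values[inter]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _left_index_mask(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Boolean 1-D selectors (left, right) along the grid's lr axis.

    Laterality is read from the affine: the world axis dominated by the
    lr voxel axis increases towards the right when its coefficient is
    positive (RAS-like world frame).  Indices exactly on the midplane
    fall in neither selector.
    """
    ax = grid.lr_axis
    idx = np.arange(grid.dims[ax], dtype=float)
    r = int(np.argmax(np.abs(grid.affine[:3, ax])))
    sign = np.sign(grid.affine[r, ax])
    signed = (idx - grid.midplane) * sign
    return signed < 0, signed > 0


def midplane_mask(grid: VoxelGrid) -> np.ndarray:
    """Boolean volume of voxels whose centre lies exactly on the midplane."""
    ax = grid.lr_axis
    on = np.abs(np.arange(grid.dims[ax]) - grid.midplane) < 1e-9
    shape = [1, 1, 1]
    shape[ax] = grid.dims[ax]
    return np.broadcast_to(on.reshape(shape), grid.dims).copy()


def hemisphere_split(vmap: VolumeMap, tumour_side: str) -> tuple[VolumeMap, VolumeMap]:
    """Split a map into (ipsilateral, contralateral) components.

    The ipsilateral component is the hemisphere matching ``tumour_side``;
    each output is zero outside its hemisphere.  Bilateral tumours are
    rejected (they are excluded from the hemispheric analysis).
    """
    if tumour_side == SIDE_BILATERAL:
        raise BilateralExclusionError(
            "bilateral tumours are excluded from the hemispheric analysis")
    if tumour_side not in (SIDE_LEFT, SIDE_RIGHT):
        raise ValueError(f"unknown tumour side {tumour_side!r}")
    grid = vmap.grid
    left, right = _left_index_mask(grid)
    ipsi_sel = left if tumour_side == SIDE_LEFT else right
    contra_sel = right if tumour_side == SIDE_LEFT else left
    ax = grid.lr_axis

    def take(sel: np.ndarray) -> VolumeMap:
        out = vmap.values.copy()
        shape = [1, 1, 1]
        shape[ax] = grid.dims[ax]
        out *= sel.reshape(shape)
        return vmap.copy_with(out)

    return take(ipsi_sel), take(contra_sel)


def _unpack(m, sig):
    """Accept an SD result (with .sd / .significant) or (VolumeMap, sig)."""
    if hasattr(m, "sd") and hasattr(m, "significant"):
        return m.sd, m.significant
    if sig is None:
        raise ValueError("a plain VolumeMap needs an explicit significance mask")
    return m, sig


def compare_pair(map_a, map_b, lesion_a: LesionMask, lesion_b: LesionMask,
                 side: str, pair_label: str = "A:B",
                 sig_a: VolumeMap | None = None,
                 sig_b: VolumeMap | None = None) -> list[ComparisonResult]:
    """Compare two SD maps with ΔVol, Dice and Corr, per scope.

    Each map is first masked with its own generating lesion.  ΔVol and
    Dice use the binarised maps, Corr the thresholded continuous maps
    (continuous values restricted to the significance support).  When the
    tumour side is unilateral, ipsilateral and contralateral rows are
    emitted in addition to the whole-brain row; bilateral patients get
    the whole-brain row only.
    """
    cont_a, bin_a = _unpack(map_a, sig_a)
    cont_b, bin_b = _unpack(map_b, sig_b)
    bin_a = mask_sd_map(bin_a, lesion_a)
    bin_b = mask_sd_map(bin_b, lesion_b)
    # thresholded continuous maps: values on the (lesion-masked) support
    ca = mask_sd_map(cont_a, lesion_a)
    cb = mask_sd_map(cont_b, lesion_b)
    ca = ca.copy_with(ca.values * bin_a.values)
    cb = cb.copy_with(cb.values * bin_b.values)

    def row(scope, ba, bb, xa, xb, sup_a, sup_b):
        return ComparisonResult(
            pair_label=pair_label, scope=scope,
            delta_vol_cm3=delta_vol(ba, bb),
            dice=dice(ba, bb),
            corr=corr_intersection(xa, xb, support_a=sup_a, support_b=sup_b),
        )

    results = [row(SCOPE_WHOLE, bin_a, bin_b, ca, cb,
                   bin_a.mask, bin_b.mask)]
    if side == SIDE_BILATERAL:
        log.info("pair %s: bilateral tumour, hemisphere scopes skipped", pair_label)
        return results
    for scope, pick in ((SCOPE_IPSI, 0), (SCOPE_CONTRA, 1)):
        ba = hemisphere_split(bin_a, side)[pick]
        bb = hemisphere_split(bin_b, side)[pick]
        xa = hemisphere_split(ca, side)[pick]
        xb = hemisphere_split(cb, side)[pick]
        results.append(row(scope, ba, bb, xa, xb, ba.mask, bb.mask))
    return results
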