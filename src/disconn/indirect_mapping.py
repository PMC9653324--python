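"""Indirect structural disconnection (iSD) mapping.

The indirect approach never touches the patient's own diffusion data:
the lesion is projected onto a population of normative control
tractograms.  For each control, the voxels visited by control
streamlines passing through the lesion form a binary visitation map;
the percentage of controls visiting each voxel is the iSD map (0-100%,
a probability of disconnection).

Instead of re-seeding a tracking engine inside the lesion, each
control's precomputed whole-brain tractogram is filtered to the
streamlines intersecting the lesion; for a fixed tractogram the two
constructions have the same support and the filtering one is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_geometry import (
    KIND_BINARY,
    KIND_SD_INDIRECT,
    LesionMask,
    Tractogram,
    VolumeMap,
    check_same_grid,
    resample_mask,
    tractogram_cells,
)

#: default and supported probability thresholds
DEFAULT_T_ISD = 0.5
T_ISD_GRID = (0.3, 0.5, 0.7)


@dataclass
class IndirectSDResult:
    """Output bundle of the indirect method for one lesion."""

    isd: VolumeMap                 # percent 0-100, kind sd_indirect
    n_controls: int
    lesion_role: str
    threshold_used: float
    significant: VolumeMap

    @property
    def sd(self) -> VolumeMap:
        return self.isd


def visitation_map(control: Tractogram, lesion: LesionMask,
                   cells: tuple[np.ndarray, np.ndarray] | None = None) -> VolumeMap:
    """Binary map of voxels visited by control streamlines crossing the lesion."""
    check_same_grid(control.grid, lesion.grid, "control tractogram and lesion")
    sid, codes = cells if cells is not None else tractogram_cells(control)
    hit_sids = np.unique(sid[lesion.voxels.ravel()[codes]])
    vis = np.zeros(control.grid.n_voxels, dtype=float)
    vis[codes[np.isin(sid, hit_sids)]] = 1.0
    return VolumeMap(vis.reshape(control.grid.dims), control.grid, KIND_BINARY)


def percentage_overlap(maps: Sequence[VolumeMap]) -> VolumeMap:
    """Percent of controls visiting each voxel; values are multiples of 100/N."""
    if len(maps) == 0:
        raise ValueError("need at least one visitation map")
    grid = maps[0].grid
    counts = np.zeros(grid.dims, dtype=np.int64)
    for m in maps:
        check_same_grid(m.grid, grid, "visitation maps")
        counts += m.values.astype(np.int64)
    return VolumeMap(counts * (100.0 / len(maps)), grid, KIND_SD_INDIRECT)


def threshold_isd(isd: VolumeMap, t: float = DEFAULT_T_ISD) -> VolumeMap:
    """Binary significance: iSD(v) > 100 t, with strict inequality."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"probability threshold must lie in (0, 1), got {t}")
    return VolumeMap((isd.values > 100.0 * t).astype(float), isd.grid, KIND_BINARY)


def compute_indirect_sd(lesion: LesionMask, atlas: Sequence[Tractogram],
                        transforms: Sequence[np.ndarray | None] | None = None,
                        threshold: float = DEFAULT_T_ISD,
                        atlas_cells: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
                        ) -> IndirectSDResult:
    """Full indirect pipeline over a control atlas.

    ``transforms[i]`` maps template world coordinates into control ``i``'s
    world frame (identity when None).  The lesion is carried to each
    control's grid, the per-control visitation map is brought back to the
    template grid, and the percentage overlap is thresholded.

    ``atlas_cells`` optionally supplies ``tractogram_cells`` of each
    control so one traversal serves many lesions.
    """
    if len(atlas) == 0:
        raise ValueError("need at least one control tractogram")
    if transforms is not None and len(transforms) != len(atlas):
        raise ValueError("need one transform per control")
    template = lesion.grid
    vis_maps = []
    for i, control in enumerate(atlas):
        tr = None if transforms is None else transforms[i]
        identity = tr is None or np.allclose(tr, np.eye(4))
        if identity and control.grid.same_as(template):
            cells = atlas_cells[i] if atlas_cells is not None else None
            vis_maps.append(visitation_map(control, lesion, cells=cells))
        else:
            les_c = resample_mask(lesion, control.grid, tr)
            cells = atlas_cells[i] if atlas_cells is not None else None
            vis = visitation_map(control, les_c, cells=cells)
            inv = None if tr is None else np.linalg.inv(tr)
            vis_maps.append(resample_mask(vis, template, inv))
    isd = percentage_overlap(vis_maps)
    sig = threshold_isd(isd, threshold)
    return IndirectSDResult(isd=isd, n_controls=len(atlas),
                            lesion_role=lesion.role,
                            threshold_used=float(threshold), significant=sig)
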