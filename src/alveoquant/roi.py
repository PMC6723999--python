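"""Concentric pleural-distance regions of interest.

The analyzed parenchyma is split into three contiguous bands by in-plane
Euclidean distance from the pleural surface: subpleural ``[0, 2)`` mm,
mantellar ``[2, 4)`` mm and core ``[4, inf)`` mm by default.  The offsets are
the inner edges of the bands; half-open intervals make the partition exact.
Distance is computed per 2D slice, consistent with the per-slice analysis,
and the flooded/atelectatic regions count as lung interior when locating the
pleural outline (they are parenchyma, just not ventilated).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .containers import (
    BAND_COR,
    BAND_MAN,
    BAND_NONE,
    BAND_SUB,
    ParenchymaMask,
    RoiPartition,
    UM_PER_MM,
)


def pleural_distance_map(mask: ParenchymaMask) -> tuple[np.ndarray, list[int]]:
    """Per-slice Euclidean distance (µm) to the nearest extra-parenchymal voxel.

    Distances follow the voxel-centre convention: a voxel of the outline
    adjacent to the exterior is one voxel side away, so the distance is never
    zero inside the mask.  Returns the distance volume and the list of slices
    whose outline was empty (their distances are all zero).
    """
    outline = mask.outline
    dist = np.zeros(outline.shape, dtype=float)
    empty: list[int] = []
    for s in range(outline.shape[0]):
        if not outline[s].any():
            empty.append(s)
            continue
        dist[s] = ndi.distance_transform_edt(outline[s]) * mask.voxel_side_um
    return dist, empty


def partition_rois(
    distance_um: np.ndarray,
    mask: ParenchymaMask,
    offsets_mm: tuple[float, float, float] = (0.0, 2.0, 4.0),
) -> RoiPartition:
    """Assign every analyzed voxel to one pleural-distance band.

    ``offsets_mm = (o1, o2, o3)`` must be strictly ascending with ``o1 = 0``;
    bands are ``SUB = [o1, o2)``, ``MAN = [o2, o3)``, ``COR = [o3, inf)``,
    guaranteeing a disjoint, exhaustive cover of the analyzed mask.
    """
    o1, o2, o3 = offsets_mm
    if not (o1 < o2 < o3):
        raise ValueError("offsets must be strictly ascending")
    if o1 != 0:
        raise ValueError("the first offset must be 0 (the pleural surface)")
    analyzed = mask.analyzed
    band = np.full(analyzed.shape, BAND_NONE, dtype=np.uint8)
    d = distance_um
    band[analyzed & (d < o2 * UM_PER_MM)] = BAND_SUB
    band[analyzed & (d >= o2 * UM_PER_MM) & (d < o3 * UM_PER_MM)] = BAND_MAN
    band[analyzed & (d >= o3 * UM_PER_MM)] = BAND_COR
    return RoiPartition(
        band_map=band,
        offsets_mm=(float(o1), float(o2), float(o3)),
        voxel_side_um=mask.voxel_side_um,
    )
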