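"""Core in-memory containers shared across the analysis stages.

All volumes are numpy arrays indexed ``(slice, row, col)`` with 0-based
coordinates.  In-plane geometry is isotropic; physical sizes are carried as a
voxel side length in micrometres.  Areas are reported in voxels and volumes in
cubic millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: ROI band codes used in :class:`RoiPartition.band_map`.
BAND_NONE = 0
BAND_SUB = 1
BAND_MAN = 2
BAND_COR = 3

#: Order and names of the regions of interest used in study tables.
ROI_NAMES = ("ALL", "SUB", "MAN", "COR")
BAND_CODE = {"SUB": BAND_SUB, "MAN": BAND_MAN, "COR": BAND_COR}

UM_PER_MM = 1000.0


@dataclass
class ImageStack:
    """A grayscale tomographic stack with physical voxel size.

    Parameters
    ----------
    voxels :
        Array of shape ``(n_slices, rows, cols)``.  Raw acquisitions are
        16-bit unsigned; intermediate enhanced images may be wider integers.
    voxel_side_um :
        Side of the (cubic) voxel in micrometres.
    """

    voxels: np.ndarray
    voxel_side_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (slice, row, col) array")
        if self.voxel_side_um <= 0:
            raise ValueError("voxel_side_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slab_thickness_mm(self) -> float:
        """Cranio-caudal extent of the imaged slab, ``n_slices * voxel_side``."""
        return self.n_slices * self.voxel_side_um / UM_PER_MM


@dataclass
class ParenchymaMask:
    """Which voxels belong to the analyzed lung parenchyma.

    ``included`` marks the manually (or phantom-) delimited parenchyma;
    ``excluded_nonventilated`` marks flooded/atelectatic regions that sit on
    the periphery of the ventilated tissue and are removed from the analysis.
    The two sets are disjoint in the sense that exclusion is a subset carved
    out of ``included``; the voxels actually analyzed are ``analyzed``.
    """

    included: np.ndarray
    excluded_nonventilated: np.ndarray = None  # type: ignore[assignment]
    voxel_side_um: float = 47.7

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.excluded_nonventilated is None:
            self.excluded_nonventilated = np.zeros_like(self.included)
        self.excluded_nonventilated = np.asarray(
            self.excluded_nonventilated, dtype=bool
        )
        if self.excluded_nonventilated.shape != self.included.shape:
            raise ValueError("mask component shapes differ")

    @property
    def analyzed(self) -> np.ndarray:
        """Boolean volume of voxels entering the airspace analysis."""
        return self.included & ~self.excluded_nonventilated

    @property
    def outline(self) -> np.ndarray:
        """Full parenchyma outline: analyzed plus excluded regions.

        The pleural distance is measured from this outline, so a flooded
        peripheral cap still counts as lung interior when locating the
        pleural surface.
        """
        return self.included | self.excluded_nonventilated


@dataclass
class AirspaceLabelMap:
    """Detected airspaces for a stack, per-slice.

    ``peaks`` holds one detection seed per airspace as ``(slice, row, col)``
    rows; ``prominences`` the enhanced-image value at each seed.  ``labels``
    is a per-slice dense labeling (1..NAs on each slice, 0 = non-gas); it is
    empty/zero until delineation has run.
    """

    peaks: np.ndarray  # (k, 3) int
    prominences: np.ndarray  # (k,)
    nas_per_slice: np.ndarray  # (n_slices,)
    labels: np.ndarray | None = None
    dropped_peaks: int = 0
    merged_peaks: int = 0

    def peaks_in_slice(self, s: int) -> np.ndarray:
        return self.peaks[self.peaks[:, 0] == s]

    @property
    def n_airspaces(self) -> int:
        return int(self.nas_per_slice.sum())


@dataclass
class RoiPartition:
    """Concentric pleural-distance bands over the analyzed parenchyma.

    ``band_map`` codes: 0 = outside the analyzed mask, 1 = subpleural,
    2 = mantellar, 3 = core.
    """

    band_map: np.ndarray
    offsets_mm: tuple[float, float, float]
    voxel_side_um: float

    def band(self, name: str) -> np.ndarray:
        """Boolean volume of one named band (``SUB``/``MAN``/``COR``)."""
        return self.band_map == BAND_CODE[name]
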