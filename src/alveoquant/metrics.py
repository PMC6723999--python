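"""Airspace metrics per (animal, PEEP, slice, ROI) and study-table pooling.

Two normalized metrics summarize each analysis cell:

* ``ASnum`` — airspace density, the number of counted airspaces divided by
  the analyzed parenchyma volume of the cell (units/mm^3).  The analyzed
  volume is the slab spanned by the cell's voxels, ``count * voxel_side^3``.
* ``ASdim`` — mean airspace surface extension, the gas area divided by the
  airspace count, reported in voxels of in-plane area.  Undefined (NaN) when
  no airspace was counted.

An airspace straddling two bands is *counted* in the band holding its
detection peak, while its *area* contributes to every band it overlaps: this
keeps counts additive across bands and gas area conserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    BAND_CODE,
    ROI_NAMES,
    AirspaceLabelMap,
    ParenchymaMask,
    RoiPartition,
    UM_PER_MM,
)

#: Study-table column names.
COLUMNS = [
    "animal",
    "peep_nominal",
    "peep_measured",
    "slice",
    "roi",
    "nas",
    "gas_area_vox",
    "analyzed_volume_mm3",
    "asnum_per_mm3",
    "asdim_vox",
]


def voxel_volume_mm3(voxel_side_um: float) -> float:
    return (voxel_side_um / UM_PER_MM) ** 3


def roi_volume(
    mask: ParenchymaMask,
    partition: RoiPartition,
    roi: str,
    slice_index: int,
) -> float:
    """Analyzed parenchyma volume (mm^3) of one ROI on one slice."""
    analyzed = mask.analyzed[slice_index]
    if roi == "ALL":
        count = int(analyzed.sum())
    else:
        count = int((analyzed & (partition.band_map[slice_index] == BAND_CODE[roi])).sum())
    return count * voxel_volume_mm3(partition.voxel_side_um)


def compute_metrics(
    labelmap: AirspaceLabelMap,
    partition: RoiPartition,
    mask: ParenchymaMask,
    animal: str = "A1",
    peep_nominal: float = np.nan,
    peep_measured: float = np.nan,
) -> pd.DataFrame:
    """Per-slice, per-ROI airspace metrics for one stack.

    Raises if the label map is inconsistent with its peak list (a label
    without a seeding peak means a corrupt map).
    """
    if labelmap.labels is None:
        raise ValueError("labelmap has no delineated labels; run delineation first")
    vol_vox = voxel_volume_mm3(partition.voxel_side_um)
    rows = []
    for s in range(labelmap.labels.shape[0]):
        lab = labelmap.labels[s]
        pk = labelmap.peaks_in_slice(s)
        n_labels = int(lab.max())
        if n_labels != len(pk) or len(np.unique(lab[lab > 0])) != len(pk):
            raise ValueError(
                f"slice {s}: {n_labels} labels but {len(pk)} peaks — corrupt label map"
            )
        band = partition.band_map[s]
        analyzed = mask.analyzed[s]
        gas = lab > 0
        peak_bands = band[pk[:, 1], pk[:, 2]] if len(pk) else np.empty(0, dtype=int)
        for roi in ROI_NAMES:
            if roi == "ALL":
                nas = len(pk)
                gas_area = int(gas.sum())
                vol = int(analyzed.sum()) * vol_vox
            else:
                code = BAND_CODE[roi]
                nas = int((peak_bands == code).sum())
                gas_area = int((gas & (band == code)).sum())
                vol = int((analyzed & (band == code)).sum()) * vol_vox
            rows.append(
                (
                    animal,
                    peep_nominal,
                    peep_measured,
                    s,
                    roi,
                    nas,
                    gas_area,
                    vol,
                    nas / vol if vol > 0 else np.nan,
                    gas_area / nas if nas > 0 else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def pool_slices(records: pd.DataFrame) -> pd.DataFrame:
    """Pool per-slice observations into per-(PEEP, ROI) group summaries.

    Slices stay individual observations (no per-animal averaging); this
    reports group mean +- SD and n for each metric in the layout of the study
    table.  Duplicate (animal, PEEP, slice, ROI) keys indicate a double-fed
    stack and raise.
    """
    key = ["animal", "peep_nominal", "slice", "roi"]
    if records.duplicated(subset=key).any():
        raise ValueError("duplicate (animal, PEEP, slice, ROI) observations")
    out = []
    for (peep, roi), grp in records.groupby(["peep_nominal", "roi"], sort=True):
        for resp, col in (("ASdim", "asdim_vox"), ("ASnum", "asnum_per_mm3")):
            vals = grp[col].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            out.append((resp, roi, peep, n, mean, sd, n == 1))
    return pd.DataFrame(
        out,
        columns=["response", "roi", "peep_nominal", "n", "mean", "sd", "single_obs"],
    )
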