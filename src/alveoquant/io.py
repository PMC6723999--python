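"""Reading and writing the on-disk formats.

Image stacks travel as multi-page 16-bit grayscale TIFF, masks as 8-bit TIFF
(0 = outside, 1 = included, 2 = excluded non-ventilated), label maps as
32-bit integer TIFF, peak lists as CSV, and series metadata (phantom spec,
seed, pressures, fractions) as a JSON sidecar next to the images.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import AirspaceLabelMap, ImageStack, ParenchymaMask
from .phantom import PeepFrame, PhantomSpec


def save_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.voxels.astype(np.uint16), photometric="minisblack")


def load_stack(path: str | Path, voxel_side_um: float) -> ImageStack:
    vox = tifffile.imread(path)
    if vox.ndim == 2:
        vox = vox[None]
    return ImageStack(vox, voxel_side_um)


def save_mask(path: str | Path, mask: ParenchymaMask) -> None:
    coded = mask.included.astype(np.uint8)
    coded[mask.excluded_nonventilated] = 2
    tifffile.imwrite(path, coded, photometric="minisblack")


def load_mask(path: str | Path, voxel_side_um: float) -> ParenchymaMask:
    coded = tifffile.imread(path)
    if coded.ndim == 2:
        coded = coded[None]
    return ParenchymaMask(
        included=coded > 0,
        excluded_nonventilated=coded == 2,
        voxel_side_um=voxel_side_um,
    )


def save_labels(path: str | Path, labelmap: AirspaceLabelMap) -> None:
    if labelmap.labels is None:
        raise ValueError("label map has not been delineated")
    tifffile.imwrite(path, labelmap.labels.astype(np.int32), photometric="minisblack")


def save_peaks_csv(path: str | Path, labelmap: AirspaceLabelMap) -> None:
    df = pd.DataFrame(labelmap.peaks, columns=["slice", "row", "col"])
    df["prominence"] = labelmap.prominences
    df.to_csv(path, index=False)


def load_peaks_csv(path: str | Path, n_slices: int) -> AirspaceLabelMap:
    df = pd.read_csv(path)
    peaks = df[["slice", "row", "col"]].to_numpy(dtype=int)
    nas = np.bincount(peaks[:, 0], minlength=n_slices)
    return AirspaceLabelMap(
        peaks=peaks,
        prominences=df["prominence"].to_numpy(dtype=np.int64),
        nas_per_slice=nas,
    )


def save_series(outdir: str | Path, frames: list[PeepFrame], spec: PhantomSpec,
                mechanism: str, fractions) -> None:
    """Write a synthetic deflation series: per-level image, truth-label and
    mask TIFFs plus one JSON sidecar from which the series can be rebuilt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": dataclasses.asdict(spec),
        "mechanism": mechanism,
        "fractions": [float(f) for f in fractions],
        "pressures": [fr.pressure for fr in frames],
        "files": [],
    }
    for i, fr in enumerate(frames):
        stem = f"peep{fr.pressure:g}"
        save_stack(outdir / f"{stem}_image.tif", fr.image)
        tifffile.imwrite(
            outdir / f"{stem}_truth.tif",
            fr.truth.label_map.astype(np.int32),
            photometric="minisblack",
        )
        save_mask(outdir / f"{stem}_mask.tif", fr.mask)
        meta["files"].append(
            {
                "pressure": fr.pressure,
                "image": f"{stem}_image.tif",
                "truth": f"{stem}_truth.tif",
                "mask": f"{stem}_mask.tif",
            }
        )
    (outdir / "series.json").write_text(json.dumps(meta, indent=2))


def load_series_meta(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "series.json").read_text())
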