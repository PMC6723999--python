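"""Synthetic lung-slice phantoms with known airspace ground truth.

The phantom emulates a mid-thoracic cross-section imaged at micrometre
resolution: a disc of parenchyma tessellated into gas-filled airspaces
(~110 µm across in healthy rabbit lungs) separated by tissue-density septa,
optionally with a flooded/atelectatic peripheral cap, phase-contrast-like
edge fringes, and additive Gaussian noise.  Deflation is modelled through the
two classic terminal-airspace mechanisms that imaging studies contrast:

``balloon``
    every open airspace shrinks in proportion, keeping its identity — the
    pattern reported for injured (ARDS-like) lungs;
``derecruitment``
    a growing subset of airspaces closes completely while survivors keep
    their size — the pattern reported for healthy lungs.

``mixed`` applies both, splitting the deflation fraction 50/50.  The names
``shape_change`` and ``crumpling`` are reserved for the remaining two
mechanisms of the classical four-way taxonomy but are not implemented.

Everything is a pure function of the :class:`PhantomSpec` (including its
seed), so a series can be regenerated bit-identically from its metadata.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .containers import ImageStack, ParenchymaMask, UM_PER_MM

LABEL_OUTSIDE = -1
LABEL_FLOODED = -2
LABEL_TISSUE = 0

MECHANISMS = ("none", "balloon", "derecruitment", "mixed")
RESERVED_MECHANISMS = ("shape_change", "crumpling")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and randomness of one synthetic stack.

    Lengths are micrometres unless suffixed ``_mm``; grayscale levels are on
    the 16-bit scale.  ``diameter_cv`` scatters individual airspace sizes;
    ``slice_size_cv`` and ``slice_count_cv`` add per-slice heterogeneity of
    mean size and airspace count (both default to 0 so that ``target_count``
    is realized exactly on every slice).
    """

    domain_radius_mm: float
    target_count: int
    mean_airspace_diameter_um: float = 110.0
    septal_thickness_um: float = 95.4
    gas_level: int = 20000
    tissue_level: int = 45000
    noise_sigma: float = 0.0
    fringe_amplitude: float = 0.0
    flooded_fraction: float = 0.0
    n_slices: int = 1
    voxel_side_um: float = 47.7
    seed: int = 0
    diameter_cv: float = 0.10
    slice_size_cv: float = 0.0
    slice_count_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue_level <= self.gas_level:
            raise ValueError("tissue_level must exceed gas_level")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if self.mean_airspace_diameter_um < 2 * self.voxel_side_um:
            raise ValueError(
                "mean airspace diameter must be at least twice the voxel side "
                "to be resolvable"
            )
        if not 0 <= self.flooded_fraction < 1:
            raise ValueError("flooded_fraction must be in [0, 1)")
        if self.noise_sigma < 0 or self.fringe_amplitude < 0:
            raise ValueError("noise_sigma and fringe_amplitude must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.domain_radius_mm <= 0 or self.voxel_side_um <= 0:
            raise ValueError("domain_radius_mm and voxel_side_um must be > 0")

    @property
    def domain_radius_vox(self) -> float:
        return self.domain_radius_mm * UM_PER_MM / self.voxel_side_um


@dataclass
class PhantomTruth:
    """Ground-truth airspace geometry for a phantom stack.

    ``label_map`` codes: ``k >= 1`` airspace id, 0 tissue/septa, -1 outside
    the parenchyma, -2 flooded/atelectatic.  Airspaces are strictly in-plane
    objects: airspace ``k`` lives on slice ``slice_of[k-1]``.
    ``closure_order`` fixes the (seeded) sequence in which airspaces close
    under derecruitment, so cumulative deflation is nested by construction.
    """

    label_map: np.ndarray  # (S, H, W) int32
    centers: np.ndarray  # (K, 2) float, (row, col)
    radii_vox: np.ndarray  # (K,)
    slice_of: np.ndarray  # (K,) int
    open_flags: np.ndarray  # (K,) bool
    areas: np.ndarray  # (K,) int, gas voxels per airspace
    closure_order: np.ndarray  # (K,) permutation of airspace indices
    spec: PhantomSpec
    mechanism: str = "none"
    fraction: float = 0.0

    @property
    def n_airspaces(self) -> int:
        return len(self.centers)

    def open_count_per_slice(self) -> np.ndarray:
        counts = np.zeros(self.spec.n_slices, dtype=int)
        np.add.at(counts, self.slice_of[self.open_flags], 1)
        return counts

    def gas_area_per_slice(self) -> np.ndarray:
        areas = np.zeros(self.spec.n_slices, dtype=int)
        np.add.at(areas, self.slice_of, self.areas)
        return areas

    def mean_equivalent_diameter_um(self) -> float:
        """Mean over open airspaces of the area-equivalent circle diameter."""
        a = self.areas[self.open_flags]
        if len(a) == 0:
            return float("nan")
        return float(np.mean(2.0 * np.sqrt(a / np.pi)) * self.spec.voxel_side_um)

    def mask(self) -> ParenchymaMask:
        """Parenchyma outline as a pipeline input (flooding undisclosed)."""
        return ParenchymaMask(
            included=self.label_map != LABEL_OUTSIDE,
            voxel_side_um=self.spec.voxel_side_um,
        )

    def true_mask(self) -> ParenchymaMask:
        """Oracle mask with the flooded cap already excluded."""
        return ParenchymaMask(
            included=self.label_map != LABEL_OUTSIDE,
            excluded_nonventilated=self.label_map == LABEL_FLOODED,
            voxel_side_um=self.spec.voxel_side_um,
        )


def _cap_offset(flooded_fraction: float) -> float:
    """Signed plane offset (units of R) cutting a circular segment of the
    requested area fraction off the unit disc."""

    def frac(h: float) -> float:
        return (np.arccos(h) - h * np.sqrt(1.0 - h * h)) / np.pi

    return brentq(lambda h: frac(h) - flooded_fraction, -0.999999, 0.999999)


def _hex_sites(radius: float, pitch: float) -> np.ndarray:
    """Hexagonal lattice points covering a disc of the given radius."""
    dy = pitch * np.sqrt(3.0) / 2.0
    rows = int(np.ceil(radius / dy)) + 1
    cols = int(np.ceil(radius / pitch)) + 1
    pts = []
    for i in range(-rows, rows + 1):
        off = 0.5 * pitch if i % 2 else 0.0
        for j in range(-cols, cols + 1):
            pts.append((i * dy, j * pitch + off))
    pts = np.asarray(pts)
    return pts[np.hypot(pts[:, 0], pts[:, 1]) <= radius]


def generate_parenchyma_truth(spec: PhantomSpec) -> PhantomTruth:
    """Tessellate a disc of parenchyma into gas airspaces with septa.

    Airspace sites sit on a jittered hexagonal lattice whose pitch is chosen
    from the requested count; each site carries a near-circular gas region
    whose radius is clipped so that at least ``septal_thickness`` of tissue
    separates it from every neighbour, from the pleural boundary and from the
    flooded cap.  Each slice is tessellated independently (consecutive
    cranio-caudal levels sample different alveoli).

    Raises
    ------
    ValueError
        If the requested count of airspaces of the requested diameter cannot
        be packed into the domain.
    """
    R = spec.domain_radius_vox
    septal_vox = spec.septal_thickness_um / spec.voxel_side_um
    margin = 3
    size = 2 * int(np.ceil(R)) + 2 * margin + 1
    c0 = (size - 1) / 2.0

    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy - c0, xx - c0)
    inside = rr <= R

    flood_dir = None
    cap_off = None
    if spec.flooded_fraction > 0:
        rng_cap = np.random.default_rng([spec.seed & 0x7FFFFFFF, 13])
        theta = rng_cap.uniform(0, 2 * np.pi)
        flood_dir = np.array([np.sin(theta), np.cos(theta)])
        cap_off = _cap_offset(spec.flooded_fraction) * R

    label = np.full((spec.n_slices, size, size), LABEL_OUTSIDE, dtype=np.int32)
    centers, radii, slice_of = [], [], []

    for s in range(spec.n_slices):
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 11, s])
        count_s = spec.target_count
        if spec.slice_count_cv > 0:
            z = np.clip(rng.standard_normal(), -2.5, 2.5)
            count_s = max(1, int(round(spec.target_count * (1 + spec.slice_count_cv * z))))
        d_scale = 1.0
        if spec.slice_size_cv > 0:
            z = np.clip(rng.standard_normal(), -2.5, 2.5)
            d_scale = float(np.clip(1 + spec.slice_size_cv * z, 0.5, 1.6))
        d_mean = spec.mean_airspace_diameter_um / spec.voxel_side_um * d_scale
        d_max = d_mean * (1 + 3 * spec.diameter_cv)

        # Lattice pitch sized to over-generate more sites than needed, then
        # subsample to the exact count; the pitch never drops below the
        # packing limit (one diameter plus one septum).
        r_place = R - d_max / 2.0 - septal_vox
        pitch_min = d_mean + septal_vox
        if r_place <= 0:
            raise ValueError(
                "infeasible packing: airspace diameter plus septal margin "
                f"({d_max + 2 * septal_vox:.1f} vox) exceeds the domain radius "
                f"({R:.1f} vox)"
            )
        sites = np.empty((0, 2))
        for overgen in (1.15, 1.4, 1.8, 2.5):
            pitch = np.sqrt(2 * np.pi * r_place**2 / (np.sqrt(3) * count_s * overgen))
            if pitch < pitch_min:
                pitch = pitch_min
            sites = _hex_sites(r_place, pitch)
            if len(sites) >= count_s:
                break
        if len(sites) < count_s and spec.flooded_fraction == 0:
            raise ValueError(
                "infeasible packing: "
                f"{count_s} airspaces of ~{d_mean:.1f} vox plus "
                f"{septal_vox:.1f} vox septa need more area than the "
                f"{np.pi * r_place**2:.0f} vox^2 domain provides "
                f"(only {len(sites)} sites fit)"
            )
        jit = 0.5 * max(0.0, pitch - (d_max + septal_vox))
        jit = min(jit, 0.35 * pitch)
        if jit > 0:
            ang = rng.uniform(0, 2 * np.pi, len(sites))
            rad = jit * np.sqrt(rng.uniform(0, 1, len(sites)))
            sites = sites + np.c_[rad * np.sin(ang), rad * np.cos(ang)]

        if cap_off is not None:
            proj = sites @ flood_dir
            keep = proj + d_max / 2.0 + septal_vox < cap_off
            sites = sites[keep]
        if len(sites) < count_s:
            if spec.flooded_fraction > 0:
                count_s = len(sites)  # flooding consumed peripheral sites
            else:
                raise ValueError(
                    "infeasible packing: only "
                    f"{len(sites)} sites fit for target_count={count_s}"
                )
        pick = rng.permutation(len(sites))[:count_s]
        sites = sites[pick]

        r_i = d_mean / 2.0 * (1 + spec.diameter_cv * np.clip(rng.standard_normal(count_s), -3, 3))
        if count_s > 1:
            nn = cKDTree(sites).query(sites, k=2)[0][:, 1]
            r_i = np.minimum(r_i, (nn - septal_vox) / 2.0)
        r_i = np.minimum(r_i, R - np.hypot(sites[:, 0], sites[:, 1]) - septal_vox)
        r_i = np.maximum(r_i, 0.56)  # every open airspace covers >= 1 voxel

        sl = label[s]
        sl[inside] = LABEL_TISSUE
        if cap_off is not None:
            cap = inside & ((yy - c0) * flood_dir[0] + (xx - c0) * flood_dir[1] >= cap_off)
            sl[cap] = LABEL_FLOODED

        base_id = len(centers)
        for i in range(count_s):
            cy, cx = sites[i, 0] + c0, sites[i, 1] + c0
            r = r_i[i]
            y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
            x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
            by, bx = np.mgrid[y0:y1, x0:x1]
            disc = (by - cy) ** 2 + (bx - cx) ** 2 <= r * r
            sl[y0:y1, x0:x1][disc] = base_id + i + 1
            centers.append((cy, cx))
            radii.append(r)
            slice_of.append(s)

    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float)
    slice_of = np.asarray(slice_of, dtype=int)
    k = len(centers)
    areas = np.bincount(label[label > 0].ravel(), minlength=k + 1)[1:].astype(np.int64)
    rng_order = np.random.default_rng([spec.seed & 0x7FFFFFFF, 17])
    return PhantomTruth(
        label_map=label,
        centers=centers,
        radii_vox=radii,
        slice_of=slice_of,
        open_flags=np.ones(k, dtype=bool),
        areas=areas,
        closure_order=rng_order.permutation(k),
        spec=spec,
    )


def _shrink_airspaces(truth: PhantomTruth, keep_frac: np.ndarray) -> None:
    """Trim every open airspace to ``round(area * keep_frac)`` voxels in
    place, keeping the voxels nearest its centre (ties by row, then col)."""
    lab = truth.label_map
    svox, rvox, cvox = np.nonzero(lab > 0)
    ids = lab[svox, rvox, cvox] - 1
    d2 = (rvox - truth.centers[ids, 0]) ** 2 + (cvox - truth.centers[ids, 1]) ** 2
    order = np.lexsort((cvox, rvox, d2, ids))
    ids_o = ids[order]
    # rank of each voxel within its airspace, in increasing centre distance
    block_start = np.r_[0, np.flatnonzero(np.diff(ids_o)) + 1]
    rank = np.arange(len(ids_o)) - np.repeat(block_start, np.diff(np.r_[block_start, len(ids_o)]))
    targets = np.maximum(1, np.round(truth.areas * keep_frac)).astype(np.int64)
    drop = rank >= targets[ids_o]
    do = order[drop]
    lab[svox[do], rvox[do], cvox[do]] = LABEL_TISSUE
    kept = np.bincount(ids_o[~drop], minlength=truth.n_airspaces)
    truth.areas = np.where(truth.open_flags, kept, 0).astype(np.int64)


def _close_airspaces(truth: PhantomTruth, n_close_per_slice: np.ndarray) -> None:
    """Close the first ``n_close`` airspaces of each slice (in the stack's
    fixed closure order), filling them with tissue, in place."""
    close_ids = []
    for s in range(truth.spec.n_slices):
        in_slice = truth.closure_order[truth.slice_of[truth.closure_order] == s]
        close_ids.extend(in_slice[: n_close_per_slice[s]])
    if not close_ids:
        return
    close_ids = np.asarray(close_ids, dtype=int)
    sel = np.isin(truth.label_map, close_ids + 1)
    truth.label_map[sel] = LABEL_TISSUE
    truth.open_flags[close_ids] = False
    truth.areas[close_ids] = 0


def apply_deflation(
    truth: PhantomTruth,
    mechanism: str,
    fraction: float,
    per_slice_fractions: Sequence[float] | None = None,
) -> PhantomTruth:
    """Deflate a base phantom truth by one mechanism.

    ``fraction`` is the deflated share of the baseline: under ``balloon``
    every airspace area is scaled to ``1 - fraction`` (within one voxel of
    quantization); under ``derecruitment`` a seeded ``round(fraction * N)``
    airspaces close completely; ``mixed`` splits the fraction 50/50 between
    the two.  ``per_slice_fractions`` optionally overrides the fraction
    slice-by-slice (used by :func:`make_peep_series` to emulate the growing
    between-slice scatter seen at low distending pressures).

    Always applied to the *base* truth, never compounded, so a pressure
    series maps each level to the same reference state.
    """
    if mechanism in RESERVED_MECHANISMS:
        raise NotImplementedError(f"mechanism {mechanism!r} is reserved but not modelled")
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown deflation mechanism {mechanism!r}")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    S = truth.spec.n_slices
    if per_slice_fractions is None:
        f_s = np.full(S, float(fraction))
    else:
        f_s = np.asarray(per_slice_fractions, dtype=float)
        if f_s.shape != (S,):
            raise ValueError("per_slice_fractions must have one entry per slice")
        if ((f_s < 0) | (f_s > 1)).any():
            raise ValueError("per-slice fractions must be in [0, 1]")

    out = copy.deepcopy(truth)
    out.mechanism = mechanism
    out.fraction = float(fraction)
    if mechanism == "none" or (f_s == 0).all():
        return out

    open_per_slice = np.zeros(S, dtype=int)
    np.add.at(open_per_slice, truth.slice_of[truth.open_flags], 1)

    if mechanism == "balloon":
        _shrink_airspaces(out, 1.0 - f_s[out.slice_of])
    elif mechanism == "derecruitment":
        _close_airspaces(out, np.round(f_s * open_per_slice).astype(int))
    else:  # mixed
        _close_airspaces(out, np.round(0.5 * f_s * open_per_slice).astype(int))
        _shrink_airspaces(out, 1.0 - 0.5 * f_s[out.slice_of])
    return out


def render_image(truth: PhantomTruth, spec: PhantomSpec) -> ImageStack:
    """Render a truth map into a 16-bit grayscale stack.

    Gas voxels take ``gas_level``; septa, flooded regions and everything
    outside the parenchyma take ``tissue_level``.  A one-voxel dark/bright
    overshoot pair of amplitude ``fringe_amplitude`` marks every gas–tissue
    boundary (the phase-contrast edge signature), then zero-mean Gaussian
    noise of sd ``noise_sigma`` is added.  Values falling outside the 16-bit
    range are clipped; the clip count is recorded in ``meta['clipped_voxels']``.
    """
    if truth.label_map.shape[0] != spec.n_slices:
        raise ValueError("truth and spec disagree on n_slices")
    img = np.where(truth.label_map > 0, float(spec.gas_level), float(spec.tissue_level))
    if spec.fringe_amplitude > 0:
        cross = ndi.generate_binary_structure(2, 1)
        for s in range(spec.n_slices):
            gas = truth.label_map[s] > 0
            rim_gas = gas & ~ndi.binary_erosion(gas, cross, border_value=0)
            rim_tis = ~gas & ndi.binary_dilation(gas, cross, border_value=0)
            img[s][rim_gas] -= spec.fringe_amplitude
            img[s][rim_tis] += spec.fringe_amplitude
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 7])
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    clipped = int(((img < 0) | (img > 65535)).sum())
    if clipped:
        warnings.warn(f"render_image clipped {clipped} voxels to the 16-bit range")
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return ImageStack(img, spec.voxel_side_um, meta={"clipped_voxels": clipped})


@dataclass
class PeepFrame:
    """One pressure step of a synthetic deflation series."""

    pressure: float
    image: ImageStack
    truth: PhantomTruth
    mask: ParenchymaMask


def make_peep_series(
    spec: PhantomSpec,
    mechanism: str,
    peep_levels: Sequence[float],
    fractions: Sequence[float],
    fraction_jitter: float = 0.0,
) -> list[PeepFrame]:
    """Render one stack per pressure step of a decremental-pressure series.

    Each level applies its deflation fraction to the *same* base truth, so
    the series is cumulative and the per-level ground truth is retained.
    ``fraction_jitter`` scatters the applied fraction per slice and level as
    ``f * (1 + jitter * z)`` with standard-normal ``z``, which makes the
    between-slice spread of the metrics grow as deflation deepens — the
    fluctuating local recruitment seen in injured lungs.
    """
    if len(peep_levels) != len(fractions):
        raise ValueError("peep_levels and fractions must have equal length")
    fr = np.asarray(fractions, dtype=float)
    if (np.diff(fr) < 0).any():
        raise ValueError("fractions must be non-decreasing along the series")
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("fractions must be in [0, 1]")

    base = generate_parenchyma_truth(spec)
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 23])
    frames: list[PeepFrame] = []
    for peep, f in zip(peep_levels, fr):
        per_slice = None
        if fraction_jitter > 0:
            z = rng.standard_normal(spec.n_slices)
            per_slice = np.clip(f * (1 + fraction_jitter * z), 0.0, 0.97)
        truth = apply_deflation(base, mechanism, float(f), per_slice_fractions=per_slice)
        frames.append(
            PeepFrame(float(peep), render_image(truth, spec), truth, truth.mask())
        )
    return frames


def ards_phantom_spec(
    seed: int,
    n_slices: int = 20,
    domain_radius_mm: float = 5.0,
    target_count: int = 700,
    **overrides,
) -> PhantomSpec:
    """Study-scale phantom: airspace density near 190/mm^3 of analyzed slab,
    airspace areas around 13 voxels at full recruitment, 10%-of-contrast
    noise, phase-contrast fringes, and per-slice heterogeneity of size and
    count as observed in lavage-injury lungs."""
    kw = dict(
        domain_radius_mm=domain_radius_mm,
        target_count=target_count,
        mean_airspace_diameter_um=194.0,
        septal_thickness_um=71.6,
        noise_sigma=2500.0,
        fringe_amplitude=4000.0,
        n_slices=n_slices,
        seed=seed,
        diameter_cv=0.10,
        slice_size_cv=0.085,
        slice_count_cv=0.15,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


#: Deflation profile reproducing the magnitude of airspace shrinkage seen
#: across a 12 -> 0 cmH2O decremental-PEEP ladder in experimental ARDS
#: (mean airspace area falling from ~13 to ~7.6 voxels).
ARDS_DEFLATION_FRACTIONS = (0.0, 0.15, 0.31, 0.39, 0.42)
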