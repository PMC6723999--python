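"""Detection chain: top-hat oracle equivalence, counting, delineation,
non-ventilated exclusion."""

import numpy as np
import pytest
from skimage.morphology import disk

import alveoquant as aq
from alveoquant.segmentation import _closing
from conftest import segment_chain


def brute_closing(img: np.ndarray, radius: int) -> np.ndarray:
    """Exhaustive in-bounds neighbourhood max followed by min."""
    offs = np.argwhere(disk(radius).astype(bool)) - radius
    h, w = img.shape

    def sweep(src, agg):
        out = np.empty_like(src)
        for i in range(h):
            for j in range(w):
                vals = [
                    src[i + di, j + dj]
                    for di, dj in offs
                    if 0 <= i + di < h and 0 <= j + dj < w
                ]
                out[i, j] = agg(vals)
        return out

    return sweep(sweep(img, max), min)


def stack(img2d, voxel=47.7):
    return aq.ImageStack(np.asarray(img2d)[None], voxel)


def full_mask(img2d, voxel=47.7):
    return aq.ParenchymaMask(np.ones((1,) + np.asarray(img2d).shape, bool),
                             voxel_side_um=voxel)


class TestTophat:
    @pytest.mark.parametrize("radius", [1, 2, 3])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_closing_matches_bruteforce(self, radius, seed):
        img = np.random.default_rng(seed).integers(0, 500, (24, 31)).astype(np.int64)
        assert np.array_equal(_closing(img, radius), brute_closing(img, radius))

    def test_single_dark_pixel(self):
        img = np.full((9, 9), 100, dtype=np.uint16)
        img[4, 4] = 60
        enh = aq.tophat_enhance(stack(img), full_mask(img),
                                radii_um=[47.7], presmooth=0)
        expected = np.zeros((9, 9), dtype=np.int64)
        expected[4, 4] = 40
        assert np.array_equal(enh.voxels[0], expected)

    def test_constant_image_enhances_to_zero(self):
        img = np.full((12, 12), 1000, dtype=np.uint16)
        enh = aq.tophat_enhance(stack(img), full_mask(img), presmooth=0)
        assert enh.voxels.max() == 0

    def test_larger_radius_dominates_on_wide_disc(self):
        """A dark disc of diameter 6: the r=4 pass responds at least as much
        as the r=2 pass at the centre (the ladder max keeps the best)."""
        img = np.full((21, 21), 200, dtype=np.int64)
        yy, xx = np.mgrid[0:21, 0:21]
        img[(yy - 10) ** 2 + (xx - 10) ** 2 <= 9] = 50
        r2 = brute_closing(img, 2) - img
        r4 = brute_closing(img, 4) - img
        assert r4[10, 10] >= r2[10, 10]
        enh = aq.tophat_enhance(stack(img.astype(np.uint16)), full_mask(img),
                                radii_um=[2 * 47.7, 4 * 47.7], presmooth=0)
        assert enh.voxels[0, 10, 10] == max(r2[10, 10], r4[10, 10])

    def test_bad_radii(self):
        img = np.zeros((5, 5), dtype=np.uint16)
        with pytest.raises(ValueError, match="empty"):
            aq.tophat_enhance(stack(img), full_mask(img), radii_um=[])
        with pytest.raises(ValueError, match="ascending"):
            aq.tophat_enhance(stack(img), full_mask(img), radii_um=[100, 100])
        with pytest.raises(ValueError, match="below one voxel"):
            aq.tophat_enhance(stack(img), full_mask(img), radii_um=[10.0])


class TestCounting:
    def test_prominence_filter(self):
        enh = np.zeros((20, 20), dtype=np.uint16)
        enh[5, 5] = 40
        enh[15, 15] = 5
        res = aq.count_airspaces(stack(enh), full_mask(enh), h_depth=10)
        assert res.nas_per_slice.tolist() == [1]
        assert res.peaks[0].tolist() == [0, 5, 5]

    def test_flat_zero_image_counts_nothing(self):
        enh = np.zeros((10, 10), dtype=np.uint16)
        res = aq.count_airspaces(stack(enh), full_mask(enh), h_depth=10)
        assert res.nas_per_slice.tolist() == [0]

    def test_plateau_counts_once_at_centroid(self):
        enh = np.zeros((15, 15), dtype=np.uint16)
        enh[6:9, 4:9] = 70  # 3x5 plateau, centroid (7, 6)
        res = aq.count_airspaces(stack(enh), full_mask(enh), h_depth=10)
        assert res.nas_per_slice.tolist() == [1]
        assert res.peaks[0].tolist() == [0, 7, 6]

    def test_close_maxima_merge_keeping_highest(self):
        enh = np.zeros((12, 12), dtype=np.uint16)
        enh[5, 5] = 50
        enh[5, 6] = 0  # gap so they are separate regional maxima
        enh[5, 7] = 60
        res = aq.count_airspaces(stack(enh), full_mask(enh), h_depth=10,
                                 min_separation_um=3 * 47.7)
        assert res.nas_per_slice.tolist() == [1]
        assert res.peaks[0].tolist() == [0, 5, 7]

    def test_h_depth_must_be_positive(self):
        enh = np.zeros((5, 5), dtype=np.uint16)
        with pytest.raises(ValueError):
            aq.count_airspaces(stack(enh), full_mask(enh), h_depth=0)

    def test_exact_recovery_on_noiseless_phantom(self, crisp_scene):
        spec, truth, image, mask = crisp_scene
        labelmap, _ = segment_chain(image, mask)
        assert np.array_equal(labelmap.nas_per_slice, truth.open_count_per_slice())


class TestDelineation:
    def test_two_discs_split_by_septum(self):
        img = np.full((20, 30), 200, dtype=np.uint16)
        yy, xx = np.mgrid[0:20, 0:30]
        left = (yy - 10) ** 2 + (xx - 9) ** 2 <= 16
        right = (yy - 10) ** 2 + (xx - 20) ** 2 <= 16
        img[left] = 50
        img[right] = 50
        peaks = aq.AirspaceLabelMap(
            peaks=np.array([[0, 10, 9], [0, 10, 20]]),
            prominences=np.array([150, 150]),
            nas_per_slice=np.array([2]),
        )
        lm = aq.delineate_airspaces(stack(img), peaks, full_mask(img),
                                    tissue_threshold=125)
        assert lm.nas_per_slice.tolist() == [2]
        septum = ~(left | right)
        assert (lm.labels[0][septum] == 0).all()
        assert (lm.labels[0] == 1).sum() == left.sum()
        assert (lm.labels[0] == 2).sum() == right.sum()

    def test_single_peak_fills_uniform_disc(self):
        img = np.full((25, 25), 200, dtype=np.uint16)
        yy, xx = np.mgrid[0:25, 0:25]
        d = (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        img[d] = 50
        peaks = aq.AirspaceLabelMap(
            peaks=np.array([[0, 12, 12]]), prominences=np.array([150]),
            nas_per_slice=np.array([1]),
        )
        lm = aq.delineate_airspaces(stack(img), peaks, full_mask(img),
                                    tissue_threshold=125)
        assert (lm.labels[0] > 0).sum() == d.sum()

    def test_peak_on_tissue_is_dropped_and_counted(self):
        img = np.full((10, 10), 200, dtype=np.uint16)
        peaks = aq.AirspaceLabelMap(
            peaks=np.array([[0, 5, 5]]), prominences=np.array([150]),
            nas_per_slice=np.array([1]),
        )
        lm = aq.delineate_airspaces(stack(img), peaks, full_mask(img),
                                    tissue_threshold=125)
        assert lm.dropped_peaks == 1
        assert lm.nas_per_slice.tolist() == [0]

    def test_phantom_areas_match_truth(self, crisp_scene):
        """Noiseless phantom: delineated area of every airspace within 10%
        of ground truth (voxel-exact here by construction)."""
        spec, truth, image, mask = crisp_scene
        labelmap, _ = segment_chain(image, mask)
        for s in range(spec.n_slices):
            pk = labelmap.peaks_in_slice(s)
            for i, p in enumerate(pk):
                tid = truth.label_map[s, p[1], p[2]]
                assert tid > 0
                det = (labelmap.labels[s] == i + 1).sum()
                assert abs(det - truth.areas[tid - 1]) <= 0.1 * truth.areas[tid - 1]


class TestExclusion:
    def build_flooded_fixture(self):
        """60x60 fully-included slice: gas background, 20x25 flooded
        rectangle on the left edge, thin septa attached to it."""
        img = np.full((60, 60), 20000, dtype=np.uint16)
        img[20:40, 0:25] = 45000  # 500-voxel cap at the mask perimeter
        img[28:31, 25:40] = 45000  # septum attached to the cap
        img[45:47, 10:50] = 45000  # free-floating septum
        return img

    def test_flooded_cap_excluded_exactly(self):
        img = self.build_flooded_fixture()
        mask = full_mask(img)
        out = aq.exclude_nonventilated(stack(img), mask, density_threshold=32500,
                                       min_region=300, opening_size=13)
        assert out.excluded_nonventilated.sum() == 500
        assert (out.analyzed.sum() == mask.analyzed.sum() - 500)

    def test_no_dense_voxels_leaves_mask_unchanged(self):
        img = np.full((30, 30), 100, dtype=np.uint16)
        mask = full_mask(img)
        out = aq.exclude_nonventilated(stack(img), mask, density_threshold=100)
        assert out.excluded_nonventilated.sum() == 0

    def test_interior_dense_region_retained(self):
        img = np.full((60, 60), 20000, dtype=np.uint16)
        img[20:40, 20:40] = 45000  # large dense block, far from perimeter
        out = aq.exclude_nonventilated(stack(img), full_mask(img),
                                       density_threshold=32500)
        assert out.excluded_nonventilated.sum() == 0

    def test_threshold_outside_range_rejected(self):
        img = np.full((10, 10), 100, dtype=np.uint16)
        with pytest.raises(ValueError, match="outside"):
            aq.exclude_nonventilated(stack(img), full_mask(img),
                                     density_threshold=5000)

    def test_exclusion_monotonic_in_cap_size(self):
        """Growing the flooded cap never increases the analyzed volume."""
        prev = None
        for width in (15, 20, 25, 30, 40):
            img = np.full((60, 60), 20000, dtype=np.uint16)
            img[15:45, 0:width] = 45000
            out = aq.exclude_nonventilated(stack(img), full_mask(img),
                                           density_threshold=32500)
            analyzed = out.analyzed.sum()
            if prev is not None:
                assert analyzed <= prev
            prev = analyzed

    def test_phantom_flooded_cap_detected(self):
        spec = aq.PhantomSpec(
            domain_radius_mm=2.5, target_count=90,
            mean_airspace_diameter_um=194.0, septal_thickness_um=95.4,
            fringe_amplitude=4000.0, flooded_fraction=0.15, n_slices=2, seed=9,
        )
        truth = aq.generate_parenchyma_truth(spec)
        image = aq.render_image(truth, spec)
        out = aq.exclude_nonventilated(image, truth.mask())
        flooded = truth.label_map == -2
        # most of the true cap is excluded ...
        overlap = (out.excluded_nonventilated & flooded).sum() / flooded.sum()
        assert overlap > 0.8
        # ... and anything else excluded is gas-free tissue hugging the cap
        from scipy import ndimage as ndi

        spurious = out.excluded_nonventilated & ~flooded
        assert (truth.label_map[spurious] == 0).all()
        for s in range(spec.n_slices):
            near_cap = ndi.binary_dilation(flooded[s], iterations=15)
            assert (spurious[s] & ~near_cap).sum() == 0


class TestRobustRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_within_5pct_at_10pct_noise(self, seed):
        spec = aq.PhantomSpec(
            domain_radius_mm=2.0, target_count=60,
            mean_airspace_diameter_um=210.0, septal_thickness_um=95.4,
            fringe_amplitude=4000.0, noise_sigma=2500.0, n_slices=2, seed=seed,
        )
        truth = aq.generate_parenchyma_truth(spec)
        image = aq.render_image(truth, spec)
        labelmap, _ = segment_chain(image, truth.mask())
        err = np.abs(labelmap.nas_per_slice - truth.open_count_per_slice())
        assert (err / truth.open_count_per_slice()).mean() <= 0.05
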