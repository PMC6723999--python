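import pytest

import alveoquant as aq


@pytest.fixture(scope="session")
def crisp_spec() -> aq.PhantomSpec:
    """Noiseless phantom meeting the exact-recovery preconditions: septa of
    two voxels and airspace diameters comfortably above four voxels."""
    return aq.PhantomSpec(
        domain_radius_mm=2.0,
        target_count=50,
        mean_airspace_diameter_um=220.0,
        septal_thickness_um=95.4,
        fringe_amplitude=4000.0,
        n_slices=3,
        seed=3,
        diameter_cv=0.03,
    )


@pytest.fixture(scope="session")
def crisp_truth(crisp_spec) -> aq.PhantomTruth:
    return aq.generate_parenchyma_truth(crisp_spec)


@pytest.fixture(scope="session")
def crisp_scene(crisp_spec, crisp_truth):
    """(spec, truth, image, mask) for the noiseless reference phantom."""
    image = aq.render_image(crisp_truth, crisp_spec)
    return crisp_spec, crisp_truth, image, crisp_truth.mask()


def segment_chain(image, mask, **kw):
    """Full detection chain used by several test modules."""
    mask = aq.exclude_nonventilated(image, mask)
    enhanced = aq.tophat_enhance(image, mask, presmooth=kw.get("presmooth", 0.8))
    peaks = aq.count_airspaces(enhanced, mask, h_depth=kw.get("h_depth"))
    return aq.delineate_airspaces(image, peaks, mask), mask


@pytest.fixture(scope="session")
def balloon_series_noiseless():
    """Small noiseless balloon deflation series with known ground truth."""
    spec = aq.PhantomSpec(
        domain_radius_mm=1.8,
        target_count=40,
        mean_airspace_diameter_um=220.0,
        septal_thickness_um=95.4,
        fringe_amplitude=4000.0,
        n_slices=3,
        seed=5,
        diameter_cv=0.03,
    )
    frames = aq.make_peep_series(
        spec, "balloon", (12, 9, 6, 3, 0), (0.0, 0.1, 0.2, 0.3, 0.4)
    )
    return spec, frames
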