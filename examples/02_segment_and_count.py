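"""Detect airspaces on a rendered phantom slice and check against truth.

The chain: exclude non-ventilated regions, enhance gas pockets with a
black top-hat ladder, count prominence-filtered intensity peaks (NAs), then
delineate each peak into its gas region.  On a noiseless phantom the counts
are exact and the delineated areas match the ground truth voxel for voxel.
"""

import numpy as np

import alveoquant as aq

spec = aq.PhantomSpec(
    domain_radius_mm=2.0,
    target_count=60,
    mean_airspace_diameter_um=210.0,
    septal_thickness_um=95.4,
    fringe_amplitude=4000.0,
    noise_sigma=2500.0,  # 10% of the gas/tissue contrast
    n_slices=2,
    seed=4,
)
truth = aq.generate_parenchyma_truth(spec)
image = aq.render_image(truth, spec)
mask = aq.exclude_nonventilated(image, truth.mask())

enhanced = aq.tophat_enhance(image, mask)
peaks = aq.count_airspaces(enhanced, mask)
labelmap = aq.delineate_airspaces(image, peaks, mask)

true_counts = truth.open_count_per_slice()
print("slice  NAs detected  NAs true  gas detected  gas true")
for s in range(spec.n_slices):
    det_gas = int((labelmap.labels[s] > 0).sum())
    print(
        f"{s:5d}  {labelmap.nas_per_slice[s]:12d}  {true_counts[s]:8d}"
        f"  {det_gas:12d}  {truth.gas_area_per_slice()[s]:8d}"
    )
err = np.abs(labelmap.nas_per_slice - true_counts) / true_counts
print(f"\nmean |count error| at 10%-contrast noise: {err.mean():.1%}")
print("(dropped peaks at tissue density:", labelmap.dropped_peaks,
      "- merged fringe-ring duplicates:", labelmap.merged_peaks, ")")
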