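"""The statistical layer on its own: reference slope, paired tests,
multiple-comparison control.

The subpleural group means of the reference decremental-PEEP study,
regressed on the measured pressures, reproduce the published slope of
0.41 voxel/cmH2O.  The Wilcoxon signed-rank test here is exact (full
sign-flip enumeration) for small samples.
"""

import numpy as np
import pandas as pd

import alveoquant as aq

measured_peep = [12.4, 9.6, 6.8, 4.1, 1.1]
sub_asdim = [13.6, 13.0, 10.9, 9.9, 9.4]

table = pd.DataFrame(
    {
        "animal": "ref", "peep_nominal": measured_peep,
        "peep_measured": measured_peep, "slice": range(5), "roi": "SUB",
        "nas": 1, "gas_area_vox": 1, "analyzed_volume_mm3": 1.0,
        "asnum_per_mm3": np.nan, "asdim_vox": sub_asdim,
    }
)
fit = aq.fit_peep_regression(table, "ASdim", "SUB", regressor="measured")
print(
    f"subpleural ASdim vs measured PEEP: m = {fit.m:.4f} (rounds to "
    f"{fit.m:.2f}), k = {fit.k:.2f}, R^2 = {fit.r_squared:.2f}"
)

# paired comparison of the same metric at the two extreme pressures
high = np.array([13.8, 12.9, 14.1, 13.0, 13.6, 13.2])
zeep = np.array([9.1, 7.4, 10.2, 6.9, 8.8, 8.0])
res = aq.wilcoxon_signed_rank(np.c_[high, zeep])
print(
    f"Wilcoxon signed-rank, PEEP 12 vs ZEEP (n={res.n_used}): "
    f"p = {res.p_value:.4f} ({res.method}; exact enumeration of 2^6 sign flips)"
)

# Bonferroni over a family of per-ROI comparisons
family = [0.004, 0.018, 0.021, 0.25]
bonf = aq.bonferroni(family, alpha=0.05)
print(
    f"Bonferroni over m={bonf.m} tests: threshold {bonf.threshold:.4f}, "
    f"decisions {bonf.decisions}"
)
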