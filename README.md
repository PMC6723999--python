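# alveoquant

Quantification of terminal lung airspaces on high-resolution tomographic
slices, built for studying how lungs deflate during a decremental PEEP
(positive end-expiratory pressure) maneuver.

## The problem

In mechanically ventilated, injured (ARDS-like) lungs it matters *how* the
parenchyma gives up gas when pressure is lowered: healthy lungs deflate
mainly by **sequential derecruitment** (whole airspaces close; their number
falls, their size holds), while injured lungs deflate **balloon-like**
(airspaces shrink in proportion; their number holds).  Telling the two
apart requires counting and sizing airspaces on slices where alveoli are
only a few voxels wide and phase-contrast fringes ring every boundary — a
regime where plain density thresholding fails.

`alveoquant` implements the full measurement chain for phase-contrast
micro-CT-like slices (16-bit TIFF stacks, ~47.7 µm voxels) plus a seeded
synthetic phantom so every stage is testable without scanner data:

* **segmentation** — peripheral flooded/atelectatic regions are excluded;
  gas pockets are enhanced with a multi-scale black top-hat ladder
  (closing − image, disc radii 2–6 voxels, voxelwise max); airspaces are
  counted as prominence-filtered intensity peaks (**NAs**) and delineated
  by growing each peak over sub-tissue-density voxels;
* **roi** — the parenchyma is banded by pleural distance: subpleural
  [0, 2) mm, mantellar [2, 4) mm, core [4, ∞) mm;
* **metrics** — per (animal, PEEP, slice, ROI): airspace density
  **ASnum = NAs / V** (units/mm³) and mean airspace extension
  **ASdim = gas area / NAs** (voxels), with ASdim · NAs = gas area exactly;
* **stats** — OLS of each response on the applied PEEP over pooled
  per-slice observations, extra-sum-of-squares F-tests between regressions,
  an exact Wilcoxon signed-rank test, Bonferroni control;
* **phantom / pipeline** — seeded phantom stacks with known airspace truth
  under balloon, derecruitment or mixed deflation, and an end-to-end
  `simulate_experiment` twin of the in-vivo protocol.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

`examples/04_decremental_peep_study.py` deflates one synthetic animal
balloon-style over the 12/9/6/3/0 cmH₂O ladder and runs the whole chain:

```python
import alveoquant as aq

spec = aq.ards_phantom_spec(seed=3, n_slices=10)
sim = aq.simulate_experiment(
    spec, mechanism="balloon",
    fractions=aq.ARDS_DEFLATION_FRACTIONS, fraction_jitter=0.5,
)
print(sim.study.table_layout.to_string(index=False))
```

prints (abridged):

```
response roi      PEEP 12       PEEP 9       PEEP 6       PEEP 3       PEEP 0     m      k   R2      p  significant
   ASdim ALL   13.0 ± 2.0   10.5 ± 1.7    7.9 ± 1.5    8.6 ± 3.4    7.4 ± 3.5  0.47   6.30 0.34 0.0000         True
   ASnum ALL 198.5 ± 34.6 198.5 ± 34.6 198.5 ± 34.6 198.5 ± 34.6 198.6 ± 34.4 -0.01 198.58 0.00 0.9917        False
```

Reading: as PEEP falls from 12 to 0 cmH₂O the mean airspace area drops from
13.0 to 7.4 voxels with a significant slope of 0.47 voxel/cmH₂O, while the
airspace density stays flat at ~199/mm³ — the balloon signature.  Running
the same script with `mechanism="derecruitment"` inverts the pattern
(ASnum falls significantly, ASdim stays flat).  The recovery table in the
same script shows the detector matching the phantom ground truth
(743.9 true vs 743.8–743.9 detected airspaces per slice-average at every
level).

The other examples each exercise one capability: phantom series and their
ground truth (`01`), detection against truth under 10%-contrast noise
(`02`), pleural-distance bands on an analytic disc (`03`), and the
statistical layer alone (`05`), including the reference subpleural
regression of group means on measured PEEP (slope 0.41 voxel/cmH₂O).

A thin CLI mirrors the stages for shell use:

```bash
alveoquant phantom --seed 1 --mechanism balloon --out series/
alveoquant segment --image series/peep12_image.tif --mask series/peep12_mask.tif --out seg/
alveoquant simulate --seed 1 --mechanism derecruitment --out study/
alveoquant run --config study.yaml --out results/
```

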