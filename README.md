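# retrack

Repeated deterministic streamline tractography for fiber-bundle
segmentation in diffusion tensor imaging (DTI).

## The problem

Deterministic streamline tractography — the workhorse of presurgical white
matter mapping — systematically underestimates the spatial extent of large
fiber bundles such as the corticospinal tract: partial-volume averaging
depresses anisotropy at the tract borders, so streamlines concentrate in
the bundle core and the reconstruction depends strongly on where the seed
region was drawn. For neurosurgical planning this underestimation is
dangerous, because resection margins are planned around the reconstructed
tract.

`retrack` implements a re-seeding strategy that recovers the bundle
borders while staying within clinical time budgets:

1. **Initial tracking** — tensor-deflection (TEND) streamlines from a seed
   ROI, restricted by an include ROI (the classic two-ROI approach), and
   rasterized to a binary fiber mask. TEND propagates with
   `v_out ∝ f·e₁ + (1−f)·((1−g)·v_in + g·D̂·v_in)` (defaults f=0, g=1,
   i.e. pure deflection `v_out ∝ D·v_in`).
2. **Centerline** — each streamline is resampled at *n* points by arc
   length and the point-wise average gives the bundle centerline.
3. **Seed-region generation** — at equally spaced centerline points a
   plane perpendicular to the local direction is erected; rays cast in the
   plane find the mask boundary, a closed periodic spline through the
   boundary points defines the seed-region contour, which is moved
   outwards by a scaling offset (SCALING, mm) to reach beyond the initial
   underestimate.
4. **Repeated tracking** — tracking is re-run from every generated region
   (the original ROIs act as *alternative* include regions), each result
   becomes a binary mask, and the masks are summed into a visitation-count
   mask with values 0..n.
5. **Fiber bundle membership (FBM)** — thresholding the count mask at an
   FBM percentage (e.g. FBM 40 = voxels covered by ≥ 40 % of the
   reconstructions) yields the final segmentation.

Segmentations are scored against ground truth with the Dice Similarity
Coefficient, DSC = 2|A∩B| / (|A|+|B|).

A synthetic tensor phantom (curved tube emulating part of the left
corticospinal tract, with partial-volume borders, Stejskal–Tanner signal
synthesis at b = 1000 s/mm² over 30 directions, and complex Gaussian noise
at SNR ≈ 65 and ≈ 32) provides ground-truthed data, and an evaluation
module sweeps the full factorial grid NOISE × SEEDS × SCALING × FBM
(3 × 8 × 6 × 10 = 1440 parameterizations).

## Worked example

```python
import numpy as np
from retrack import (PhantomConfig, SeedPlan, BinaryMask, generate_phantom,
                     run_repeated_tracking, run_two_roi, fbm_threshold, dice)

ph = generate_phantom(PhantomConfig(noise_level=1, rng_seed=7))   # SNR ~65
truth = BinaryMask(ph.truth.bundle_mask, ph.truth.grid)

two_roi = run_two_roi(ph.tensors, ph.truth.seed_roi, ph.truth.include_roi)
print(f"two-ROI baseline DSC: {dice(two_roi, truth):.3f}")

res = run_repeated_tracking(ph.tensors, ph.truth.seed_roi,
                            ph.truth.include_roi, SeedPlan(33, 2.0))
for fbm in (30, 40, 50):
    seg = fbm_threshold(res.count_mask, fbm)
    print(f"repeated, FBM {fbm}: DSC {dice(seg, truth):.3f}")
```

prints:

```
two-ROI baseline DSC: 0.505
repeated, FBM 30: DSC 0.729
repeated, FBM 40: DSC 0.708
repeated, FBM 50: DSC 0.692
```

The two-ROI reconstruction misses the partial-volume border of the bundle
(DSC ≈ 0.51); re-seeding from 33 contours scaled 2 mm outwards recovers it
(DSC ≈ 0.69–0.73 in the preferred FBM 30–50 band).

The same pipeline is scriptable from the shell:

```bash
retrack phantom --noise-level 1 --seed 7 --out ph/
retrack fit --dwi ph/dwi.nii.gz --bval ph/dwi.bval --bvec ph/dwi.bvec --out fit/
retrack repeat --tensors fit/tensor.nii.gz --seed-roi ph/roi_seed.nii.gz \
    --include-roi ph/roi_include.nii.gz --seeds 33 --scaling 2 --fbm 30,40,50 --out rep/
retrack eval --result rep/fbm_40.nii.gz --truth ph/truth_bundle.nii.gz
```

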