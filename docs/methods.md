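# Methods

This note documents the model implemented by `pupilfcm`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Problem and model

Pupil segmentation is a two-class labeling problem (pupil vs everything
else) on 8-bit eye-camera images in which the pupil is the darkest
coherent structure. Pure intensity clustering fails exactly where eye
images are hard: eyelashes and shadows share the pupil's gray range,
specular glints puncture the pupil with near-saturated pixels, and
pupil/iris contrast can be low. The pipeline addresses this by combining
three ingredients around a fuzzy c-means (FCM) core.

**Gray-level histogram FCM.** Instead of clustering N pixels, the
algorithm clusters the occupied gray levels ξ_j, each weighted by its
pixel count γ_j. This is an exact reformulation — γ_j is precisely pixel
multiplicity — and reduces the per-iteration cost from O(N·C) to
O(256·C). The equivalence to per-pixel FCM (uniform prior, shared
initialization, centers within 1e-4) is asserted by test against an
independently implemented per-pixel algorithm.

**Spatial prior.** A Gaussian weight field
W(l) = (1/√(2π))·exp(−‖l−l_c‖²/2σ²) is centered on a pupil-centroid
estimate l_c and reduced to one weight per gray level (mean over the
pixels carrying that level; levels absent from the image get the global
mean weight). Because the per-level weight carries no cluster index it
cancels in the membership normalization; its effect is confined to the
center update, where it pulls each center toward levels that are both
populous and spatially plausible. One consequence is proved numerically
and relied on: the prior's global constant is irrelevant (the printed
normalization of the weight formula is typographically ambiguous; any
positive scale yields identical memberships and centers).

**Reliability-gated local filter.** Each pixel's 5×5 window is screened
against the robust reference x_o = (median + mean)/2: neighbors deviating
from x_o by more than the window RMS deviation σ_k are unreliable and
carry zero weight. Reliable neighbors are weighted by
exp(−d)·exp(−(x_o−x_r)²/(λ_g·σ_g²)), where σ_g² is the mean squared
deviation of the reliable intensities and λ_g controls how strongly
intensity differences suppress a neighbor. The response is a convex
combination of reliable intensities, so it can never leave their range —
a property-tested contract. The filter removes impulse noise and glint
rims while preserving step edges exactly (at a clean two-region border
the minority population is unreliable and contributes nothing).

**Postprocessing.** The minimum converged center is the pupil class; its
value is reported as the "pupil threshold". The mask is a pure
256-entry lookup (maximum membership ⇔ nearest center for a
cluster-independent prior), and the pupil center is the centroid of the
largest 8-connected component (area ≥ `min_area`) after a 3×3 opening.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `n_clusters` C | 5 | – | intensity classes; pupil resolved post hoc as the minimum center |
| `fuzziness` m | 2 | – | membership softness; 2 is the standard choice |
| `max_iter` t | 1000 | iterations | hard stop for the alternating updates |
| `tol` e | 1e-4 | objective units | stop when \|ΔJ\| ≤ e |
| `window` w | 5 | px | local filter window, fixed at 5×5 |
| `lambda_g` λ_g | 3 | – | gray-level influence factor of the filter |
| `sigma` σ | 3 | px | spatial prior width |
| `dark_fraction` | 0.05 | – | pixel share defining the dark set for the centroid estimate |
| `clip_limit` | 0.01 | – | CLAHE clipping (scikit-image normalized convention) |
| `tiles` | 8×8 | – | CLAHE tile grid |
| `min_area` | 50 | px | smallest mask component accepted as pupil |

The first seven are the method's standard experimental settings; the
remaining knobs are implementation defaults chosen once: CLAHE runs
through scikit-image's `equalize_adapthist` (its normalized clip-limit
convention, mild 0.01 default — the clustering, not CLAHE tuning, is the
contribution), and `min_area` = 50 px rejects speckle while accepting
any plausible pupil at the image scales used here.

## Numerical decisions

- **"Middle value" of the window** is the median (13th order statistic),
  chosen because the reference is explicitly meant to resist extreme
  neighborhood values; `center_mode="central"` preserves the
  geometric-center alternative.
- **Reliability threshold is non-strict** (deviation equal to σ_k is
  reliable), so constant windows keep all 25 neighbors and are exact
  fixed points of the filter.
- **σ_g² over the reliable set only**, with an ε = 1e-6 guard: a flat
  reliable neighborhood sets the gray coefficient to 1 rather than 0/0.
- **Borders** use mirror padding so every pixel owns a full window;
  responses are rounded to integers in [0, 255] because the clustering
  operates on integer gray levels.
- **FCM initialization** is deterministic: centers evenly spaced between
  the minimum and maximum occupied level (a seeded random-membership
  alternative exists). Coincident centers are separated by 1e-6; an
  empty cluster is reseeded at the occupied level farthest from the
  surviving centers.
- **Exact center hits** get crisp membership 1 (lowest index on ties),
  removing the singularity of the membership update.
- **Prior normalization inside the solver.** The stopping rule
  \|ΔJ\| ≤ e is absolute while J scales linearly with the prior's
  arbitrary constant, so `run_fcm` rescales the per-level weights to
  unit mean over occupied levels before iterating. This makes the whole
  run — including its iteration count — invariant to the prior's scale
  and keeps e commensurate between weighted and unweighted runs.
- **Prior floor.** With σ = 3 px the raw per-level weights of gray
  levels far from the centroid underflow toward 0 (ratios beyond 1e80 on
  a 200×200 frame), which would make every center update degenerate: all
  centers would collapse onto near-centroid levels. The pipeline
  therefore floors occupied levels at the global mean weight — the same
  fallback the reduction already applies to unoccupied levels —
  preserving the near-centroid enhancement (roughly the image/pupil area
  ratio) while keeping distant levels on a common, well-conditioned
  scale. `reduce_to_gray_levels(..., floor_at_mean=False)` exposes the
  unfloored reduction.
- **Centroid dark set**: the threshold is the largest gray level whose
  cumulative pixel fraction is ≤ `dark_fraction` (fallback: the darkest
  occupied level, so the set is never empty). An interpolated quantile
  would select the background whenever dark pixels are rarer than the
  fraction.
- **Degenerate inputs**: constant images pass through CLAHE unchanged,
  collapse to a single occupied level, and exercise the
  empty-cluster/exact-hit paths without error; the mask is then the
  whole frame and a warning is logged.

## Synthetic data: what it emulates and what it does not

`synthetic.generate_eye` renders a dark pupil ellipse, an iris disk,
bright sclera, specular glint disks (excluded from the truth mask —
a reflection occludes the pupil, it is not pupil tissue), dark
random-walk eyelash strokes from the top edge, a horizontal illumination
ramp, and additive Gaussian noise, all driven by one seed. Difficulty
presets: *clean* (pupil/iris contrast ≥ 60 levels), *glint* (1–3 spots
overlapping the pupil), *low_contrast* (pupil 10–40 vs iris 60–90),
*lashes* (near-pupil-intensity strokes), *mixed* (cycle of the four).
Test-suite problem sizes — 200×200 suites of 30 images end to end,
16×16 for exact filter-oracle agreement, 32×32 for the
histogram/pixel equivalence — were chosen as the smallest scales at
which every structure (pupil, annulus, glints, lashes) is resolved.

Not emulated: off-axis eyelids, corneal reflections off glasses, motion
blur, IR sensor characteristics, photorealistic texture, or video
dynamics. Passing tests therefore demonstrate correctness of the
algorithmic contracts and recovery under the modeled confounders, not
performance on any particular camera.

## Known limitations

- The per-level prior cannot separate two structures sharing the same
  gray level (an eyelash at exactly pupil intensity is indistinguishable
  at the histogram level); it only re-weights levels. Lash-heavy images
  consequently cost AC/SP, which the ablation table reproduces.
- With C greater than the number of distinct intensity modes (e.g. a
  noiseless three-level render), surplus centers crowd the dark mode and
  the minimum-center rule then captures only part of the pupil.
  Realistic sensor noise removes the degeneracy.
- The filter's deliberate outlier replacement reconstructs pupil-valued
  pixels under glint rims; under the glints-are-not-pupil truth
  convention those count as false positives, slightly lowering
  specificity on glint-only imagery even as it stabilizes localization.
- The centroid estimate assumes the darkest pixels belong mainly to one
  pupil; a large dark distractor can bias it (the
  `largest_component=True` pass mitigates, not eliminates, this).
- Histogram clustering quantizes filter responses to integers; sub-level
  contrast below one gray level is invisible to the objective.
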