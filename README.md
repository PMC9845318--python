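# glottalgap

Localization and quantification of posterior glottal gaps from per-frame
vocal-fold segmentation masks.

## The problem

High-speed videoendoscopy (HSV, typically 4000 frames/s at 256 × 256 px)
resolves individual vibratory cycles of the vocal folds, and deep-learning
segmenters turn each frame into a labeled mask with four regions:
background, left vocal fold, right vocal fold, and glottis (the opening
between the folds). The standard readout — the glottal area waveform, the
glottal area per frame — tells a clinician *that* closure is incomplete but
not *where*. For findings such as a posterior (rear) glottal gap, e.g. in
laryngopharyngeal reflux work-ups, the location of the residual opening is
the clinically meaningful quantity.

`glottalgap` implements the geometric post-processing that turns label
masks into localized gap widths, for voice researchers and engineers
working with segmented HSV:

1. **Reference frame** — the frame with the largest glottal area (a robust
   argmax: segmentation noise rarely moves it).
2. **Midline** — points are placed on every contact edge between the left
   and right fold and a least-squares line is fitted by regressing *x on y*:
   slope of x against y is b = Σ(x−x̄)(y−ȳ) / Σ(y−ȳ)², so the fitted glottal
   axis minimizes horizontal residuals and an exactly vertical axis is
   representable (an ordinary y-on-x fit fails as the axis approaches
   vertical).
3. **Collision points** — the midline's entry/exit through the fold∪glottis
   union and through the glottis itself, found by exact traversal of the
   pixel grid.
4. **Anchor ratio** — at the reference frame, the point a fraction f (e.g.
   10%) from the rear of the glottis collision segment is re-expressed as a
   normalized position on the *fold* collision segment and frozen. The fold
   segment exists even when the glottis closes, so the anchor can be
   relocated in every frame and moves, rotates and zooms with the folds.
5. **Gap distance** — per frame, the chord of the glottis region along the
   perpendicular to that frame's midline through the relocated anchor, in
   pixels; 0 when closed.

Groups of subjects (rear glottal gap vs normal closure) are compared with a
linear mixed-effects model fitted by REML — group as fixed effect, a random
intercept per subject — reported as least-squares means with Wald 95%
confidence intervals and a t test on N−2 between-subject degrees of
freedom.

Because clinical HSV databases are private, the package ships a synthetic
phonation-mask simulator (`glottalgap.synthetic`) that renders oscillating
glottis masks with a configurable persistent posterior gap, rotation,
translation, zoom and boundary jitter. It provides ground truth for every
geometric and statistical test.

## Worked example

```python
import pandas as pd
from glottalgap import (
    generate_cohort, measure_sequence, fit_group_comparison,
)

# 20 normal subjects and 30 with a ~4 px posterior gap, 100 frames each
cohort = generate_cohort(n_normal=20, n_gap=30, gap_px=4.0, seed=1)
table = pd.concat(
    [measure_sequence(seq, fractions=[0.10, 0.50]) for seq, _ in cohort],
    ignore_index=True,
)
for f in (0.10, 0.50):
    r = fit_group_comparison(table, f)
    print(
        f"{f:.0%} line: normal {r.lsmean_normal:.2f} px, "
        f"gap {r.lsmean_gap:.2f} px, diff {r.diff:.2f} px "
        f"(95% CI {r.ci95_low:.2f}..{r.ci95_high:.2f}), p = {r.p_value:.3g}"
    )
```

prints

```
10% line: normal 0.16 px, gap 3.48 px, diff 3.32 px (95% CI 2.80..3.84), p = 3.8e-17
50% line: normal 7.76 px, gap 7.12 px, diff -0.64 px (95% CI -1.44..0.17), p = 0.118
```

The 10% line (10% of the way from the rear of the glottis) crosses the
posterior gap: the gap group measures ≈ 3.5 px — the cohort's realized mean
gap of 3.58 px lies inside the confidence interval — while normals measure
almost nothing, and the difference is overwhelmingly significant. The 50%
line sits mid-membranous where both groups oscillate identically, so no
difference is detected. That contrast — significant posteriorly, null at
mid-glottis — is exactly what localized quantification is for.

The same pipeline is scriptable from the shell:

```bash
glottalgap --seed 1 simulate --out cohort/            # PNG masks + ground truth
glottalgap --fractions 0.1,0.5 measure --input cohort/ --out gaps.csv
glottalgap compare --input gaps.csv --out report.md
glottalgap --seed 1 run --out results/                # all three in one go
```

Masks are exchanged as indexed PNGs (left fold blue, right fold yellow,
glottis teal) with a JSON sidecar for fps/subject/group; measurements as
CSV; reports as markdown. `measure --overlays DIR` renders per-frame
overlays of the midline and measurement lines. A `gamma_correct` utility
(v → 255·(v/255)^γ) is included for preprocessing raw frames whose camera
gamma differs from what a segmentation network was trained on.

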