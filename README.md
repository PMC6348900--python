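# shgtensor

Structure-tensor quantification of collagen organization in
second-harmonic-generation (SHG) images of corneal stroma.

SHG microscopy images fibrillar collagen without staining, which makes it the
tool of choice for asking how treatments such as UVA/riboflavin corneal
cross-linking (CXL) change the arrangement of stromal lamellae. Those changes
are often invisible to the eye, so they must be quantified. This package
implements the standard quantitative workflow for depth-sequential SHG stacks
of cornea — and, because no public SHG corneal datasets exist, a synthetic
generator that renders rabbit-like (partially aligned, disorganizing with
depth) and chicken-like (orthogonally interwoven, rotating with depth)
stromal textures with known ground truth, so every stage is testable.

## The measurement

For an image `I(x, y)` the structure tensor is the Gaussian-windowed outer
product of the intensity gradient,

    J = G_rho * [ I_x^2    I_x I_y ]
                [ I_x I_y  I_y^2   ]

with derivatives at scale sigma_g (default 1 µm) and window rho (default
4 µm). Its eigenvalues lambda_1 >= lambda_2 >= 0 give, per pixel,

* **orientation** theta — the direction of the eigenvector of lambda_2
  (along the fibers), axial, in [0°, 180°);
* **degree of isotropy (DoI)** — the coherence
  (lambda_1 − lambda_2)/(lambda_1 + lambda_2) in [0, 1]; 0 for isotropic
  texture, 1 for perfect alignment.

From the orientation field the package derives the **preferential-orientation
(PO) histogram** over [0°, 180°) (coherence-weighted votes, max bin
normalized to 1), detects PO peaks on the circular histogram, computes the
**structural dispersion (SD)** — the standard deviation of the
probability-normalized bin heights, which rises with alignment — and
classifies the arrangement: *nonorganized* (DoI < 0.20 or no PO),
*partially aligned* (0.20 ≤ DoI ≤ 0.70), *highly aligned* (DoI > 0.70).

Group comparisons mirror study practice: Kolmogorov–Smirnov tests between PO
histograms, Welch t-tests on normalized depth-intensity profiles and on mean
DoI pooled by stromal third (anterior / mid / posterior), with significance
at p < 0.05.

## Worked example

```python
import numpy as np
from shgtensor import (SyntheticParams, gen_crosshatch, orientation_field,
                       doi_map, po_histogram, classify_organization)

params = SyntheticParams(
    image_size_px=(512, 512),
    family_orientations_deg=(20.0, 110.0),   # two interwoven families
    concentration_kappa=32.0,                # tight angular dispersion
    fiber_spacing_um=5.0,
    seed=42,
)
image, truth = gen_crosshatch(params)
field = orientation_field(image)
dmap = doi_map(field)
hist = po_histogram(field)
cls = classify_organization(dmap.mean_doi, hist.peaks)

print(f"mean DoI: {dmap.mean_doi:.3f}")
print(f"structural dispersion: {hist.sd:.4f}")
for angle, height in hist.peaks:
    print(f"PO at {angle:.1f} deg (height {height:.2f})")
print(f"organization: {cls.label}")
```

prints

```
mean DoI: 0.634
structural dispersion: 0.0116
PO at 110.8 deg (height 0.93)
PO at 20.8 deg (height 0.89)
organization: partially_aligned
```

Two preferential orientations are recovered within a degree of the requested
families (20° and 110°, i.e. 90° apart), the mean DoI of 0.63 falls in the
partially-aligned band typical of interwoven stroma, and the arrangement is
classified accordingly.

## Command line

```sh
shgtensor generate --orientations 0,90 --n-planes 12 --out stack.tiff
shgtensor preprocess stack.tiff --out pre/
shgtensor tensor stack.tiff --out tensor/
shgtensor run --scenario rabbit_cxl_emulation --seed 1 --out results/
```

`run` executes a full seeded cohort emulation (generate → frame-average →
tensor → statistics) and writes `planes.csv`, `comparison.json`,
`doi_by_location.csv`, a parameter manifest and figures (DoI bars with SD
error bars, normalized depth profiles, PO histograms).

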