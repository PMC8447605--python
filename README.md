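# colocquant

Quantification of multi-marker co-localization and receptor-trafficking
assays in fluorescence micrographs.

When two or three fluorescently labelled markers (say a receptor R, a
second receptor G, and a recycling-endosome marker F such as labelled
transferrin) are imaged by confocal microscopy, the question "do these
molecules occupy the same compartment?" is answered at pixel scale:
within a region of interest (ROI) of *N* pixels, how often and how
strongly do the channels coincide? `colocquant` implements that analysis
end to end, for cell biologists quantifying receptor trafficking and
endosomal co-localization:

* **À trous wavelet band-pass pre-filter.** The undecimated B3-spline
  wavelet transform splits each channel into planes `w_1 … w_J` plus a
  smooth residual with exact reconstruction; dropping the finest plane
  removes single-pixel speckle noise and dropping the residual removes
  diffuse background, leaving the punctate structures of interest.
* **Expression fractions** `F_R = N_R / N` — the fraction of ROI pixels
  where a channel is strictly positive.
* **Overlap fractions** from combined images `I_RG = I_R × I_G` and
  `I_RFG = I_R × I_F × I_G`: `OF_RG = N_RG / N`, `OF_RFG = N_RFG / N`.
* **Manders coefficients** with Costes automatic thresholds:
  `M1 = Σ_{I_G > T_G} I_R / Σ I_R`, `M2 = Σ_{I_R > T_R} I_G / Σ I_G`,
  where `T_R`, `T_G` descend along the orthogonal (total-least-squares)
  regression line between the channels until sub-threshold pixels are
  uncorrelated. A three-marker variant scores `I_FR = I_F × I_R` against
  the third channel with thresholds `T_FR`, `T_G`.
* **Assay quantifiers**: receptor-recycling time courses (percentage of
  receptor-positive cells over DAPI-counted nuclei, referred to time
  zero) with automated nucleus segmentation or manual count tables, and
  the invasion-assay depth ratio (fluorescence beyond 40 µm over total,
  from 20 µm serial sections).
* **Condition statistics**: median ± SD summaries and two-tailed
  Student/Welch t tests with configurable significance stars.
* **Synthetic scene generator**: confocal-like scenes — nuclei,
  membrane rings, Gaussian puncta with a *planted* co-localized
  fraction, read noise and speckle — providing ground truth for every
  stage.

## Worked example

Generate six synthetic three-marker scenes (half of the puncta shared
between channels) and quantify them:

```python
import numpy as np
from colocquant import (SceneParams, generate_scene, ROIMask,
                        compute_all_metrics)

scene, truth = generate_scene(SceneParams(
    channels=("R", "G", "F"), coloc_fraction=0.5,
    speckle_density=0.01, seed=1))
roi = ROIMask.full(scene[0].shape)
m = compute_all_metrics(scene, roi, scene_id="demo")
print(f"F_R={m.f_r:.4f}  OF_RG={m.of_rg:.4f}  OF_RFG={m.of_rfg:.4f}")
print(f"M1={m.m1:.3f}  M2={m.m2:.3f}  T_R={m.costes.t_a:.4f}")
```

prints

```
F_R=0.0359  OF_RG=0.0170  OF_RFG=0.0167
M1=0.484  M2=0.485  T_R=0.0039
```

Read: 3.6% of ROI pixels express the R marker, 1.7% carry both R and G
(and nearly all of those also carry F), and 48% of R intensity sits in
G-positive compartments — matching the planted 50% shared-puncta
fraction. The same pipeline runs from the shell over a manifest of TIFF
files:

```sh
colocquant simulate --n-scenes 6 --coloc-fraction 0.5 --out-dir sim
colocquant coloc sim/manifest.csv --out-dir results
colocquant recycle counts.csv --out-dir recycling
colocquant invade sections.csv --out-dir invasion
```

`coloc` writes `metrics.csv` (one row per scene: `f_r, f_g, f_f, of_rg,
of_rf, of_rfg, m1, m2, t_a, t_b, …`), `comparisons.csv` (pairwise
condition t tests per metric) and a run log with the config digest.

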