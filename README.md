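# brightmux

Computational pipeline for **multispectral brightfield multiplex
immunohistochemistry (IHC)**: chromogenic stains with narrow absorbance
bands, imaged through matched narrow illumination channels on a monochrome
camera, and separated per pixel by spectral unmixing.

Conventional brightfield IHC tops out at two or three stains because
chromogen spectra are broad and color cameras only see RGB. Pairing
narrow-band covalently deposited chromogens with up to 12 narrow
illumination channels turns each pixel into a C-channel absorbance
spectrum, and per-pixel non-negative least squares recovers the relative
concentration of every stain — four or five biomarkers plus a hematoxylin
counterstain on one slide, while keeping the familiar brightfield view.

The package is aimed at people building or validating such imaging
pipelines: it contains the full computational chain plus a synthetic
phantom generator, so everything is testable without slide data.

## The model

Per pixel and illumination channel, with a tissue image and a blank
(tissue-free) image of the same field:

    T = tissue / blank              transmitted fraction (flat-fielded)
    A = -log10(T)                   absorbance (optical density, OD)
    A = E c,  c >= 0                Beer–Lambert mixing

`E` is the channels × chromogens matrix of **normalized extinction
coefficients** — each dye's median on-slide absorbance per channel, scaled
to 1.0 at its strongest channel — measured once from single-stain
calibration slides. Unmixing solves, per pixel,

    c = argmin ||E c − a||₂   subject to   c ≥ 0

Two measured coefficient tables ship as fixtures (`table1_tungsten`, six
filtered-tungsten channels; `table2_led`, twelve filtered-LED channels) for
the chromogens dabsyl, rhodamine 110, TAMRA, sulforhodamine 101,
hematoxylin, and Cy5.

Modules: `spectral_model` (channels, chromogens, calibration, crosstalk),
`radiometry` (counts ↔ transmission ↔ absorbance, TIFF I/O),
`unmixing` (NNLS and pseudo-inverse solvers, residual metrics),
`rendering` (brightfield / fluorescence-like pseudo-color composites),
`phantom` (synthetic scenes, forward acquisition model, knife-edge
targets), `characterization` (auto-exposure, flat-field RMSD, knife-edge
MTF and resolution). See `docs/methods.md` for the full treatment.

## Worked example

Simulate a noisy 8-bit acquisition of a 4-plex assay (4 biomarker
chromogens + hematoxylin, 12 LED channels), unmix it, and check recovery:

```python
import numpy as np
import brightmux as bm

E = bm.table2_led().select_chromogens(["dabsyl", "Rhod110", "TAMRA", "HTX", "Cy5"])
xt = bm.crosstalk_stats(E, ["dabsyl", "Rhod110", "TAMRA", "Cy5"])
print(f"crosstalk min/max/mean: {xt.min:.3f} / {xt.max:.3f} / {xt.mean:.3f}")

scene = bm.make_scene(bm.SceneLayout(), E, seed=1)          # ground truth
tissue, blank = bm.forward_model(scene, bm.DetectorModel(noise="poisson"))
A = bm.to_absorbance(bm.to_transmission(tissue, blank))
result = bm.unmix_stack(A, E)

metrics = bm.residual_metrics(A, result, E)
print(f"mean |residual|: {metrics.mean_abs_error:.4f} OD "
      f"({metrics.relative_error_pct:.2f}% of max absorbance)")
for name in ("dabsyl", "Rhod110", "TAMRA", "Cy5"):
    k = result.chromogens.index(name)
    stained = scene.truth[:, :, k] > 0
    ratio = (np.median(result.values[:, :, k][stained])
             / np.median(scene.truth[:, :, k][stained]))
    print(f"{name:8s} stained-region median recovery: {ratio:.3f}")
```

Output:

```
crosstalk min/max/mean: 0.005 / 0.481 / 0.260
mean |residual|: 0.0315 OD (0.79% of max absorbance)
dabsyl   stained-region median recovery: 1.003
Rhod110  stained-region median recovery: 1.015
TAMRA    stained-region median recovery: 1.016
Cy5      stained-region median recovery: 1.018
```

Neighboring-dye crosstalk up to 0.48 is removed by the unmixing: the
reconstruction misfits the observed absorbance by 0.03 OD on average
(under 1% of the assay's maximum absorbance), and each biomarker's
stained-region median concentration comes back within 2% of ground truth
despite 8-bit shot-noise acquisition. Composites for visual review come
from `render_brightfield` / `render_fluorescence` after
`normalize_abundance`.

The same pipeline is scriptable from the shell:

```sh
brightmux simulate --table table2 --seed 1 --out-dir scene/
brightmux unmix scene/tissue.tif scene/blank.tif --table table2 --out map.tif
brightmux render map.tif --mode brightfield --out composite.png
brightmux characterize scene/blank.tif --out report.json
```

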