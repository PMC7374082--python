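# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `brightmux`, in the order the pipeline runs.

## Imaging model

A multispectral brightfield acquisition illuminates a slide sequentially
with C narrow bandpass channels and records one monochrome frame per
channel, plus a *blank* stack at a tissue-free location. The blank defines
100% transmission per pixel per channel. The radiometric chain is

    T = tissue / blank            (transmitted fraction; flat-fields the image)
    A = -log10(T)                 (absorbance = optical density)

Absorbance is the linear domain: K co-deposited chromogens with per-pixel
concentrations `c >= 0` and a channels-by-chromogens matrix `E` of
normalized extinction coefficients produce `A = E @ c` (Beer–Lambert).

Numerical choices: transmission is clamped to `[1e-4, 1]`, giving an OD
ceiling of 4.0 — deeper densities are not measurable at 8–12 bit detector
depth. Blank pixels of zero counts, over-bright ratios (T > 1), and
saturated raw counts are clamped and *flagged* in a per-pixel validity mask
rather than raised as errors, so whole-field processing never aborts on
isolated dead pixels. Log base 10 matches the optical-density convention;
a natural log would simply rescale all coefficients. No dark-frame
subtraction is applied.

## Reference-spectrum calibration

`build_reference_matrix` measures `E` from one single-stain absorbance
stack per chromogen:

1. **Peak channel** — the channel with the largest *mean* absorbance over
   all pixels, ties broken toward the shorter wavelength. The mean is used
   deliberately: a per-channel median over all pixels is identically zero
   whenever the stain covers less than half the field, which is the normal
   situation on calibration slides, and would make peak detection
   degenerate. Masking and coefficient measurement below still use medians.
2. **Mask** — pixels whose peak-channel absorbance exceeds a threshold
   (default 0.2 OD: well above blank-field noise at 8-bit quantization,
   well below typical stain densities).
3. **Coefficients** — per channel, the median absorbance over masked
   pixels; the column is then divided by its maximum, so every column peaks
   at exactly 1.0.

An empty mask raises a calibration error naming the chromogen. Measured
off-peak coefficients may be slightly negative (blank-field noise around
zero absorbance); they are preserved in `E`, not clipped — non-negativity
belongs to the concentrations, not the basis.

Two measured coefficient tables ship as CSV fixtures: a 6-channel
filtered-tungsten set and a 12-channel filtered-LED set, for six chromogens
(dabsyl, Rhod110, TAMRA, SRhod101, hematoxylin, Cy5). CSVs store 3 decimal
places by default (the tables' printed precision); internal arithmetic is
full double precision.

## Crosstalk statistics

For a wavelength-ordered chromogen subset, `crosstalk_stats` reports, for
each adjacent pair, each dye's normalized coefficient at its neighbor's
peak channel, plus min/max/mean. On the tungsten table this gives
0.034–0.274 for the widely spaced (dabsyl, TAMRA, Cy5) set and a maximum of
0.688 for the full five-dye set. The mean is reported for completeness but
depends on the exact pooling convention, which is less standardized than
the extreme values; only min/max are treated as calibration anchors.

## Spectral unmixing

Per pixel, concentrations solve the non-negative least-squares problem

    c = argmin ||E c - a||_2   s.t.  c >= 0

via `scipy.optimize.nnls`. The stack solver takes a fast path: the
unconstrained least-squares solution is computed for all pixels at once,
and only pixels with a negative component are re-solved by the active-set
NNLS — by the KKT conditions the two coincide wherever the unconstrained
solution is already feasible, so the fast path is exact, not approximate.
An unconstrained pseudo-inverse solver with post-hoc clipping is provided
for comparison; on strictly positive solutions it matches NNLS exactly, and
on noisy data its mean abundance error is never smaller.

A stack may be acquired on a declared subset of the matrix's channels
(assays often oversample); the solver selects the matching rows, requiring
channels >= chromogens and full column rank (rank deficiency raises an
error naming the collinear columns). The counterstain is a regular column
of `E`, so unmixing is always joint over stains plus counterstain.

`residual_metrics` reports the mean absolute reconstruction error
`|E c - a|` over pixels and channels (absorbance units), the same error as
a percentage of the stack's maximum observed absorbance, and a per-channel
split (crosstalk-heavy center wavelengths fit worst).

### Estimator bias under shot noise

The non-negativity constraint makes the per-pixel estimator biased at low
signal-to-noise: for a chromogen absent from a pixel, roughly half the
noise draws would take its unconstrained estimate negative; clipping those
at zero forces the refit to pull down positively correlated columns.
Monte-Carlo analysis at 8-bit, ~220-count acquisition shows stained-region
median abundances of the four narrow-band biomarker chromogens recovered
within 5% (typically 2–4%), while the broad-spectrum hematoxylin
counterstain — correlated with every other column — is systematically 3–8%
low depending on its density. The tests therefore assert 5% recovery for
biomarker chromogens and 10% for the counterstain; the counterstain's role
is morphological context and crosstalk absorption, not quantification.
Noiseless, unquantized acquisitions invert exactly (to 1e-6) for any scene
whose total OD stays below the 4.0 ceiling.

## Rendering

The brightfield composite treats each marker's display color as defining an
RGB extinction vector, its complement: per RGB channel j,

    OD_j = s * sum_k c_k (1 - color_k[j]),    pixel_j = 10^(-OD_j)

with global density scale `s` (default 1). This model is the package's own
definition of pseudo-color compositing: it is additive in OD and
multiplicative in transmission, so overlapping stains darken to a mixed hue
exactly as co-deposited absorbers do under transmitted light, and empty
pixels render white. The fluorescence-like composite is the familiar
additive model `sum_k c_k color_k` clipped at 1 on black.

Planes are normalized per marker before compositing (per-plane maximum by
default; a percentile option, default p = 99, is available because a single
hot pixel otherwise dims an entire plane). Display gamma defaults to 2.2
for screens; use 1.0 for quantitative export. The default palette mimics
the chromogens' visual appearance (yellow dabsyl, purple TAMRA, teal Cy5,
blue hematoxylin) and is fully overridable — color choice is a
visualization aid, not science.

## Synthetic phantom

The phantom generator exists so every stage is testable without slide data.
Scenes are fields of disk nuclei (radius 4–7 px) with a cytoplasmic annulus
(3 px) and thin membrane ring (1.5 px); every nucleus carries the
counterstain and each marker is deposited in a random cell fraction
(default 0.4) with one of the three localizations. Default densities:
marker peak OD 1.0 (a strong chromogenic stain), counterstain OD 0.5 (a
deliberately light hematoxylin), both jittered ±30% per cell; overlapping
deposits add in OD.

The forward model computes `A = E @ c`, `T = 10^-A`, multiplies by an
illumination profile and a per-channel full scale (default 220 counts on an
8-bit detector, emulating an auto-exposed system sitting just below
saturation), then applies optional Poisson shot noise, integer rounding
(on by default; exact-recovery tests disable it), and clipping at the
detector maximum. The default illumination profile is a radially symmetric
quadratic vignette with 15% falloff at the mid-edge and a per-channel
center jitter of 5% of the image size.

All randomness derives from one scene seed fanned out to fixed per-stage
seed sequences (geometry, marker assignment, acquisition noise,
illumination jitter), so enabling noise never changes the geometry draws.

What the phantom does *not* emulate: tissue texture, chromogen
co-deposition interference (later deposits attenuated by earlier ones at
the same site), optical scattering, chromatic focus shifts, stage drift.
Passing phantom tests therefore validates the computational pipeline —
radiometry, unmixing, rendering, characterization — not the histochemistry
of any real assay.

## Optical characterization

**Auto-exposure** iterates a capture function toward a mean blank intensity
of `target_fraction` (default 0.875) of full scale with a saturated-pixel
budget (default 1e-4) and a 2% tolerance: multiplicative steps until the
target is bracketed, then bisection, never more than 50 iterations
(monotone detectors are guaranteed to converge or to report a trace).

**Flat-field RMSD** is the per-channel standard deviation of a blank stack
in counts — zero iff the field is constant, offset-invariant.

**Knife-edge MTF** uses a slanted-edge-style procedure: per-row subpixel
edge localization (gradient centroid) and a straight-line fit for the edge
angle; projection of all pixels onto the edge normal, binned at 0.25 px
into an oversampled edge-spread function (empty bins interpolated);
differentiation to the line-spread profile; Hann window about the peak;
FFT magnitude normalized to MTF(0) = 1, reported up to the 0.5 cycles/px
Nyquist limit. The central-difference derivative's low-pass response
(`sinc(2 f * 0.25)`) is divided out in closed form. Against analytic
oracles the estimator is accurate to ~0.01 contrast at low-to-mid
frequencies for Gaussian edges and the 3%-cutoff resolution is within 2%
(vertical edges) or ~0.5% (slanted edges, the recommended geometry).

**Resolution** is defined as one full cycle at the first 3%-contrast
crossing of the MTF, `pixel_pitch / f_c`, with the crossing found by linear
interpolation. This cycle convention is documented and oracle-tested rather
than anchored to any particular instrument's quoted figure.

Limitation: on single noisy frames the MTF tail is contaminated by the
noise floor of the spectrum magnitude, which can shift the 3% crossing
substantially; characterization protocols should average repeated captures
(the kind of 100-frame averaging used in practice) before edge analysis.

## Problem sizes

Default test and acceptance problem sizes are chosen for fast, deterministic
desk-scale runs: 192×192 scenes with ~120 cells for noisy unmixing studies
(a 192×192×12 stack unmixes in well under a second thanks to the KKT fast
path), 96×96 single-stain stacks for calibration, 128×128 knife-edge
targets. All results above were computed at these sizes; the pipeline is
linear in pixel count.
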