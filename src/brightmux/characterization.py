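"""Optical-system characterization: exposure tuning, field flatness, MTF.

Three measurements qualify a multispectral brightfield imaging system before
it is used on specimens:

* **Auto-exposure** — for each illumination channel, find the exposure time
  at which a blank field sits near the top of the detector's dynamic range
  while keeping the saturated-pixel fraction within budget.
* **Flat-field statistics** — the root-mean-square deviation of each blank
  field summarizes the illumination profile's non-uniformity (blank division
  compensates it during imaging, but flatter fields give better
  signal-to-noise).
* **Knife-edge MTF** — a slanted-edge procedure: locate the edge per row,
  project pixels onto the edge normal, bin into an oversampled edge-spread
  function, differentiate to the line-spread profile, window and Fourier
  transform to the modulation transfer function.  The spatial resolution is
  read off as one full cycle at the frequency where the MTF first drops to a
  cutoff contrast (3% by convention here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .radiometry import ImageStack

__all__ = [
    "ExposureResult",
    "MTFCurve",
    "auto_exposure",
    "flatness_rmsd",
    "knife_edge_mtf",
    "resolution_from_mtf",
    "ExposureError",
]


class ExposureError(RuntimeError):
    """Auto-exposure failed to converge or the detector is unusable."""


@dataclass(frozen=True)
class ExposureResult:
    """Converged state of the auto-exposure loop for one channel."""

    exposure_ms: float
    mean_intensity: float
    saturated_fraction: float
    iterations: int
    trace: tuple = ()

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be > 0")
        if not 0.0 <= self.saturated_fraction <= 1.0:
            raise ValueError("saturated fraction must be in [0, 1]")


def auto_exposure(
    capture: Callable[[float], np.ndarray],
    target_fraction: float = 0.875,
    max_saturated_fraction: float = 1e-4,
    bit_depth: int = 8,
    tol: float = 0.02,
    initial_exposure: float = 1.0,
    min_exposure: float = 1e-6,
    max_iter: int = 50,
) -> ExposureResult:
    """Tune exposure until a blank field nearly fills the dynamic range.

    *capture* maps an exposure time (ms) to a counts image and must be
    monotone nondecreasing in exposure.  The loop first scales the exposure
    multiplicatively toward ``target_fraction * full_scale`` mean intensity,
    then refines by bisection once the target is bracketed; it accepts when
    the mean lies within ``tol`` (fraction of full scale) of the target and
    the saturated-pixel fraction is within budget.

    Raises
    ------
    ExposureError
        If the detector is saturated even at *min_exposure*, or the loop
        fails to converge within *max_iter* iterations (the exception
        message carries the iteration trace).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    full = 2**bit_depth - 1
    target = target_fraction * full
    lo = 0.0  # highest exposure known to undershoot
    hi = np.inf  # lowest exposure known to overshoot / saturate
    exposure = float(initial_exposure)
    trace: list[tuple[float, float, float]] = []
    for iteration in range(1, max_iter + 1):
        img = np.asarray(capture(exposure), dtype=float)
        mean = float(img.mean())
        sat = float((img >= full).mean())
        trace.append((exposure, mean, sat))
        if abs(mean - target) <= tol * full and sat <= max_saturated_fraction:
            return ExposureResult(exposure, mean, sat, iteration, tuple(trace))
        overshoot = mean > target or sat > max_saturated_fraction
        if overshoot:
            if sat >= 1.0 and exposure <= min_exposure:
                raise ExposureError(
                    f"detector fully saturated at minimum exposure "
                    f"{min_exposure} ms"
                )
            hi = min(hi, exposure)
        else:
            lo = max(lo, exposure)
        if np.isfinite(hi) and lo > 0.0:
            exposure = 0.5 * (lo + hi)  # bracketed: bisect
        elif np.isfinite(hi):
            exposure = max(hi / 2.0, min_exposure)
        else:
            # multiplicative step toward the target, bounded
            factor = np.clip(target / max(mean, 1e-9), 1.0, 10.0)
            exposure = exposure * float(factor)
    raise ExposureError(
        f"auto-exposure did not converge in {max_iter} iterations; "
        f"trace (exposure, mean, saturated): {trace}"
    )


def flatness_rmsd(blank: ImageStack) -> np.ndarray:
    """Per-channel RMS deviation of a blank field from its mean, in counts.

    ``RMSD_c = sqrt(mean((pixel - mean_c)**2))`` — zero iff the field is
    constant, and invariant to adding a constant offset.  A surrogate for
    the overall non-uniformity of the illumination profile.
    """
    if blank.domain != "counts":
        raise ValueError(f"expected counts stack, got {blank.domain!r}")
    if blank.pixels.size == 0:
        raise ValueError("empty image")
    flat = blank.pixels.reshape(-1, blank.shape[2])
    return flat.std(axis=0)


@dataclass(frozen=True)
class MTFCurve:
    """Modulation transfer function: contrast vs. spatial frequency.

    Frequencies are in cycles/pixel, ascending from 0; contrast is
    normalized so ``contrast[0] == 1``.
    """

    frequencies: np.ndarray
    contrast: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "contrast", c)
        if f.shape != c.shape or f.ndim != 1:
            raise ValueError("frequencies and contrast must be equal-length 1-D")
        if (f < 0).any() or (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be nonnegative and ascending")
        if abs(c[0] - 1.0) > 1e-9:
            raise ValueError("contrast must be normalized to 1 at zero frequency")

    def at(self, f: float) -> float:
        """Contrast at frequency *f*, linearly interpolated."""
        return float(np.interp(f, self.frequencies, self.contrast))


def _edge_positions(img: np.ndarray) -> np.ndarray:
    """Subpixel edge column per row: centroid of the gradient magnitude
    within a window around the strongest gradient."""
    grad = np.abs(np.gradient(img, axis=1))
    H, W = img.shape
    positions = np.empty(H)
    cols = np.arange(W)
    for y in range(H):
        g = grad[y]
        peak = int(np.argmax(g))
        left, right = max(0, peak - 10), min(W, peak + 11)
        w = g[left:right]
        total = w.sum()
        positions[y] = (cols[left:right] * w).sum() / total if total > 0 else peak
    return positions


def knife_edge_mtf(
    edge: ImageStack,
    channel: Union[str, int],
    bin_width: float = 0.25,
    min_contrast: float = 0.10,
) -> MTFCurve:
    """Estimate the MTF of one channel from a near-vertical knife-edge image.

    Procedure: (1) locate the edge per row at subpixel precision and fit a
    straight line to estimate the edge angle; (2) project every pixel onto
    the edge-normal axis and average into bins of *bin_width* pixels — an
    oversampled edge-spread function; (3) differentiate to the line-spread
    profile; (4) apply a Hann window centered on the profile peak, Fourier
    transform, and normalize the magnitude so MTF(0) = 1.

    Raises
    ------
    ValueError
        If the image contains no detectable edge (intensity swing below
        *min_contrast* of the observed range).
    """
    if isinstance(channel, str):
        idx = edge.channel_set.index(channel)
    else:
        idx = int(channel)
    img = np.asarray(edge.pixels[:, :, idx], dtype=float)
    H, W = img.shape
    swing = img.max() - img.min()
    if swing < min_contrast * max(img.max(), 1e-12):
        raise ValueError(
            f"no detectable edge in channel {channel!r}: intensity swing "
            f"{swing:g} below {min_contrast:.0%} of range"
        )
    # (1) edge line x = a + b*y
    pos = _edge_positions(img)
    rows = np.arange(H)
    b, a = np.polyfit(rows, pos, 1)
    # (2) signed distance of every pixel to the edge line, ESF binning
    yy, xx = np.mgrid[0:H, 0:W]
    d = (xx - (a + b * yy)) / np.hypot(1.0, b)
    half_span = min(abs(d.min()), abs(d.max()))
    keep = np.abs(d) <= half_span
    bins = np.round(d[keep] / bin_width).astype(int)
    offset = bins.min()
    n_bins = bins.max() - offset + 1
    sums = np.bincount(bins - offset, weights=img[keep], minlength=n_bins)
    counts = np.bincount(bins - offset, minlength=n_bins)
    centers = (np.arange(n_bins) + offset) * bin_width
    filled = counts > 0
    esf = np.interp(centers, centers[filled], sums[filled] / counts[filled])
    # (3) differentiate ESF -> line-spread profile
    lsf = np.gradient(esf, bin_width)
    # (4) Hann window about the peak, FFT magnitude, normalize
    peak = int(np.argmax(np.abs(lsf)))
    half = min(peak, len(lsf) - 1 - peak)
    if half < 2:
        raise ValueError("edge too close to the image border to window the profile")
    windowed = lsf[peak - half : peak + half + 1] * np.hanning(2 * half + 1)
    n_fft = max(1024, len(windowed))
    spectrum = np.abs(np.fft.rfft(windowed, n=n_fft))
    if spectrum[0] <= 0:
        raise ValueError("degenerate line-spread profile (zero integral)")
    freqs = np.fft.rfftfreq(n_fft, d=bin_width)
    contrast = spectrum / spectrum[0]
    # undo the central-difference derivative's low-pass response
    # (gradient over +-bin_width attenuates by sinc(2 f bin_width))
    contrast = contrast / np.sinc(2.0 * freqs * bin_width)
    keep_f = freqs <= 0.5  # report up to the pixel Nyquist frequency
    return MTFCurve(freqs[keep_f], contrast[keep_f])


def resolution_from_mtf(
    curve: MTFCurve, cutoff_contrast: float = 0.03, pixel_pitch: float = 1.0
) -> float:
    """Spatial resolution from the MTF's first crossing below a cutoff.

    The crossing frequency ``f_c`` (cycles/pixel) is found by linear
    interpolation; the resolution is one full cycle at that frequency,
    ``pixel_pitch / f_c`` (same length unit as *pixel_pitch*, typically µm).

    Raises
    ------
    ValueError
        If the curve never drops below the cutoff in the measured range, or
        the cutoff is at/above the zero-frequency contrast (crossing at
        f = 0 is degenerate).
    """
    f, c = curve.frequencies, curve.contrast
    if cutoff_contrast >= c[0]:
        raise ValueError(
            f"cutoff contrast {cutoff_contrast} is not below MTF(0) = {c[0]}; "
            "crossing frequency would be zero"
        )
    below = np.flatnonzero(c < cutoff_contrast)
    if below.size == 0:
        raise ValueError(
            f"MTF never drops below {cutoff_contrast} within the measured "
            f"range (min contrast {c.min():.4f})"
        )
    i = int(below[0])
    f_c = f[i - 1] + (c[i - 1] - cutoff_contrast) * (f[i] - f[i - 1]) / (
        c[i - 1] - c[i]
    )
    return pixel_pitch / f_c
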