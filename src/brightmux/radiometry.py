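"""Raw counts -> transmission -> absorbance conversions with blank correction.

A multispectral brightfield acquisition records, per illumination channel,
a monochrome image of transmitted light (raw detector counts) plus a blank
image at a tissue-free location of the slide, which represents 100%
transmission and the full illumination pattern.  Dividing tissue by blank
gives the transmitted fraction per pixel — simultaneously flat-fielding the
image spatially and spectrally — and the decadic log of that fraction is the
absorbance (optical density), the linear domain in which chromogen
contributions add (Beer–Lambert).

Stacks are stored as H x W x C arrays with a declared domain, and can be
round-tripped to multipage TIFF (one page per channel) with a YAML sidecar
carrying channel metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .spectral_model import ChannelSet, LightChannel

__all__ = [
    "ImageStack",
    "to_transmission",
    "to_absorbance",
    "to_transmission_from_absorbance",
    "read_stack",
    "write_stack",
    "TRANSMISSION_FLOOR",
    "ABSORBANCE_CEILING",
]

#: Lower clamp on transmission.  ODs deeper than the corresponding ceiling
#: are unmeasurable at 8–12 bit detector depth.
TRANSMISSION_FLOOR = 1e-4
#: Absorbance ceiling implied by the transmission floor: -log10(1e-4) = 4.
ABSORBANCE_CEILING = 4.0

_DOMAINS = ("counts", "transmission", "absorbance")


@dataclass(frozen=True)
class ImageStack:
    """H x W x C stack of per-channel pixel values with a declared domain.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, C)
        Channel-last image data.  Counts are non-negative and bounded by the
        detector full scale; transmission lies in [0, 1]; absorbance is
        non-negative (after clamping).
    domain : {"counts", "transmission", "absorbance"}
    channel_set : ChannelSet
        C must equal the number of channels; page/plane order is channel order.
    bit_depth : int, optional
        Detector bit depth; meaningful only in the counts domain.
    valid : ndarray of bool, shape (H, W, C), optional
        Per-pixel validity flags (False where a blank was zero or a count
        saturated).  ``None`` means all valid.
    """

    pixels: np.ndarray
    domain: str
    channel_set: ChannelSet
    bit_depth: Optional[int] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3:
            raise ValueError(f"pixels must be H x W x C, got shape {px.shape}")
        if self.domain not in _DOMAINS:
            raise ValueError(f"domain must be one of {_DOMAINS}, got {self.domain!r}")
        if px.shape[2] != len(self.channel_set):
            raise ValueError(
                f"stack has {px.shape[2]} planes but channel set has "
                f"{len(self.channel_set)} channels"
            )
        if self.valid is not None and self.valid.shape != px.shape:
            raise ValueError("validity mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def full_scale(self) -> Optional[int]:
        if self.bit_depth is None:
            return None
        return 2**self.bit_depth - 1

    def validity(self) -> np.ndarray:
        """Validity mask, materialized (all-True if no flags recorded)."""
        if self.valid is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.valid


def _check_same_geometry(a: ImageStack, b: ImageStack) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"shape mismatch: {a.pixels.shape} vs {b.pixels.shape}")
    if a.channel_set.labels != b.channel_set.labels:
        raise ValueError(
            f"channel set mismatch: {a.channel_set.labels} vs {b.channel_set.labels}"
        )


def to_transmission(tissue: ImageStack, blank: ImageStack) -> ImageStack:
    """Divide a tissue stack by its blank stack to get transmitted fraction.

    The blank, acquired at a clear slide location, defines 100% transmission
    per pixel per channel, so the ratio is flat-fielded by construction: any
    illumination pattern common to tissue and blank cancels.

    The ratio is clamped to [``TRANSMISSION_FLOOR``, 1].  Pixels where the
    blank is zero are set to the floor and flagged invalid rather than
    raising, so whole-field processing never aborts on isolated dead pixels;
    over-bright pixels (ratio > 1) are clamped to 1 and flagged; saturated
    raw counts (at full scale, when ``bit_depth`` is set) are flagged too.
    """
    if tissue.domain != "counts" or blank.domain != "counts":
        raise ValueError(
            f"to_transmission expects counts stacks, got {tissue.domain!r} "
            f"and {blank.domain!r}"
        )
    _check_same_geometry(tissue, blank)
    t = np.asarray(tissue.pixels, dtype=float)
    b = np.asarray(blank.pixels, dtype=float)
    valid = tissue.validity() & blank.validity()
    dead = b <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(dead, TRANSMISSION_FLOOR, t / np.where(dead, 1.0, b))
    overbright = T > 1.0
    T = np.clip(T, TRANSMISSION_FLOOR, 1.0)
    valid &= ~dead
    valid &= ~overbright
    for stack in (tissue, blank):
        if stack.full_scale is not None:
            valid &= stack.pixels < stack.full_scale
    return ImageStack(T, "transmission", tissue.channel_set, valid=valid)


def to_absorbance(T: ImageStack) -> ImageStack:
    """Log-transform transmission to absorbance (optical density).

    A = -log10(T); full transmission maps to 0 and the transmission floor
    maps to the ceiling ``ABSORBANCE_CEILING``.
    """
    if T.domain != "transmission":
        raise ValueError(f"expected transmission domain, got {T.domain!r}")
    A = -np.log10(np.clip(T.pixels, TRANSMISSION_FLOOR, 1.0))
    return ImageStack(A, "absorbance", T.channel_set, valid=T.valid)


def to_transmission_from_absorbance(A: ImageStack) -> ImageStack:
    """Invert the log transform: T = 10**(-A).

    Exact inverse of :func:`to_absorbance` (to better than 1e-12) inside the
    clamp-free interior; used to turn rendered composite planes back into a
    brightfield-like representation.
    """
    if A.domain != "absorbance":
        raise ValueError(f"expected absorbance domain, got {A.domain!r}")
    T = np.power(10.0, -np.asarray(A.pixels, dtype=float))
    return ImageStack(T, "transmission", A.channel_set, valid=A.valid)


# ---------------------------------------------------------------------------
# Multipage TIFF I/O with YAML channel sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multipage TIFF (page order = channel order) + sidecar.

    Counts are stored as unsigned integers at the declared bit depth (8-bit
    -> uint8, deeper -> uint16); transmission and absorbance as 32-bit float.
    Channel metadata, domain and bit depth go to ``<path>.yaml``.
    """
    path = Path(path)
    pages = np.moveaxis(stack.pixels, -1, 0)
    if stack.domain == "counts":
        dtype = np.uint8 if (stack.bit_depth or 16) <= 8 else np.uint16
        pages = np.round(pages).astype(dtype)
    else:
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "domain": stack.domain,
        "bit_depth": stack.bit_depth,
        "channels": [
            {"label": c.label, "center_nm": c.center_wavelength, "fwhm_nm": c.fwhm}
            for c in stack.channel_set
        ],
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_stack(path) -> ImageStack:
    """Read a multipage TIFF stack and its YAML sidecar back to an ImageStack."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = yaml.safe_load(_sidecar_path(path).read_text())
    channel_set = ChannelSet(
        tuple(
            LightChannel(str(c["label"]), float(c["center_nm"]), float(c["fwhm_nm"]))
            for c in meta["channels"]
        )
    )
    return ImageStack(
        np.moveaxis(pages, 0, -1).astype(float),
        meta["domain"],
        channel_set,
        bit_depth=meta.get("bit_depth"),
    )
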