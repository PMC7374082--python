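"""Pseudo-color composites from unmixed abundance maps.

Two composite styles are provided.  The *brightfield* renderer treats each
marker's display color as defining an RGB extinction vector — the complement
``1 - color`` — scaled by abundance, sums these optical densities over
markers, and exponentiates back to transmission (``10**-OD``) per RGB
channel.  This is additive in OD and multiplicative in transmission, so
overlapping stains darken to a mixed hue exactly as co-deposited absorbers do
in transmitted light, and an empty pixel renders white.  The *fluorescence*
renderer is the familiar additive model on a black background:
``sum_k c_k * color_k`` clipped at 1.

Abundances are normalized per plane (max or an upper percentile) before
rendering for color balance, and a gamma curve can be applied for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .unmixing import AbundanceMap

__all__ = [
    "RenderSpec",
    "DEFAULT_PALETTE",
    "normalize_abundance",
    "render_brightfield",
    "render_fluorescence",
    "apply_gamma",
    "select_markers",
]

#: Named palette loosely mimicking how the chromogens look under the
#: microscope: dabsyl yellow, TAMRA purple, Cy5 teal, Rhod110 red-orange,
#: SRhod101 magenta, hematoxylin blue.
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    "dabsyl": (1.0, 0.85, 0.1),
    "Rhod110": (1.0, 0.45, 0.15),
    "TAMRA": (0.6, 0.2, 0.7),
    "SRhod101": (0.9, 0.2, 0.5),
    "HTX": (0.25, 0.35, 0.8),
    "Cy5": (0.1, 0.7, 0.7),
}

_FALLBACK_COLORS = [
    (1.0, 0.2, 0.2),
    (0.2, 1.0, 0.2),
    (0.2, 0.4, 1.0),
    (1.0, 0.8, 0.1),
    (0.8, 0.2, 0.9),
    (0.1, 0.9, 0.9),
]


@dataclass(frozen=True)
class RenderSpec:
    """Display parameters for compositing.

    Parameters
    ----------
    colors : mapping marker -> RGB triple in [0, 1]
        Markers missing from the mapping fall back to the default palette,
        then to a generic rotation.
    mode : {"brightfield", "fluorescence"}
    included_markers : sequence of str, optional
        Subset of planes to composite; ``None`` means all.
    gamma : float
        Display gamma (out = in ** (1/gamma)); 2.2 suits screens, 1.0 keeps
        values linear for quantitative export.
    normalization : "max" or ("percentile", p)
        Per-plane normalization statistic.
    density_scale : float
        Global OD scale of the brightfield model (1.0 = unit abundance gives
        OD 1 in the complementary channels).
    """

    colors: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    mode: str = "brightfield"
    included_markers: Optional[tuple[str, ...]] = None
    gamma: float = 2.2
    normalization: object = "max"
    density_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("brightfield", "fluorescence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        for name, rgb in self.colors.items():
            arr = np.asarray(rgb, dtype=float)
            if arr.shape != (3,) or arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"invalid RGB for {name!r}: {rgb}")
        norm = self.normalization
        if norm != "max":
            try:
                kind, p = norm
            except (TypeError, ValueError):
                raise ValueError(
                    f"normalization must be 'max' or ('percentile', p), got {norm!r}"
                ) from None
            if kind != "percentile" or not 0 < p <= 100:
                raise ValueError(f"invalid normalization {norm!r}")

    def color_of(self, name: str, index: int) -> np.ndarray:
        if name in self.colors:
            return np.asarray(self.colors[name], dtype=float)
        if name in DEFAULT_PALETTE:
            return np.asarray(DEFAULT_PALETTE[name], dtype=float)
        return np.asarray(_FALLBACK_COLORS[index % len(_FALLBACK_COLORS)], float)


def select_markers(abundance: AbundanceMap, subset: Sequence[str]) -> AbundanceMap:
    """Restrict an abundance map to a marker subset (order of *subset* kept)."""
    return abundance.select(subset)


def normalize_abundance(abundance: AbundanceMap, spec: RenderSpec) -> AbundanceMap:
    """Scale each included plane into [0, 1] for color balancing.

    With ``"max"`` normalization each plane is divided by its maximum; with
    ``("percentile", p)`` by its p-th percentile, then clipped at 1 (robust
    to isolated hot pixels).  An all-zero plane passes through unchanged.
    """
    m = abundance
    if spec.included_markers is not None:
        m = m.select(spec.included_markers)
    if m.values.min() < 0:
        raise ValueError("abundance map has negative values")
    out = np.empty_like(m.values)
    for k in range(m.values.shape[2]):
        plane = m.values[:, :, k]
        if spec.normalization == "max":
            stat = plane.max()
        else:
            stat = float(np.percentile(plane, spec.normalization[1]))
        if stat <= 0:
            out[:, :, k] = 0.0
        else:
            out[:, :, k] = np.clip(plane / stat, 0.0, 1.0)
    return AbundanceMap(out, m.chromogens, m.residual, m.valid)


def _require_normalized(abundance: AbundanceMap) -> None:
    if abundance.values.size and abundance.values.max() > 1.0 + 1e-9:
        raise ValueError(
            "abundance map is not normalized to [0, 1]; call "
            "normalize_abundance first"
        )
    if abundance.values.size and abundance.values.min() < 0:
        raise ValueError("abundance map has negative values")


def render_brightfield(abundance: AbundanceMap, spec: RenderSpec) -> np.ndarray:
    """Composite a normalized map as a white-background brightfield image.

    Per RGB channel j:  OD_j = sum_k c_k * (1 - color_k[j]) * s, then
    pixel_j = 10**(-OD_j), with s = ``spec.density_scale``.  Zero abundance
    gives pure white; increasing any abundance never brightens any channel;
    two overlapping stains multiply their transmissions (Beer–Lambert).

    Returns an H x W x 3 float image in [0, 1].
    """
    _require_normalized(abundance)
    H, W, K = abundance.shape
    od = np.zeros((H, W, 3))
    for k, name in enumerate(abundance.chromogens):
        color = spec.color_of(name, k)
        od += abundance.values[:, :, k:k + 1] * (1.0 - color) * spec.density_scale
    return np.power(10.0, -od)


def render_fluorescence(abundance: AbundanceMap, spec: RenderSpec) -> np.ndarray:
    """Composite a normalized map as a black-background fluorescence-like image.

    pixel = sum_k c_k * color_k, clipped at 1.  Linear in abundance below
    the clip; zero abundance gives black.
    """
    _require_normalized(abundance)
    H, W, K = abundance.shape
    img = np.zeros((H, W, 3))
    for k, name in enumerate(abundance.chromogens):
        img += abundance.values[:, :, k:k + 1] * spec.color_of(name, k)
    return np.clip(img, 0.0, 1.0)


def apply_gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma-correct an image in [0, 1]: out = in ** (1/gamma).

    gamma = 1 is the identity; endpoints 0 and 1 are fixed for any gamma.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    image = np.asarray(image, dtype=float)
    if image.size and (image.min() < 0 or image.max() > 1):
        raise ValueError("image must lie in [0, 1]")
    return np.power(image, 1.0 / gamma)
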