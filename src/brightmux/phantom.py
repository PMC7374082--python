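"""Synthetic phantom generator: scenes, forward acquisition model, test targets.

Every other module in the package can be exercised without real slide data:
this module builds ground-truth chromogen concentration fields that loosely
mimic stained tissue (disk nuclei with a counterstain, nuclear / cytoplasmic
/ membrane markers on random cell subsets), pushes them through a
Beer–Lambert forward model of the acquisition (per-pixel absorbance
``A = E @ c``, transmission ``10**-A``, illumination vignetting, optional
Poisson shot noise, integer quantization, detector clipping), and generates
knife-edge targets for resolution characterization.

All randomness is a pure function of (parameters, seed).  A single scene
seed fans out to fixed per-stage seed sequences (geometry, marker
assignment, acquisition noise, illumination jitter), so enabling one stage's
randomness never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .radiometry import ImageStack
from .spectral_model import ExtinctionMatrix

__all__ = [
    "MarkerRule",
    "SceneLayout",
    "PhantomScene",
    "DetectorModel",
    "make_scene",
    "make_single_stain_scene",
    "forward_model",
    "make_knife_edge",
    "illumination_profile",
]

# spawn keys for per-stage generators hanging off the one scene seed
_STAGE_GEOMETRY = 0
_STAGE_MARKERS = 1
_STAGE_ACQUISITION = 2
_STAGE_ILLUMINATION = 3


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class MarkerRule:
    """How one chromogen is deposited in the scene.

    kind : {"nuclear", "cytoplasm", "membrane"}
        Nuclear markers fill the nucleus disk, cytoplasmic markers the
        annulus around it, membrane markers a thin outer ring.
    fraction : float
        Probability that a given cell expresses the marker.
    mean_od : float
        Mean peak optical density deposited in positive cells; the actual
        per-cell amplitude is jittered ±30% around this.
    """

    kind: str = "nuclear"
    fraction: float = 0.4
    mean_od: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("nuclear", "cytoplasm", "membrane"):
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.mean_od < 0:
            raise ValueError("mean_od must be >= 0")


@dataclass(frozen=True)
class SceneLayout:
    """Geometry and staining rules of a synthetic scene.

    ``markers`` maps chromogen names (columns of the extinction matrix) to
    :class:`MarkerRule`; unmentioned chromogens stay zero.  ``counterstain``
    names the chromogen deposited in every nucleus (pass ``None`` for none),
    at a deliberately light OD as counterstains are in practice.
    """

    shape: tuple[int, int] = (192, 192)
    n_cells: int = 120
    nucleus_radius: tuple[float, float] = (4.0, 7.0)
    cytoplasm_width: float = 3.0
    membrane_width: float = 1.5
    markers: Optional[Mapping[str, MarkerRule]] = None
    counterstain: Optional[str] = "HTX"
    counterstain_od: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        rmin, rmax = self.nucleus_radius
        if not 0 < rmin <= rmax:
            raise ValueError("nucleus_radius must satisfy 0 < min <= max")
        margin = rmax + self.cytoplasm_width + self.membrane_width
        if 2 * margin >= min(self.shape):
            raise ValueError(
                f"cell geometry (outer radius {margin:g}) exceeds image bounds "
                f"{self.shape}"
            )


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth concentration fields plus the matrix that generated them."""

    truth: np.ndarray  # H x W x K, OD-scaled, >= 0
    chromogens: tuple[str, ...]
    E: ExtinctionMatrix
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.truth, dtype=float)
        object.__setattr__(self, "truth", t)
        if t.min() < 0:
            raise ValueError("truth fields must be non-negative")
        if t.shape[2] != len(self.E.chromogen_names):
            raise ValueError("truth planes must match extinction-matrix columns")


def _default_rules(
    names: Sequence[str], counterstain: Optional[str]
) -> dict[str, MarkerRule]:
    kinds = ("nuclear", "cytoplasm", "membrane")
    rules = {}
    i = 0
    for n in names:
        if n == counterstain:
            continue
        rules[n] = MarkerRule(kind=kinds[i % 3], fraction=0.4, mean_od=1.0)
        i += 1
    return rules


def make_scene(layout: SceneLayout, E: ExtinctionMatrix, seed: int) -> PhantomScene:
    """Generate a reproducible synthetic scene for the chromogens of *E*.

    Cells are disks at random positions (kept fully inside the image);
    every nucleus receives the counterstain, and each marker is deposited in
    a random cell subset according to its :class:`MarkerRule`.  Deposits
    from overlapping cells add, as co-deposited absorbers do in OD.
    """
    names = E.chromogen_names
    if layout.counterstain is not None and layout.counterstain not in names:
        raise ValueError(
            f"counterstain {layout.counterstain!r} is not a matrix column {names}"
        )
    markers = dict(
        layout.markers
        if layout.markers is not None
        else _default_rules(names, layout.counterstain)
    )
    unknown = [n for n in markers if n not in names]
    if unknown:
        raise ValueError(f"marker chromogens {unknown} not in matrix columns {names}")

    H, W = layout.shape
    K = len(names)
    truth = np.zeros((H, W, K))
    geom = _stage_rng(seed, _STAGE_GEOMETRY)
    assign = _stage_rng(seed, _STAGE_MARKERS)

    rmin, rmax = layout.nucleus_radius
    outer_margin = rmax + layout.cytoplasm_width + layout.membrane_width
    yy, xx = np.mgrid[0:H, 0:W]
    cs_idx = names.index(layout.counterstain) if layout.counterstain else None

    for _ in range(layout.n_cells):
        cy = geom.uniform(outer_margin, H - outer_margin)
        cx = geom.uniform(outer_margin, W - outer_margin)
        r_nuc = geom.uniform(rmin, rmax)
        r = np.hypot(yy - cy, xx - cx)
        nucleus = r <= r_nuc
        cytoplasm = (r > r_nuc) & (r <= r_nuc + layout.cytoplasm_width)
        r_out = r_nuc + layout.cytoplasm_width
        membrane = (r > r_out) & (r <= r_out + layout.membrane_width)
        region = {"nuclear": nucleus, "cytoplasm": cytoplasm, "membrane": membrane}
        if cs_idx is not None:
            truth[:, :, cs_idx][nucleus] += layout.counterstain_od * assign.uniform(
                0.7, 1.3
            )
        for name, rule in markers.items():
            positive = assign.random() < rule.fraction
            amplitude = rule.mean_od * assign.uniform(0.7, 1.3)
            if positive and rule.mean_od > 0:
                truth[:, :, names.index(name)][region[rule.kind]] += amplitude
    return PhantomScene(truth, names, E, seed)


def make_single_stain_scene(
    E: ExtinctionMatrix,
    chromogen: str,
    seed: int,
    shape: tuple[int, int] = (96, 96),
    n_cells: int = 40,
    mean_od: float = 1.0,
) -> PhantomScene:
    """Scene stained by a single chromogen in every cell — a calibration slide."""
    layout = SceneLayout(
        shape=shape,
        n_cells=n_cells,
        markers={chromogen: MarkerRule(kind="nuclear", fraction=1.0, mean_od=mean_od)},
        counterstain=None,
    )
    return make_scene(layout, E, seed)


# ---------------------------------------------------------------------------
# Detector / acquisition model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectorModel:
    """Acquisition parameters of the simulated monochrome camera.

    full_scale : float or per-channel array
        Mean blank level in counts (default 220, typical of an 8-bit system
        auto-exposed to sit just under saturation).
    noise : {"none", "poisson"}
        Poisson shot noise on the expected count at each pixel.
    quantize : bool
        Round counts to integers (on by default; exact-recovery tests turn
        it off).
    illumination : {"vignette", "flat"} or ndarray
        Per-channel illumination profile.  "vignette" builds a radially
        symmetric quadratic falloff (``edge_falloff`` at the mid-edge) whose
        center is jittered per channel; an explicit H x W x C array in
        (0, 1] may be supplied instead.
    """

    bit_depth: int = 8
    full_scale: Union[float, Sequence[float]] = 220.0
    noise: str = "none"
    quantize: bool = True
    illumination: Union[str, np.ndarray] = "vignette"
    edge_falloff: float = 0.15
    center_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        fs = np.atleast_1d(np.asarray(self.full_scale, dtype=float))
        if (fs > 2**self.bit_depth - 1).any():
            raise ValueError("full_scale exceeds the detector maximum count")
        if (fs <= 0).any():
            raise ValueError("full_scale must be positive")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


def illumination_profile(
    detector: DetectorModel, shape: tuple[int, int], n_channels: int, seed: int
) -> np.ndarray:
    """H x W x C illumination field in (0, 1] for the given detector model."""
    H, W = shape
    if isinstance(detector.illumination, np.ndarray):
        prof = np.asarray(detector.illumination, dtype=float)
        if prof.shape != (H, W, n_channels):
            raise ValueError(
                f"illumination profile shape {prof.shape} != {(H, W, n_channels)}"
            )
        if prof.min() <= 0 or prof.max() > 1:
            raise ValueError("illumination profile must lie in (0, 1]")
        return prof
    if detector.illumination == "flat":
        return np.ones((H, W, n_channels))
    if detector.illumination != "vignette":
        raise ValueError(f"unknown illumination model {detector.illumination!r}")
    rng = _stage_rng(seed, _STAGE_ILLUMINATION)
    yy, xx = np.mgrid[0:H, 0:W]
    half = min(H, W) / 2.0
    prof = np.empty((H, W, n_channels))
    for c in range(n_channels):
        cy = (H - 1) / 2.0 + rng.uniform(-1, 1) * detector.center_jitter * min(H, W)
        cx = (W - 1) / 2.0 + rng.uniform(-1, 1) * detector.center_jitter * min(H, W)
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / half**2
        prof[:, :, c] = 1.0 - detector.edge_falloff * r2
    return np.clip(prof, 1e-3, 1.0)


def _detect(
    expected: np.ndarray, detector: DetectorModel, rng: np.random.Generator
) -> np.ndarray:
    counts = expected
    if detector.noise == "poisson":
        counts = rng.poisson(np.maximum(counts, 0.0)).astype(float)
    if detector.quantize:
        counts = np.round(counts)
    return np.clip(counts, 0.0, detector.max_count)


def forward_model(
    scene: PhantomScene, detector: DetectorModel
) -> tuple[ImageStack, ImageStack]:
    """Simulate acquisition of a scene: returns (tissue, blank) counts stacks.

    Per pixel: absorbance ``A = E @ c``, transmission ``T = 10**-A``; the
    blank is ``profile * full_scale`` and the tissue ``T *`` that, each then
    passed through the detector (Poisson noise, rounding, clipping) as
    configured.
    """
    H, W, K = scene.truth.shape
    E = scene.E.E
    n_ch = E.shape[0]
    A = scene.truth.reshape(-1, K) @ E.T
    T = np.power(10.0, -A).reshape(H, W, n_ch)
    prof = illumination_profile(detector, (H, W), n_ch, scene.seed)
    fs = np.broadcast_to(
        np.atleast_1d(np.asarray(detector.full_scale, dtype=float)), (n_ch,)
    )
    blank_expected = prof * fs
    tissue_expected = T * blank_expected
    rng = _stage_rng(scene.seed, _STAGE_ACQUISITION)
    tissue = _detect(tissue_expected, detector, rng)
    blank = _detect(blank_expected, detector, rng)
    cs = scene.E.channel_set
    return (
        ImageStack(tissue, "counts", cs, bit_depth=detector.bit_depth),
        ImageStack(blank, "counts", cs, bit_depth=detector.bit_depth),
    )


# ---------------------------------------------------------------------------
# Characterization targets
# ---------------------------------------------------------------------------


def make_knife_edge(
    detector: DetectorModel,
    channel_set,
    shape: tuple[int, int],
    edge_position: float,
    blur_sigma: Union[float, Sequence[float]],
    seed: int,
    angle_deg: float = 0.0,
    dark_fraction: float = 0.05,
) -> ImageStack:
    """Simulate a knife-edge target: dark left half, bright right half.

    The ideal step at subpixel column *edge_position* (optionally tilted by
    *angle_deg* from vertical) is convolved with a per-channel Gaussian PSF
    of width *blur_sigma* and sampled at pixel centers: the edge profile is
    the Gaussian CDF of the signed distance to the edge line.  ``sigma = 0``
    gives a pure step.  Illumination, noise and quantization follow the
    detector model.
    """
    H, W = shape
    if not 0 < edge_position < W:
        raise ValueError(f"edge_position {edge_position} outside (0, {W})")
    n_ch = len(channel_set)
    sigmas = np.broadcast_to(
        np.atleast_1d(np.asarray(blur_sigma, dtype=float)), (n_ch,)
    )
    if (sigmas < 0).any():
        raise ValueError("blur_sigma must be >= 0")
    yy, xx = np.mgrid[0:H, 0:W]
    theta = np.deg2rad(angle_deg)
    # signed distance to the edge line through (edge_position, H/2)
    d = (xx - edge_position) * np.cos(theta) + (yy - (H - 1) / 2.0) * np.sin(theta)
    esf = np.empty((H, W, n_ch))
    for c, s in enumerate(sigmas):
        esf[:, :, c] = norm.cdf(d / s) if s > 0 else (d >= 0).astype(float)
    prof = illumination_profile(detector, (H, W), n_ch, seed)
    fs = np.broadcast_to(
        np.atleast_1d(np.asarray(detector.full_scale, dtype=float)), (n_ch,)
    )
    expected = (dark_fraction + (1.0 - dark_fraction) * esf) * prof * fs
    rng = _stage_rng(seed, _STAGE_ACQUISITION)
    counts = _detect(expected, detector, rng)
    return ImageStack(counts, "counts", channel_set, bit_depth=detector.bit_depth)
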