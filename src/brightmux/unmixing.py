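"""Per-pixel spectral unmixing of absorbance stacks by non-negative least squares.

In the Beer–Lambert model the absorbance vector ``a`` observed at one pixel
across C illumination channels is a non-negative combination of the chromogen
extinction columns: ``a ≈ E @ c`` with concentrations ``c >= 0``.  Unmixing
solves, per pixel,

    c = argmin ||E c - a||_2   subject to  c >= 0

via NNLS (:func:`scipy.optimize.nnls`).  An unconstrained pseudo-inverse
solver with post-hoc clipping is provided for comparison; on pixels where the
NNLS solution is strictly positive the two agree exactly (KKT conditions).

The stack solver takes a fast path: pixels whose unconstrained least-squares
solution is already non-negative are, by the KKT conditions, at the NNLS
optimum, so only the remaining pixels go through the active-set solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml
from scipy.optimize import nnls

from .radiometry import ImageStack
from .spectral_model import ExtinctionMatrix

__all__ = [
    "AbundanceMap",
    "unmix_pixel",
    "unmix_stack",
    "pinv_unmix_stack",
    "residual_metrics",
    "ResidualMetrics",
    "read_abundance_map",
    "write_abundance_map",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class AbundanceMap:
    """H x W x K map of relative chromogen concentrations (proportional to OD).

    ``values`` are non-negative by construction (the NNLS constraint).
    ``residual`` holds the per-pixel mean absolute fitting residual in
    absorbance units.  Plane order matches the extinction-matrix columns.
    """

    values: np.ndarray
    chromogens: tuple[str, ...]
    residual: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "chromogens", tuple(self.chromogens))
        if v.ndim != 3 or v.shape[2] != len(self.chromogens):
            raise ValueError(
                f"values shape {v.shape} inconsistent with "
                f"{len(self.chromogens)} chromogens"
            )
        if self.residual is not None and self.residual.shape != v.shape[:2]:
            raise ValueError("residual plane must be H x W")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def plane(self, name: str) -> np.ndarray:
        return self.values[:, :, self.chromogens.index(name)]

    def select(self, subset: Sequence[str]) -> "AbundanceMap":
        """Restrict to the chromogens in *subset* (see rendering.select_markers)."""
        subset = list(subset)
        if not subset:
            raise ValueError("marker subset is empty")
        unknown = [n for n in subset if n not in self.chromogens]
        if unknown:
            raise KeyError(f"unknown markers {unknown}; have {self.chromogens}")
        idx = [self.chromogens.index(n) for n in subset]
        return AbundanceMap(
            self.values[:, :, idx], tuple(subset), self.residual, self.valid
        )


def _check_basis(E: np.ndarray, names: Sequence[str]) -> None:
    C, K = E.shape
    if C < K:
        raise ValueError(
            f"underdetermined system: {C} channels for {K} chromogens"
        )
    if np.linalg.matrix_rank(E, tol=_RANK_RTOL * np.linalg.norm(E)) < K:
        # name the (nearly) collinear column pairs for the error message
        norms = np.linalg.norm(E, axis=0)
        G = (E / np.where(norms == 0, 1.0, norms)).T @ (
            E / np.where(norms == 0, 1.0, norms)
        )
        bad = [
            (names[i], names[j])
            for i in range(K)
            for j in range(i + 1, K)
            if abs(G[i, j]) > 1 - 1e-9
        ]
        raise ValueError(
            f"extinction matrix is rank deficient; collinear columns: {bad or names}"
        )


def _subset_basis(
    A: ImageStack, E: ExtinctionMatrix
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Rows of E matching the stack's channels (declared-subset support)."""
    if A.channel_set.labels == E.channel_set.labels:
        Em = E.E
    else:
        try:
            rows = [E.channel_set.index(l) for l in A.channel_set.labels]
        except KeyError as exc:
            raise ValueError(
                f"stack channels {A.channel_set.labels} are not a subset of the "
                f"matrix channels {E.channel_set.labels}"
            ) from exc
        Em = E.E[rows, :]
    _check_basis(Em, E.chromogen_names)
    return Em, E.chromogen_names


def unmix_pixel(a: np.ndarray, E: ExtinctionMatrix | np.ndarray) -> np.ndarray:
    """Solve one pixel's NNLS problem.

    Parameters
    ----------
    a : array, shape (C,)
        Absorbance vector across the channels of *E*.
    E : ExtinctionMatrix or ndarray (C, K)

    Returns
    -------
    c : array, shape (K,)
        Non-negative concentrations minimizing ||E c - a||_2; deterministic.
    """
    if isinstance(E, ExtinctionMatrix):
        Em, names = E.E, E.chromogen_names
    else:
        Em = np.asarray(E, dtype=float)
        names = tuple(f"col{k}" for k in range(Em.shape[1]))
    a = np.asarray(a, dtype=float)
    if a.shape != (Em.shape[0],):
        raise ValueError(f"absorbance vector shape {a.shape} != ({Em.shape[0]},)")
    _check_basis(Em, names)
    c, _ = nnls(Em, a)
    return c


def _solve_stack(A_flat: np.ndarray, Em: np.ndarray) -> np.ndarray:
    """NNLS for every row of A_flat (pixels x channels) against basis Em."""
    n_pix, _ = A_flat.shape
    K = Em.shape[1]
    # Unconstrained LS first: wherever it is non-negative it satisfies the
    # NNLS KKT conditions, so only the remaining pixels need the active-set
    # solver.
    C_ls = np.linalg.lstsq(Em, A_flat.T, rcond=None)[0].T
    out = np.maximum(C_ls, 0.0)
    needs = np.flatnonzero((C_ls < -1e-12).any(axis=1))
    for i in needs:
        out[i], _ = nnls(Em, A_flat[i])
    return out.reshape(n_pix, K)


def unmix_stack(A: ImageStack, E: ExtinctionMatrix) -> AbundanceMap:
    """Unmix every pixel of an absorbance stack.

    The stack's channel set must equal the matrix's channels or be a declared
    subset of them (the acquisition may oversample; C >= K must still hold).
    The result carries a residual plane: per-pixel mean |E c - a| in
    absorbance units.  Flagged (invalid) pixels are unmixed anyway and keep
    their flag.
    """
    if A.domain != "absorbance":
        raise ValueError(f"expected absorbance stack, got {A.domain!r}")
    Em, names = _subset_basis(A, E)
    H, W, C = A.shape
    flat = A.pixels.reshape(-1, C)
    conc = _solve_stack(flat, Em)
    resid = np.abs(conc @ Em.T - flat).mean(axis=1)
    valid = None
    if A.valid is not None:
        valid = A.valid.all(axis=2)
    return AbundanceMap(
        conc.reshape(H, W, len(names)),
        names,
        residual=resid.reshape(H, W),
        valid=valid,
    )


def pinv_unmix_stack(A: ImageStack, E: ExtinctionMatrix) -> AbundanceMap:
    """Unconstrained (pseudo-inverse) unmixing with negatives clipped to zero.

    The matrix-inverse alternative to NNLS: ``c = pinv(E) a`` followed by
    clipping at zero.  On pixels whose NNLS solution is strictly positive in
    every component the two methods coincide; elsewhere clipping is generally
    suboptimal in the least-squares sense.
    """
    if A.domain != "absorbance":
        raise ValueError(f"expected absorbance stack, got {A.domain!r}")
    Em, names = _subset_basis(A, E)
    H, W, C = A.shape
    flat = A.pixels.reshape(-1, C)
    conc = np.maximum(flat @ np.linalg.pinv(Em).T, 0.0)
    resid = np.abs(conc @ Em.T - flat).mean(axis=1)
    valid = A.valid.all(axis=2) if A.valid is not None else None
    return AbundanceMap(
        conc.reshape(H, W, len(names)),
        names,
        residual=resid.reshape(H, W),
        valid=valid,
    )


@dataclass(frozen=True)
class ResidualMetrics:
    """Unmixing-fit residual summary.

    ``mean_abs_error`` — mean over pixels and channels of |E c - a|, in
    absorbance units.  ``relative_error_pct`` — the same error as a
    percentage of the stack's maximum observed absorbance.
    ``per_channel_mae`` — the error split by channel, which localizes where
    in the spectrum crosstalk is hardest to fit.
    """

    mean_abs_error: float
    relative_error_pct: float
    per_channel_mae: np.ndarray
    channel_labels: tuple[str, ...]


def residual_metrics(
    A: ImageStack,
    abundance: AbundanceMap,
    E: ExtinctionMatrix,
    exclude_flagged: bool = False,
) -> ResidualMetrics:
    """Compare an absorbance stack with its unmixed reconstruction E @ c."""
    if A.domain != "absorbance":
        raise ValueError(f"expected absorbance stack, got {A.domain!r}")
    Em, names = _subset_basis(A, E)
    if abundance.chromogens != names:
        raise ValueError(
            f"abundance chromogens {abundance.chromogens} do not match matrix "
            f"columns {names}"
        )
    H, W, C = A.shape
    if abundance.shape[:2] != (H, W):
        raise ValueError("abundance map and stack differ in image size")
    flat_a = A.pixels.reshape(-1, C)
    flat_c = abundance.values.reshape(-1, len(names))
    keep = np.ones(flat_a.shape[0], dtype=bool)
    if exclude_flagged and A.valid is not None:
        keep = A.valid.all(axis=2).reshape(-1)
    if not keep.any():
        raise ValueError("no unflagged pixels to evaluate")
    err = np.abs(flat_c[keep] @ Em.T - flat_a[keep])
    a_max = float(flat_a[keep].max())
    mae = float(err.mean())
    rel = 100.0 * mae / a_max if a_max > 0 else float("nan")
    return ResidualMetrics(
        mean_abs_error=mae,
        relative_error_pct=rel,
        per_channel_mae=err.mean(axis=0),
        channel_labels=A.channel_set.labels,
    )


# ---------------------------------------------------------------------------
# Serialization: multipage float TIFF + YAML plane manifest
# ---------------------------------------------------------------------------


def write_abundance_map(abundance: AbundanceMap, path) -> None:
    """Write planes (+ residual, if present) as 32-bit float multipage TIFF."""
    path = Path(path)
    planes = [abundance.values[:, :, k] for k in range(len(abundance.chromogens))]
    names = list(abundance.chromogens)
    if abundance.residual is not None:
        planes.append(abundance.residual)
        names.append("__residual__")
    tifffile.imwrite(path, np.stack(planes).astype(np.float32))
    path.with_suffix(path.suffix + ".yaml").write_text(
        yaml.safe_dump({"planes": names}, sort_keys=False)
    )


def read_abundance_map(path) -> AbundanceMap:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    names = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())[
        "planes"
    ]
    residual = None
    if names and names[-1] == "__residual__":
        residual = pages[-1].astype(float)
        pages, names = pages[:-1], names[:-1]
    return AbundanceMap(
        np.moveaxis(pages, 0, -1).astype(float), tuple(names), residual=residual
    )
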