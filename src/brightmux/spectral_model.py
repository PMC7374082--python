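"""Chromogens, illumination channels, and the normalized extinction matrix.

In chromogenic multiplex immunohistochemistry each dye (chromogen) is imaged
through a set of narrow illumination channels on a monochrome camera.  The
spectral signature of a chromogen is summarized, at the channel level, by a
column of *normalized extinction coefficients*: the chromogen's median
absorbance in each channel, scaled so its most strongly absorbing channel
equals 1.0.  The channels-by-chromogens matrix of these columns is the basis
used for per-pixel spectral unmixing.

This module defines the channel / chromogen / matrix types, builds reference
matrices from single-stain calibration stacks, computes neighboring-chromogen
crosstalk statistics, and serializes coefficient tables as CSV.  Two measured
coefficient tables (a six-channel filtered-tungsten set and a twelve-channel
filtered-LED set) ship as package fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LightChannel",
    "ChannelSet",
    "Chromogen",
    "ExtinctionMatrix",
    "CrosstalkSummary",
    "CalibrationError",
    "build_reference_matrix",
    "crosstalk_stats",
    "read_coefficient_table",
    "write_coefficient_table",
    "table1_tungsten",
    "table2_led",
]


class CalibrationError(RuntimeError):
    """Raised when a reference spectrum cannot be measured from a stack."""


@dataclass(frozen=True)
class LightChannel:
    """One illumination channel: a bandpass filter on a light source.

    Parameters
    ----------
    label : str
        Short unique name, conventionally the filter center wavelength.
    center_wavelength : float
        Filter center wavelength in nm; must lie in the visible/near range
        (300, 800).
    fwhm : float
        Filter full width at half maximum in nm; must be positive.
    """

    label: str
    center_wavelength: float
    fwhm: float

    def __post_init__(self) -> None:
        if not 300.0 < self.center_wavelength < 800.0:
            raise ValueError(
                f"channel {self.label!r}: center wavelength "
                f"{self.center_wavelength} nm outside (300, 800)"
            )
        if self.fwhm <= 0:
            raise ValueError(f"channel {self.label!r}: FWHM must be > 0")


@dataclass(frozen=True)
class ChannelSet:
    """Ordered collection of illumination channels.

    The order is the acquisition order and is preserved through every image
    stack and coefficient matrix.
    """

    channels: tuple[LightChannel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels: {labels}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([c.center_wavelength for c in self.channels])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def subset(self, labels: Sequence[str]) -> "ChannelSet":
        """New ChannelSet restricted to *labels*, in the order given."""
        return ChannelSet(tuple(self.channels[self.index(l)] for l in labels))

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)


@dataclass(frozen=True)
class Chromogen:
    """A chromogenic dye, identified by name and its peak-absorbance channel."""

    name: str
    peak_channel: str


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Channels-by-chromogens matrix of normalized extinction coefficients.

    ``E[i, k]`` is chromogen ``k``'s relative absorbance in channel ``i``,
    scaled so each column's maximum is 1.0.  Measured off-peak entries may be
    slightly negative (blank-field noise); the column peak is always positive.
    """

    channel_set: ChannelSet
    chromogens: tuple[Chromogen, ...]
    E: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromogens", tuple(self.chromogens))
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        if E.shape != (len(self.channel_set), len(self.chromogens)):
            raise ValueError(
                f"matrix shape {E.shape} does not match "
                f"{len(self.channel_set)} channels x {len(self.chromogens)} chromogens"
            )
        labels = self.channel_set.labels
        for c in self.chromogens:
            if c.peak_channel not in labels:
                raise ValueError(
                    f"chromogen {c.name!r}: peak channel {c.peak_channel!r} "
                    f"not in channel set {labels}"
                )

    @property
    def chromogen_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromogens)

    @property
    def n_channels(self) -> int:
        return len(self.channel_set)

    @property
    def n_chromogens(self) -> int:
        return len(self.chromogens)

    def chromogen_index(self, name: str) -> int:
        try:
            return self.chromogen_names.index(name)
        except ValueError:
            raise KeyError(f"no chromogen named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.E[:, self.chromogen_index(name)]

    def peak_channel(self, name: str) -> str:
        return self.chromogens[self.chromogen_index(name)].peak_channel

    def select_chromogens(self, names: Sequence[str]) -> "ExtinctionMatrix":
        """Sub-matrix keeping only *names* (columns), in the order given."""
        idx = [self.chromogen_index(n) for n in names]
        return ExtinctionMatrix(
            self.channel_set,
            tuple(self.chromogens[i] for i in idx),
            self.E[:, idx],
        )

    def select_channels(self, labels: Sequence[str]) -> "ExtinctionMatrix":
        """Sub-matrix keeping only the channels *labels* (rows).

        Peak channels are re-derived from the remaining rows, so the result
        is self-consistent even if a chromogen's original peak is dropped.
        """
        sub = self.channel_set.subset(labels)
        rows = [self.channel_set.index(l) for l in labels]
        E = self.E[rows, :]
        chroms = tuple(
            Chromogen(c.name, sub.labels[int(np.argmax(E[:, k]))])
            for k, c in enumerate(self.chromogens)
        )
        return ExtinctionMatrix(sub, chroms, E)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.E, columns=list(self.chromogen_names))
        df.insert(0, "label", list(self.channel_set.labels))
        df.insert(1, "center_nm", [c.center_wavelength for c in self.channel_set])
        df.insert(2, "fwhm_nm", [c.fwhm for c in self.channel_set])
        return df


# ---------------------------------------------------------------------------
# Reference-matrix calibration from single-stain stacks
# ---------------------------------------------------------------------------

#: Default mask threshold in absorbance units on the peak channel: well above
#: blank-field noise at 8-bit quantization, well below typical stain OD.
DEFAULT_MASK_THRESHOLD = 0.2


def build_reference_matrix(
    singlestain_stacks: Iterable,
    channel_set: ChannelSet,
    chromogen_names: Sequence[str],
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> ExtinctionMatrix:
    """Measure a normalized extinction matrix from single-stain absorbance stacks.

    For each chromogen's stack: the peak channel is the channel of largest
    median absorbance over all pixels (ties broken toward the shorter
    wavelength); a mask selects pixels whose peak-channel absorbance exceeds
    ``mask_threshold``; the chromogen's coefficient in each channel is the
    median absorbance over masked pixels; finally the column is scaled so the
    strongest channel is exactly 1.0.

    Parameters
    ----------
    singlestain_stacks : iterable of ImageStack
        One absorbance-domain stack per chromogen, all sharing *channel_set*.
    channel_set : ChannelSet
        Common acquisition channels, in order.
    chromogen_names : sequence of str
        Names paired positionally with the stacks.
    mask_threshold : float
        Absorbance threshold on the peak channel delineating stained pixels.

    Returns
    -------
    ExtinctionMatrix
        Column maxima are exactly 1.0.

    Raises
    ------
    CalibrationError
        If a chromogen's mask is empty (threshold too high for the stack).
    ValueError
        On domain or channel-set mismatches.
    """
    stacks = list(singlestain_stacks)
    names = list(chromogen_names)
    if len(stacks) != len(names):
        raise ValueError(
            f"{len(stacks)} stacks but {len(names)} chromogen names"
        )
    columns = []
    chromogens = []
    wavelengths = channel_set.wavelengths
    for name, stack in zip(names, stacks):
        if stack.domain != "absorbance":
            raise ValueError(
                f"stack for {name!r} is in {stack.domain!r} domain, expected absorbance"
            )
        if stack.channel_set.labels != channel_set.labels:
            raise ValueError(
                f"stack for {name!r} has channel set {stack.channel_set.labels}, "
                f"expected {channel_set.labels}"
            )
        A = stack.pixels.reshape(-1, len(channel_set))
        # Peak channel by mean absorbance over all pixels (the median is
        # degenerate when the stain covers less than half the field); ties
        # break toward the shorter wavelength.
        score = A.mean(axis=0)
        best = score >= score.max()
        peak = int(np.flatnonzero(best)[np.argmin(wavelengths[best])])
        mask = A[:, peak] > mask_threshold
        if not mask.any():
            raise CalibrationError(
                f"calibration failed for chromogen {name!r}: no pixels exceed "
                f"mask threshold {mask_threshold} in peak channel "
                f"{channel_set.labels[peak]!r}"
            )
        coeffs = np.median(A[mask], axis=0)
        colmax = coeffs.max()
        if colmax <= 0:
            raise CalibrationError(
                f"calibration failed for chromogen {name!r}: non-positive peak "
                f"median absorbance ({colmax:g})"
            )
        column = coeffs / colmax
        peak_idx = int(np.argmax(column))
        columns.append(column)
        chromogens.append(Chromogen(name, channel_set.labels[peak_idx]))
    return ExtinctionMatrix(channel_set, tuple(chromogens), np.column_stack(columns))


# ---------------------------------------------------------------------------
# Crosstalk statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrosstalkSummary:
    """Neighboring-chromogen crosstalk coefficients and their summary stats.

    ``pairs`` maps ``(dye, neighbor_peak_channel)`` to the dye's normalized
    coefficient at that neighbor's peak channel; two entries per adjacent
    pair in the wavelength ordering.
    """

    pairs: dict = field(default_factory=dict)
    values: tuple[float, ...] = ()

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def crosstalk_stats(
    E: ExtinctionMatrix, chromogen_subset: Sequence[str]
) -> CrosstalkSummary:
    """Crosstalk coefficients between spectrally adjacent chromogens.

    For each adjacent pair (i, i+1) of *chromogen_subset*, ordered by peak
    wavelength, the coefficients reported are E[peak(i+1), i] and
    E[peak(i), i+1]: each dye's normalized absorbance at its neighbor's peak
    channel.  Small values mean well-separated dyes; values approaching 1
    mean strong spectral overlap the unmixing must correct.

    Raises
    ------
    ValueError
        If the subset has fewer than two chromogens, is not ordered by peak
        wavelength, or two chromogens share a peak channel.
    KeyError
        If a name is not a column of *E*.
    """
    names = list(chromogen_subset)
    if len(names) < 2:
        raise ValueError("crosstalk needs at least two chromogens")
    peaks = [E.peak_channel(n) for n in names]
    if len(set(peaks)) != len(peaks):
        raise ValueError(f"chromogens share a peak channel: {dict(zip(names, peaks))}")
    wl = [
        E.channel_set.channels[E.channel_set.index(p)].center_wavelength
        for p in peaks
    ]
    if any(b < a for a, b in zip(wl, wl[1:])):
        raise ValueError(
            f"chromogen subset must be ordered by peak wavelength; got peaks {wl}"
        )
    pairs: dict = {}
    for (name_i, peak_i), (name_j, peak_j) in zip(
        zip(names, peaks), zip(names[1:], peaks[1:])
    ):
        pairs[(name_i, peak_j)] = float(E.column(name_i)[E.channel_set.index(peak_j)])
        pairs[(name_j, peak_i)] = float(E.column(name_j)[E.channel_set.index(peak_i)])
    return CrosstalkSummary(pairs=pairs, values=tuple(pairs.values()))


# ---------------------------------------------------------------------------
# CSV serialization and packaged fixtures
# ---------------------------------------------------------------------------

_META_COLUMNS = ("label", "center_nm", "fwhm_nm")


def write_coefficient_table(E: ExtinctionMatrix, path, decimals: int = 3) -> None:
    """Write *E* as CSV: one row per channel, one column per chromogen.

    Coefficients are written with *decimals* decimal places (default 3,
    matching the printed precision of published tables); pass a larger value
    to preserve more of the float precision.
    """
    df = E.to_dataframe()
    float_fmt = f"%.{decimals}f"
    df.to_csv(path, index=False, float_format=float_fmt)


def read_coefficient_table(path, normalization_tol: float = 1e-9) -> ExtinctionMatrix:
    """Read a coefficient CSV written by :func:`write_coefficient_table`.

    Expects header ``label,center_nm,fwhm_nm,<chromogen...>``.  Each
    chromogen's peak channel is the row of its maximum coefficient.  If any
    column maximum differs from 1.0 by more than *normalization_tol* a
    warning is issued (the matrix is accepted but flagged un-normalized).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed coefficient table {path}: {exc}") from exc
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"coefficient table {path} lacks required columns {missing}; "
            f"header must start with {','.join(_META_COLUMNS)}"
        )
    chromogen_names = [c for c in df.columns if c not in _META_COLUMNS]
    if not chromogen_names:
        raise ValueError(f"coefficient table {path} has no chromogen columns")
    for i, row in df.iterrows():
        for col in ("center_nm", "fwhm_nm", *chromogen_names):
            if not np.isfinite(pd.to_numeric(row[col], errors="coerce")):
                # +2: header line and 1-based numbering
                raise ValueError(
                    f"malformed value {row[col]!r} in column {col!r} at line {i + 2} "
                    f"of {path}"
                )
    channel_set = ChannelSet(
        tuple(
            LightChannel(str(r.label), float(r.center_nm), float(r.fwhm_nm))
            for r in df.itertuples()
        )
    )
    E = df[chromogen_names].to_numpy(dtype=float)
    colmax = E.max(axis=0)
    off = np.abs(colmax - 1.0) > normalization_tol
    if off.any():
        bad = {chromogen_names[k]: float(colmax[k]) for k in np.flatnonzero(off)}
        warnings.warn(
            f"coefficient table {path} is not normalized to unit column maxima: {bad}",
            UserWarning,
            stacklevel=2,
        )
    chromogens = tuple(
        Chromogen(n, channel_set.labels[int(np.argmax(E[:, k]))])
        for k, n in enumerate(chromogen_names)
    )
    return ExtinctionMatrix(channel_set, chromogens, E)


def _load_fixture(name: str) -> ExtinctionMatrix:
    with resources.as_file(
        resources.files("brightmux.data").joinpath(name)
    ) as path:
        return read_coefficient_table(path)


def table1_tungsten() -> ExtinctionMatrix:
    """Measured 6-channel filtered-tungsten coefficient table (packaged fixture)."""
    return _load_fixture("table1_tungsten.csv")


def table2_led() -> ExtinctionMatrix:
    """Measured 12-channel filtered-LED coefficient table (packaged fixture)."""
    return _load_fixture("table2_led.csv")
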