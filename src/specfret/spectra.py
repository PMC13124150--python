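"""Sampled optical traces: emission/absorption spectra and chromatograms.

A :class:`Spectrum` is a pair of equal-length arrays — a strictly increasing
abscissa (nm for optical spectra, mL for chromatograms) and an intensity in
arbitrary units — plus acquisition metadata.  All downstream analyses
(blank subtraction, donor scaling, ratio traces) are pointwise operations on
these arrays; when two traces live on different grids they are first brought
onto the coarser of the two grids by linear interpolation so that no data
are invented.

File format: two-column delimited text (comma or tab, auto-detected), an
optional header line whose first token is non-numeric, decimal points only.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateSpectrumError,
    FormatError,
    GridError,
    RangeError,
)

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "subtract_blank",
    "interpolate_to_grid",
    "common_grid",
    "normalize",
    "locate_maximum",
]


class SpectrumKind(str, Enum):
    EMISSION = "emission"
    ABSORPTION = "absorption"
    CHROMATOGRAM = "chromatogram"


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical trace on a strictly increasing abscissa grid.

    Parameters
    ----------
    abscissa:
        Strictly increasing sample positions (nm or mL), length >= 3.
    intensity:
        Signal values, same length as ``abscissa`` (arbitrary units).
    kind:
        One of ``emission``, ``absorption``, ``chromatogram``.
    excitation_nm:
        Excitation wavelength; mandatory for emission spectra.
    sample_id:
        Free-text sample identifier.
    condition:
        Optional condition label (``apo``, ``zinc``, solvent name, ...).
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: SpectrumKind = SpectrumKind.EMISSION
    excitation_nm: float | None = None
    sample_id: str = ""
    condition: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "abscissa", x)
        object.__setattr__(self, "intensity", y)
        if x.ndim != 1 or y.ndim != 1:
            raise FormatError("abscissa and intensity must be 1-D arrays")
        if x.size != y.size:
            raise FormatError(
                f"length mismatch: {x.size} abscissa vs {y.size} intensity values"
            )
        if x.size < 3:
            raise FormatError(f"spectrum needs >= 3 samples, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise FormatError("non-finite abscissa values")
        if np.any(np.diff(x) <= 0):
            raise FormatError("abscissa must be strictly increasing")
        kind = SpectrumKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is SpectrumKind.EMISSION and self.excitation_nm is None:
            raise FormatError("emission spectra require excitation_nm")

    # -- convenience -------------------------------------------------------

    def __len__(self) -> int:
        return int(self.abscissa.size)

    @property
    def x_min(self) -> float:
        return float(self.abscissa[0])

    @property
    def x_max(self) -> float:
        return float(self.abscissa[-1])

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a replaced intensity array."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def value_at(self, x: float) -> float:
        """Linearly interpolated intensity at a single abscissa point."""
        if not (self.x_min <= x <= self.x_max):
            raise RangeError(f"{x} outside [{self.x_min}, {self.x_max}]")
        return float(np.interp(x, self.abscissa, self.intensity))

    def integral(self, interval: tuple[float, float] | None = None) -> float:
        """Trapezoidal integral, optionally restricted to ``interval``.

        Interval endpoints are included by linear interpolation even when
        they fall between grid points.
        """
        if interval is None:
            return float(np.trapezoid(self.intensity, self.abscissa))
        lo, hi = _check_interval(interval)
        if lo < self.x_min or hi > self.x_max:
            raise RangeError(
                f"interval [{lo}, {hi}] outside data range "
                f"[{self.x_min}, {self.x_max}]"
            )
        inner = (self.abscissa > lo) & (self.abscissa < hi)
        xs = np.concatenate(([lo], self.abscissa[inner], [hi]))
        ys = np.interp(xs, self.abscissa, self.intensity)
        return float(np.trapezoid(ys, xs))


def _check_interval(interval: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise RangeError(f"empty or inverted interval ({lo}, {hi})")
    return lo, hi


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_two_columns(text: str, path: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f for f in line.replace("\t", ",").split(",") if f.strip() != ""]
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            x, y = float(fields[0]), float(fields[1])
        except ValueError:
            if lineno == 1:
                continue  # header line
            continue  # reject non-numeric data rows
        xs.append(x)
        ys.append(y)
    if len(xs) < 3:
        raise FormatError(f"{path}: fewer than 3 numeric rows")
    return np.asarray(xs), np.asarray(ys)


def read_spectrum(
    path: str | os.PathLike[str] | io.TextIOBase,
    kind: SpectrumKind | str = SpectrumKind.EMISSION,
    **metadata,
) -> Spectrum:
    """Read a two-column delimited text file into a validated Spectrum.

    ``metadata`` keys (``excitation_nm``, ``sample_id``, ``condition``) are
    forwarded to the :class:`Spectrum` constructor.  Non-numeric data rows
    are dropped; a leading header line is tolerated.
    """
    if isinstance(path, io.TextIOBase):
        text, name = path.read(), "<stream>"
    else:
        name = os.fspath(path)
        with open(name, "r", encoding="utf-8") as fh:
            text = fh.read()
    x, y = _parse_two_columns(text, name)
    return Spectrum(abscissa=x, intensity=y, kind=SpectrumKind(kind), **metadata)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike[str]) -> None:
    """Write a spectrum as CSV with a one-line header."""
    header = {
        SpectrumKind.CHROMATOGRAM: "volume_mL,intensity",
        SpectrumKind.ABSORPTION: "wavelength_nm,absorbance",
        SpectrumKind.EMISSION: "wavelength_nm,intensity",
    }[spectrum.kind]
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for x, y in zip(spectrum.abscissa, spectrum.intensity):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Grid handling and pointwise arithmetic
# ---------------------------------------------------------------------------

def interpolate_to_grid(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid``; extrapolation is refused."""
    g = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                   dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise RangeError("grid must be a non-empty 1-D array")
    if np.any(np.diff(g) <= 0):
        raise RangeError("grid must be strictly increasing")
    if g[0] < s.x_min or g[-1] > s.x_max:
        raise RangeError(
            f"grid [{g[0]}, {g[-1]}] exceeds data range [{s.x_min}, {s.x_max}]"
        )
    y = np.interp(g, s.abscissa, s.intensity)
    return replace(s, abscissa=g, intensity=y)


def common_grid(a: Spectrum, b: Spectrum,
                interval: tuple[float, float] | None = None) -> np.ndarray:
    """Shared grid for pointwise arithmetic on two spectra.

    The coarser of the two native grids is used, restricted to the overlap
    of both ranges (and to ``interval`` when given), so interpolation only
    ever removes resolution.
    """
    lo = max(a.x_min, b.x_min)
    hi = min(a.x_max, b.x_max)
    if interval is not None:
        ilo, ihi = _check_interval(interval)
        lo, hi = max(lo, ilo), min(hi, ihi)
    if not lo < hi:
        raise GridError("spectra have no overlapping abscissa range")
    step_a = np.median(np.diff(a.abscissa))
    step_b = np.median(np.diff(b.abscissa))
    donor = a if step_a >= step_b else b
    mask = (donor.abscissa >= lo - 1e-12) & (donor.abscissa <= hi + 1e-12)
    g = donor.abscissa[mask]
    if g.size < 2:
        raise GridError("overlap too small for a common grid")
    return g


def subtract_blank(sample: Spectrum, blank: Spectrum,
                   interpolate: bool = True) -> Spectrum:
    """Pointwise ``sample - blank``; metadata is copied from ``sample``.

    With ``interpolate=False`` the grids must match exactly, otherwise both
    traces are resampled onto their common (coarser) grid first.  Negative
    residuals are kept: clipping would bias downstream ratios.
    """
    same = (len(sample) == len(blank)
            and np.array_equal(sample.abscissa, blank.abscissa))
    if not same:
        if not interpolate:
            raise GridError("abscissa grids differ and interpolation disabled")
        g = common_grid(sample, blank)
        sample = interpolate_to_grid(sample, g)
        blank = interpolate_to_grid(blank, g)
    return sample.with_intensity(sample.intensity - blank.intensity)


# ---------------------------------------------------------------------------
# Normalization and peak location
# ---------------------------------------------------------------------------

def normalize(
    s: Spectrum,
    mode: str = "max",
    arg: float | tuple[float, float] | None = None,
) -> Spectrum:
    """Rescale a spectrum by one of three conventions.

    ``max``
        Divide by the maximum intensity (peak becomes 1).
    ``at_abscissa``
        Divide by the (interpolated) intensity at ``arg`` (a position).
    ``region_integral``
        Divide by the trapezoidal integral over ``arg`` (an interval,
        defaulting to the full range), so the integral becomes 1.
    """
    if mode == "max":
        denom = float(np.max(s.intensity))
    elif mode == "at_abscissa":
        if arg is None:
            raise RangeError("at_abscissa mode requires an abscissa argument")
        denom = s.value_at(float(arg))
    elif mode == "region_integral":
        interval = (s.x_min, s.x_max) if arg is None else (arg[0], arg[1])
        denom = s.integral(interval)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not np.isfinite(denom) or denom <= 0:
        raise DegenerateSpectrumError(
            f"normalizer {denom!r} is not positive ({mode} mode)"
        )
    return s.with_intensity(s.intensity / denom)


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available shorter window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if window == 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def locate_maximum(
    s: Spectrum,
    search_interval: tuple[float, float] | None = None,
    smooth_window: int | None = None,
) -> float:
    """Abscissa of the maximum intensity.

    Optionally restricted to ``search_interval`` and preceded by a centered
    moving average of odd width ``smooth_window`` (default: raw argmax, as
    used for reported emission-maximum and elution-volume tables).  Ties
    resolve to the smallest abscissa.
    """
    x, y = s.abscissa, s.intensity.astype(float)
    if smooth_window is not None:
        y = moving_average(y, smooth_window)
    if search_interval is not None:
        lo, hi = _check_interval(search_interval)
        if hi < s.x_min or lo > s.x_max:
            raise RangeError("search interval outside data range")
        mask = (x >= lo) & (x <= hi)
        if not np.any(mask):
            raise RangeError("search interval contains no samples")
        x, y = x[mask], y[mask]
    return float(x[int(np.argmax(y))])
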