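"""Reading, validation, correction and resampling of fluorescence emission spectra.

A :class:`Spectrum` is a wavelength/intensity pair on a strictly increasing
nanometre grid, typically a Laurdan emission scan acquired between 400 and
600 nm.  Before any band-shape analysis the raw scan is corrected for the
spectral sensitivity of the detection channel (a multiplicative
instrument-response curve) and for Raman scattering of the solvent (a blank
recorded on a probe-free sample, subtracted).  Both corrections live in a
:class:`CorrectionBundle`.

All interpolation in this module is linear: emission spectra sampled at
1 nm are smooth on that scale and higher-order schemes introduce ringing
near the steep blue edge of the bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import (
    CoverageError,
    SpectrumParseError,
    SpectrumValidationError,
    WavelengthRangeError,
)

logger = logging.getLogger(__name__)

#: Default acquisition window (nm) of the emission scans.
DEFAULT_WINDOW = (400.0, 600.0)


@dataclass(frozen=True)
class Spectrum:
    """An emission spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray
        Emission wavelengths in nm, strictly increasing.
    intensities : ndarray
        Fluorescence intensities (arbitrary counts), same length.  Negative
        values are tolerated (they occur transiently after blank
        subtraction) but must be clipped before fitting.
    label : str
        Free-text sample label, conventionally ``"system;temperature_C;melittin_uM"``.
    window : tuple of float
        Declared acquisition window in nm; all wavelengths must fall inside.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1:
            raise SpectrumValidationError("wavelengths and intensities must be 1-D")
        if wl.size != it.size:
            raise SpectrumValidationError(
                f"length mismatch: {wl.size} wavelengths vs {it.size} intensities"
            )
        if wl.size < 1:
            raise SpectrumValidationError("a spectrum needs at least 1 sample")
        if not np.all(np.isfinite(wl)):
            raise SpectrumValidationError("non-finite wavelength values")
        if not np.all(np.isfinite(it)):
            raise SpectrumValidationError("non-finite intensity values")
        if np.any(np.diff(wl) <= 0):
            bad = int(np.argmax(np.diff(wl) <= 0))
            raise SpectrumValidationError(
                f"wavelengths must be strictly increasing (violation after index {bad}, "
                f"{wl[bad]:g} -> {wl[bad + 1]:g} nm)"
            )
        lo, hi = self.window
        if wl[0] < lo - 1e-9 or wl[-1] > hi + 1e-9:
            raise SpectrumValidationError(
                f"wavelengths [{wl[0]:g}, {wl[-1]:g}] outside declared window "
                f"[{lo:g}, {hi:g}] nm"
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        """(min, max) wavelength actually sampled, in nm."""
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def intensity_at(self, wavelength: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated intensity at the given wavelength(s).

        Raises
        ------
        WavelengthRangeError
            If any requested wavelength lies outside the sampled span.
        """
        w = np.atleast_1d(np.asarray(wavelength, dtype=float))
        lo, hi = self.span
        if np.any(w < lo) or np.any(w > hi):
            raise WavelengthRangeError(
                f"requested wavelength outside sampled span [{lo:g}, {hi:g}] nm"
            )
        out = np.interp(w, self.wavelengths, self.intensities)
        return out if np.ndim(wavelength) else float(out[0])

    def scaled(self, factor: float) -> "Spectrum":
        """Return a copy with all intensities multiplied by ``factor``."""
        return replace(self, intensities=self.intensities * float(factor))


@dataclass(frozen=True)
class CorrectionBundle:
    """Instrument-response and blank corrections for a measurement session.

    ``response_wavelengths``/``response_factors`` define a multiplicative
    correction (dimensionless, > 0) for the spectral sensitivity of the
    emission channel; ``blank`` is the spectrum of the probe-free sample
    capturing Raman and scattering artifacts.  Either part may be omitted.
    """

    response_wavelengths: Optional[np.ndarray] = None
    response_factors: Optional[np.ndarray] = None
    blank: Optional[Spectrum] = None

    def __post_init__(self) -> None:
        has_w = self.response_wavelengths is not None
        has_f = self.response_factors is not None
        if has_w != has_f:
            raise SpectrumValidationError(
                "instrument response needs both wavelengths and factors"
            )
        if has_w:
            w = np.asarray(self.response_wavelengths, dtype=float)
            f = np.asarray(self.response_factors, dtype=float)
            object.__setattr__(self, "response_wavelengths", w)
            object.__setattr__(self, "response_factors", f)
            if w.size != f.size or w.ndim != 1:
                raise SpectrumValidationError("response arrays must be 1-D, same length")
            if np.any(np.diff(w) <= 0):
                raise SpectrumValidationError("response wavelengths must be increasing")
            if not np.all(np.isfinite(f)) or np.any(f <= 0):
                raise SpectrumValidationError("response factors must be finite and > 0")

    def response_on(self, grid: np.ndarray) -> np.ndarray:
        """Response factors interpolated onto ``grid`` (ones if absent)."""
        if self.response_wavelengths is None:
            return np.ones_like(np.asarray(grid, dtype=float))
        w, f = self.response_wavelengths, self.response_factors
        if grid[0] < w[0] - 1e-9 or grid[-1] > w[-1] + 1e-9:
            raise CoverageError(
                f"instrument response covers [{w[0]:g}, {w[-1]:g}] nm but the "
                f"spectrum needs [{grid[0]:g}, {grid[-1]:g}] nm"
            )
        return np.interp(grid, w, f)

    def blank_on(self, grid: np.ndarray) -> np.ndarray:
        """Blank intensities interpolated onto ``grid`` (zeros if absent)."""
        if self.blank is None:
            return np.zeros_like(np.asarray(grid, dtype=float))
        lo, hi = self.blank.span
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise CoverageError(
                f"blank covers [{lo:g}, {hi:g}] nm but the spectrum needs "
                f"[{grid[0]:g}, {grid[-1]:g}] nm"
            )
        return np.interp(grid, self.blank.wavelengths, self.blank.intensities)


def read_spectrum(
    path: str | Path,
    label: str | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> Spectrum:
    """Read a two-column (wavelength, intensity) text or CSV spectrum.

    Accepts plain whitespace- or comma-separated numeric columns, with an
    optional ``wavelength,intensity`` header line.  A YAML sidecar
    ``<path>.yaml`` with keys ``system``, ``temperature_C`` and
    ``melittin_uM``, when present, supplies the label.

    Raises
    ------
    SpectrumParseError
        Malformed rows (the message names the first offending line).
    SpectrumValidationError
        Duplicate or non-monotone wavelengths, out-of-window values.
    """
    path = Path(path)
    wl: list[float] = []
    it: list[float] = []
    comment_label: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# label:"):
                comment_label = line.removeprefix("# label:").strip()
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if not wl and parts and not _is_number(parts[0]):
                continue  # header line
            if len(parts) < 2 or not (_is_number(parts[0]) and _is_number(parts[1])):
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected two numeric columns, got {line!r}"
                )
            wl.append(float(parts[0]))
            it.append(float(parts[1]))
    if len(wl) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    if len(set(wl)) != len(wl):
        raise SpectrumValidationError(f"{path}: duplicate wavelengths")
    if label is None:
        label = _sidecar_label(path) or comment_label
    return Spectrum(np.array(wl), np.array(it), label=label or "", window=window)


def write_spectrum(s: Spectrum, path: str | Path, header: bool = True) -> None:
    """Write a spectrum as ``wavelength,intensity`` CSV (full float precision).

    A non-empty label is preserved in a ``# label:`` comment line that
    :func:`read_spectrum` understands.
    """
    path = Path(path)
    with open(path, "w") as fh:
        if s.label:
            fh.write(f"# label: {s.label}\n")
        if header:
            fh.write("wavelength,intensity\n")
        for w, i in zip(s.wavelengths, s.intensities):
            fh.write(f"{float(w)!r},{float(i)!r}\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _sidecar_label(path: Path) -> str | None:
    side = path.with_suffix(path.suffix + ".yaml")
    if not side.exists():
        return None
    meta = yaml.safe_load(side.read_text())
    if not isinstance(meta, dict):
        return None
    return "{};{};{}".format(
        meta.get("system", ""), meta.get("temperature_C", ""), meta.get("melittin_uM", "")
    )


def correct_spectrum(
    s: Spectrum,
    corrections: CorrectionBundle,
    order: str = "subtract_then_multiply",
) -> Spectrum:
    """Apply blank subtraction and instrument-response correction.

    The default order subtracts the blank first and multiplies by the
    response afterwards (scattering artifacts are seen through the same
    detector and share its sensitivity); ``order="multiply_then_subtract"``
    applies the response to both sample and blank before subtracting.
    With the default order the output at each wavelength is
    ``max(0, (s - blank) * response)``; negative residuals left by blank
    noise are clipped to zero (with a logged warning) because the band
    fitting requires nonnegative data.
    """
    if order not in ("subtract_then_multiply", "multiply_then_subtract"):
        raise ValueError(f"unknown correction order {order!r}")
    grid = s.wavelengths
    resp = corrections.response_on(grid)
    blank = corrections.blank_on(grid)
    if order == "subtract_then_multiply":
        out = (s.intensities - blank) * resp
    else:
        out = s.intensities * resp - blank * resp
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.warning(
            "clipping %d negative intensities after blank subtraction (%s)",
            n_neg,
            s.label or "unlabelled spectrum",
        )
        out = np.clip(out, 0.0, None)
    return replace(s, intensities=out)


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly resample a spectrum onto a new wavelength grid.

    The new grid must lie within the sampled span (no extrapolation); values
    at shared grid points are reproduced exactly.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid[0] < lo or grid[-1] > hi:
        raise WavelengthRangeError(
            f"resampling grid [{grid[0]:g}, {grid[-1]:g}] exceeds sampled span "
            f"[{lo:g}, {hi:g}] nm"
        )
    return replace(
        s,
        wavelengths=grid,
        intensities=np.interp(grid, s.wavelengths, s.intensities),
    )
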