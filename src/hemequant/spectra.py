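"""Electronic absorption spectra and Beer's-law primitives.

A :class:`Spectrum` is a wavelength/absorbance series recorded in a cuvette
of known pathlength.  All downstream heme quantification reduces to Beer's
law ``A = eps * C * l`` applied at single wavelengths, so the operations
here are deliberately minimal: exact linear interpolation, pointwise
differences on a shared grid, and prominence-based peak picking.  No
smoothing or baseline correction is ever applied implicitly.

Absorbances are stored exactly as read (cuvette scale, pathlength
uncorrected); ``dilution_factor`` is bookkeeping that operations apply only
when they document original-solution output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal


class SpectrumError(ValueError):
    """Malformed spectrum data or an operation outside its domain."""


@dataclass(frozen=True)
class Spectrum:
    """An absorption spectrum: wavelengths (nm, strictly increasing) and
    absorbances (AU), with cuvette pathlength (cm) and the dilution factor
    that maps cuvette concentrations back to the original solution."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    pathlength_cm: float = 1.0
    dilution_factor: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise SpectrumError("wavelengths and absorbances must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise SpectrumError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            if np.any(np.diff(wl) == 0) or wl.size != np.unique(wl).size:
                raise SpectrumError("duplicate wavelengths in spectrum")
            raise SpectrumError("wavelengths must be strictly increasing")
        if self.pathlength_cm <= 0:
            raise SpectrumError("pathlength_cm must be > 0")
        if self.dilution_factor < 1:
            raise SpectrumError("dilution_factor must be >= 1")

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def covers(self, wavelength: float) -> bool:
        return self.wl_min <= wavelength <= self.wl_max

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)


@dataclass(frozen=True)
class PeakList:
    """Detected local maxima: (wavelength nm, absorbance AU, prominence AU),
    sorted by wavelength."""

    peaks: tuple = field(default_factory=tuple)

    def wavelengths(self) -> list:
        return [p[0] for p in self.peaks]

    def to_csv(self) -> str:
        lines = ["wavelength_nm,absorbance,prominence"]
        lines += [f"{w:g},{a:g},{p:g}" for w, a, p in self.peaks]
        return "\n".join(lines) + "\n"


def _sorted_spectrum(wl: np.ndarray, ab: np.ndarray, **kw) -> Spectrum:
    order = np.argsort(wl, kind="stable")
    return Spectrum(wl[order], ab[order], **kw)


def read_spectrum(path, pathlength_cm: float = 1.0, dilution_factor: float = 1.0,
                  label: str = "") -> Spectrum:
    """Read a two-column (wavelength nm, absorbance AU) delimited text file.

    Accepts whitespace, comma, or tab separation; '#' comment lines and an
    optional non-numeric header line are ignored.  The returned spectrum is
    sorted ascending by wavelength; duplicate wavelengths are rejected.
    """
    wl, ab = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            try:
                x, y = float(parts[0]), float(parts[1])
            except (IndexError, ValueError):
                if lineno == 1:  # tolerated header
                    continue
                raise SpectrumError(f"{path}: malformed row at line {lineno}: {raw.rstrip()!r}")
            wl.append(x)
            ab.append(y)
    if len(wl) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data points")
    return _sorted_spectrum(np.array(wl), np.array(ab),
                            pathlength_cm=pathlength_cm,
                            dilution_factor=dilution_factor,
                            label=label or str(path))


def write_spectrum(s: Spectrum, path, header: str = "") -> None:
    """Write the two-column dialect :func:`read_spectrum` consumes."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for w, a in zip(s.wavelengths, s.absorbances):
            fh.write(f"{w:.6g},{a:.8g}\n")


def absorbance_at(s: Spectrum, wavelength: float) -> float:
    """Linear interpolation of absorbance; exact at grid points."""
    if not s.covers(wavelength):
        raise SpectrumError(
            f"wavelength {wavelength} nm outside spectrum range "
            f"[{s.wl_min}, {s.wl_max}] nm")
    return float(np.interp(wavelength, s.wavelengths, s.absorbances))


def beer_concentration(absorbance: float, epsilon: float, pathlength_cm: float = 1.0) -> float:
    """Concentration from Beer's law, ``C = A / (eps * l)``.

    With ``epsilon`` in mM^-1 cm^-1 and ``pathlength_cm`` in cm the result
    is in mM.
    """
    if epsilon <= 0:
        raise SpectrumError("epsilon must be > 0")
    if pathlength_cm <= 0:
        raise SpectrumError("pathlength_cm must be > 0")
    return absorbance / (epsilon * pathlength_cm)


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise ``a - b`` on a's grid over the overlapping range.

    b is linearly interpolated onto a's grid; both spectra must share the
    cuvette pathlength.
    """
    if a.pathlength_cm != b.pathlength_cm:
        raise SpectrumError("difference_spectrum requires equal pathlengths")
    lo, hi = max(a.wl_min, b.wl_min), min(a.wl_max, b.wl_max)
    if lo >= hi:
        raise SpectrumError("spectra do not overlap in wavelength")
    mask = (a.wavelengths >= lo) & (a.wavelengths <= hi)
    if mask.sum() < 2:
        raise SpectrumError("overlap contains fewer than 2 grid points")
    wl = a.wavelengths[mask]
    ab = a.absorbances[mask] - np.interp(wl, b.wavelengths, b.absorbances)
    return Spectrum(wl, ab, pathlength_cm=a.pathlength_cm,
                    dilution_factor=a.dilution_factor,
                    label=f"({a.label})-({b.label})")


def find_peaks(s: Spectrum, min_prominence: float, boxcar: int = 0) -> PeakList:
    """Local maxima with topographic prominence >= ``min_prominence``.

    Operates on the raw points; ``boxcar`` (odd width, default off) is an
    explicit opt-in moving-average smoother applied before peak picking.
    """
    if min_prominence <= 0:
        raise SpectrumError("min_prominence must be > 0")
    y = s.absorbances
    if boxcar:
        if boxcar % 2 == 0 or boxcar < 1:
            raise SpectrumError("boxcar width must be odd and positive")
        y = np.convolve(y, np.ones(boxcar) / boxcar, mode="same")
    idx, props = scipy.signal.find_peaks(y, prominence=min_prominence)
    peaks = tuple(
        (float(s.wavelengths[i]), float(s.absorbances[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    )
    return PeakList(peaks=peaks)
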