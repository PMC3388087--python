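"""Pyridine hemochromogen heme quantification and extinction coefficients.

Heme is extracted from a protein preparation into alkaline pyridine,
oxidized with ferricyanide, then reduced with dithionite.  The reduced
bis-pyridine Fe(II) hemochrome has a sharp 557-nm band with a known
extinction coefficient (34.53 mM^-1 cm^-1 for protoheme IX), so the heme
concentration in the cuvette follows directly from Beer's law, and the
concentration in the original protein solution from the mixing volumes.

Knowing the absolute heme concentration of a preparation then converts the
native spectrum's absorbances into extinction coefficients of the intact
heme-protein complex at any wavelength where only the heme absorbs — and,
for a fully heme-occupied preparation, at 280 nm where protein and heme
both contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .spectra import Spectrum, SpectrumError, absorbance_at, beer_concentration, difference_spectrum

#: Reduced pyridine hemochrome extinction coefficient at 557 nm, mM^-1 cm^-1.
EPSILON_557 = 34.53

#: Assay mixing volumes (uL): alkaline-pyridine stock, ferricyanide, protein.
DEFAULT_V_STOCK_UL = 500.0
DEFAULT_V_FERRICYANIDE_UL = 3.0
DEFAULT_V_PROTEIN_UL = 500.0

#: Negative A557 more negative than this triggers a warning before clamping.
_A557_NEGATIVE_TOL = -0.005


@dataclass(frozen=True)
class HemochromeAssay:
    """Recorded spectra and mixing volumes of one hemochromogen assay.

    The dilution factor of the protein in the cuvette is
    ``(v_stock + v_ferricyanide + v_protein) / v_protein`` — 1003/500 =
    2.006 at the default volumes.  Dithionite is added as crystals and
    contributes no volume.
    """

    reduced: Spectrum
    oxidized: Optional[Spectrum] = None
    v_stock_uL: float = DEFAULT_V_STOCK_UL
    v_ferricyanide_uL: float = DEFAULT_V_FERRICYANIDE_UL
    v_protein_uL: float = DEFAULT_V_PROTEIN_UL
    epsilon557: float = EPSILON_557

    def __post_init__(self) -> None:
        for name in ("v_stock_uL", "v_ferricyanide_uL", "v_protein_uL", "epsilon557"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.reduced.covers(557.0)):
            raise SpectrumError("reduced spectrum must cover 557 nm (500-600 nm window)")

    @property
    def dilution_factor(self) -> float:
        return (self.v_stock_uL + self.v_ferricyanide_uL + self.v_protein_uL) / self.v_protein_uL


@dataclass(frozen=True)
class HemeQuantResult:
    heme_cuvette_uM: float
    heme_solution_uM: float
    dilution_factor: float
    a557: float
    mode: str

    def as_dict(self) -> dict:
        return {
            "heme_cuvette_uM": self.heme_cuvette_uM,
            "heme_solution_uM": self.heme_solution_uM,
            "dilution_factor": self.dilution_factor,
            "a557": self.a557,
            "mode": self.mode,
        }


def hemochrome_quantify(assay: HemochromeAssay, mode: str = "reduced") -> HemeQuantResult:
    """Heme concentration from the 557-nm hemochrome band.

    mode="reduced" reads A557 from the reduced spectrum (the default);
    mode="reduced-minus-oxidized" reads it from the difference spectrum,
    which cancels any redox-insensitive background.  Result carries both
    cuvette- and original-solution-scale concentrations in uM.
    """
    if mode == "reduced":
        a557 = absorbance_at(assay.reduced, 557.0)
    elif mode == "reduced-minus-oxidized":
        if assay.oxidized is None:
            raise SpectrumError("reduced-minus-oxidized mode requires an oxidized spectrum")
        a557 = absorbance_at(difference_spectrum(assay.reduced, assay.oxidized), 557.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if a557 < 0:
        if a557 < _A557_NEGATIVE_TOL:
            warnings.warn(
                f"A557 = {a557:.4f} AU is negative beyond tolerance; clamping to 0",
                stacklevel=2)
        a557_eff = 0.0
    else:
        a557_eff = a557

    heme_cuvette_mM = beer_concentration(a557_eff, assay.epsilon557, assay.reduced.pathlength_cm)
    heme_cuvette_uM = heme_cuvette_mM * 1e3
    dilution = assay.dilution_factor
    return HemeQuantResult(
        heme_cuvette_uM=heme_cuvette_uM,
        heme_solution_uM=heme_cuvette_uM * dilution,
        dilution_factor=dilution,
        a557=a557,
        mode=mode,
    )


def derive_extinction(native: Spectrum, heme_solution_uM: float,
                      wavelengths: Sequence[float]) -> dict:
    """Extinction coefficients of the native complex at given wavelengths.

    ``eps(lambda) = A(lambda) / (C_heme_mM * l)`` with the native spectrum
    and heme concentration on the same (original-solution) scale.  With one
    heme per dimer the per-heme and per-holo-dimer coefficients coincide.
    Returns {wavelength_nm: eps_mM_cm} in mM^-1 cm^-1.
    """
    if heme_solution_uM <= 0:
        raise ValueError("heme_solution_uM must be > 0")
    heme_mM = heme_solution_uM * 1e-3
    return {
        float(wl): absorbance_at(native, wl) / (heme_mM * native.pathlength_cm)
        for wl in wavelengths
    }


def derive_epsilon280_holo(native: Spectrum, holo_dimer_uM: float) -> float:
    """280-nm extinction coefficient of the holo dimer (mM^-1 cm^-1).

    Meaningful only for preparations whose heme occupancy is ~1: at 280 nm
    both the protein and the heme absorb, so the ratio A280 / C is a pure
    holo-species coefficient only when no apo protein is present.  The
    caller asserts that condition.
    """
    if holo_dimer_uM <= 0:
        raise ValueError("holo_dimer_uM must be > 0")
    return absorbance_at(native, 280.0) / (holo_dimer_uM * 1e-3 * native.pathlength_cm)
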