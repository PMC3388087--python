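"""Synthetic data generators with known ground truth.

Every pipeline stage (spectral peak finding, hemochrome quantification,
extinction derivation, occupancy estimation, fragment-mass matching) can be
exercised end-to-end on simulated inputs whose true parameters are known.

Absorption bands are modeled as Gaussians in wavelength, parameterized by
(center, sd width, extinction at center); at each band center the
noise-free absorbance obeys Beer's law exactly by construction, which is
the property the downstream two-point arithmetic relies on.  Gaussian
lineshapes make no claim of spectroscopic realism (no Voigt profiles,
scattering baselines, or drift) — they are adequate because all downstream
analysis reads absorbances at single wavelengths.

Default band parameters describe a ferric-heme protein complex whose
one-heme-per-dimer spectrum shows bands at 367, 450 and 556 nm
(eps 59 / 70 / 12.9 mM^-1 cm^-1), a total holo 280-nm extinction of
91 mM^-1 cm^-1, and an apo-dimer 280-nm extinction of 48 mM^-1 cm^-1.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .hemochrome import DEFAULT_V_FERRICYANIDE_UL, DEFAULT_V_PROTEIN_UL, DEFAULT_V_STOCK_UL, EPSILON_557
from .protein_mass import MassPeak, ProteinConstruct, neutral_to_mz, sequence_mass
from .spectra import Spectrum

# Default band widths (sd, nm): resolved from each other on a 1-nm grid.
WIDTH_280 = 15.0
WIDTH_SORET = 20.0
WIDTH_556 = 12.0
WIDTH_HEMOCHROME_557 = 6.0

DEFAULT_EPS450 = 70.0
DEFAULT_EPS367 = 59.0
DEFAULT_EPS556 = 12.9
DEFAULT_EPS280_HOLO = 91.0
DEFAULT_EPS280_APO = 48.0


@dataclass(frozen=True)
class BandModel:
    """Gaussian absorption bands of one species:
    (center nm, sd width nm, extinction at center mM^-1 cm^-1)."""

    bands: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for c, w, e in self.bands:
            if w <= 0 or e <= 0:
                raise ValueError("band widths and extinctions must be > 0")

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        """Model extinction coefficient (mM^-1 cm^-1) at each wavelength."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for c, w, e in self.bands:
            out += e * np.exp(-((wl - c) ** 2) / (2 * w ** 2))
        return out


@dataclass(frozen=True)
class SimulationSpec:
    """Concentrations, grid, noise and seed of one simulated measurement."""

    holo_dimer_uM: float = 0.0
    apo_dimer_uM: float = 0.0
    grid_start_nm: float = 250.0
    grid_stop_nm: float = 700.0
    grid_step_nm: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.holo_dimer_uM < 0 or self.apo_dimer_uM < 0:
            raise ValueError("concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_step_nm <= 0 or self.grid_stop_nm <= self.grid_start_nm:
            raise ValueError("invalid wavelength grid")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop_nm - self.grid_start_nm) / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)


def calibrated_band_model(centers, widths, target_eps) -> BandModel:
    """Band model whose *total* extinction at each center equals the target.

    Overlapping Gaussian tails mean the amplitude of each band is not the
    extinction at its center; solving the small linear system
    ``sum_j a_j exp(-(c_i - c_j)^2 / 2 w_j^2) = eps_i`` makes the noise-free
    spectrum obey Beer's law exactly at every band center.
    """
    c = np.asarray(centers, dtype=float)
    w = np.asarray(widths, dtype=float)
    e = np.asarray(target_eps, dtype=float)
    M = np.exp(-((c[:, None] - c[None, :]) ** 2) / (2 * w[None, :] ** 2))
    amps = np.linalg.solve(M, e)
    if np.any(amps <= 0):
        raise ValueError("band targets not realizable with positive amplitudes")
    return BandModel(bands=tuple(zip(c.tolist(), w.tolist(), amps.tolist())))


def default_holo_bands(eps367: float = DEFAULT_EPS367,
                       eps450: float = DEFAULT_EPS450,
                       eps556: float = DEFAULT_EPS556,
                       eps280_holo: float = DEFAULT_EPS280_HOLO) -> BandModel:
    """Holo-species band model whose total extinction at 280/367/450/556 nm
    equals the configured values exactly."""
    return calibrated_band_model(
        centers=(280.0, 367.0, 450.0, 556.0),
        widths=(WIDTH_280, WIDTH_SORET, WIDTH_SORET, WIDTH_556),
        target_eps=(eps280_holo, eps367, eps450, eps556))


def default_apo_band(eps280_apo: float = DEFAULT_EPS280_APO) -> BandModel:
    return BandModel(bands=((280.0, WIDTH_280, eps280_apo),))


def simulate_native_spectrum(spec: SimulationSpec,
                             holo_bands: BandModel = None,
                             apo_band: BandModel = None) -> Spectrum:
    """Native spectrum of a holo/apo mixture.

    A(l) = sum_species C_mM * eps_species(l) * pathlength + N(0, noise_sd).
    At each band center the noise-free absorbance obeys Beer's law exactly.
    """
    holo_bands = holo_bands if holo_bands is not None else default_holo_bands()
    apo_band = apo_band if apo_band is not None else default_apo_band()
    wl = spec.grid()
    a = (spec.holo_dimer_uM * 1e-3 * holo_bands.epsilon(wl)
         + spec.apo_dimer_uM * 1e-3 * apo_band.epsilon(wl)) * spec.pathlength_cm
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.normal(0.0, spec.noise_sd, size=wl.size)
    return Spectrum(wl, a, pathlength_cm=spec.pathlength_cm,
                    label=f"simulated native (seed={spec.seed})")


def simulate_hemochrome_pair(heme_solution_uM: float,
                             spec: SimulationSpec = None,
                             epsilon557: float = EPSILON_557) -> Tuple[Spectrum, Spectrum]:
    """(oxidized, reduced) hemochrome spectra for a given solution heme.

    The protein solution is diluted into the assay cuvette by the standard
    volumes (1003/500 = 2.006).  The reduced spectrum carries the sharp
    557-nm band at ``epsilon557``; the oxidized spectrum has only a broad
    featureless ferric band.  Both run 500-600 nm.
    """
    if heme_solution_uM < 0:
        raise ValueError("heme_solution_uM must be >= 0")
    if spec is None:
        spec = SimulationSpec(grid_start_nm=500.0, grid_stop_nm=600.0)
    dilution = (DEFAULT_V_STOCK_UL + DEFAULT_V_FERRICYANIDE_UL + DEFAULT_V_PROTEIN_UL) \
        / DEFAULT_V_PROTEIN_UL
    cuvette_mM = heme_solution_uM / dilution * 1e-3
    wl = np.arange(500.0, 600.0 + spec.grid_step_nm, spec.grid_step_nm)

    # alpha band at 557 (total extinction there exactly epsilon557) plus a
    # weaker beta band near 525
    reduced_bands = calibrated_band_model(
        centers=(557.0, 525.0),
        widths=(WIDTH_HEMOCHROME_557, 10.0),
        target_eps=(epsilon557, 17.5))
    oxidized_bands = BandModel(bands=((540.0, 25.0, 9.0),))

    rng = np.random.default_rng(spec.seed)
    spectra = []
    for bands in (oxidized_bands, reduced_bands):
        a = (cuvette_mM * bands.epsilon(wl) * spec.pathlength_cm
             if cuvette_mM > 0 else np.zeros_like(wl))
        if spec.noise_sd > 0:
            a = a + rng.normal(0.0, spec.noise_sd, size=wl.size)
        spectra.append(Spectrum(wl, a, pathlength_cm=spec.pathlength_cm,
                                dilution_factor=dilution,
                                label=f"simulated hemochrome (seed={spec.seed})"))
    return spectra[0], spectra[1]


def simulate_degradation(construct: ProteinConstruct,
                         n_fragments: int,
                         calib_error_frac: float = 0.0,
                         seed: int = 0,
                         min_length: int = 10) -> Tuple[List[Tuple[int, int, float]], List[MassPeak]]:
    """Random contiguous degradation fragments and their [M+H]+ peaks.

    Returns (true fragments as (start_ref, end_ref, neutral mass), peaks).
    Peaks carry a multiplicative calibration error ~ N(0, calib_error_frac)
    and unit-free intensities decreasing with mass (heavier species ionize
    less efficiently in linear-mode MALDI).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    L = len(construct)
    if L < min_length:
        raise ValueError(f"construct too short (< {min_length} residues)")
    rng = np.random.default_rng(seed)
    truths, peaks = [], []
    for _ in range(n_fragments):
        length = int(rng.integers(min_length, L + 1))
        i = int(rng.integers(0, L - length + 1))
        j = i + length - 1
        mass = sequence_mass(construct.sequence[i:j + 1])
        mz = neutral_to_mz(mass)
        if calib_error_frac > 0:
            mz *= 1.0 + rng.normal(0.0, calib_error_frac)
        truths.append((construct.ref_numbers[i], construct.ref_numbers[j], mass))
        peaks.append(MassPeak(mz=float(mz), intensity=float(1e4 / (1.0 + mass / 1e3)),
                              charge=1))
    return truths, peaks


def random_construct(length: int, seed: int = 0, label: str = "synthetic") -> ProteinConstruct:
    """Uniformly random construct of the 20 standard residues, numbered 1..length."""
    rng = np.random.default_rng(seed)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(letters[k] for k in rng.integers(0, 20, size=length))
    return ProteinConstruct(sequence=seq, ref_numbers=tuple(range(1, length + 1)),
                            label=label)
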