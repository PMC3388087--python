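"""Heme occupancy from absorbance ratios under a two-component mixture model.

A recombinant heme-protein preparation is a mixture of holo dimers (one
heme each) and apo dimers.  Only the holo species absorbs at the 450-nm
heme band, while both species absorb at 280 nm:

    A450 = eps450 * H
    A280 = eps280_holo * H + eps280_apo * P

with H, P the holo/apo dimer concentrations.  The purity index
RZ = A450/A280 therefore determines the occupancy O = H / (H + P):

    O = eps280_apo * RZ / (eps280_apo * RZ + eps450 - eps280_holo * RZ)

which is 0 at RZ = 0 and exactly 1 at the pure-holo ratio
RZ = eps450 / eps280_holo.

The apo 280-nm coefficient comes from the sequence via the Trp/Tyr/cystine
increments of Pace et al. (5500/1490/125 M^-1 cm^-1); occupancy can also be
measured directly as the molar ratio of heme (hemochrome assay) to dimeric
protein (colorimetric protein assay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .spectra import Spectrum, absorbance_at

# 280-nm molar extinction increments (M^-1 cm^-1), Trp / Tyr / cystine.
EPS280_TRP = 5500.0
EPS280_TYR = 1490.0
EPS280_CYSTINE = 125.0

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: RZ may exceed the pure-holo ratio by this much before a warning is raised.
_RZ_SUPER_TOL = 0.02

#: Baseline noise can push A450, and hence RZ, slightly negative for an apo
#: preparation; beyond this the signal is treated as nonsense.
_RZ_NEGATIVE_TOL = -0.02


@dataclass(frozen=True)
class ExtinctionSet:
    """Per-species extinction coefficients (mM^-1 cm^-1) of a heme-protein
    complex; with one heme per dimer the per-heme and per-holo-dimer bases
    coincide."""

    species: str
    eps450: float
    eps280_holo: float
    eps280_apo: float
    eps367: Optional[float] = None
    eps556: Optional[float] = None
    basis: str = "per holo dimer (= per heme)"

    def __post_init__(self) -> None:
        for name in ("eps450", "eps280_holo", "eps280_apo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("eps367", "eps556"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when given")
        if self.eps280_holo <= self.eps280_apo:
            raise ValueError(
                "eps280_holo must exceed eps280_apo: the holo complex absorbs "
                "at 280 nm through both its protein and heme moieties")

    @property
    def rz_pure_holo(self) -> float:
        """A450/A280 of a fully occupied preparation."""
        return self.eps450 / self.eps280_holo


@dataclass(frozen=True)
class OccupancyResult:
    rz: float
    occupancy: float          # clamped to [0, 1]
    raw_occupancy: float      # unclamped, for QC
    holo_uM: Optional[float] = None
    apo_uM: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"rz": self.rz, "occupancy": self.occupancy, "raw_occupancy": self.raw_occupancy}
        if self.holo_uM is not None:
            d["holo_uM"] = self.holo_uM
            d["apo_uM"] = self.apo_uM
        return d


def pace_epsilon280(sequence: str, n_cystine: int = 0, multimer: int = 1) -> float:
    """Sequence-based 280-nm extinction coefficient (mM^-1 cm^-1).

    eps280 (M^-1 cm^-1) = 5500 nTrp + 1490 nTyr + 125 n_cystine, scaled by
    the number of chains in the multimer.  Cystine defaults to 0 (chains
    handled reduced); it may not exceed nCys // 2.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence is empty")
    bad = sorted(set(seq) - _AA20)
    if bad:
        raise ValueError(f"unknown residue letters: {''.join(bad)}")
    if multimer < 1:
        raise ValueError("multimer must be >= 1")
    n_cys = seq.count("C")
    if n_cystine < 0 or n_cystine > n_cys // 2:
        raise ValueError(f"n_cystine must be in [0, {n_cys // 2}] for {n_cys} Cys")
    eps_M = EPS280_TRP * seq.count("W") + EPS280_TYR * seq.count("Y") + EPS280_CYSTINE * n_cystine
    return eps_M * multimer / 1e3


def rz_value(native: Spectrum) -> float:
    """The A450/A280 ratio of a native spectrum (the RZ purity index)."""
    a280 = absorbance_at(native, 280.0)
    if a280 <= 0:
        raise ValueError(f"A280 = {a280:g} AU; RZ requires A280 > 0")
    return absorbance_at(native, 450.0) / a280


def heme_occupancy(rz: float, eps: ExtinctionSet,
                   a280: Optional[float] = None,
                   pathlength_cm: float = 1.0) -> OccupancyResult:
    """Heme occupancy O = H/(H+P) from the RZ ratio.

    Inverts the two-component mixture model (module docstring).  The raw
    value is clamped to [0, 1] for downstream use and preserved unclamped
    for QC; an RZ meaningfully above the pure-holo ratio triggers a
    super-stoichiometric-signal warning.  If the absolute ``a280`` (AU) is
    supplied, the holo and apo dimer concentrations (uM) are also solved.
    """
    if rz < _RZ_NEGATIVE_TOL:
        raise ValueError(f"rz = {rz:g} is negative beyond baseline-noise tolerance")
    if rz > eps.rz_pure_holo + _RZ_SUPER_TOL:
        warnings.warn(
            f"RZ = {rz:.3f} exceeds the pure-holo ratio "
            f"{eps.rz_pure_holo:.3f}: super-stoichiometric heme signal "
            f"(raw_occupancy > 1 reported)", stacklevel=2)
    if rz == eps.rz_pure_holo:
        # algebraic fixed point of the mixture model; evaluating the formula
        # here would lose it to rounding
        raw = 1.0
    else:
        num = eps.eps280_apo * rz
        den = eps.eps280_apo * rz + eps.eps450 - eps.eps280_holo * rz
        raw = num / den
    occ = min(1.0, max(0.0, raw))

    holo_uM = apo_uM = None
    if a280 is not None:
        # A450 = rz * A280; H from the 450-nm band, P from the 280 residual.
        a450 = rz * a280
        holo_mM = a450 / (eps.eps450 * pathlength_cm)
        apo_mM = (a280 / pathlength_cm - eps.eps280_holo * holo_mM) / eps.eps280_apo
        holo_uM = holo_mM * 1e3
        apo_uM = apo_mM * 1e3
    return OccupancyResult(rz=rz, occupancy=occ, raw_occupancy=raw,
                           holo_uM=holo_uM, apo_uM=apo_uM)


def occupancy_direct(heme_uM: float, protein_dimer_uM: float) -> float:
    """Occupancy as the molar ratio heme : dimeric protein.

    Not clamped — values slightly above 1 reflect the combined error of the
    heme and protein assays and are informative as such.
    """
    if protein_dimer_uM <= 0:
        raise ValueError("protein_dimer_uM must be > 0")
    if heme_uM < 0:
        raise ValueError("heme_uM must be >= 0")
    return heme_uM / protein_dimer_uM
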