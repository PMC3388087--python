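"""Intact-protein masses and contiguous degradation-fragment matching.

Linear-mode MALDI-TOF of a dissolved protein crystal yields singly
protonated [M+H]+ ions of whatever polypeptides the crystal contained.
When a crystal grown over months contains a proteolytic fragment rather
than the full-length construct, the observed neutral masses can be
explained by searching every contiguous stretch of the construct sequence
for average masses within tolerance.  Fragment masses for all O(L^2)
windows are evaluated in O(1) each via prefix sums of residue masses.

Average (not monoisotopic) masses are the default, appropriate for
linear-mode spectra of 4-30 kDa species; monoisotopic masses are available
behind a flag.  Coordinates are reference residue numbers, both ends
inclusive.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

# IUPAC average residue (amino-acid minus water) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.0153
WATER_MONO = 18.010565
PROTON_AVERAGE = 1.008
PROTON_MONO = 1.007276

#: Default mass tolerance as a fraction of the target (0.15% ~ 10 Da at 6.8 kDa).
DEFAULT_TOLERANCE_FRAC = 0.0015

#: Sentinel reference numbers: initiator Met = 0, C-terminal tag residues < 0.
MET_REF = 0


class MassError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinConstruct:
    """An expression construct: one-letter sequence plus per-residue
    reference numbers (native span strictly increasing; initiator Met 0 and
    tag residues negative by convention)."""

    sequence: str
    ref_numbers: tuple
    met_retained: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "ref_numbers", tuple(int(r) for r in self.ref_numbers))
        if len(self.sequence) != len(self.ref_numbers):
            raise MassError("sequence and ref_numbers must have equal length")
        bad = sorted(set(self.sequence) - set(AVERAGE_RESIDUE_MASS))
        if bad:
            raise MassError(f"unknown residue letters: {''.join(bad)}")
        native = [r for r in self.ref_numbers if r > 0]
        if any(b <= a for a, b in zip(native, native[1:])):
            raise MassError("native-span reference numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)

    def index_of(self, ref: int) -> int:
        try:
            return self.ref_numbers.index(ref)
        except ValueError:
            raise MassError(f"reference residue {ref} not in construct "
                            f"[{self.ref_numbers[0]}..{self.ref_numbers[-1]}]") from None


@dataclass(frozen=True)
class MassPeak:
    """One MALDI peak: m/z (Th), arbitrary intensity, charge state."""

    mz: float
    intensity: float = 0.0
    charge: int = 1
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise MassError("mz must be > 0")
        if self.charge < 1:
            raise MassError("charge must be >= 1")


@dataclass(frozen=True)
class MassMatch:
    """A contiguous fragment [start_ref, end_ref] (inclusive) explaining an
    observed neutral mass; delta = fragment - target."""

    start_ref: int
    end_ref: int
    neutral_mass: float
    delta: float
    ppm: float


def _mass_table(monoisotopic: bool):
    if monoisotopic:
        return MONOISOTOPIC_RESIDUE_MASS, WATER_MONO
    return AVERAGE_RESIDUE_MASS, WATER_AVERAGE


def sequence_mass(sequence: str, monoisotopic: bool = False) -> float:
    """Neutral mass of an intact chain: residue masses + one water."""
    table, water = _mass_table(monoisotopic)
    try:
        return sum(table[a] for a in sequence.upper()) + water
    except KeyError as e:
        raise MassError(f"unknown residue letter {e.args[0]!r}") from None


def average_mass(construct: ProteinConstruct,
                 start_ref: Optional[int] = None,
                 end_ref: Optional[int] = None,
                 monoisotopic: bool = False) -> float:
    """Neutral mass (Da) of construct residues start_ref..end_ref inclusive.

    Defaults to the whole chain.  Rounding is left to reporting code.
    """
    i = 0 if start_ref is None else construct.index_of(start_ref)
    j = len(construct) - 1 if end_ref is None else construct.index_of(end_ref)
    if i > j:
        raise MassError(f"start_ref {start_ref} is after end_ref {end_ref}")
    return sequence_mass(construct.sequence[i:j + 1], monoisotopic=monoisotopic)


def mz_to_neutral(peak: MassPeak, monoisotopic: bool = False) -> float:
    """Neutral mass of an [M+zH]z+ ion: ``mz * z - z * m_proton``."""
    proton = PROTON_MONO if monoisotopic else PROTON_AVERAGE
    return peak.mz * peak.charge - peak.charge * proton


def neutral_to_mz(neutral_mass: float, charge: int = 1, monoisotopic: bool = False) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass (inverse of mz_to_neutral)."""
    proton = PROTON_MONO if monoisotopic else PROTON_AVERAGE
    return (neutral_mass + charge * proton) / charge


def fragment_search(construct: ProteinConstruct,
                    targets: Sequence[float],
                    tolerance_da: Optional[float] = None,
                    tolerance_frac: Optional[float] = None,
                    monoisotopic: bool = False) -> list:
    """All contiguous fragments whose neutral mass matches each target.

    Per-target tolerance is ``tolerance_da`` if given, else
    ``tolerance_frac * target`` (default fraction 0.15%).  Fragment masses
    come from a prefix-sum array, so each of the L(L+1)/2 windows costs
    O(1).  Each target's matches are sorted by |delta| ascending, ties
    broken by longer fragment first, then smaller start_ref.  Returns a
    list (one entry per target) of lists of :class:`MassMatch`.
    """
    if len(targets) == 0:
        raise MassError("empty target list")
    if tolerance_da is not None and tolerance_da <= 0:
        raise MassError("tolerance_da must be > 0")
    if tolerance_frac is not None and tolerance_frac <= 0:
        raise MassError("tolerance_frac must be > 0")
    if tolerance_da is None and tolerance_frac is None:
        tolerance_frac = DEFAULT_TOLERANCE_FRAC

    table, water = _mass_table(monoisotopic)
    L = len(construct)
    prefix = np.zeros(L + 1)
    for k, aa in enumerate(construct.sequence):
        prefix[k + 1] = prefix[k] + table[aa]

    results = []
    for target in targets:
        tol = tolerance_da if tolerance_da is not None else tolerance_frac * target
        matches = []
        # residue-sum window for this target, used to bound j per i
        lo_sum, hi_sum = target - tol - water, target + tol - water
        for i in range(L):
            j_lo = bisect.bisect_left(prefix, prefix[i] + lo_sum, lo=i + 1)
            j_hi = bisect.bisect_right(prefix, prefix[i] + hi_sum, lo=i + 1)
            for jp in range(j_lo, j_hi):
                j = jp - 1
                mass = prefix[jp] - prefix[i] + water
                delta = mass - target
                matches.append(MassMatch(
                    start_ref=construct.ref_numbers[i],
                    end_ref=construct.ref_numbers[j],
                    neutral_mass=float(mass),
                    delta=float(delta),
                    ppm=float(delta / target * 1e6),
                ))
        matches.sort(key=lambda m: (abs(m.delta),
                                    -(m.end_ref - m.start_ref),
                                    m.start_ref))
        results.append(matches)
    return results


def construct_from_fasta(fasta: Union[str, "SeqIO.SeqRecord"],
                         native_range: Optional[tuple] = None,
                         numbering_start: int = 1,
                         n_term_met: bool = True,
                         c_term_tag: str = "",
                         label: str = "") -> ProteinConstruct:
    """Build an expression construct from a FASTA record.

    ``fasta`` is a path (first record read with Biopython) or a SeqRecord.
    ``native_range=(start, end)`` selects reference residues (inclusive)
    under a numbering in which the record's first residue is
    ``numbering_start``.  The construct is [Met if retained] + native span
    + C-terminal tag; Met carries reference number 0 and tag residues
    negative sentinels.
    """
    if hasattr(fasta, "seq"):
        record = fasta
    else:
        record = next(SeqIO.parse(fasta, "fasta"))
    full = str(record.seq).upper().rstrip("*")
    first_ref = numbering_start
    last_ref = numbering_start + len(full) - 1
    if native_range is None:
        start, end = first_ref, last_ref
    else:
        start, end = int(native_range[0]), int(native_range[1])
    if not (first_ref <= start <= end <= last_ref):
        raise MassError(
            f"range {start}:{end} outside record numbering [{first_ref}..{last_ref}]")
    native = full[start - first_ref: end - first_ref + 1]
    seq = ("M" if n_term_met else "") + native + c_term_tag
    refs = (([MET_REF] if n_term_met else [])
            + list(range(start, end + 1))
            + [-(k + 1) for k in range(len(c_term_tag))])
    return ProteinConstruct(sequence=seq, ref_numbers=tuple(refs),
                            met_retained=n_term_met,
                            label=label or record.id)


def read_peak_csv(path) -> list:
    """Read a peak list CSV (mz, intensity[, charge]); '#' and header lines ignored."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                mz = float(parts[0])
            except ValueError:
                if lineno == 1:
                    continue
                raise MassError(f"{path}: malformed row at line {lineno}")
            intensity = float(parts[1]) if len(parts) > 1 else 0.0
            charge = int(parts[2]) if len(parts) > 2 else 1
            peaks.append(MassPeak(mz=mz, intensity=intensity, charge=charge))
    return peaks
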