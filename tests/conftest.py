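"""Shared fixtures: synthetic spectra, FASTA records, and PDB files.

All fixture data are generated programmatically; structure files are
synthetic Calpha traces, not deposited coordinates.
"""

import numpy as np
import pytest

from hemequant.occupancy import ExtinctionSet
from hemequant import synthetic as syn


@pytest.fixture
def eps_batstar():
    """Extinction set of the bat star heme-binding-domain dimer
    (eps450 70, eps280_holo 91, eps280_apo 48 mM^-1 cm^-1)."""
    return ExtinctionSet(species="bat star HBD", eps450=70.0,
                         eps280_holo=91.0, eps280_apo=48.0,
                         eps367=59.0, eps556=12.9)


@pytest.fixture
def pure_holo_spectrum():
    """Noise-free native spectrum of a pure holo preparation at 7.3 uM."""
    return syn.simulate_native_spectrum(
        syn.SimulationSpec(holo_dimer_uM=7.3, noise_sd=0.0))


def format_pdb_atom(serial, name, resname, chain, resseq, xyz,
                    altloc=" ", icode=" ", occ=1.0, b=0.0, element=" C"):
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def write_ca_pdb(path, coords, chain="A", start_resseq=1, resname="ALA",
                 extra_lines=()):
    """Write a synthetic Calpha-only PDB file (one CA per residue)."""
    lines = []
    for k, xyz in enumerate(coords):
        lines.append(format_pdb_atom(k + 1, " CA ", resname, chain,
                                     start_resseq + k, xyz))
    lines.extend(extra_lines)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def helical_trace(n, seed=0, noise=0.0):
    """Synthetic alpha-helix-like Calpha trace (rise 1.5 A, radius 2.3 A)."""
    t = np.arange(n) * (2 * np.pi / 3.6)
    xyz = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
    if noise > 0:
        xyz = xyz + np.random.default_rng(seed).normal(0, noise, xyz.shape)
    return xyz


@pytest.fixture
def ca_trace():
    return helical_trace(30)


@pytest.fixture
def fasta_record(tmp_path):
    """Synthetic 500-residue FASTA record, numbered 1-500."""
    rng = np.random.default_rng(42)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(letters[k] for k in rng.integers(0, 20, size=500))
    p = tmp_path / "synthetic_record.fasta"
    p.write_text(">synthetic_500aa synthetic test record\n"
                 + "\n".join(seq[i:i + 60] for i in range(0, 500, 60)) + "\n")
    return p, seq
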