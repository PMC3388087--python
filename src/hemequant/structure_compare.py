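"""Calpha superposition of homologous protein domains.

Reads Calpha traces from PDB-format files, pairs residues between two
models by a constant residue-number offset (appropriate for colinear,
near-identical homologues; an explicit pair list can override), and
computes the least-squares rigid-body superposition via the Kabsch/SVD
construction with the proper-rotation correction, reporting the overall
RMSD and per-residue deviations.  All paired atoms are weighted equally
and no outliers are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import gemmi
import numpy as np


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class StructureModel:
    """An ordered Calpha trace: (ref_number, insertion_code, residue_name,
    xyz) per residue, single chain."""

    label: str
    chain_id: str
    residues: tuple  # of (ref_number:int, icode:str, resname:str, np.ndarray xyz)

    def __post_init__(self) -> None:
        keys = [(r[0], r[1]) for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate (ref_number, insertion_code) in chain")
        for r in self.residues:
            if not np.all(np.isfinite(r[3])):
                raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)

    def ref_numbers(self) -> list:
        return [r[0] for r in self.residues]

    def coords(self) -> np.ndarray:
        return np.array([r[3] for r in self.residues], dtype=float)


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body fit of mobile onto target: x_fit = rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    per_residue_dev: tuple  # of (pair_label, deviation A)

    def as_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd_A": self.rmsd,
            "n_atoms": self.n_atoms,
            "per_residue_dev_A": [[lab, d] for lab, d in self.per_residue_dev],
        }


def read_calpha(pdb_path, chain: str, ref_range: Optional[tuple] = None,
                label: str = "") -> StructureModel:
    """Calpha trace of one chain from a PDB-format file.

    Keeps CA atoms only (first conformer: blank altloc or 'A'); HETATM
    residues without CA are skipped with a warning.  ``ref_range=(lo, hi)``
    restricts to that inclusive residue-number span.
    """
    st = gemmi.read_pdb(str(pdb_path))
    st.setup_entities()
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise StructureError(
            f"{pdb_path}: chain {chain!r} not found "
            f"(available: {[c.name for c in model]})")
    residues = []
    for res in ch:
        if res.is_water():
            continue
        num = res.seqid.num
        if ref_range is not None and not (ref_range[0] <= num <= ref_range[1]):
            continue
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "\0", "A"):
                ca = atom
                break
        if ca is None:
            if res.het_flag == "A":  # polymer residue with no CA is suspicious
                warnings.warn(f"{pdb_path}: residue {res.name} {num} has no CA; skipped",
                              stacklevel=2)
            continue
        icode = res.seqid.icode.strip() if res.seqid.icode else ""
        residues.append((num, icode, res.name,
                         np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    residues.sort(key=lambda r: (r[0], r[1]))
    return StructureModel(label=label or f"{pdb_path}:{chain}", chain_id=chain,
                          residues=tuple(residues))


def pair_residues(a: StructureModel, b: StructureModel, offset: int = 0
                  ) -> Tuple[np.ndarray, np.ndarray, list, dict]:
    """Pair residues where a.ref_number = b.ref_number + offset.

    Returns (coords_a, coords_b, pair_labels, counts) with counts reporting
    paired/unpaired totals; order follows a.
    """
    b_index = {r[0]: r for r in b.residues}
    xa, xb, labels = [], [], []
    for ra in a.residues:
        rb = b_index.get(ra[0] - offset)
        if rb is None:
            continue
        xa.append(ra[3])
        xb.append(rb[3])
        labels.append(f"{ra[2]}{ra[0]}/{rb[2]}{rb[0]}")
    counts = {"paired": len(xa),
              "unpaired_a": len(a) - len(xa),
              "unpaired_b": len(b) - len(xa)}
    if not xa:
        raise StructureError(f"no residue pairs at offset {offset}")
    return np.array(xa), np.array(xb), labels, counts


def superpose(coords_mobile: np.ndarray, coords_target: np.ndarray,
              pair_labels: Optional[Sequence[str]] = None) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto target (Kabsch).

    The optimal rotation is U = V diag(1,1,det(VW^T)) W^T from the SVD of
    the covariance of the centered coordinate sets; the determinant
    correction guarantees a proper rotation (no reflection) even for
    chirally mismatched inputs.  Requires >= 3 non-collinear pairs.
    """
    X = np.asarray(coords_mobile, dtype=float)
    Y = np.asarray(coords_target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise StructureError("coordinate sets must be matching (n, 3) arrays")
    n = X.shape[0]
    if n < 3:
        raise StructureError("superposition requires at least 3 atom pairs")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    # collinearity check: rank of the centered mobile set
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2 or np.linalg.matrix_rank(Y0, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) coordinate geometry")
    H = X0.T @ Y0
    V, _, Wt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Wt.T @ V.T))
    D = np.diag([1.0, 1.0, d])
    R = Wt.T @ D @ V.T
    t = yc - R @ xc
    fitted = X @ R.T + t
    dev = np.linalg.norm(fitted - Y, axis=1)
    rmsd = float(np.sqrt(np.mean(dev ** 2)))
    labels = list(pair_labels) if pair_labels is not None else [str(i) for i in range(n)]
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms=n,
        per_residue_dev=tuple(zip(labels, dev.tolist())))


def superpose_models(mobile: StructureModel, target: StructureModel,
                     offset: int = 0) -> Tuple[SuperpositionResult, dict]:
    """Pair by residue-number offset, then superpose; returns (result, pairing counts)."""
    xa, xb, labels, counts = pair_residues(mobile, target, offset=offset)
    return superpose(xa, xb, pair_labels=labels), counts


def write_transformed(mobile_pdb, chain: str, result: SuperpositionResult, out_path) -> None:
    """Write the mobile structure with the fitted transform applied (PDB format)."""
    st = gemmi.read_pdb(str(mobile_pdb))
    R, t = result.rotation, result.translation
    mat = gemmi.Mat33(R.tolist())
    vec = gemmi.Vec3(*t.tolist())
    tr = gemmi.Transform(mat, vec)
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    p = tr.apply(atom.pos)
                    atom.pos = gemmi.Position(p.x, p.y, p.z)
    st.write_pdb(str(out_path))
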