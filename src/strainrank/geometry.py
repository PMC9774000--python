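"""Backbone geometry: structure reading and phi/psi torsion computation.

Candidate fibril core structures arrive as PDB or mmCIF files; one chain is
selected and its backbone torsions are computed directly from coordinates, so
no external torsion program is needed on the calculated side of the
comparison.

Conventions: torsions follow the IUPAC sign rule (cis = 0 deg, trans
reported as +180 deg), the output range is (-180, 180], and torsions are
refused across chain breaks (peptide C(i)-N(i+1) distance >= 2.5 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import DataError, GeometryError
from .tables import AA_3TO1, TorsionEntry, TorsionTable, wrap_angle

__all__ = [
    "Residue",
    "StructureModel",
    "read_structure",
    "dihedral_angle",
    "compute_torsions",
    "PEPTIDE_BOND_MAX",
]

#: maximum C(i)-N(i+1) distance (Angstrom) still treated as a peptide bond
PEPTIDE_BOND_MAX = 2.5

_COLLINEAR_TOL = 1e-9  # squared-norm floor (A^2) for the torsion cross products


@dataclass
class Residue:
    residue_number: int
    residue_type: str  # 1-letter
    atoms: dict[str, np.ndarray]  # atom name -> xyz (A)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class StructureModel:
    """Backbone coordinates of a single chain of one fibril core model."""

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    #: residue numbers that lack a complete N/CA/C backbone (kept, but no torsions)
    incomplete: frozenset[int] = frozenset()

    def __post_init__(self):
        numbers = [r.residue_number for r in self.residues]
        if numbers != sorted(numbers) or len(set(numbers)) != len(numbers):
            raise DataError("residues must be strictly ordered by residue_number")
        for r in self.residues:
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise DataError(
                        f"non-finite coordinate for {name} of residue {r.residue_number}"
                    )

    def residue_numbers(self) -> list[int]:
        return [r.residue_number for r in self.residues]


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(
    path: str,
    chain_id: Optional[str] = None,
    model_index: int = 0,
    structure_id: Optional[str] = None,
) -> StructureModel:
    """Read one chain of a PDB or mmCIF file into a :class:`StructureModel`.

    Heteroatoms are dropped, alternate locations are resolved to the
    highest-occupancy conformer, and residues with an incomplete N/CA/C
    backbone are retained but flagged so torsions are never computed across
    them.

    Parameters
    ----------
    chain_id : str, optional
        Chain to extract; default "A". An absent chain raises
        :class:`DataError` listing the chains present.
    model_index : int
        Index of the model to use (0 = first model, the default).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise DataError(f"cannot parse structure file {path}: {exc}") from None
    if len(st) == 0:
        raise DataError(f"{path} contains no models")
    if model_index >= len(st):
        raise DataError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    want = chain_id or "A"
    chain = model.find_chain(want)
    if chain is None:
        available = [c.name for c in model]
        raise DataError(f"chain {want!r} not found; available chains: {available}")

    residues: list[Residue] = []
    incomplete: set[int] = set()
    for res in chain:
        if res.het_flag != "A":
            continue  # skip HETATM (waters, ligands)
        rtype = AA_3TO1.get(res.name.upper())
        if rtype is None:
            continue  # non-standard residue: outside the comparison
        by_name: dict[str, list[gemmi.Atom]] = {}
        for atom in res:
            by_name.setdefault(atom.name.upper(), []).append(atom)
        atoms = {}
        for name, variants in by_name.items():
            pos = _pick_altloc(variants).pos
            atoms[name] = np.array([pos.x, pos.y, pos.z], dtype=float)
        num = res.seqid.num
        r = Residue(num, rtype, atoms)
        if not r.has_backbone():
            incomplete.add(num)
        residues.append(r)
    residues.sort(key=lambda r: r.residue_number)
    sid = structure_id or st.name or str(path)
    return StructureModel(sid, want, residues, frozenset(incomplete))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC convention.

    cis is 0 deg; trans is reported as +180 (range (-180, 180]). The angle is
    antisymmetric under reversal of the point order. Raises
    :class:`GeometryError` if three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if n1 @ n1 <= _COLLINEAR_TOL or n2 @ n2 <= _COLLINEAR_TOL:
        raise GeometryError("collinear points: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2n
    return wrap_angle(float(np.degrees(np.arctan2(y, x))))


def compute_torsions(model: StructureModel, source_label: Optional[str] = None) -> TorsionTable:
    """Backbone phi/psi torsions of a chain model.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1). Terminal residues, residues flagged as incomplete, and residues
    adjacent to a chain break (C-N distance >= 2.5 A or non-consecutive
    numbering gap without a peptide bond) yield no entry for the undefined
    angle. Only residues with BOTH angles defined are emitted.
    """
    residues = [r for r in model.residues if r.has_backbone()]
    entries = []
    for k, res in enumerate(residues):
        prev = residues[k - 1] if k > 0 else None
        nxt = residues[k + 1] if k + 1 < len(residues) else None
        if prev is None or nxt is None:
            continue
        # peptide-bond continuity on both sides
        if np.linalg.norm(res.atoms["N"] - prev.atoms["C"]) >= PEPTIDE_BOND_MAX:
            continue
        if np.linalg.norm(nxt.atoms["N"] - res.atoms["C"]) >= PEPTIDE_BOND_MAX:
            continue
        phi = dihedral_angle(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
        psi = dihedral_angle(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
        entries.append(TorsionEntry(res.residue_number, res.residue_type, phi, psi))
    label = source_label if source_label is not None else f"Cal:{model.structure_id}"
    return TorsionTable(entries, source_label=label)
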