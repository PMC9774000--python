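"""Core tabular containers shared across the pipeline.

A :class:`ShiftTable` holds per-residue, per-atom chemical shifts (ppm) and is
used both for the observed solid-state NMR assignment and for shifts
calculated from a candidate structure. A :class:`TorsionTable` holds backbone
phi/psi angles (degrees), again from either side of the comparison. A
:class:`SecondaryShiftProfile` holds the secondary shifts dCA, dCB and the
derived statistic S = dCA - dCB whose sign separates helical (S > 0) from
extended (S < 0) conformation. A :class:`RandomCoilTable` is the per-residue-
type random-coil reference needed to form secondary shifts.

All containers validate their domain invariants on construction and are
immutable afterwards; readers and simulators construct them, analysis code
only consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import DataError

__all__ = [
    "AA_3TO1",
    "AA_1TO3",
    "ShiftEntry",
    "ShiftTable",
    "TorsionEntry",
    "TorsionTable",
    "SecondaryShiftEntry",
    "SecondaryShiftProfile",
    "RandomCoilTable",
    "normalize_residue_type",
    "normalize_atom_name",
    "wrap_angle",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: atoms the pipeline cares about (backbone + CB); CO is normalized to C
BACKBONE_ATOMS = frozenset({"CA", "CB", "C", "N"})


def normalize_residue_type(code: str) -> str:
    """Return the 1-letter amino acid code for a 1- or 3-letter input."""
    code = code.strip().upper()
    if len(code) == 1 and code in AA_1TO3:
        return code
    if code in AA_3TO1:
        return AA_3TO1[code]
    raise DataError(f"unknown residue type {code!r}")


def normalize_atom_name(name: str) -> str:
    """Uppercase the atom name and collapse the C/CO dialect split."""
    name = name.strip().upper()
    return "C" if name == "CO" else name


def wrap_angle(angle_deg: float) -> float:
    """Normalize an angle in degrees to the interval (-180, 180].

    -180 is reported as +180 so that trans torsions have a single
    representation and comparisons never straddle the branch cut.
    """
    wrapped = math.fmod(angle_deg, 360.0)
    if wrapped > 180.0:
        wrapped -= 360.0
    elif wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


def _shift_in_bounds(atom_name: str, shift: float) -> bool:
    if not math.isfinite(shift):
        return False
    if atom_name.startswith("N"):
        return 0.0 <= shift <= 200.0
    if atom_name.startswith("C"):
        return 0.0 <= shift <= 250.0
    return True


@dataclass(frozen=True)
class ShiftEntry:
    residue_number: int
    residue_type: str  # 1-letter
    atom_name: str
    shift: float  # ppm


class ShiftTable:
    """Per-residue, per-atom chemical shifts with a provenance label.

    Invariants enforced at construction: (residue_number, atom_name) unique,
    shifts finite and inside sanity bounds (carbon 0-250 ppm, nitrogen
    0-200 ppm), and glycine never carries a CB entry.
    """

    def __init__(self, entries: Iterable[ShiftEntry], source_label: str = ""):
        ents = []
        index: dict[tuple[int, str], float] = {}
        types: dict[int, str] = {}
        for e in entries:
            rt = normalize_residue_type(e.residue_type)
            an = normalize_atom_name(e.atom_name)
            if rt == "G" and an == "CB":
                raise DataError(
                    f"glycine at residue {e.residue_number} cannot carry a CB shift"
                )
            if not _shift_in_bounds(an, e.shift):
                raise DataError(
                    f"shift {e.shift!r} for {an} of residue {e.residue_number} "
                    "is non-finite or outside sanity bounds"
                )
            key = (e.residue_number, an)
            if key in index:
                raise DataError(
                    f"duplicate shift for residue {e.residue_number} atom {an}"
                )
            prev = types.get(e.residue_number)
            if prev is not None and prev != rt:
                raise DataError(
                    f"conflicting residue types {prev}/{rt} at residue "
                    f"{e.residue_number}"
                )
            index[key] = e.shift
            types[e.residue_number] = rt
            ents.append(ShiftEntry(e.residue_number, rt, an, e.shift))
        self._entries = tuple(sorted(ents, key=lambda e: (e.residue_number, e.atom_name)))
        self._index = index
        self._types = types
        self.source_label = source_label

    @property
    def entries(self) -> tuple[ShiftEntry, ...]:
        return self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return (
            self._entries == other._entries
            and self.source_label == other.source_label
        )

    def residue_numbers(self) -> list[int]:
        return sorted(self._types)

    def residue_type(self, residue_number: int) -> Optional[str]:
        return self._types.get(residue_number)

    def get(self, residue_number: int, atom_name: str) -> Optional[float]:
        return self._index.get((residue_number, normalize_atom_name(atom_name)))

    def has(self, residue_number: int, atom_name: str) -> bool:
        return (residue_number, normalize_atom_name(atom_name)) in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.residue_number, e.residue_type, e.atom_name, e.shift)
                for e in self._entries
            ],
            columns=["residue_number", "residue_type", "atom_name", "shift"],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ShiftTable {self.source_label!r}: {len(self._entries)} shifts, "
            f"{len(self._types)} residues>"
        )


@dataclass(frozen=True)
class TorsionEntry:
    residue_number: int
    residue_type: str
    phi: float  # degrees, (-180, 180]
    psi: float  # degrees, (-180, 180]
    classification_flag: Optional[str] = None


class TorsionTable:
    """Per-residue backbone phi/psi angles in degrees, normalized to (-180, 180]."""

    def __init__(self, entries: Iterable[TorsionEntry], source_label: str = ""):
        index: dict[int, TorsionEntry] = {}
        for e in entries:
            if e.residue_number in index:
                raise DataError(f"duplicate torsion entry for residue {e.residue_number}")
            if not (math.isfinite(e.phi) and math.isfinite(e.psi)):
                raise DataError(f"non-finite torsion at residue {e.residue_number}")
            index[e.residue_number] = TorsionEntry(
                e.residue_number,
                normalize_residue_type(e.residue_type),
                wrap_angle(e.phi),
                wrap_angle(e.psi),
                e.classification_flag,
            )
        self._index = dict(sorted(index.items()))
        self.source_label = source_label

    @property
    def entries(self) -> tuple[TorsionEntry, ...]:
        return tuple(self._index.values())

    def __len__(self) -> int:
        return len(self._index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TorsionTable):
            return NotImplemented
        return self._index == other._index and self.source_label == other.source_label

    def residue_numbers(self) -> list[int]:
        return list(self._index)

    def get(self, residue_number: int) -> Optional[TorsionEntry]:
        return self._index.get(residue_number)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.residue_number, e.residue_type, e.phi, e.psi, e.classification_flag)
                for e in self.entries
            ],
            columns=["residue_number", "residue_type", "phi", "psi", "classification"],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<TorsionTable {self.source_label!r}: {len(self)} residues>"


@dataclass(frozen=True)
class SecondaryShiftEntry:
    residue_number: int
    delta_ca: Optional[float]
    delta_cb: Optional[float]
    s_value: Optional[float]


class SecondaryShiftProfile:
    """Per-residue secondary shifts and the S = dCA - dCB statistic.

    The invariant ``s_value present iff both deltas present`` is enforced;
    glycines therefore never carry an S value.
    """

    def __init__(self, entries: Iterable[SecondaryShiftEntry], source_label: str = ""):
        index: dict[int, SecondaryShiftEntry] = {}
        for e in entries:
            if e.residue_number in index:
                raise DataError(f"duplicate profile entry for residue {e.residue_number}")
            both = e.delta_ca is not None and e.delta_cb is not None
            if (e.s_value is not None) != both:
                raise DataError(
                    f"residue {e.residue_number}: s_value must be present exactly "
                    "when both delta_ca and delta_cb are"
                )
            index[e.residue_number] = e
        self._index = dict(sorted(index.items()))
        self.source_label = source_label

    @property
    def entries(self) -> tuple[SecondaryShiftEntry, ...]:
        return tuple(self._index.values())

    def __len__(self) -> int:
        return len(self._index)

    def residue_numbers(self) -> list[int]:
        return list(self._index)

    def get(self, residue_number: int) -> Optional[SecondaryShiftEntry]:
        return self._index.get(residue_number)

    def s_values(self) -> dict[int, float]:
        return {
            e.residue_number: e.s_value
            for e in self.entries
            if e.s_value is not None
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.residue_number, e.delta_ca, e.delta_cb, e.s_value)
                for e in self.entries
            ],
            columns=["residue_number", "delta_ca", "delta_cb", "s_value"],
        )


class RandomCoilTable:
    """Random-coil reference shifts per residue type (1-letter keys).

    All 20 standard amino acids must be present; glycine has a CA value only.
    Values are sanity-bounded to [10, 75] ppm, the plausible range for
    aliphatic carbon random-coil shifts.
    """

    def __init__(
        self,
        values: Mapping[str, tuple[float, Optional[float]]],
        provenance_label: str = "",
    ):
        table: dict[str, tuple[float, Optional[float]]] = {}
        for code, (rc_ca, rc_cb) in values.items():
            rt = normalize_residue_type(code)
            if rt == "G":
                rc_cb = None
            elif rc_cb is None:
                raise DataError(f"residue type {rt} requires a CB random-coil value")
            for v in (rc_ca,) + ((rc_cb,) if rc_cb is not None else ()):
                if not (10.0 <= v <= 75.0):
                    raise DataError(
                        f"random-coil value {v} for {rt} outside [10, 75] ppm"
                    )
            table[rt] = (rc_ca, rc_cb)
        missing = set(AA_1TO3) - set(table)
        if missing:
            raise DataError(f"random-coil table missing residue types {sorted(missing)}")
        self._table = table
        self.provenance_label = provenance_label

    def rc_ca(self, residue_type: str) -> float:
        return self._table[normalize_residue_type(residue_type)][0]

    def rc_cb(self, residue_type: str) -> Optional[float]:
        return self._table[normalize_residue_type(residue_type)][1]

    def __contains__(self, residue_type: str) -> bool:
        try:
            return normalize_residue_type(residue_type) in self._table
        except DataError:
            return False
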