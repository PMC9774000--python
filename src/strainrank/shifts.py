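"""Secondary chemical shift analysis.

The secondary shift of a nucleus is its observed shift minus the random-coil
reference shift of the residue type. For CA and CB the combination
S = dCA - dCB is a robust secondary-structure indicator: helices give S > 0,
extended/beta conformation gives S < 0. Both the observed assignment and each
structure-calculated shift table are pushed through the same operation with
the same random-coil reference, so the two S series live on a common scale.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

from .errors import DataError
from .tables import (
    RandomCoilTable,
    SecondaryShiftEntry,
    SecondaryShiftProfile,
    ShiftTable,
)

__all__ = [
    "load_random_coil",
    "read_random_coil_csv",
    "secondary_shifts",
    "classify_sign",
]


def _rc_from_frame(df: pd.DataFrame, provenance_label: str) -> RandomCoilTable:
    values = {}
    for _, row in df.iterrows():
        rc_cb = row["rc_cb"]
        values[str(row["residue"])] = (
            float(row["rc_ca"]),
            None if pd.isna(rc_cb) else float(rc_cb),
        )
    return RandomCoilTable(values, provenance_label=provenance_label)


def read_random_coil_csv(path: str, provenance_label: Optional[str] = None) -> RandomCoilTable:
    """Load a user-supplied random-coil table (columns residue, rc_ca, rc_cb)."""
    df = pd.read_csv(path)
    missing = {"residue", "rc_ca", "rc_cb"} - set(df.columns)
    if missing:
        raise DataError(f"random-coil CSV missing columns {sorted(missing)}")
    return _rc_from_frame(df, provenance_label or str(path))


def load_random_coil() -> RandomCoilTable:
    """Packaged generic CA/CB random-coil reference (Wishart-style values).

    The reference set is deliberately pluggable (see
    :func:`read_random_coil_csv`): absolute S values shift by a per-residue-
    type constant between published reference sets, though sign patterns are
    stable for strongly structured residues.
    """
    with resources.files("strainrank.data").joinpath("random_coil.csv").open() as fh:
        df = pd.read_csv(fh)
    return _rc_from_frame(
        df, "packaged Wishart-style random-coil CA/CB reference (DSS, pH/temp generic)"
    )


def secondary_shifts(shifts: ShiftTable, rc: RandomCoilTable) -> SecondaryShiftProfile:
    """Convert a shift table to per-residue dCA, dCB and S = dCA - dCB.

    Glycines (no CB) receive delta_ca only and no S value. A residue type not
    covered by the random-coil table raises :class:`DataError`.
    """
    entries = []
    for num in shifts.residue_numbers():
        rtype = shifts.residue_type(num)
        if rtype not in rc:
            raise DataError(f"residue type {rtype!r} at {num} not in random-coil table")
        ca = shifts.get(num, "CA")
        cb = shifts.get(num, "CB")
        delta_ca = None if ca is None else ca - rc.rc_ca(rtype)
        rc_cb = rc.rc_cb(rtype)
        delta_cb = None if (cb is None or rc_cb is None) else cb - rc_cb
        if delta_ca is None and delta_cb is None:
            continue  # residue assigned only for atoms outside CA/CB
        s = delta_ca - delta_cb if (delta_ca is not None and delta_cb is not None) else None
        entries.append(SecondaryShiftEntry(num, delta_ca, delta_cb, s))
    return SecondaryShiftProfile(entries, source_label=shifts.source_label)


def classify_sign(profile: SecondaryShiftProfile, epsilon_s: float = 0.0) -> dict[int, int]:
    """Map residue number -> sign of S in {-1, 0, +1}.

    ``epsilon_s`` is a dead-band: |S| < epsilon_s classifies as 0. The default
    0.0 is the strict sign used by the sign-disagreement count; the dead-band
    exists for sensitivity analysis only.
    """
    signs: dict[int, int] = {}
    for num, s in profile.s_values().items():
        if abs(s) < epsilon_s or s == 0.0:
            signs[num] = 0
        else:
            signs[num] = 1 if s > 0 else -1
    return signs
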