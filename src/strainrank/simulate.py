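"""Synthetic cross-beta fibril data with known ground truth.

The generator produces everything the comparison pipeline consumes, with the
statistical structure the analysis assumes: a backbone built to an explicit
per-segment torsion program (beta-strand background with localized kinks), a
noisy observed shift table generated by a forward model in which strand
residues have S = dCA - dCB < 0 and helical residues S > 0, and decoy
structures that differ from the truth only in where their kinks sit — the
feature that actually distinguishes fibril strains of one sequence.

All randomness flows through explicit seeds; no global random state is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DataError, ParameterError
from .geometry import Residue, StructureModel
from .tables import (
    AA_1TO3,
    RandomCoilTable,
    ShiftEntry,
    ShiftTable,
    TorsionEntry,
    TorsionTable,
    wrap_angle,
)

__all__ = [
    "Segment",
    "TorsionProgram",
    "ForwardShiftModel",
    "DEFAULT_OFFSETS",
    "TAU_DGAE_SEQUENCE",
    "TAU_DGAE_START",
    "STRAND_PHI_PSI",
    "KINK_PHI_PSI",
    "default_tau_program",
    "generate_backbone",
    "program_torsions",
    "simulate_shift_table",
    "make_decoys",
    "write_backbone_pdb",
    "write_minimal_nmrstar",
    "write_shiftx2_csv",
    "write_talosn_table",
]

SEGMENT_LABELS = ("strand", "helix", "kink", "coil")

#: tau(297-391) — the proteolysis-resistant PHF core fragment (dGAE),
#: 2N4R full-length numbering starting at I297
TAU_DGAE_SEQUENCE = (
    "IKHVPGGGS"                        # 297-305 (end of R2)
    "VQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQ"  # 306-336 (R3)
    "VEVKSEKLDFKDRVQSKIGSLDNITHVPGGGN"  # 337-368 (R4)
    "KKIETHKLTFRENAKAKTDHGAE"          # 369-391 (R')
)
TAU_DGAE_START = 297

STRAND_PHI_PSI = (-135.0, 135.0)
KINK_PHI_PSI = (-80.0, 0.0)

# ideal backbone geometry used by the generator
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_OMEGA = 180.0


@dataclass(frozen=True)
class Segment:
    start_residue: int
    end_residue: int  # inclusive
    phi: float
    psi: float
    label: str

    def __post_init__(self):
        if self.label not in SEGMENT_LABELS:
            raise ParameterError(f"unknown segment label {self.label!r}")
        if self.end_residue < self.start_residue:
            raise ParameterError("segment end before start")

    def __len__(self) -> int:
        return self.end_residue - self.start_residue + 1


@dataclass
class TorsionProgram:
    """Per-segment phi/psi program over a sequence (ground-truth secondary
    structure of one synthetic fibril core)."""

    segments: list[Segment]
    sequence: str
    start_residue: int = 1
    name: str = "truth"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if any(c not in AA_1TO3 for c in self.sequence):
            raise ParameterError("sequence contains non-standard residues")
        segs = sorted(self.segments, key=lambda s: s.start_residue)
        expected = self.start_residue
        for s in segs:
            if s.start_residue != expected:
                raise ParameterError(
                    "segments must be contiguous, non-overlapping and cover the sequence"
                )
            expected = s.end_residue + 1
        if expected != self.start_residue + len(self.sequence):
            raise ParameterError("segments do not cover the sequence exactly")
        self.segments = [
            Segment(s.start_residue, s.end_residue, wrap_angle(s.phi), wrap_angle(s.psi), s.label)
            for s in segs
        ]

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_numbers(self) -> list[int]:
        return list(range(self.start_residue, self.start_residue + len(self.sequence)))

    def residue_type(self, residue_number: int) -> str:
        return self.sequence[residue_number - self.start_residue]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Per-residue (phi, psi, label) arrays in residue order."""
        n = len(self.sequence)
        phi = np.empty(n)
        psi = np.empty(n)
        labels = [""] * n
        for s in self.segments:
            lo = s.start_residue - self.start_residue
            hi = s.end_residue - self.start_residue + 1
            phi[lo:hi] = s.phi
            psi[lo:hi] = s.psi
            for k in range(lo, hi):
                labels[k] = s.label
        return phi, psi, labels

    def label_of(self, residue_number: int) -> str:
        for s in self.segments:
            if s.start_residue <= residue_number <= s.end_residue:
                return s.label
        raise KeyError(residue_number)

    def kinks(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "kink"]


def default_tau_program(name: str = "truth") -> TorsionProgram:
    """Ground-truth program for the packaged tau(297-391) system.

    Beta-strand background with two kink windows placed on the repeat-region
    PGGG turns (332-335 and 364-367), where real tau fibril folds localize
    their departures from extended conformation.
    """
    segs = [
        Segment(297, 331, *STRAND_PHI_PSI, "strand"),
        Segment(332, 335, *KINK_PHI_PSI, "kink"),
        Segment(336, 363, *STRAND_PHI_PSI, "strand"),
        Segment(364, 367, *KINK_PHI_PSI, "kink"),
        Segment(368, 391, *STRAND_PHI_PSI, "strand"),
    ]
    return TorsionProgram(segs, TAU_DGAE_SEQUENCE, TAU_DGAE_START, name=name)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: new atom d with |c-d| = bond,
    angle(b,c,d) = angle_deg and torsion(a,b,c,d) = torsion_deg."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_backbone(program: TorsionProgram, chain_id: str = "A") -> StructureModel:
    """Build an N/CA/C backbone realizing the program's phi/psi exactly.

    Ideal bond lengths (N-CA 1.458, CA-C 1.525, C-N 1.329 A), fixed bond
    angles and trans peptide bonds (omega = 180 deg) are used; construction
    is deterministic. phi of the first residue and psi of the last are not
    realizable (no flanking peptide plane) and are ignored.
    """
    nres = len(program.sequence)
    if nres < 3:
        raise ParameterError("backbone generation needs at least 3 residues")
    phi, psi, _ = program.arrays()

    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    theta = math.radians(180.0 - _ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([math.cos(math.pi - theta), math.sin(math.pi - theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, nres):
        prev = coords[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues = [
        Residue(program.start_residue + i, program.sequence[i], coords[i])
        for i in range(nres)
    ]
    return StructureModel(program.name, chain_id, residues)


def program_torsions(program: TorsionProgram, source_label: Optional[str] = None,
                     interior_only: bool = True) -> TorsionTable:
    """The program's own phi/psi as a :class:`TorsionTable` (exact values).

    With ``interior_only`` (default) the first and last residues are dropped,
    mirroring which angles a backbone can actually realize.
    """
    nums = program.residue_numbers()
    if interior_only:
        nums = nums[1:-1]
    phi, psi, _ = program.arrays()
    entries = [
        TorsionEntry(
            num,
            program.residue_type(num),
            phi[num - program.start_residue],
            psi[num - program.start_residue],
            "Strong",
        )
        for num in nums
    ]
    return TorsionTable(entries, source_label=source_label or program.name)


DEFAULT_OFFSETS = {
    "strand": (-1.5, 2.0),
    "helix": (2.6, -0.5),
    "kink": (0.0, 0.0),
    "coil": (0.0, 0.0),
}


@dataclass
class ForwardShiftModel:
    """Forward model mapping secondary-structure label to CA/CB shift offsets.

    Offsets are added to the random-coil value per residue, plus i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` (ppm) per atom. The
    default offsets encode the sign rule the S statistic relies on: strands
    give S < 0, helices S > 0; they are simulator parameters, not literature
    shift predictions.
    """

    offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        d_ca, d_cb = self.offsets["strand"]
        if not (d_ca < 0 < d_cb):
            raise ParameterError("strand offsets must satisfy dCA < 0 < dCB (S < 0)")
        d_ca, d_cb = self.offsets["helix"]
        if not (d_cb < 0 < d_ca):
            raise ParameterError("helix offsets must satisfy dCA > 0 > dCB (S > 0)")


def simulate_shift_table(
    program: TorsionProgram,
    rc: RandomCoilTable,
    model: ForwardShiftModel,
    source_label: str = "NMR",
) -> ShiftTable:
    """Observed-style shift table for a program under the forward model.

    dCA_i = rc_CA(type_i) + offset_CA(label_i) + N(0, noise_sd^2), CB
    analogous; glycines emit CA only. Reproducible from ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    entries = []
    for num in program.residue_numbers():
        rtype = program.residue_type(num)
        if rtype not in rc:
            raise DataError(f"residue type {rtype!r} not covered by random-coil table")
        d_ca, d_cb = model.offsets[program.label_of(num)]
        ca = rc.rc_ca(rtype) + d_ca
        if model.noise_sd > 0:
            ca += rng.normal(0.0, model.noise_sd)
        entries.append(ShiftEntry(num, rtype, "CA", ca))
        rc_cb = rc.rc_cb(rtype)
        if rc_cb is not None:
            cb = rc_cb + d_cb
            if model.noise_sd > 0:
                cb += rng.normal(0.0, model.noise_sd)
            entries.append(ShiftEntry(num, rtype, "CB", cb))
    return ShiftTable(entries, source_label=source_label)


def _signed_offsets(kink_shift_range: Union[int, tuple[int, int]]) -> list[int]:
    if isinstance(kink_shift_range, int):
        lo, hi = 1, kink_shift_range
    else:
        lo, hi = kink_shift_range
    if not (1 <= lo <= hi):
        raise ParameterError(f"infeasible kink shift range {kink_shift_range!r}")
    mags = range(lo, hi + 1)
    return [-m for m in mags] + [m for m in mags]


def make_decoys(
    truth: TorsionProgram,
    n_decoys: int,
    kink_shift_range: Union[int, tuple[int, int]] = 4,
    seed: int = 0,
) -> list[TorsionProgram]:
    """Decoy programs differing from truth only in kink placement.

    Every kink of the truth program is translated by a nonzero signed offset
    (magnitude within ``kink_shift_range``, an int max or (min, max) tuple);
    the joint offset vectors are drawn without replacement, so all decoys are
    distinct from the truth and from each other. Vacated positions revert to
    the flanking strand's phi/psi. Raises :class:`ParameterError` when fewer
    feasible placements exist than requested decoys.
    """
    kinks = truth.kinks()
    if not kinks:
        raise ParameterError("truth program has no kink segment to move")
    phi0, psi0, labels0 = truth.arrays()
    n = len(truth.sequence)
    offsets = _signed_offsets(kink_shift_range)

    kink_windows = [
        (k.start_residue - truth.start_residue, len(k)) for k in kinks
    ]
    protected = {
        i for i, lab in enumerate(labels0) if lab not in ("strand", "kink")
    }

    def feasible(combo: tuple[int, ...]) -> bool:
        new_windows = []
        for (lo, length), off in zip(kink_windows, combo):
            nlo = lo + off
            if nlo < 0 or nlo + length > n:
                return False
            win = set(range(nlo, nlo + length))
            if win & protected:
                return False
            new_windows.append(win)
        for a, b in itertools.combinations(new_windows, 2):
            if a & b:
                return False
        return True

    combos = [c for c in itertools.product(offsets, repeat=len(kinks)) if feasible(c)]
    if len(combos) < n_decoys:
        raise ParameterError(
            f"only {len(combos)} feasible decoy placements for {n_decoys} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = [combos[i] for i in rng.choice(len(combos), size=n_decoys, replace=False)]

    # strand background to fill vacated kink windows
    strand_segs = [s for s in truth.segments if s.label == "strand"]
    if not strand_segs:
        raise ParameterError("decoy generation expects a strand background")
    bg_phi, bg_psi = strand_segs[0].phi, strand_segs[0].psi

    decoys = []
    for d, combo in enumerate(chosen):
        phi, psi, labels = phi0.copy(), psi0.copy(), list(labels0)
        for (lo, length), kink, off in zip(kink_windows, kinks, combo):
            for i in range(lo, lo + length):
                phi[i], psi[i], labels[i] = bg_phi, bg_psi, "strand"
        for (lo, length), kink, off in zip(kink_windows, kinks, combo):
            for i in range(lo + off, lo + off + length):
                phi[i], psi[i], labels[i] = kink.phi, kink.psi, "kink"
        segs = []
        run_start = 0
        for i in range(1, n + 1):
            if i == n or (phi[i], psi[i], labels[i]) != (phi[run_start], psi[run_start], labels[run_start]):
                segs.append(
                    Segment(
                        truth.start_residue + run_start,
                        truth.start_residue + i - 1,
                        phi[run_start],
                        psi[run_start],
                        labels[run_start],
                    )
                )
                run_start = i
        decoys.append(
            TorsionProgram(segs, truth.sequence, truth.start_residue, name=f"decoy{d + 1:02d}")
        )
    return decoys


# ---------------------------------------------------------------------------
# fixture writers: every reader in the I/O layer has a generated test input

def write_backbone_pdb(model: StructureModel, path: str) -> None:
    """Write an N/CA/C backbone as a minimal single-chain PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.structure_id
    md = gemmi.Model(1)
    chain = gemmi.Chain(model.chain_id)
    for res in model.residues:
        r = gemmi.Residue()
        r.name = AA_1TO3[res.residue_type]
        r.seqid = gemmi.SeqId(res.residue_number, " ")
        r.het_flag = "A"
        for atom_name in ("N", "CA", "C"):
            if atom_name not in res.atoms:
                continue
            a = gemmi.Atom()
            a.name = atom_name
            x, y, z = res.atoms[atom_name]
            a.pos = gemmi.Position(float(x), float(y), float(z))
            a.element = gemmi.Element(atom_name[0])
            a.occ = 1.0
            a.b_iso = 0.0
            r.add_atom(a)
        chain.add_residue(r)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


def write_minimal_nmrstar(table: ShiftTable, path: str, entry_id: str = "synthetic") -> None:
    """Write a minimal NMR-STAR v3 assigned-chemical-shift saveframe.

    Values are written with full float precision so a read-back round-trips
    bit-for-bit. Residue numbers go to both Seq_ID (1-based) and Auth_seq_ID
    (as tabulated).
    """
    nums = table.residue_numbers()
    first = min(nums) if nums else 1
    lines = [
        f"data_{entry_id}",
        "",
        "save_assigned_chem_shift_list_1",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.ID             1",
        "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Entity_ID",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "      _Atom_chem_shift.Auth_seq_ID",
    ]
    for i, e in enumerate(table.entries, start=1):
        lines.append(
            f"      {i} 1 {e.residue_number - first + 1} {AA_1TO3[e.residue_type]} "
            f"{e.atom_name} {e.shift!r} {e.residue_number}"
        )
    lines += ["   stop_", "save_", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_shiftx2_csv(table: ShiftTable, path: str) -> None:
    """Write a ShiftX2-style CSV (NUM,RES,ATOMNAME,SHIFT), full precision."""
    with open(path, "w") as fh:
        fh.write("NUM,RES,ATOMNAME,SHIFT\n")
        for e in table.entries:
            fh.write(f"{e.residue_number},{e.residue_type},{e.atom_name},{e.shift!r}\n")


def write_talosn_table(torsions: TorsionTable, path: str) -> None:
    """Write a TALOS-N-style prediction table (pred.tab layout)."""
    lines = [
        "REMARK synthetic torsion predictions",
        f"DATA FIRST_RESID {torsions.residue_numbers()[0] if len(torsions) else 1}",
        "",
        "VARS   RESID RESNAME PHI PSI DPHI DPSI DIST S2 COUNT CS_COUNT CLASS",
        "FORMAT %4d %s %8.3f %8.3f %8.3f %8.3f %8.3f %5.3f %2d %2d %s",
        "",
    ]
    for e in torsions.entries:
        cls = e.classification_flag or "Strong"
        lines.append(
            f"{e.residue_number:4d} {e.residue_type} {e.phi:8.3f} {e.psi:8.3f} "
            f"{5.0:8.3f} {5.0:8.3f} {0.0:8.3f} {0.900:5.3f} 25  6 {cls}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
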