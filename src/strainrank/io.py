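"""Readers and writers for the external formats the pipeline touches.

Observed assignments arrive as NMR-STAR v3 (the BMRB deposition format, read
here through gemmi's STAR/CIF parser), structure-calculated shifts as
ShiftX2-style tables, shift-derived torsion predictions as TALOS-N prediction
tables, and results leave as CSV/JSON metric reports. Every reader is a pure
function of the file content.
"""

from __future__ import annotations

import json
import logging
from typing import Optional, Sequence

import gemmi
import pandas as pd

from .errors import DataError, FormatError
from .metrics import REPORT_COLUMNS, MetricReport
from .tables import (
    ShiftEntry,
    ShiftTable,
    TorsionEntry,
    TorsionTable,
    normalize_atom_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_nmrstar_shifts",
    "read_shiftx2_output",
    "read_talosn_predictions",
    "write_metric_report",
    "read_metric_report",
]

_CS_TAGS = [
    "_Atom_chem_shift.Entity_ID",
    "_Atom_chem_shift.Seq_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
    "_Atom_chem_shift.Auth_seq_ID",
]


def _find_shift_loop(doc) -> list[gemmi.cif.Table]:
    # NMR-STAR keeps the loop inside an assigned_chemical_shifts saveframe,
    # but tolerate a bare block-level loop too
    tables = []
    for block in doc:
        scopes = [block] + [item.frame for item in block if item.frame is not None]
        for scope in scopes:
            t = scope.find_mmcif_category("_Atom_chem_shift.")
            if len(t) > 0:
                tables.append(t)
    return tables


def read_nmrstar_shifts(
    path: str,
    entity_selector: Optional[str] = None,
    residue_offset: Optional[int] = None,
    source_label: str = "NMR",
) -> ShiftTable:
    """Read the assigned-chemical-shift loop of an NMR-STAR v3 file.

    Residue numbering policy: the author numbering column (``Auth_seq_ID``)
    is used when present — BMRB depositions for tau carry full-length 2N4R
    numbers there — otherwise the sequence-relative ``Seq_ID`` plus
    ``residue_offset`` (default 0). The offset never touches author numbers,
    which are taken as already being in the full-length frame.

    ``entity_selector`` restricts rows to one Entity_ID. Duplicate
    (residue, atom) rows and glycine CB rows are rejected with a
    :class:`DataError` naming the residue.
    """
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse NMR-STAR file {path}: {exc}") from None
    loops = _find_shift_loop(doc)
    if not loops:
        raise FormatError(f"{path}: no assigned chemical shift loop (_Atom_chem_shift)")

    entries = []
    for table in loops:
        tags = [t[len("_Atom_chem_shift.") :] for t in table.tags]
        col = {name: i for i, name in enumerate(tags)}
        for need in ("Seq_ID", "Comp_ID", "Atom_ID", "Val"):
            if need not in col:
                raise FormatError(f"{path}: shift loop lacks _Atom_chem_shift.{need}")
        for row in table:
            if entity_selector is not None and "Entity_ID" in col:
                if row[col["Entity_ID"]] != str(entity_selector):
                    continue
            auth = row[col["Auth_seq_ID"]] if "Auth_seq_ID" in col else "."
            if auth not in (".", "?", ""):
                num = int(auth)
            else:
                num = int(row[col["Seq_ID"]]) + (residue_offset or 0)
            comp = row[col["Comp_ID"]]
            atom = row[col["Atom_ID"]]
            try:
                val = float(row[col["Val"]])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric shift {row[col['Val']]!r} at residue {num}"
                ) from None
            entries.append(ShiftEntry(num, comp, atom, val))
    try:
        return ShiftTable(entries, source_label=source_label)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from None


_SHIFTX2_ACCEPTED = {"CA", "CB", "C", "N"}

_SHIFTX2_COLNAMES = {
    "num": {"NUM", "RESID", "RES_NUM", "RESNUM", "NUMBER"},
    "res": {"RES", "RESNAME", "RES_NAME", "AA"},
    "atom": {"ATOMNAME", "ATOM", "ATOM_NAME", "NUCLEUS"},
    "shift": {"SHIFT", "VALUE", "CS", "PREDICTED"},
}


def read_shiftx2_output(path: str, structure_id: str) -> ShiftTable:
    """Read a ShiftX2-style predicted-shift table (CSV or whitespace columns).

    Only backbone-relevant atoms (CA, CB, C/CO, N) are kept; other rows are
    skipped and the skip count logged. The result carries
    ``source_label = "Cal:<structure_id>"``.
    """
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty ShiftX2 table")

    def split(ln: str) -> list[str]:
        return [f.strip() for f in ln.split(",")] if "," in ln else ln.split()

    cols = {"num": 0, "res": 1, "atom": 2, "shift": 3}
    first_fields = split(lines[0][1])
    header_like = any(f.upper() in _SHIFTX2_COLNAMES["shift"] | _SHIFTX2_COLNAMES["num"]
                      for f in first_fields)
    if header_like:
        upper = [f.upper() for f in first_fields]
        for key, names in _SHIFTX2_COLNAMES.items():
            hits = [i for i, f in enumerate(upper) if f in names]
            if not hits:
                raise FormatError(
                    f"{path}: line {lines[0][0]}: cannot locate a {key} column in header"
                )
            cols[key] = hits[0]
        lines = lines[1:]

    entries = []
    skipped = 0
    for lineno, ln in lines:
        fields = split(ln)
        if len(fields) <= max(cols.values()):
            raise FormatError(f"{path}: line {lineno}: too few columns")
        atom = normalize_atom_name(fields[cols["atom"]])
        if atom not in _SHIFTX2_ACCEPTED:
            skipped += 1
            continue
        try:
            num = int(fields[cols["num"]])
            val = float(fields[cols["shift"]])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric residue number or shift"
            ) from None
        entries.append(ShiftEntry(num, fields[cols["res"]], atom, val))
    if skipped:
        logger.info("%s: skipped %d non-backbone atom rows", path, skipped)
    return ShiftTable(entries, source_label=f"Cal:{structure_id}")


DEFAULT_TALOS_CLASSES = ("Strong", "Generous")


def read_talosn_predictions(
    path: str,
    accepted_classes: Sequence[str] = DEFAULT_TALOS_CLASSES,
    source_label: str = "NMR",
) -> TorsionTable:
    """Read a TALOS-N prediction table (pred.tab layout).

    The ``VARS`` header line names the columns; PHI and PSI must be present.
    Only rows whose classification is in ``accepted_classes`` (default
    confident predictions: Strong, Generous) and whose angles are real
    predictions (not the 9999 placeholder) are kept; drops are logged.
    Angles are normalized to (-180, 180].
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    vars_line = None
    data_rows: list[tuple[int, list[str]]] = []
    for i, ln in enumerate(raw):
        s = ln.strip()
        if not s or s.startswith(("REMARK", "DATA", "FORMAT", "#")):
            continue
        if s.startswith("VARS"):
            vars_line = s.split()[1:]
            continue
        data_rows.append((i + 1, s.split()))
    if vars_line is None:
        # headerless table: assume the canonical column order
        vars_line = ["RESID", "RESNAME", "PHI", "PSI", "DPHI", "DPSI", "DIST", "S2", "COUNT", "CS_COUNT", "CLASS"]
    col = {name.upper(): i for i, name in enumerate(vars_line)}
    for need in ("RESID", "RESNAME", "PHI", "PSI"):
        if need not in col:
            raise FormatError(f"{path}: prediction table lacks a {need} column")

    accepted = {c.lower() for c in accepted_classes}
    entries = []
    dropped: list[int] = []
    for lineno, fields in data_rows:
        if len(fields) <= max(col["RESID"], col["RESNAME"], col["PHI"], col["PSI"]):
            raise FormatError(f"{path}: line {lineno}: too few columns")
        try:
            num = int(fields[col["RESID"]])
            phi = float(fields[col["PHI"]])
            psi = float(fields[col["PSI"]])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric field") from None
        cls = fields[col["CLASS"]] if "CLASS" in col and len(fields) > col["CLASS"] else "Strong"
        if cls.lower() not in accepted or abs(phi) > 360.0 + 1e-9 or abs(psi) > 360.0 + 1e-9:
            dropped.append(num)
            continue
        entries.append(TorsionEntry(num, fields[col["RESNAME"]], phi, psi, cls))
    if dropped:
        logger.info("%s: dropped %d residues outside accepted classes: %s",
                    path, len(dropped), dropped)
    return TorsionTable(entries, source_label=source_label)


def write_metric_report(report: MetricReport, path: str, format: str = "csv") -> None:
    """Write a metric report as CSV (flat table) or JSON (table + per-residue).

    Column order is fixed (structure_id, sigma_cs_ppm, n_cs, sigma_a, n_a,
    sigma_psiphi_deg, n_psiphi, rank_cs, rank_a, rank_psiphi, fold_label) and
    row order is the report's deterministic ranking order.
    """
    if report.frame.empty:
        raise DataError("refusing to write an empty metric report")
    if format == "csv":
        report.frame.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "rows": report.frame.to_dict(orient="records"),
            "per_residue": {
                sid: {str(k): v for k, v in sorted(vals.items())}
                for sid, vals in report.per_residue.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_metric_report(path: str, format: str = "csv") -> MetricReport:
    """Inverse of :func:`write_metric_report` (value-preserving round-trip)."""
    if format == "csv":
        df = pd.read_csv(path)
        per_res: dict = {}
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["rows"])
        per_res = {
            sid: {int(k): float(v) for k, v in vals.items()}
            for sid, vals in payload["per_residue"].items()
        }
    else:
        raise FormatError(f"unknown report format {format!r}")
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: report missing columns {sorted(missing)}")
    df = df[REPORT_COLUMNS]
    df["fold_label"] = df["fold_label"].astype(object).where(df["fold_label"].notna(), None)
    for col in ("n_cs", "sigma_a", "n_a", "n_psiphi", "rank_cs", "rank_a", "rank_psiphi"):
        df[col] = df[col].astype(int)
    for col in ("sigma_cs_ppm", "sigma_psiphi_deg"):
        df[col] = df[col].astype(float)
    return MetricReport(df, per_res)
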