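"""Strain-discrimination metrics and structure ranking.

Three scalar metrics compare an observed NMR assignment against one candidate
fibril core structure over the matched residues:

* ``sigma_cs`` — sum over residues of |dCA_cal - dCA_nmr| + |dCB_cal -
  dCB_nmr| in ppm (absolute per-residue CA and CB chemical-shift difference);
* ``sigma_a`` — number of residues whose S = dCA - dCB statistic has opposite
  sign on the two sides (a zero product counts as agreement), i.e. a count of
  secondary-structure sign disagreements that localizes kink placement;
* ``sigma_psiphi`` — sum over residues of |phi_cal - phi_nmr| +
  |psi_cal - psi_nmr| in degrees, by default using the minimal circular
  difference in [0, 180].

``delta_alphabeta`` is the per-residue decomposition of ``sigma_cs`` (its sum
over residues equals sigma_cs exactly), used for structure coloring.
``rank_structures`` assembles per-structure values into a report ranked
independently per metric, sorted by ascending sign-disagreement count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import DataError, ParameterError
from .shifts import classify_sign
from .tables import SecondaryShiftProfile, ShiftTable, TorsionTable

__all__ = [
    "AMBIGUOUS_POLICIES",
    "TAU_PGGG_GROUPS",
    "ResidueFlags",
    "MatchedResidueSet",
    "match_residues",
    "sigma_cs",
    "sigma_a",
    "sigma_psiphi",
    "delta_alphabeta",
    "MetricRow",
    "MetricReport",
    "rank_structures",
]

#: the two repeat-region PGGG windows (2N4R numbering) whose assignment is
#: ambiguous in the tau(297-391) system
TAU_PGGG_GROUPS = ((332, 335), (364, 367))

AMBIGUOUS_POLICIES = ("exclude", "assign-to-first", "assign-to-second", "both")
_POLICY_ALIASES = {"assign-to-332": "assign-to-first", "assign-to-364": "assign-to-second"}


@dataclass(frozen=True)
class ResidueFlags:
    nmr_ca: bool = False
    nmr_cb: bool = False
    cal_ca: bool = False
    cal_cb: bool = False
    nmr_phi_psi: bool = False
    cal_phi_psi: bool = False


@dataclass
class MatchedResidueSet:
    """Per-residue eligibility flags for each metric.

    ``pairs`` maps residue number to :class:`ResidueFlags`; eligibility is
    derived per metric (a CA term needs the CA shift on both sides, the sign
    metric needs CA and CB on both sides, the torsion metric needs phi/psi on
    both sides). ``mask_label`` records the matching policy for audit.
    """

    pairs: dict[int, ResidueFlags]
    mask_label: str = ""

    def residues(self) -> list[int]:
        return sorted(self.pairs)

    def cs_ca(self) -> list[int]:
        return [r for r, f in sorted(self.pairs.items()) if f.nmr_ca and f.cal_ca]

    def cs_cb(self) -> list[int]:
        return [r for r, f in sorted(self.pairs.items()) if f.nmr_cb and f.cal_cb]

    def a_eligible(self) -> list[int]:
        return [
            r
            for r, f in sorted(self.pairs.items())
            if f.nmr_ca and f.nmr_cb and f.cal_ca and f.cal_cb
        ]

    def psiphi_eligible(self) -> list[int]:
        return [
            r for r, f in sorted(self.pairs.items()) if f.nmr_phi_psi and f.cal_phi_psi
        ]


def _group_residues(groups: Sequence[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for lo, hi in groups:
        out.update(range(lo, hi + 1))
    return out


def match_residues(
    nmr_shifts: ShiftTable,
    cal_shifts: ShiftTable,
    nmr_torsions: Optional[TorsionTable] = None,
    cal_torsions: Optional[TorsionTable] = None,
    ambiguous_policy: str = "exclude",
    ambiguous_groups: Sequence[tuple[int, int]] = (),
) -> MatchedResidueSet:
    """Intersect the observed and calculated tables into per-metric masks.

    All tables must already share one numbering frame. ``ambiguous_groups``
    lists residue ranges (inclusive) whose observed assignment cannot be
    placed uniquely (e.g. a PGGG stretch fitting two repeats);
    ``ambiguous_policy`` decides their fate: ``exclude`` (default) drops them
    from every metric, ``assign-to-first``/``assign-to-second`` keep only the
    named group, ``both`` keeps all groups as tabulated.
    """
    policy = _POLICY_ALIASES.get(ambiguous_policy, ambiguous_policy)
    if policy not in AMBIGUOUS_POLICIES:
        raise ParameterError(
            f"unknown ambiguous_policy {ambiguous_policy!r}; expected one of "
            f"{AMBIGUOUS_POLICIES + tuple(_POLICY_ALIASES)}"
        )
    drop: set[int] = set()
    if ambiguous_groups:
        if policy == "exclude":
            drop = _group_residues(ambiguous_groups)
        elif policy == "assign-to-first":
            drop = _group_residues(ambiguous_groups[1:])
        elif policy == "assign-to-second":
            drop = _group_residues(ambiguous_groups[:1])
        # "both": keep everything

    nmr_t = nmr_torsions.residue_numbers() if nmr_torsions is not None else []
    cal_t = cal_torsions.residue_numbers() if cal_torsions is not None else []
    candidates = (
        set(nmr_shifts.residue_numbers()) | set(nmr_t)
    ) & (set(cal_shifts.residue_numbers()) | set(cal_t))
    candidates -= drop

    pairs: dict[int, ResidueFlags] = {}
    for num in sorted(candidates):
        flags = ResidueFlags(
            nmr_ca=nmr_shifts.has(num, "CA"),
            nmr_cb=nmr_shifts.has(num, "CB"),
            cal_ca=cal_shifts.has(num, "CA"),
            cal_cb=cal_shifts.has(num, "CB"),
            nmr_phi_psi=num in nmr_t,
            cal_phi_psi=num in cal_t,
        )
        pairs[num] = flags
    if not pairs:
        raise DataError(
            "no residues in common between the observed and calculated tables"
        )
    return MatchedResidueSet(pairs, mask_label=f"policy={policy}")


def sigma_cs(
    nmr: ShiftTable,
    cal: ShiftTable,
    matched: MatchedResidueSet,
    partial_atoms: bool = True,
) -> tuple[float, int]:
    """Summed absolute CA+CB shift difference (ppm) and residue count.

    With ``partial_atoms`` (default) a residue missing one atom on either
    side still contributes the available atom's term; with it off, non-
    glycine residues must have CA and CB on both sides to contribute at all.
    ``n`` counts residues contributing at least one term.
    """
    total = 0.0
    contributing: set[int] = set()
    ca_set = set(matched.cs_ca())
    cb_set = set(matched.cs_cb())
    for num in matched.residues():
        has_ca = num in ca_set
        has_cb = num in cb_set
        if not partial_atoms:
            is_gly = nmr.residue_type(num) == "G" or cal.residue_type(num) == "G"
            if not is_gly and not (has_ca and has_cb):
                continue
            if is_gly and not has_ca:
                continue
        terms = 0.0
        used = False
        if has_ca:
            terms += abs(cal.get(num, "CA") - nmr.get(num, "CA"))
            used = True
        if has_cb:
            terms += abs(cal.get(num, "CB") - nmr.get(num, "CB"))
            used = True
        if used:
            total += terms
            contributing.add(num)
    return total, len(contributing)


def sigma_a(
    nmr_profile: SecondaryShiftProfile,
    cal_profile: SecondaryShiftProfile,
    matched: MatchedResidueSet,
    epsilon_s: float = 0.0,
) -> tuple[int, int]:
    """Count residues whose S statistic changes sign between the two sides.

    A residue scores 1 when S_cal * S_nmr < 0 and 0 otherwise, so a zero S on
    either side counts as agreement. ``epsilon_s`` widens "zero" to a
    dead-band for sensitivity analysis. Returns (count, n_eligible).
    """
    nmr_sign = classify_sign(nmr_profile, epsilon_s)
    cal_sign = classify_sign(cal_profile, epsilon_s)
    count = 0
    n = 0
    for num in matched.a_eligible():
        sn = nmr_sign.get(num)
        sc = cal_sign.get(num)
        if sn is None or sc is None:
            continue
        n += 1
        if sn * sc < 0:
            count += 1
    if n == 0:
        raise DataError("no residues eligible for the sign-disagreement metric")
    return count, n


def _angle_diff(a: float, b: float, circular: bool) -> float:
    d = abs(a - b)
    if circular:
        d = min(d, 360.0 - d)
    return d


def sigma_psiphi(
    nmr_torsions: TorsionTable,
    cal_torsions: TorsionTable,
    matched: MatchedResidueSet,
    circular: bool = True,
) -> tuple[float, int]:
    """Summed absolute phi/psi difference (degrees) and residue count.

    With ``circular`` (default) each difference is the minimal circular
    distance in [0, 180], so a 170 vs -170 pair scores 20 not 340; the naive
    behaviour is available for sensitivity checks.
    """
    total = 0.0
    n = 0
    for num in matched.psiphi_eligible():
        en = nmr_torsions.get(num)
        ec = cal_torsions.get(num)
        if en is None or ec is None:
            continue
        total += _angle_diff(ec.phi, en.phi, circular)
        total += _angle_diff(ec.psi, en.psi, circular)
        n += 1
    if n == 0:
        raise DataError("no residues eligible for the torsion-difference metric")
    return total, n


def delta_alphabeta(
    nmr: ShiftTable,
    cal: ShiftTable,
    matched: MatchedResidueSet,
    partial_atoms: bool = True,
) -> dict[int, float]:
    """Per-residue |dCA| + |dCB| shift difference (ppm).

    The values sum exactly to :func:`sigma_cs` over the same matched set;
    this is the per-residue diagnostic used to color structures.
    """
    ca_set = set(matched.cs_ca())
    cb_set = set(matched.cs_cb())
    out: dict[int, float] = {}
    for num in matched.residues():
        has_ca = num in ca_set
        has_cb = num in cb_set
        if not partial_atoms:
            is_gly = nmr.residue_type(num) == "G" or cal.residue_type(num) == "G"
            if not is_gly and not (has_ca and has_cb):
                continue
            if is_gly and not has_ca:
                continue
        val = 0.0
        used = False
        if has_ca:
            val += abs(cal.get(num, "CA") - nmr.get(num, "CA"))
            used = True
        if has_cb:
            val += abs(cal.get(num, "CB") - nmr.get(num, "CB"))
            used = True
        if used:
            out[num] = val
    return out


@dataclass
class MetricRow:
    structure_id: str
    sigma_cs: float
    n_cs: int
    sigma_a: int
    n_a: int
    sigma_psiphi: float
    n_psiphi: int
    fold_label: Optional[str] = None
    per_residue_delta_ab: dict[int, float] = field(default_factory=dict)


@dataclass
class MetricReport:
    """Ranked per-structure metric table (machine-readable analogue of a
    strain-comparison summary table).

    ``frame`` columns: structure_id, sigma_cs_ppm, n_cs, sigma_a, n_a,
    sigma_psiphi_deg, n_psiphi, rank_cs, rank_a, rank_psiphi, fold_label.
    Rows are sorted by ascending sigma_a, ties broken by ascending
    sigma_psiphi then structure_id. Rank columns are independent per metric,
    ascending, ties sharing the smaller rank.
    """

    frame: pd.DataFrame
    per_residue: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self):
        for col, lo in (("sigma_cs_ppm", 0.0), ("sigma_psiphi_deg", 0.0)):
            if (self.frame[col] < lo).any():
                raise DataError(f"{col} must be non-negative")
        if ((self.frame["sigma_a"] < 0) | (self.frame["sigma_a"] > self.frame["n_a"])).any():
            raise DataError("sigma_a must lie in [0, n_a]")

    def row(self, structure_id: str) -> pd.Series:
        sel = self.frame[self.frame["structure_id"] == structure_id]
        if sel.empty:
            raise KeyError(structure_id)
        return sel.iloc[0]

    def best(self, metric: str = "sigma_a") -> str:
        col = {"sigma_cs": "rank_cs", "sigma_a": "rank_a", "sigma_psiphi": "rank_psiphi"}[metric]
        return str(self.frame.loc[self.frame[col].idxmin(), "structure_id"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetricReport):
            return NotImplemented
        return self.frame.equals(other.frame) and self.per_residue == other.per_residue


REPORT_COLUMNS = [
    "structure_id",
    "sigma_cs_ppm",
    "n_cs",
    "sigma_a",
    "n_a",
    "sigma_psiphi_deg",
    "n_psiphi",
    "rank_cs",
    "rank_a",
    "rank_psiphi",
    "fold_label",
]


def rank_structures(rows: Iterable[MetricRow]) -> MetricReport:
    """Rank candidate structures per metric and assemble the report.

    Each metric is ranked independently, ascending (minimal value gets rank
    1; ties share the smaller rank). The output row order is ascending
    sigma_a, ties broken by ascending sigma_psiphi, then structure_id
    lexicographically — so the first row is the overall sign-metric winner.
    """
    rows = list(rows)
    if not rows:
        raise DataError("rank_structures needs at least one structure")
    ids = [r.structure_id for r in rows]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate structure_id in ranking input")
    df = pd.DataFrame(
        {
            "structure_id": ids,
            "sigma_cs_ppm": [r.sigma_cs for r in rows],
            "n_cs": [r.n_cs for r in rows],
            "sigma_a": [r.sigma_a for r in rows],
            "n_a": [r.n_a for r in rows],
            "sigma_psiphi_deg": [r.sigma_psiphi for r in rows],
            "n_psiphi": [r.n_psiphi for r in rows],
            "fold_label": [r.fold_label for r in rows],
        }
    )
    df["rank_cs"] = df["sigma_cs_ppm"].rank(method="min").astype(int)
    df["rank_a"] = df["sigma_a"].rank(method="min").astype(int)
    df["rank_psiphi"] = df["sigma_psiphi_deg"].rank(method="min").astype(int)
    df = df.sort_values(
        ["sigma_a", "sigma_psiphi_deg", "structure_id"], kind="mergesort"
    ).reset_index(drop=True)
    df = df[REPORT_COLUMNS]
    per_res = {r.structure_id: dict(r.per_residue_delta_ab) for r in rows}
    return MetricReport(df, per_res)
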