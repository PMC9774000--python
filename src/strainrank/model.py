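"""Model/results interface for assignment-vs-structure comparison.

:class:`StrainComparison` is built from an observed shift table (and
optionally observed torsion predictions) plus a panel of candidate fibril
core structures; :meth:`StrainComparison.fit` evaluates the three
discrimination metrics and the per-residue shift-difference diagnostic for
every candidate and returns a :class:`StrainComparisonResults` holding the
ranked report, per-residue series for plotting, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import DataError
from .metrics import (
    MatchedResidueSet,
    MetricReport,
    MetricRow,
    delta_alphabeta,
    match_residues,
    rank_structures,
    sigma_a,
    sigma_cs,
    sigma_psiphi,
)
from .shifts import load_random_coil, secondary_shifts
from .tables import RandomCoilTable, SecondaryShiftProfile, ShiftTable, TorsionTable

__all__ = ["Candidate", "StrainComparison", "StrainComparisonResults"]


@dataclass
class Candidate:
    """One candidate fibril core: calculated shifts and (optionally) torsions."""

    structure_id: str
    shifts: ShiftTable
    torsions: Optional[TorsionTable] = None
    fold_label: Optional[str] = None


class StrainComparison:
    """Compare an NMR shift assignment against a panel of candidate structures.

    Parameters
    ----------
    observed_shifts : ShiftTable
        The experimental assignment (all tables must share one numbering frame).
    candidates : sequence of Candidate
        Structure-calculated shift tables (e.g. read from ShiftX2 output)
        with optional structure-derived torsion tables.
    observed_torsions : TorsionTable, optional
        Shift-derived torsion predictions for the observed side (e.g. a
        TALOS-N table). Without it the torsion metric is skipped.
    rc : RandomCoilTable, optional
        Random-coil reference for secondary shifts; defaults to the packaged
        table.
    epsilon_s : float
        Dead-band for the sign of S (0 = strict sign, the default).
    circular : bool
        Use minimal circular differences for the torsion metric (default on).
    partial_atoms : bool
        Let residues missing one of CA/CB contribute the available atom's
        term to the shift metric (default on).
    ambiguous_policy, ambiguous_groups
        Handling of residue ranges whose assignment is ambiguous (e.g. the
        tau PGGG repeats); default excludes them from every metric.
    """

    def __init__(
        self,
        observed_shifts: ShiftTable,
        candidates: Sequence[Candidate],
        observed_torsions: Optional[TorsionTable] = None,
        rc: Optional[RandomCoilTable] = None,
        epsilon_s: float = 0.0,
        circular: bool = True,
        partial_atoms: bool = True,
        ambiguous_policy: str = "exclude",
        ambiguous_groups: Sequence[tuple[int, int]] = (),
    ):
        if not candidates:
            raise DataError("comparison needs at least one candidate structure")
        ids = [c.structure_id for c in candidates]
        if len(set(ids)) != len(ids):
            raise DataError("candidate structure_ids must be unique")
        self.observed_shifts = observed_shifts
        self.candidates = list(candidates)
        self.observed_torsions = observed_torsions
        self.rc = rc if rc is not None else load_random_coil()
        self.epsilon_s = epsilon_s
        self.circular = circular
        self.partial_atoms = partial_atoms
        self.ambiguous_policy = ambiguous_policy
        self.ambiguous_groups = tuple(ambiguous_groups)

    def fit(self) -> "StrainComparisonResults":
        """Evaluate all metrics per candidate and rank the panel."""
        nmr_profile = secondary_shifts(self.observed_shifts, self.rc)
        rows = []
        cal_profiles: dict[str, SecondaryShiftProfile] = {}
        matches: dict[str, MatchedResidueSet] = {}
        for cand in self.candidates:
            matched = match_residues(
                self.observed_shifts,
                cand.shifts,
                self.observed_torsions,
                cand.torsions,
                ambiguous_policy=self.ambiguous_policy,
                ambiguous_groups=self.ambiguous_groups,
            )
            cal_profile = secondary_shifts(cand.shifts, self.rc)
            cs_val, n_cs = sigma_cs(
                self.observed_shifts, cand.shifts, matched, self.partial_atoms
            )
            a_val, n_a = sigma_a(nmr_profile, cal_profile, matched, self.epsilon_s)
            if self.observed_torsions is not None and cand.torsions is not None:
                pp_val, n_pp = sigma_psiphi(
                    self.observed_torsions, cand.torsions, matched, self.circular
                )
            else:
                pp_val, n_pp = 0.0, 0
            dab = delta_alphabeta(
                self.observed_shifts, cand.shifts, matched, self.partial_atoms
            )
            rows.append(
                MetricRow(
                    structure_id=cand.structure_id,
                    sigma_cs=cs_val,
                    n_cs=n_cs,
                    sigma_a=a_val,
                    n_a=n_a,
                    sigma_psiphi=pp_val,
                    n_psiphi=n_pp,
                    fold_label=cand.fold_label,
                    per_residue_delta_ab=dab,
                )
            )
            cal_profiles[cand.structure_id] = cal_profile
            matches[cand.structure_id] = matched
        report = rank_structures(rows)
        return StrainComparisonResults(self, report, nmr_profile, cal_profiles, matches)


class StrainComparisonResults:
    """Fitted comparison: ranked metric report plus per-residue diagnostics."""

    def __init__(
        self,
        model: StrainComparison,
        report: MetricReport,
        nmr_profile: SecondaryShiftProfile,
        cal_profiles: dict[str, SecondaryShiftProfile],
        matches: dict[str, MatchedResidueSet],
    ):
        self.model = model
        self.report = report
        self.nmr_profile = nmr_profile
        self.cal_profiles = cal_profiles
        self.matches = matches

    @property
    def frame(self) -> pd.DataFrame:
        return self.report.frame

    def best(self, metric: str = "sigma_a") -> str:
        """structure_id with the minimal value of the given metric."""
        return self.report.best(metric)

    def s_series(self, structure_id: str) -> pd.DataFrame:
        """Tidy per-residue S-statistic comparison (observed vs calculated)."""
        cal = self.cal_profiles[structure_id]
        nmr_s = self.nmr_profile.s_values()
        cal_s = cal.s_values()
        residues = sorted(set(nmr_s) | set(cal_s))
        return pd.DataFrame(
            {
                "residue_number": residues,
                "s_nmr": [nmr_s.get(r) for r in residues],
                "s_cal": [cal_s.get(r) for r in residues],
            }
        )

    def delta_ab_series(self, structure_id: str) -> pd.DataFrame:
        """Tidy per-residue CA+CB absolute shift difference for one structure."""
        dab = self.report.per_residue.get(structure_id, {})
        return pd.DataFrame(
            {
                "residue_number": sorted(dab),
                "delta_alphabeta_ppm": [dab[r] for r in sorted(dab)],
            }
        )

    def summary(self) -> str:
        """Human-readable ranking table with per-metric minima flagged (*)."""
        df = self.frame.copy()
        flag_cs = df["rank_cs"] == 1
        flag_a = df["rank_a"] == 1
        flag_pp = df["rank_psiphi"] == 1
        lines = [
            "Strain comparison: observed assignment vs candidate structures",
            f"random-coil reference: {self.model.rc.provenance_label}",
            f"ambiguous policy: {self.model.ambiguous_policy}; "
            f"circular torsion differences: {self.model.circular}",
            "",
            f"{'structure':<12}{'S_CS (ppm)':>12}{'n':>4}{'S_A':>6}{'n':>4}"
            f"{'S_PsiPhi (deg)':>16}{'n':>4}  fold",
        ]
        for i, row in df.iterrows():
            cs = f"{row.sigma_cs_ppm:.4f}{'*' if flag_cs[i] else ' '}"
            a = f"{row.sigma_a:d}{'*' if flag_a[i] else ' '}"
            pp = f"{row.sigma_psiphi_deg:.1f}{'*' if flag_pp[i] else ' '}"
            lines.append(
                f"{row.structure_id:<12}{cs:>12}{row.n_cs:>4}{a:>6}{row.n_a:>4}"
                f"{pp:>16}{row.n_psiphi:>4}  {row.fold_label or '-'}"
            )
        lines.append("")
        lines.append("* = best (minimal) value per metric; rows sorted by S_A")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StrainComparisonResults: {len(self.frame)} structures, "
            f"best by sign metric = {self.best('sigma_a')!r}>"
        )
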