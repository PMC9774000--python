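"""End-to-end orchestration: simulate fixture panels and run comparisons.

``run_simulate`` writes a self-contained fixture directory (truth + decoy
backbones as PDB, an observed NMR-STAR shift table simulated from the truth,
per-structure predicted-shift tables, and a TALOS-style torsion table).
``run_compare`` consumes exactly that layout — or real data prepared the same
way — and writes a ranked metric report with a run manifest. Both are pure
functions of their :class:`RunConfig`, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .errors import DataError, ParameterError
from .geometry import compute_torsions, read_structure
from .io import (
    read_nmrstar_shifts,
    read_shiftx2_output,
    read_talosn_predictions,
    write_metric_report,
)
from .metrics import MetricReport
from .model import Candidate, StrainComparison
from .shifts import load_random_coil, read_random_coil_csv
from .simulate import (
    ForwardShiftModel,
    default_tau_program,
    generate_backbone,
    make_decoys,
    program_torsions,
    simulate_shift_table,
    write_backbone_pdb,
    write_minimal_nmrstar,
    write_shiftx2_csv,
    write_talosn_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_compare", "run_simulate", "convention_variants"]

_STRUCTURE_SUFFIXES = (".pdb", ".cif", ".mmcif")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; JSON round-trips losslessly."""

    assignment: Optional[str] = None        # NMR-STAR file with observed shifts
    structures: Optional[str] = None        # directory of PDB/mmCIF candidates
    pred_shifts: Optional[str] = None       # directory of <id>.csv predicted shifts
    talos: Optional[str] = None             # TALOS-style observed torsion table
    rc_table: Optional[str] = None          # random-coil CSV (default: packaged)
    out_dir: str = "strainrank_out"
    chain: str = "A"
    ambiguous_policy: str = "exclude"
    ambiguous_groups: list = field(default_factory=list)  # [[start, end], ...]
    circular: bool = True
    partial_atoms: bool = True
    epsilon_s: float = 0.0
    strict: bool = False                    # error (not skip) on missing pred shifts
    emit_variants: bool = False             # also write convention-variant reports
    # simulation parameters
    seed: int = 0
    n_decoys: int = 9
    noise_sd: float = 0.3
    kink_shift_min: int = 2
    kink_shift_max: int = 4

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _load_candidates(config: RunConfig) -> list[Candidate]:
    struct_dir = Path(config.structures)
    pred_dir = Path(config.pred_shifts)
    if not struct_dir.is_dir():
        raise DataError(f"structure directory {struct_dir} does not exist")
    if not pred_dir.is_dir():
        raise DataError(f"predicted-shift directory {pred_dir} does not exist")
    candidates = []
    for path in sorted(struct_dir.iterdir()):
        if path.suffix.lower() not in _STRUCTURE_SUFFIXES:
            continue
        sid = path.stem
        pred = pred_dir / f"{sid}.csv"
        if not pred.exists():
            msg = f"no predicted-shift file for structure {sid} (expected {pred})"
            if config.strict:
                raise DataError(msg)
            logger.warning("%s; skipping", msg)
            continue
        model = read_structure(str(path), chain_id=config.chain, structure_id=sid)
        torsions = compute_torsions(model)
        shifts = read_shiftx2_output(str(pred), sid)
        candidates.append(Candidate(sid, shifts, torsions))
    if not candidates:
        raise DataError("no candidate structures with predicted shifts found")
    return candidates


def _build_model(config: RunConfig) -> StrainComparison:
    observed = read_nmrstar_shifts(config.assignment)
    observed_torsions = (
        read_talosn_predictions(config.talos) if config.talos else None
    )
    rc = read_random_coil_csv(config.rc_table) if config.rc_table else load_random_coil()
    candidates = _load_candidates(config)
    logger.info(
        "compare: %d observed shifts over %d residues, %d candidates",
        len(observed), len(observed.residue_numbers()), len(candidates),
    )
    return StrainComparison(
        observed,
        candidates,
        observed_torsions=observed_torsions,
        rc=rc,
        epsilon_s=config.epsilon_s,
        circular=config.circular,
        partial_atoms=config.partial_atoms,
        ambiguous_policy=config.ambiguous_policy,
        ambiguous_groups=[tuple(g) for g in config.ambiguous_groups],
    )


def convention_variants(model: StrainComparison) -> dict[str, MetricReport]:
    """Re-fit the comparison under every analysis-convention combination.

    Varies circular vs naive torsion differencing, partial vs strict atom
    terms, and the ambiguous-residue policy, so a real-data report exposes
    which convention a published table used.
    """
    out: dict[str, MetricReport] = {}
    policies = ("exclude", "both") if model.ambiguous_groups else ("exclude",)
    for circular in (True, False):
        for partial in (True, False):
            for policy in policies:
                variant = StrainComparison(
                    model.observed_shifts,
                    model.candidates,
                    observed_torsions=model.observed_torsions,
                    rc=model.rc,
                    epsilon_s=model.epsilon_s,
                    circular=circular,
                    partial_atoms=partial,
                    ambiguous_policy=policy,
                    ambiguous_groups=model.ambiguous_groups,
                )
                key = (
                    f"circular={'on' if circular else 'off'}"
                    f"_atoms={'partial' if partial else 'strict'}"
                    f"_ambiguous={policy}"
                )
                out[key] = variant.fit().report
    return out


def run_compare(config: RunConfig):
    """Load inputs, fit the comparison, write ranked reports + manifest.

    Returns the fitted :class:`StrainComparisonResults`. Output files:
    ``report.csv``, ``report.json``, ``s_series_<best>.csv``,
    ``delta_alphabeta_<best>.csv``, ``manifest.json`` and (optionally)
    ``variants/<convention>.csv``.
    """
    model = _build_model(config)
    results = model.fit()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metric_report(results.report, str(out / "report.csv"), "csv")
    write_metric_report(results.report, str(out / "report.json"), "json")
    best = results.best("sigma_a")
    results.s_series(best).to_csv(out / f"s_series_{best}.csv", index=False)
    results.delta_ab_series(best).to_csv(out / f"delta_alphabeta_{best}.csv", index=False)
    if config.emit_variants:
        vdir = out / "variants"
        vdir.mkdir(exist_ok=True)
        for key, report in convention_variants(model).items():
            write_metric_report(report, str(vdir / f"{key}.csv"), "csv")
    manifest = {
        "tool": "strainrank",
        "version": __version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "n_candidates": len(model.candidates),
        "residue_masks": {
            sid: {
                "matched": len(m.residues()),
                "cs_ca": len(m.cs_ca()),
                "cs_cb": len(m.cs_cb()),
                "sign_eligible": len(m.a_eligible()),
                "torsion_eligible": len(m.psiphi_eligible()),
            }
            for sid, m in results.matches.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results


def run_simulate(config: RunConfig) -> Path:
    """Write a synthetic truth+decoys fixture directory.

    Layout: ``observed.str`` (noisy truth shifts, NMR-STAR),
    ``talos_pred.tab`` (truth torsions, TALOS layout),
    ``structures/<name>.pdb`` and ``pred_shifts/<name>.csv`` for the truth
    and each decoy, plus ``manifest.json``. The directory is directly
    consumable by :func:`run_compare`.
    """
    if config.kink_shift_min < 1 or config.kink_shift_max < config.kink_shift_min:
        raise ParameterError("invalid kink shift range")
    out = Path(config.out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    (out / "pred_shifts").mkdir(parents=True, exist_ok=True)

    truth = default_tau_program()
    decoys = make_decoys(
        truth,
        config.n_decoys,
        (config.kink_shift_min, config.kink_shift_max),
        seed=config.seed,
    )
    rc = read_random_coil_csv(config.rc_table) if config.rc_table else load_random_coil()

    observed_model = ForwardShiftModel(noise_sd=config.noise_sd, seed=config.seed)
    observed = simulate_shift_table(truth, rc, observed_model, source_label="NMR")
    write_minimal_nmrstar(observed, str(out / "observed.str"), entry_id="synthetic_truth")
    write_talosn_table(program_torsions(truth), str(out / "talos_pred.tab"))

    noiseless = ForwardShiftModel(noise_sd=0.0, seed=config.seed)
    programs = [truth] + decoys
    for prog in programs:
        backbone = generate_backbone(prog)
        write_backbone_pdb(backbone, str(out / "structures" / f"{prog.name}.pdb"))
        pred = simulate_shift_table(prog, rc, noiseless, source_label=f"Cal:{prog.name}")
        write_shiftx2_csv(pred, str(out / "pred_shifts" / f"{prog.name}.csv"))

    manifest = {
        "tool": "strainrank",
        "version": __version__,
        "kind": "synthetic_fixture",
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "structures": [p.name for p in programs],
        "truth": truth.name,
        "kinks": {
            p.name: [[s.start_residue, s.end_residue] for s in p.kinks()]
            for p in programs
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
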