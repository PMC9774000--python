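import numpy as np
import pytest

from strainrank import (
    RunConfig,
    ShiftEntry,
    ShiftTable,
    TorsionEntry,
    TorsionTable,
    default_tau_program,
    load_random_coil,
    run_simulate,
)
from strainrank.tables import AA_1TO3


@pytest.fixture(scope="session")
def rc():
    return load_random_coil()


@pytest.fixture(scope="session")
def tau_truth():
    return default_tau_program()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A full synthetic truth+decoys fixture directory (seeded)."""
    out = tmp_path_factory.mktemp("synthetic") / "fix"
    run_simulate(RunConfig(out_dir=str(out), seed=7, n_decoys=5, noise_sd=0.3))
    return out


def random_paired_shift_tables(rng, rc, n_residues=30):
    """Paired random observed/calculated shift tables plus plain-dict views
    for the brute-force oracles."""
    aa = sorted(AA_1TO3)
    residues = sorted(rng.choice(np.arange(297, 392), size=n_residues, replace=False))
    nmr_entries, cal_entries = [], []
    nmr_view, cal_view = {}, {}
    for r in residues:
        rtype = aa[rng.integers(len(aa))]
        for entries, view, side in ((nmr_entries, nmr_view, "n"), (cal_entries, cal_view, "c")):
            atoms = {}
            if rng.random() < 0.9:
                atoms["CA"] = rc.rc_ca(rtype) + rng.uniform(-8, 8)
            if rtype != "G" and rng.random() < 0.85:
                atoms["CB"] = rc.rc_cb(rtype) + rng.uniform(-8, 8)
            for atom, val in atoms.items():
                entries.append(ShiftEntry(int(r), rtype, atom, float(val)))
            if atoms:
                view[int(r)] = atoms
    return (
        ShiftTable(nmr_entries, "NMR"),
        ShiftTable(cal_entries, "Cal:random"),
        nmr_view,
        cal_view,
        [int(r) for r in residues],
    )


def random_paired_torsion_tables(rng, n_residues=30):
    residues = sorted(rng.choice(np.arange(297, 392), size=n_residues, replace=False))
    aa = sorted(AA_1TO3)
    nmr_entries, cal_entries = [], []
    nmr_view, cal_view = {}, {}
    for r in residues:
        rtype = aa[rng.integers(len(aa))]
        for entries, view in ((nmr_entries, nmr_view), (cal_entries, cal_view)):
            if rng.random() < 0.9:
                phi = float(rng.uniform(-179.999, 180.0))
                psi = float(rng.uniform(-179.999, 180.0))
                entries.append(TorsionEntry(int(r), rtype, phi, psi))
                view[int(r)] = (phi, psi)
    return (
        TorsionTable(nmr_entries, "NMR"),
        TorsionTable(cal_entries, "Cal:random"),
        nmr_view,
        cal_view,
        [int(r) for r in residues],
    )
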