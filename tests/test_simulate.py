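import numpy as np
import pytest

from strainrank import (
    Candidate,
    ForwardShiftModel,
    ParameterError,
    Segment,
    StrainComparison,
    TorsionProgram,
    classify_sign,
    default_tau_program,
    generate_backbone,
    make_decoys,
    match_residues,
    secondary_shifts,
    sigma_cs,
    simulate_shift_table,
)
from strainrank.simulate import TAU_DGAE_SEQUENCE


class TestTorsionProgram:
    def test_segments_must_cover_sequence(self):
        with pytest.raises(ParameterError):
            TorsionProgram([Segment(1, 3, -135, 135, "strand")], "VKLIV", 1)

    def test_segments_must_be_contiguous(self):
        segs = [Segment(1, 2, -135, 135, "strand"), Segment(4, 5, -80, 0, "kink")]
        with pytest.raises(ParameterError):
            TorsionProgram(segs, "VKLIV", 1)

    def test_packaged_tau_program_layout(self):
        prog = default_tau_program()
        assert len(TAU_DGAE_SEQUENCE) == 95
        assert prog.residue_numbers()[0] == 297
        assert prog.residue_numbers()[-1] == 391
        # the single cysteine of the core fragment sits at 322
        assert prog.residue_type(322) == "C"
        assert [s.start_residue for s in prog.kinks()] == [332, 364]


class TestGenerateBackbone:
    def test_deterministic(self):
        prog = default_tau_program()
        a = generate_backbone(prog)
        b = generate_backbone(prog)
        for ra, rb in zip(a.residues, b.residues):
            for atom in ("N", "CA", "C"):
                assert np.array_equal(ra.atoms[atom], rb.atoms[atom])

    def test_peptide_bond_lengths_ideal(self):
        bb = generate_backbone(default_tau_program())
        for prev, nxt in zip(bb.residues, bb.residues[1:]):
            d = np.linalg.norm(nxt.atoms["N"] - prev.atoms["C"])
            assert d == pytest.approx(1.329, abs=1e-9)


class TestSimulateShiftTable:
    def test_zero_noise_recovers_offsets_exactly(self, rc, tau_truth):
        model = ForwardShiftModel(noise_sd=0.0)
        table = simulate_shift_table(tau_truth, rc, model)
        prof = secondary_shifts(table, rc)
        for num in tau_truth.residue_numbers():
            d_ca, d_cb = model.offsets[tau_truth.label_of(num)]
            e = prof.get(num)
            assert e.delta_ca == pytest.approx(d_ca, abs=1e-12)
            if tau_truth.residue_type(num) != "G":
                assert e.delta_cb == pytest.approx(d_cb, abs=1e-12)
                assert e.s_value == pytest.approx(d_ca - d_cb, abs=1e-12)

    def test_same_seed_identical_tables(self, rc, tau_truth):
        m = ForwardShiftModel(noise_sd=0.5, seed=123)
        assert simulate_shift_table(tau_truth, rc, m) == simulate_shift_table(tau_truth, rc, m)

    def test_different_seed_differs(self, rc, tau_truth):
        a = simulate_shift_table(tau_truth, rc, ForwardShiftModel(noise_sd=0.5, seed=1))
        b = simulate_shift_table(tau_truth, rc, ForwardShiftModel(noise_sd=0.5, seed=2))
        assert a != b

    def test_sign_rule_invariants_enforced(self):
        with pytest.raises(ParameterError):
            ForwardShiftModel(offsets={"strand": (1.5, 2.0), "helix": (2.6, -0.5),
                                       "kink": (0, 0), "coil": (0, 0)})
        with pytest.raises(ParameterError):
            ForwardShiftModel(noise_sd=-0.1)


class TestMakeDecoys:
    def test_contract_distinct_and_moved(self, tau_truth):
        decoys = make_decoys(tau_truth, n_decoys=5, kink_shift_range=4, seed=0)
        assert len(decoys) == 5
        truth_kinks = {(s.start_residue, s.end_residue) for s in tau_truth.kinks()}
        seen = set()
        for d in decoys:
            kinks = tuple(sorted((s.start_residue, s.end_residue) for s in d.kinks()))
            assert set(kinks) != truth_kinks  # every decoy moved at least one kink
            assert kinks not in seen
            seen.add(kinks)
            assert d.sequence == tau_truth.sequence

    def test_same_seed_identical_decoy_set(self, tau_truth):
        a = make_decoys(tau_truth, 5, 4, seed=9)
        b = make_decoys(tau_truth, 5, 4, seed=9)
        assert [d.segments for d in a] == [d.segments for d in b]

    def test_infeasible_request_raises(self, tau_truth):
        with pytest.raises(ParameterError):
            make_decoys(tau_truth, n_decoys=10_000, kink_shift_range=1, seed=0)

    def test_sign_vector_difference_count_for_far_moved_kink(self, rc):
        # single kink on non-glycine residues, moved by >= its own length:
        # sign vectors must differ at exactly 2 x kink length positions
        seq = "VKLIVEWTASVKLIVEWTAS"  # no glycines, no prolines
        truth = TorsionProgram(
            [Segment(1, 8, -135, 135, "strand"),
             Segment(9, 11, -80, 0, "kink"),
             Segment(12, 20, -135, 135, "strand")],
            seq, 1,
        )
        model = ForwardShiftModel(noise_sd=0.0)
        truth_signs = classify_sign(secondary_shifts(simulate_shift_table(truth, rc, model), rc))
        decoys = make_decoys(truth, n_decoys=6, kink_shift_range=(3, 5), seed=3)
        for d in decoys:
            d_signs = classify_sign(secondary_shifts(simulate_shift_table(d, rc, model), rc))
            diff = [n for n in truth_signs if truth_signs[n] != d_signs[n]]
            assert len(diff) == 2 * 3


class TestEndToEndRecovery:
    def test_truth_ranks_first_by_sign_metric(self, rc, tau_truth):
        decoys = make_decoys(tau_truth, n_decoys=9, kink_shift_range=(2, 4), seed=0)
        noiseless = ForwardShiftModel(noise_sd=0.0)
        candidates = [
            Candidate(p.name, simulate_shift_table(p, rc, noiseless, f"Cal:{p.name}"))
            for p in [tau_truth] + decoys
        ]
        observed = simulate_shift_table(
            tau_truth, rc, ForwardShiftModel(noise_sd=0.3, seed=42)
        )
        results = StrainComparison(observed, candidates, rc=rc).fit()
        assert results.report.row("truth").rank_a == 1
        assert results.report.row("truth").rank_cs == 1

    def test_expected_sigma_cs_increases_with_noise(self, rc, tau_truth):
        noiseless = ForwardShiftModel(noise_sd=0.0)
        truth_pred = simulate_shift_table(tau_truth, rc, noiseless, "Cal:truth")
        means = []
        for sd in (0.0, 0.2, 0.5, 1.0):
            vals = []
            for seed in range(50):
                obs = simulate_shift_table(
                    tau_truth, rc, ForwardShiftModel(noise_sd=sd, seed=seed)
                )
                matched = match_residues(obs, truth_pred)
                vals.append(sigma_cs(obs, truth_pred, matched)[0])
            means.append(float(np.mean(vals)))
        # Spearman rho = 1 on the means over the noise grid
        assert means == sorted(means)
        assert all(b > a for a, b in zip(means, means[1:]))
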