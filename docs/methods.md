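# Methods

## The comparison model

The package treats strain identification as a scoring problem: an observed
solid-state NMR assignment (per-residue Cα/Cβ shifts, optionally
shift-derived Φ/Ψ predictions) is compared against each member of a panel of
candidate fibril core structures, each represented by structure-predicted
shifts and by torsions computed from its coordinates. No structure is
refined and no probability model is fitted; the three metrics are
deterministic functionals of the matched residues, and "inference" is the
ranking they induce.

Assumptions worth making explicit:

- **Cα/Cβ shifts carry the secondary-structure signal.** CO/N shifts are
  deliberately excluded: their secondary-shift response is weaker and more
  sensitive to hydrogen bonding and neighbors.
- **All tables share one numbering frame.** For tau work that frame is the
  full-length 2N4R numbering (297–391 for the core fragment). The NMR-STAR
  reader prefers author numbering and falls back to sequence numbering plus
  a user offset.
- **Candidate shift predictions are trusted as given.** Predicted shifts
  (ShiftX2-style tables) and torsion predictions (TALOS-N-style tables) are
  inputs; their accuracy bounds what the metrics can resolve. Predicted-shift
  RMSDs of ~0.5 ppm for ¹³C and torsion-prediction RMSDs of ~12° are typical
  for such tools, which is why the sign-based Σ_A is more robust than the
  magnitude-based Σ_CS / Σ_ΨΦ for closely related folds.

## Metric definitions and conventions

Σ_CS sums |Cal − NMR| over Cα and Cβ; Σ_A counts residues with
S^Cal·S^NMR < 0 where S = ΔδCα − ΔδCβ; Σ_ΨΦ sums |ΔΦ| + |ΔΨ|; Δαβ is the
per-residue decomposition of Σ_CS (their sum is exactly Σ_CS — asserted as a
test invariant). Conventions the definitions leave open were fixed as
follows, each with a switch so a published table computed under the other
choice can be reproduced:

- **Zero products count as agreement in Σ_A** (strict two-branch definition:
  A_i = 0 when the product is ≥ 0). An `epsilon_s` dead-band (default 0.0)
  can widen "zero" for sensitivity analysis.
- **Circular angle differences, default on.** |170° − (−170°)| is 20°, not
  340°; the naive behaviour is available (`circular=False`) because some
  published tables appear to use plain absolute differences (values above
  360°·n are only reachable that way).
- **Partial atom terms, default on.** A residue missing one of Cα/Cβ on
  either side contributes the available atom's term to Σ_CS rather than being
  dropped; `n_cs` reports coverage. Strict per-residue exclusion is available
  (`partial_atoms=False`). This maximizes use of sparse solid-state
  assignments.
- **Ambiguous segments are excluded by default.** Repetitive stretches (the
  tau PGGG motifs at 332–335/364–367) that cannot be placed uniquely in the
  assignment are dropped from every metric; policies `assign-to-first`,
  `assign-to-second` and `both` are available. `strainrank.TAU_PGGG_GROUPS`
  packages the tau ranges.
- **Ranking**: independent ascending ranks per metric, ties sharing the
  smaller rank; output rows sorted by ascending Σ_A, ties broken by ascending
  Σ_ΨΦ, then structure id — so the first row is the sign-metric winner and
  the order is deterministic.

## Geometry

Torsions follow the IUPAC convention (cis = 0°, trans reported as +180°,
range (−180°, 180°]). Note the convention's true symmetries: a torsion is
*invariant* under reversing the four-point order and antisymmetric under
mirror reflection; both are tested against an independently coded
projection-formula oracle. Φ(i) uses C(i−1)–N(i)–Cα(i)–C(i), Ψ(i) uses
N(i)–Cα(i)–C(i)–N(i+1); torsions are refused across chain breaks
(C(i)–N(i+1) ≥ 2.5 Å) and at residues with incomplete backbones, and only
residues with both angles defined are emitted. Structure files are read with
gemmi (PDB and mmCIF); default chain "A" (per-chain analysis of fibril rungs
is possible by re-running with another chain id); alternate locations
resolve to the highest-occupancy conformer, ties broken by altloc id.

## Secondary shifts

Δδ is observed minus a per-residue-type random-coil reference. The packaged
reference is a generic Wishart-style Cα/Cβ table (DSS-referenced,
temperature/pH generic); because published reference sets differ by small
per-residue-type constants, the table is user-replaceable
(`read_random_coil_csv`), and both sides of every comparison always use the
*same* table, so reference-set choice largely cancels in Σ_A; Σ_CS compares
raw shifts and never uses the reference at all. Glycine has no Cβ,
hence no S value: glycines contribute Cα terms to Σ_CS but never to Σ_A.

## Synthetic data: what it emulates and what it does not

The generator builds backbones by natural-extension placement with ideal
bond lengths (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å), fixed bond angles
(N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°) and trans peptide bonds,
realizing an explicit per-segment Φ/Ψ program exactly; `compute_torsions`
inverts it to ~1e−12°, which is the geometry module's core acceptance
property. The default system is the 95-residue tau(297–391) core fragment
(2N4R numbering), β-strand background (Φ,Ψ = −135°,135°) with kinks
(−80°,0°) on the two repeat PGGG turns — where real tau folds localize their
turns. Decoys translate kink windows by nonzero offsets (joint offset
vectors drawn without replacement), emulating strains that differ only in
where the β-sheet folds.

Observed shifts come from a label-based forward model: random-coil value
plus a per-label offset (strand: dCα = −1.5, dCβ = +2.0 ppm; helix: +2.6,
−0.5; kink/coil: 0, 0) plus i.i.d. Gaussian noise per atom (default
0.3 ppm, matching a realistic predictor/measurement error scale). The
offsets are chosen to satisfy the sign rule (strand S < 0, helix S > 0),
not to reproduce literature shift surfaces. All randomness flows through
explicit `numpy` Generators seeded per call; there is no global random
state, and fixture generation is byte-deterministic given a seed.

What the synthetic data does **not** emulate — and therefore what passing
tests do not show about real data: realistic per-atom shift prediction
(kinks here have exactly zero secondary shift, so their S is exactly 0 and
the zero-product agreement branch of Σ_A is exercised often — real kinks
have small nonzero S of varying sign); sequence-dependent random-coil
corrections; correlated prediction errors along the chain; missing or
ambiguous assignments beyond the explicit PGGG masks; and fibril-specific
effects (inter-rung contacts, static disorder). Recovery of the truth at
rank 1 on synthetic panels validates the metric logic and plumbing, not the
discriminating power on experimental assignments, which is bounded by
predictor accuracy.

## Problem sizes and numerical choices

The packaged study uses the 95-residue tau program, truth + 9 decoys with
kink shifts of 2–4 residues, 0.3 ppm noise, and 100 seeds for recovery-rate
estimates (50 seeds per point for the noise-response curve over
{0, 0.2, 0.5, 1.0} ppm) — sizes chosen so a full run completes in seconds
while estimating rates to a few percent. Tolerances: torsion round-trips are
asserted at 1e−6° (observed ~1e−12°); the torsion primitive agrees with an
independent oracle to 1e−9°; metric/oracle agreement to 1e−9 ppm or degrees;
collinearity in torsions is rejected below a 1e−9 Å² squared-cross-product
floor. Angles are normalized to (−180°, 180°] with −180° mapped to +180° so
trans torsions have a single representation.

## Known limitations

- Σ_ΨΦ compares angles pointwise; it has no notion of cooperative
  displacement, so one large kink mismatch and many small deviations can
  score alike.
- Predicted shifts for a candidate structure must come from an external
  predictor; the package deliberately does not implement shift prediction.
- The NMR-STAR reader targets the assigned-chemical-shift loop of v3
  depositions; NEF and v2 dialects are out of scope.
- Per-chain torsion averaging over fibril rungs is not automated (re-run per
  chain instead).
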