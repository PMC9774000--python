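# strainrank

Rank candidate amyloid-fibril core structures against a solid-state NMR
chemical-shift assignment.

## The problem

Fibrils formed by one protein sequence can adopt distinct core folds
("strains"): tau filaments from Alzheimer's disease, corticobasal
degeneration or argyrophilic grain disease share nearly identical β-strand
content but fold those strands differently, with the differences concentrated
in short **kinks** — localized departures from extended conformation. A
solid-state NMR assignment of an in-vitro fibril (Cα/Cβ chemical shifts,
which are strongly secondary-structure dependent) can therefore be scored
against a panel of candidate core structures to ask which known fold the
sample adopts, without solving the structure.

`strainrank` implements that comparison for anyone with (a) an assignment in
NMR-STAR v3 format, (b) candidate structures as PDB/mmCIF, (c) per-structure
predicted shifts (e.g. ShiftX2 output), and optionally (d) shift-derived
torsion predictions (e.g. a TALOS-N table).

## The metrics

With δ the chemical shift, Δδ = δ − δ_rc the secondary shift against a
random-coil reference, and *S* = ΔδCα − ΔδCβ (positive in helices, negative
in extended/β conformation), the package scores each candidate structure
*Cal* against the assignment *NMR* over the matched residues *i*:

- **Σ_CS** = Σᵢ |δCαᵢ^Cal − δCαᵢ^NMR| + |δCβᵢ^Cal − δCβᵢ^NMR|  (ppm) —
  total Cα/Cβ shift disagreement;
- **Σ_A** = Σᵢ Aᵢ, with Aᵢ = 1 if Sᵢ^Cal·Sᵢ^NMR < 0 and 0 otherwise — the
  number of residues whose secondary-structure sign flips between assignment
  and structure, i.e. a direct count of misplaced kinks;
- **Σ_ΨΦ** = Σᵢ |Φᵢ^Cal − Φᵢ^NMR| + |Ψᵢ^Cal − Ψᵢ^NMR|  (degrees), by default
  with minimal circular differences;
- **Δαβᵢ** = |δCαᵢ^Cal − δCαᵢ^NMR| + |δCβᵢ^Cal − δCβᵢ^NMR| — the per-residue
  decomposition of Σ_CS, for coloring structures.

Candidates are ranked independently per metric (minimum = rank 1) and the
report is sorted by ascending Σ_A, the most strain-discriminating of the
three.

A synthetic-data module generates the entire study offline: ideal-geometry
cross-β backbones built from explicit Φ/Ψ programs (tau(297–391) by default,
kinks on the PGGG turns), decoy structures that differ only in kink
placement, and noisy observed shift tables from a forward model in which
strands give S < 0 and helices S > 0.

## Worked example

Simulate a ground-truth fibril with four kink-shifted decoys, then rank the
panel against the noisy "observed" assignment:

```
$ strainrank simulate --out demo --seed 11 --n-decoys 4
synthetic fixture written to demo

$ strainrank compare --assignment demo/observed.str --structures demo/structures \
    --pred-shifts demo/pred_shifts --talos demo/talos_pred.tab --out demo_out

structure     S_CS (ppm)   n   S_A   n  S_PsiPhi (deg)   n  fold
truth           39.8499*  95    0*  82            4.5*  93  -
decoy01         63.4898   95    1   82         1903.7   93  -
decoy04         64.7796   95    1   82         1904.0   93  -
decoy03         69.4665   95    1   82         2283.5   93  -
decoy02         76.9677   95    1   82         3043.0   93  -

* = best (minimal) value per metric; rows sorted by S_A
```

Reading the numbers: the true structure wins every metric. Its Σ_CS ≈ 40 ppm
is pure measurement noise (0.3 ppm Gaussian noise per atom over ~177 atoms);
the decoys pick up an extra ~25 ppm from the relocated kinks. Σ_A = 0 means
no residue disagrees in secondary-structure sign with the truth, while each
decoy shows sign flips at its displaced kink. Σ_ΨΦ ≈ 4.5° for the truth is
the PDB coordinate-precision floor (3 decimals in Å), against ~2000° for
kinks in the wrong place. The same comparison is available as a library:

```python
from strainrank import StrainComparison, Candidate, read_nmrstar_shifts
model = StrainComparison(observed, candidates, observed_torsions=talos)
results = model.fit()
print(results.summary()); results.frame  # ranked pandas DataFrame
```

For real data, run ShiftX2 on each candidate PDB and TALOS-N on the
assignment first (both external programs), then point `compare` at their
output; `strainrank fetch` can download PDB/BMRB entries, and
`compare --variants` additionally writes the report under every analysis
convention (circular vs naive angle differences, partial vs strict atom
terms, each ambiguous-residue policy).

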