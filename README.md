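# lexatools

Tools for two quantitative questions around small-molecule inhibition of
LexA self-cleavage — the reaction that derepresses the bacterial SOS
response and, with it, stress-induced acquisition of antibiotic
resistance:

1. **What shape is the cleavage-site region (CSR)?** The scissile loop of
   LexA is a tight β-turn; classifying it (and candidate turn mimetics)
   requires backbone torsions, turn detection and turn-type assignment
   from structure files.
2. **How well does an inhibitor slow cleavage?** Cleavage timecourses
   followed by gel densitometry decay as a first-order exponential; an
   inhibitor titration is summarised by an effectiveness parameter φ and
   a dissociation constant K_d.

The intended users are structural bioinformaticians and biochemists
analysing LexA-family proteases or β-turn motifs generally, and anyone
fitting band-intensity decay kinetics of an autoproteolytic enzyme under
inhibition.

## Models

**Turn geometry.** A β-turn is a four-residue window i..i+3 with
Cα(i)–Cα(i+3) ≤ 7 Å, classified from the central torsions
(φ_{i+1}, ψ_{i+1}, φ_{i+2}, ψ_{i+2}) against the canonical types I, I′,
II, II′, VIII, VIa1, VIa2, VIb (±30° on all four angles, one angle
allowed ±45°; cis ω into i+2 for the VI types), with IV as catch-all.
The turn-closing hydrogen bond is measured as O(i)···N(i+3) and, with an
idealised amide hydrogen, O(i)···H(i+3).

**Kinetics.** Intact-protein fraction follows
[LexA]/[LexA]₀ = e^(−kt). Rates fitted per inhibitor condition follow

    k_i = k₀ / (1 + r/φ),   r = [I]:[LexA],

so φ is the molar ratio at which the rate halves, and
K_d = φ·[LexA]₀. Fitting is nonlinear least squares (statsmodels-style
model/results objects with `summary()`, standard errors and seeded
bootstrap intervals; the default bootstrap resimulates whole timecourses
from the fitted model so that first-stage rate uncertainty is
propagated).

Everything the pipelines consume can be generated in-package: seeded
timecourse simulations, peptide backbones built from prescribed torsions
(including an ideal type II turn and a synthetic stand-in for the LexA
CSR), PDB-text fixtures and toy screening tables.

## Worked example

```python
from lexatools import SimulationConfig, simulate_cleavage_series, EffectivenessModel

# a titration experiment: 6 inhibitor concentrations, 5-min sampling
tcs = simulate_cleavage_series(SimulationConfig(seed=1))
model = EffectivenessModel.from_timecourses(tcs)
fit = model.fit()
print(fit.summary())
```

```
Inhibitor effectiveness fit: k_i = k0 / (1 + r/phi)
  k0   0.10396 /min  (SE 0.001)
  phi  39.9003       (SE 1.34)
  K_d  267.332 uM  (= phi x 6.7 uM LexA)
  n = 6 ratios, converged=True
```

The simulation's true parameters were k₀ = 0.1 min⁻¹ and φ = 43.422
(K_d 290.9 µM at 6.7 µM protein); at the default noise level (sd 0.03 on
the band-intensity fraction) a single experiment recovers φ to roughly
±10%, and `model.bootstrap(n_boot=500, seed=1)` puts the 95% interval at
φ ∈ [33.2, 46.7] (K_d ∈ [222, 313] µM), which covers the truth.
`fit.plot()` draws the k-vs-ratio curve with the half-rate point marked.

On the structural side:

```python
from lexatools import build_peptide, synthetic_csr_spec, detect_turns

chain = build_peptide(synthetic_csr_spec())   # CSR stand-in, residues 83-86
turn = detect_turns(chain)[0]
print(turn.i_residue_number, turn.sequence, turn.turn_type)
```

```
83 GLU-GLY-ALA-ALA II
```

i.e. the published CSR torsions classify the LexA cleavage loop as a
strict type II β-turn.

The same pipelines are scriptable through the `lexatools` console
command (`turns`, `kinetics-fit`, `simulate`, `screen-summary`,
`hydropathy`, `make-fixture-pdb`); exit codes are 0 (ok), 2 (unusable
input), 3 (non-convergence).

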