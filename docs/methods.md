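# Methods

`lexatools` bundles the two quantitative analyses around covalent and
β-turn-mimetic inhibition of LexA self-cleavage: the backbone geometry of
the cleavage-site region (CSR) β-turn, and the first-order kinetics of the
cleavage reaction under an inhibitor titration. This note records the
models, the defaults, and the choices made where more than one reasonable
design existed.

## β-turn geometry

### Torsions

Backbone torsions follow the IUPAC convention (cis = 0°, trans = 180°,
range (−180°, 180°]):

- φ(i) = C(i−1)–N(i)–Cα(i)–C(i)
- ψ(i) = N(i)–Cα(i)–C(i)–N(i+1)
- ω(i) = Cα(i−1)–C(i−1)–N(i)–Cα(i), the peptide bond *into* residue i

Torsions are undefined at chain termini and on either side of a chain
break; two residues count as bonded when their C–N distance is at most
2.0 Å. Torsions are never computed across breaks.

### Turn detection and classification

A β-turn is any four-residue window i..i+3 of consecutively bonded
residues with Cα(i)–Cα(i+3) ≤ 7.0 Å (the `ca_cutoff` parameter) and
defined central torsions. Overlapping windows are all reported.
Classification uses the classical canonical table over (φ1, ψ1, φ2, ψ2)
of residues i+1 and i+2:

| type | φ1 | ψ1 | φ2 | ψ2 | cis ω(i+2)? |
|------|-----|-----|-----|-----|------|
| I    | −60 | −30 | −90 | 0   | no |
| I′   | 60  | 30  | 90  | 0   | no |
| II   | −60 | 120 | 80  | 0   | no |
| II′  | 60  | −120| −80 | 0   | no |
| VIII | −60 | −30 | −120| 120 | no |
| VIa1 | −60 | 120 | −90 | 0   | yes |
| VIa2 | −120| 120 | −60 | 0   | yes |
| VIb  | −135| 135 | −75 | 160 | yes |
| IV   | catch-all | | | | |

The matching rule is the standard one: all four angles within ±30° of a
type's canonical values, with at most one angle allowed out to ±45°
(flagged `relaxed_match`); angle differences are taken on the circle.
Types are tried in fixed table order with strict matches preferred over
relaxed ones, and anything unmatched is type IV. The VI types are only
eligible when the peptide bond into i+2 is cis (|ω| ≤ 30°). Users can
extend the table with additional centroid+tolerance entries (e.g. newer
clustering-derived turn classes); no such entries ship built in because
there is no single published canonical set for them. An optional,
torsion-based helix filter (φ ∈ [−100, −30] and ψ ∈ [−80, −5] at both
central residues) can drop windows inside regular helices; it is off by
default because the motivating application is an isolated loop.

Applied to the CSR of *E. coli* LexA, the central torsions published for
residues 84–85 ((−58.86°, 126.78°) and (79.02°, −24.45°)) classify as a
strict type II turn.

### Turn-closing hydrogen bond

The O(i)···N(i+3) distance is measured directly. For the O(i)···H(i+3)
distance, the amide hydrogen is constructed at 1.01 Å from N(i+3) in the
peptide plane, along the reverse bisector of the C(i+2)→N and Cα(i+3)→N
directions (the idealised sp² placement); prolines have no amide H and
return an undefined O···H distance. Crystal structures rarely include
hydrogens, and published O···H values depend on the (usually unstated)
placement method, so distances computed this way should be compared with
literature values only loosely (±0.1–0.2 Å).

### PDB input/output

Parsing and serialisation go through `gemmi`. Only ATOM records with atom
names N, CA, C, O are kept; HETATM records are dropped; residues without
a Cα are skipped with a warning. Alternate locations resolve to the
highest-occupancy conformer, ties broken by the alphabetically first
altloc code. Model 1 of multi-model files is read unless another index is
requested; insertion codes are carried alongside author residue numbers.
Coordinates survive a write/read round trip to the format's 0.001 Å
precision.

## Peptide construction from torsions

`build_peptide` places N, Cα, C sequentially by the
natural-extension/NeRF construction (each atom from the previous three
via bond length, bond angle, torsion), with carbonyl oxygens in the
peptide plane anti to the next amide nitrogen. Fixed internal geometry:
N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; N-Cα-C 111.2°,
Cα-C-N 116.2°, C-N-Cα 121.7°, Cα-C-O 120.8°. The builder's contract is
that recomputing torsions on the built chain reproduces the prescription
to better than 1e−6°, which the test suite checks on random
prescriptions.

A deliberate limitation: a rebuild from torsions with ideal geometry does
not reproduce a crystal structure's absolute distances. For the CSR turn,
the rebuild from the published φ/ψ gives Cα(83)–Cα(86) = 4.96 Å and
O(83)···H(86) = 2.22 Å against the published crystal-derived 5.405 Å and
2.610 Å: the missing ~0.4 Å lives in the real structure's bond angles
(τ = N-Cα-C in turns commonly sits several degrees above the ideal
111.2°), which φ/ψ values do not encode. The synthetic CSR fixture
(`synthetic_csr_spec`) is therefore labelled a stand-in: torsion-level
results on it are exact, distance-level results are approximate. The
geometry constants are standard textbook values and are not adjusted to
any particular target structure.

## Cleavage kinetics

### Model

Self-cleavage consumes intact LexA irreversibly, so the intact-band
intensity decays as a single exponential (first-order, unimolecular):

    [LexA]/[LexA]₀ = e^(−kt)

Timecourses are normalised by the t = 0 aliquot, so the fitted model is
the one-parameter f(t) = e^(−kt) with amplitude pinned at 1 — a floating
amplitude would let the fit absorb t = 0 error that experimentally
propagates into every point of the series. The fit is unweighted
nonlinear least squares on the fraction scale (no error model is assumed
for densitometry), initialised from the log-linear regression slope and
constrained to k ≥ 0. Fits with no decay signal return k = 0 flagged
`at_bound`. Standard errors come from the linearised covariance; R² is
reported on the fraction scale.

With a 1:1 inhibitor–protein equilibrium, the observed rate across an
inhibitor titration follows

    k_i = k₀ / (1 + r/φ),    r = [I]:[LexA] molar ratio

where k₀ is the uninhibited rate and the effectiveness φ is the molar
ratio at which the rate halves (k_i(φ) = k₀/2 exactly). The default
workflow is two-stage, matching how gel timecourses are analysed: one
rate fit per condition, then the effectiveness curve through the fitted
rates (a ratio-0 control is required unless k₀ is fixed). φ > 0 is
enforced; a flat rate profile is reported as φ = ∞ with a
`no_inhibition` flag rather than a spurious finite estimate.

The dissociation constant is K_d = φ·[LexA]₀: φ is a dimensionless molar
ratio, so multiplying by the protein concentration converts the
half-effect ratio into the inhibitor concentration at half-effect. The
protein concentration is an explicit input; for convenience
`molar_concentration(mass_µg, volume_µL, MW)` converts assay loadings,
with the *E. coli* LexA monomer mass 22,358 Da supplied as an overridable
default. At the standard 15 µg / 100 µL reaction loading this gives
[LexA]₀ = 6.71 µM, and φ = 43.422 maps to K_d ≈ 291 µM; published K_d
values near 286 µM correspond to a protein mass within ~2% of this
default, so the conversion is reported with the mass it used.

### Uncertainty

`EffectivenessModel.bootstrap` provides percentile confidence intervals
with two resampling schemes:

- **parametric** (default when the model was built from timecourses):
  new band-fraction timecourses are simulated from the fitted
  effectiveness curve, with the noise standard deviation estimated from
  the observed timecourse residuals, and both fitting stages are rerun
  per replicate. This propagates first-stage rate uncertainty into the
  interval.
- **case**: classical resampling of (ratio, k) pairs, the only option
  when nothing but the rate points is available. With a typical
  titration of ~6 designed ratios this interval runs systematically
  narrow: in simulation at the default study conditions its 95% interval
  covers the true φ only ~53% of the time, versus ~90% for the
  parametric scheme — which is why the parametric scheme is the default
  rather than the more familiar case bootstrap. (A residual bootstrap
  on the rate points was also evaluated at ~72% coverage and rejected.)

Resamples on which the model is unidentifiable (too few distinct ratios,
or a lost control with k₀ free) are skipped and counted. All resampling
is driven by an explicit integer seed and is exactly reproducible.
Bootstrap replicate rate fits use a vectorised Gauss–Newton solver for
the same one-parameter least-squares problem as the primary fit.

### Numerical settings

Nonlinear fits run with tolerances of 1e−15 (xtol/ftol/gtol), so
noiseless inputs recover their generating parameters to ~1e−8 or better;
initial values come from closed-form heuristics (log-linear slope for k;
the control rate and the first ratio crossing k₀/2 for (k₀, φ)). Rates
below numerical zero are clipped at 0 and flagged.

## Synthetic data

`simulate_cleavage_series` emulates an inhibitor titration of
RecA-mediated LexA cleavage monitored by gel densitometry. Defaults are
the studied conditions: inhibitor at 1000/500/250/125/62.5/0 µM against
6.7 µM LexA, sampled at 0–25 min in 5-min steps, k₀ = 0.1 min⁻¹,
φ = 43.422, additive Gaussian noise of sd 0.03 on the fraction scale
(clipped at zero; a multiplicative log-normal option exists). The t = 0
point is kept noise-free because it is the normalisation anchor — its
experimental error is shared by all points of a series rather than
scattering independently. The generator draws from exactly the model the
fitters assume; recovery tests on it therefore demonstrate correctness
of the estimation machinery, not robustness to the ways real gel data
deviate (saturated bands, background subtraction error, correlated lane
effects, partial-cleavage plateaus). Under these conditions the median
relative error of φ̂ is ~7% and the parametric bootstrap's 95% interval
covers the true φ in ≈90% of replicates.

`make_toy_screen_table` builds deterministic compound tables for the
screening bookkeeping; `default_screen_table` reproduces the studied
two-library funnel (2276 β-turn mimetics docked / 53 purchased / 0
active; 8607 covalent candidates docked / 80 purchased / 1 active),
whose pooled rates display as 1.22% (virtual) and 0.75% (in vitro).
Hit-rate denominators are compounds-docked for the virtual screen and
compounds-tested for the in-vitro screen; displayed percentages round
half-up to two decimals while the raw value is retained.

## Hydropathy

Per-residue hydrophobicity uses the Kyte–Doolittle scale (−4.5 for Arg to
+4.5 for Ile), embedded as a constant table and cross-checked in the test
suite against Biopython's copy. Smoothed profiles are centred
window means (odd window, default 9); positions within half a window of
either terminus have no smoothed value.

## Known limitations

- Distance-level conclusions from torsion-rebuilt structures carry the
  ideal-geometry caveat described above; analyses of deposited
  coordinates do not.
- The kinetics module assumes complete first-order decay to zero; it does
  not model partial cleavage plateaus, RecA filament-formation kinetics,
  or pH dependence of the autocleavage rate.
- The two-stage effectiveness fit is the default; a joint fit of all
  timecourses in one likelihood is not implemented.
- Turn classification covers the classical type system plus a user
  extension hook; it is not a full secondary-structure assignment.
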