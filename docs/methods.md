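# Methods

## Scope and model overview

`strandlogic` models a cell-free biosensing reaction in which allosteric
transcription factors (aTFs) gate T7 RNA-polymerase transcription of short RNA
invader strands ("InvadeR"), and those invaders drive toehold-mediated DNA
strand displacement (TMSD) circuits ending in a fluorophore/quencher signal
gate. Everything is deterministic mass action: concentrations are µM-scale,
so copy numbers are astronomically large and stochastic effects are
negligible. Units are fixed package-wide — concentrations in µM (templates
are entered in nM and converted on parse), time in minutes, bimolecular rate
constants in µM⁻¹·min⁻¹.

Three reaction families are compiled from a circuit description:

**aTF binding.** For each regulated template T with aTF R (a dimer) and
ligand L:

    R + T   ⇌ RT        (k_on_op, k_off_op)
    R + sL  ⇌ RLs       (k_on_lig, k_off_lig)

The ligand step is a single lumped cooperative reaction of order
s = `ligand_stoichiometry`; ligand-bound aTF cannot bind the operator, and
only operator-free template transcribes. The packaged circuits use s = 1: a
single bound ligand is taken to release the operator, which is consistent
with TetR biochemistry (one inducer per dimer already collapses operator
affinity) and reproduces a sub-stoichiometric half-maximal induction point.
With s = 2 every network reaction would still compile (as an order-3 lumped
step), but 5 µM of dimer would then require ~10 µM of ligand before any
de-repression — a dose-response shifted well above the observed window.

**Transcription.** Free template produces its transcript catalytically at
`k_tx · tx_efficiency_factor` per minute. T7 RNAP (ng amounts) and NTPs
(>10 mM) are in vast excess over nM templates on the 2-h timescale, so no
resource depletion or enzyme saturation is modelled, and no RNA/DNA
degradation is included (the cell-free system has no added nucleases;
observed signals plateau rather than decay).

**TMSD.** Invader–gate reactions are bimolecular with rate constant

    k(n) = k_tmsd_max · 10^(−decade_per_nt · max(0, n_sat − n))

for an n-nucleotide toehold — the standard exponential toehold law,
saturating at `n_sat` = 6 nt with `k_tmsd_max` = 60 µM⁻¹·min⁻¹ (≈10⁶
M⁻¹ s⁻¹). Three design-feature modifiers multiply this base rate:

* `mismatch_penalty` (default 5·10⁻³) for displacement across a deliberate
  mismatch. This implements the NOT-gate bias: sequestration of an invader
  by its RNA NOT gate runs at the full toehold rate, while the competing
  path for that invader (signal gate, or OR gate in the NAND layout) carries
  the penalty. The penalty must be ≲10⁻² because the competing gate is
  present at 5 µM while the NOT-gate RNA accumulates from zero; a weaker
  bias would let the invader reach the reporter during the first minutes of
  the reaction.
* `structure_penalty[transcript]` (default 1.0) scales all TMSD reactions of
  one RNA invader — the hook for secondary-structure effects on invasion
  speed. It deliberately multiplies displacement, not production;
  transcription-efficiency variation is a separate per-template multiplier
  (`tx_efficiency_factor`), because the two effects are experimentally
  separable.
* AND gates open by reversible toehold exchange with their first invader
  (forward at the 5-nt toehold rate, reverse at `k_rev_toehold_exchange` =
  60 min⁻¹) and fire irreversibly with the second invader through a short
  3-nt toehold. The clamp-dependent leak pathway releases output from the
  first invader alone at `clamp_leak0 · 10^(−clamp_decay_per_bp · clamp_bp)`
  — with the packaged 7-bp clamp, ≈4·10⁻⁵ µM⁻¹·min⁻¹, small enough that a
  single-input condition stays below the visible threshold for 2 h.

Signal, OR and threshold-gate displacements are irreversible (their products
retain no toehold). RNA NOT gates sequester their invader irreversibly;
threshold gates consume it to inert waste.

## Calibrated default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_tx | 10 | min⁻¹ | ~0.5 µM·min⁻¹ invader flux from a 50 nM template; puts induced detection in single-digit minutes |
| k_on_op / k_off_op (TetR) | 300 / 0.6 | µM⁻¹min⁻¹ / min⁻¹ | K_d = 2 nM operator affinity; release in ~2 min after induction |
| k_on_op / k_off_op (SmtB) | 300 / 1.2 | — | K_d = 4 nM |
| k_on_lig / k_off_lig (TetR) | 60 / 6·10⁻⁴ | — | effectively irreversible inducer binding (K_d = 10⁻⁵ µM) |
| k_on_lig / k_off_lig (SmtB) | 60 / 18 | — | effective zinc affinity 0.3 µM: spreads the response across 2–10 µM zinc |
| k_tmsd_max, n_sat, decade_per_nt | 60, 6, 1.0 | — | literature-scale saturated TMSD rate and toehold law |
| mismatch_penalty | 0.005 | — | NOT-gate bias (above) |
| clamp_leak0, clamp_decay_per_bp | 0.6, 0.6 | — | 7-bp clamp suppresses AND leak ~10⁴-fold |
| k_rev_toehold_exchange | 60 | min⁻¹ | AND opening unfavourable (K ≈ 0.1 µM⁻¹) until the second invader commits |

These magnitudes were set from literature scales and then refined against the
standard sensor conditions (50 nM template, 5 µM TetR dimer, 5 µM signal
gate) so that the packaged library computes its truth tables and the TetR
dose-response lands inside its observed window; the refinement procedure was
a coarse analytic bracketing of each constraint followed by numerical
verification (the working notes live outside the package).

Per-aTF binding constants live in `KineticParams.tf_binding`; the flat
`k_on_op`/... fields are fall-backs for aTFs without an entry. One global
pair could not describe both TetR (tight, switch-like) and SmtB (weaker,
graded) behaviour.

### Library composition choices

Where a concentration is not pinned by the standard sensor conditions it is a
package design choice: unregulated invader templates run at 10 nM so that a
NOT-gate template at 100 nM (TetR) or 300 nM (SmtB, compensating its partial
~13% de-repressed transcription at 10 µM zinc) always out-produces the
invader it must sequester; all DNA gates are 5 µM; SmtB dimer is 1 µM —
sub-stoichiometric to the 2–10 µM zinc range, which is what makes a graded
zinc response (and hence a multi-tube ADC) possible at all. Logic circuits
use the standard 8-nt-toehold signal gate; comparator/ADC circuits use the
slowed 4-nt version so the 8-nt threshold gate outcompetes it 100-fold.

## Readout conventions

Simulated fluorescence is the free fluorophore-strand concentration, reported
1:1 in µM-equivalent-fluorescein (MEF). Measured arbitrary units convert via
a linear calibration fitted to a fluorescein dilution series: replicates
averaged per concentration, blank subtracted, any concentration with a
saturated replicate excluded, least squares restricted to the 0–3.125 µM
linear range. A reaction is ON when MEF strictly exceeds 0.5 (the visible
threshold); logic tables are read at 120 min (the kinetic runs are 2 h),
dose-responses at 60 min, ADC strips at 100 min using raw (un-normalized)
MEF. The baseline-subtracted normalization
f(x) = (MEF_t=x − MEF_t=0)/(MaxMEF − MEF_t=0) is provided for model–data
comparison only.

## Comparator and ADC design

A threshold gate (same invader, saturating 8-nt toehold, unlabeled) delays
activation by roughly θ/v, where θ is its concentration and v the invader
production rate — the quasi-static picture holds within 10% once the
threshold gate is ≥100× faster than the signal gate. `design_thresholds`
calibrates a strip of J tubes for breakpoints c₁<…<c_J at a fixed read time:
tube j's θ_j is found by bisection (Brent, relative tolerance 10⁻³) so that
MEF(read time) equals the ON threshold at the *geometric* midpoint of
(c_{j−1}, c_j), with c₀ = c₁/4 standing in for the largest blank-like input.
The geometric midpoint is used because the dose-response is naturally viewed
on a log axis; it places both adjacent breakpoints safely inside the tube's
ON and OFF regions. Every design is audited before being returned: simulated
patterns at all breakpoints must be thermometer codes with ON-counts 1…J.
Consequence of midpoint calibration: inputs *between* breakpoints near a
tube's switch point may decode into the neighbouring bin; at the breakpoints
and bin midpoints the decode is exact.

## Numerical choices

Networks integrate with SciPy's BDF and an analytic Jacobian (rate constants
span >4 decades; the operator-binding relaxation rate is ~10³ min⁻¹).
Default tolerances rtol = 10⁻⁹, atol = 10⁻¹² hold every conserved total
(template DNA, aTF, ligand, fluorophore/quencher strands, gate scaffolds,
released outputs) to <10⁻⁸ relative drift; truth-table and design runs relax
to 10⁻⁷/10⁻¹⁰ for speed. Output is sampled on a 1-min grid (the
plate-reader cadence); threshold crossings are refined by linear
interpolation within the bracketing interval. Negative excursions below
atol are clipped to zero; anything larger raises. Conservation vectors are
constructed from per-species strand/protein/ligand content and are verified
to lie in the left null space of the stoichiometry matrix.

## Synthetic data

The generator emulates the data layouts the pipeline consumes — kinetic reads
(1-min interval, 2 h, 3 replicates), fluorescein standard plates (two-fold
serial dilution from 50 µM, 12 samples including the blank, 9 replicates,
detector ceiling with saturation flags) and end-point dose-response series.
Noise is stylized, not fitted: reading = clean·(1 + cv·ε₁) + sd·ε₂ with
cv = 2% and sd = 0.05 MEF by default, chosen to match the visual scale of
replicate scatter in this kind of experiment. All generators are pure
functions of (inputs, seed). What passing tests on these fixtures do *not*
show: real plate reads have drifting baselines, edge effects, and
condition-correlated errors; real reactions batch-vary in RNAP activity; none
of that is generated.

## Parameter fitting

Weighted nonlinear least squares on log-parameters (positivity by
construction), trust-region (`least_squares`, method "trf") with seeded
multistart (default 8 starts: bounds midpoint plus log-uniform draws); each
trace — not each point — carries equal weight. The default identifiability
suite fits (k_tx, k_tmsd_max, SmtB k_off_lig) on four conditions of a zinc
sensor with a deliberately slowed 3-nt signal gate: uninduced, partially
induced (3 µM), induced (10 µM), induced + 2.5 µM threshold gate. The slow
reporter is essential — with the standard 8-nt gate, displacement relaxes in
~0.2 s and k_tmsd_max leaves no signature on a 1-min grid. Uncertainty
reporting is residual-based only; no posterior inference.

## Known limitations

* No sequence-level thermodynamics: toehold length, mismatches, clamps and
  secondary structure enter as lumped rate modifiers, not predictions from
  sequence.
* No RNAP/NTP resource coupling, no degradation, no temperature dependence
  (37 °C assumed throughout).
* The lumped one-step ligand model cannot represent sequential-site
  occupancy kinetics; with stoichiometry 2 it produces an order-3 elementary
  step.
* Spurious transcription from 3′ toeholds is out of scope (all modelled
  gates are 5′-toehold designs), as are aptamer-based reporters, real
  water-matrix effects and lyophilization.
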