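# Methods

## Model and assumptions

The package implements a two-state concerted (MWC-type) description of
modulator-linked enzyme activation. Assumptions, in order of consequence:

- **Two conformations in fast equilibrium.** A and B interconvert much
  faster than turnover, so observed kinetics are population-weighted
  averages. L_U = [B]/[A] for the substrate-free enzyme and L_L for the
  substrate-bound enzyme; values « 1 mean A is favored.
- **Concerted switching.** All n activating modulator sites flip between
  states together; binding constants are occupancy-independent (the same
  K per state regardless of how many modulator molecules are already
  bound), which is what makes the binding polynomials (1 + K·[L])ⁿ exact.
- **Binding does not alter turnover within a state** (σ_A = σ_B = 1): the
  modulator acts purely by redistributing populations.
- **Inhibition is B-confined.** The competitive inhibitory site(s) (m
  copies, constant K_BI) are effective only in conformation B; K_AI is
  fixed at 0. Loading either constraint differently triggers an explicit
  override warning.
- **Michaelis–Menten within the observed parameters.** Velocities are
  v = E₀·kcat_obs·[S]/(Km_obs + [S]); initial rates are the primitive
  observable (no progress-curve fitting).

Units: concentrations in µM (enzyme in nM), rates s⁻¹, association
constants µM⁻¹, energies kJ/mol, temperature kelvin.

## The two specificity-constant representations

The printed specificity-constant expression — the population-weighted
average of kcat_A/Km_A and kcat_B/Km_B over substrate-free weights — is not
algebraically equal to kcat_obs/Km_obs, because Km_B is a free parameter not
linked to the thermodynamic cycle implied by (L_U, L_L, K_BU/K_BL). Under
the shipped presets the two curves differ by up to ~80% across 0.1–10 µM
modulator. Both are implemented (`observed_efficiency` and
`efficiency_ratio`), the `efficiency_consistency` diagnostic reports their
maximum relative gap, and reports always show both. Consequences for
fitting:

- A profile **estimated from velocity data** can only contain the ratio;
  fitting such profiles uses `efficiency_model="ratio"` (the CLI default).
  For m ≥ 1 the affinity stage is then under-determined by exactly one
  dimension — the Km numerator is a degree-(n+m) polynomial whose
  coefficients number one fewer than the unknowns — so (L_U, K_BU, K_BI)
  ride an exact ridge and only their identifiable combinations are pinned.
  Affected parameters surface as `bound-hit` when the optimizer expresses
  the ridge by running to a bound.
- A profile whose efficiency column follows the **printed form**
  (`synth.model_profile(..., efficiency="eq3")`) supplies the independent
  information that breaks the ridge; the library fitting default is
  therefore `efficiency_model="eq3"`, which additionally floats Km_B.
  Under it, noiseless recovery of every floated parameter is exact to
  optimizer precision on all presets.
- Km_A is tied to Km⁰ throughout (the affinity stage floats Km⁰ and Km_B
  only; the presets satisfy Km_A = Km⁰). When Km_B is not floated (ratio
  representation) it is reported at its cycle-implied value
  Km⁰·L_U·K_BUⁿ/(L_L·K_BLⁿ), status `derived:cycle`; the cycle closure is
  reported, never enforced.

## Staged fit

Stage 1 fits the kcat curve for (kcat_A, kcat_B, K_AL, K_BL, L_L); stage 2
freezes those bit-identically and fits the Km and efficiency curves jointly
for (Km⁰, K_AU, K_BU, L_U[, K_BI][, Km_B]), with equal weight on relative
residuals of the two curves so that µM-scale and s⁻¹µM⁻¹-scale data
contribute comparably. Optimization is bounded least squares
(`scipy.optimize.least_squares`, trf) on log₁₀-transformed parameters,
multi-start: one heuristic start (end-point turnovers, transition-midpoint
reciprocals for binding constants) plus seven seeded log-uniform jitters.
Bounds per class: turnover 10⁻⁴–10⁴ s⁻¹, Michaelis constants 10⁻³–10⁵ µM,
association constants 10⁻⁸–10⁶ µM⁻¹, allosteric constants 10⁻¹⁵–10⁶.
Tolerances 10⁻¹⁵ (xtol/ftol/gtol) so noiseless fits reach residual sums
~10⁻³⁰. A fitted parameter landing within a decade of a bound is demoted to
`bound-hit`: the data did not determine it.

A kcat curve with < 0.1% relative spread (or the `equal_kcat` constraint,
for gate-disrupted mutants whose conformations share a turnover number)
makes stage 1 degenerate: a flat curve carries no information on
(K_AL, K_BL, L_L), so those are re-floated in stage 2 — they still enter
the Km denominator — unless pinned via `fixed_params`. The recommended
treatment for a mutant series is the one used for the gate-disrupted
preset: carry the wild-type binding constants over as fixed and float only
(kcat, Km⁰, Km_B, L_U, L_L).

## Site-number selection

The smallest-(n, m) rule: both stages run for every candidate pair
(defaults n ∈ {1..4}, m ∈ {0,1,2}); the selected pair is the
lexicographically smallest whose total RSS is within 5% (relative) of the
global best, plus an absolute floor of 10⁻¹⁶ so the margin stays meaningful
when the best RSS is numerically zero on noiseless data. No information
criterion is used — the rule operationalizes "the minimum model that
accounts for the data"; because candidates are scanned smallest-first, a
larger pair that merely matches the best fit never displaces a smaller
adequate one.

## Rate estimation

Replicates are averaged per (S, L) cell before regression (per-replicate
fitting available behind a flag). Rows above S = 25 µM are excluded before
fitting; the linearity flag is raised when the full-range double-reciprocal
r² falls below 0.98 while the retained-range r² does not. The threshold is
a package choice: clean Michaelis–Menten data sit at r² ≈ 1 to machine
precision, while the substrate-inhibited regime falls far below once
activation has lowered Km (at low modulator, with Km ≈ 60 µM, the
uncompetitive term bends the plot too little to cross it — the flag is a
per-group diagnostic, strongest where the phenomenon is strongest).
(kcat, Km) estimates are taken from the nonlinear Michaelis–Menten fit
initialized by the double-reciprocal line; the linear estimate and its r²
are retained as the linearity diagnostic.

## Synthetic assay

`generate_dataset` emulates the initial-rate structure of a
fluorogenic-substrate proteasome assay: 2 nM enzyme, substrate grid
5–25 µM (50 and 100 µM optionally appended for linearity demonstrations),
modulator grid {0, 0.1, 0.3, 0.5, 1, 2, 3, 5, 10} µM, three replicates,
310.15 K. Noise is multiplicative Gaussian with CV 0.05 by default (a
stand-in — the true scatter of such assays is not characterized here),
truncated at zero, fully seeded. Substrate inhibition is an uncompetitive
phenomenological term, v = E₀·kcat_obs·S/(Km_obs + S·(1+S/Ksi)), present
only so the linearity diagnostics are exercisable; it models no specific
mechanism. What the generator does *not* emulate: fluorescence calibration
and detector noise, substrate depletion, enzyme instability, pipetting
covariance between replicates — so passing recovery tests demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to real-world systematics.

Presets anchor every quantity that has a stated magnitude: conformational
gaps of 32.7 (unbound) and 26.1 kJ/mol (substrate-bound) for the wild-type
presets and 8.3 kJ/mol for the gate-disrupted mutant, per-step binding
contributions of 21.4 and 23.9 kJ/mol (K_BU/K_AU = 4000 exactly;
K_BL/K_AL = exp(23.9/RT) ≈ 1.06×10⁴ — the "about 4000-fold" shorthand is
kept for the substrate-free ratio only, since 23.9 kJ/mol implies the
larger figure), and site numbers (3, 0), (2, 1), (2, 1). All remaining
scales (turnover numbers, Michaelis constants, absolute K values) are
fixture choices, set once so that activation completes by ≈3 µM
(human-like) or ≈1 µM (yeast-like) modulator, and are listed in each
scheme's `fixture_choices`.

## Numerical and convention choices

- R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹ exactly; default temperature 310.15 K
  (37 °C assay; this is also the unique temperature at which a 4000-fold
  ratio corresponds to 21.4 kJ/mol — at 298.15 K it would be 20.6).
- Sign convention: ΔG(A→B) = −RT·ln L, positive when A is favored; every
  ladder row carries a favored-state label so the sign can never be
  misread. Occupancy scaling uses exact (unrounded) γ and δ; with exact
  γ = 4000 the triple-bound unbound-state value is −31.5 kJ/mol
  (32.7 − 3×21.39), which rounds differently from arithmetic done on
  rounded per-step values.
- IC50 is found by a 4096-point geometric scan plus bisection to 10⁻⁶ µM;
  multiple crossings return the smallest with a warning; a pure activator
  returns an explicit not-found (None).
- Bootstrap intervals are residual-bootstrap percentiles (≥100 replicates,
  joint row resampling of the three curves' residuals, refits at the
  fitted (n, m)); failed refits are dropped and counted, with a warning
  above 20%.
- Velocities drawn negative under noise are truncated at zero and counted
  in the dataset metadata.

## Problem sizes

Default study sizes keep every analysis interactive: 9-point modulator
grids, 5-point substrate grids, 3 replicates, 12-pair selection sweeps with
8 optimizer starts per stage, 20-seed recovery studies, and 100–200
bootstrap replicates. These are the package's chosen defaults; all are
parameters.

## Known limitations

- **The L_L/K_BL ridge under noise.** With the anchored per-step energies,
  K_BL ≈ 50 µM⁻¹ (or larger for the yeast-like preset), so the default
  modulator grid never samples below 1/K_BL where L_L and K_BL decouple;
  at 5% noise only the product L_L·K_BLⁿ is identified and L_L itself runs
  to its bound (flagged). Recovering L_L individually from noisy data
  would require modulator points at ≲0.02 µM or much lower noise.
- **Ratio-representation under-determination for m ≥ 1** (see above).
- The substrate-inhibition term is phenomenological; its Ksi has no
  mechanistic reading.
- No enthalpy/entropy decomposition, no temperature-dependence fitting,
  no modelling of the proteasome's other catalytic activities, no
  progress-curve analysis.
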