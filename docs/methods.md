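# Methods

This note documents the models, conventions, numerical choices and known
limitations of `desle`.

## Thermodynamic model

**Liquidus equation.** For a simple eutectic (pure solids, complete liquid
miscibility), the liquidus of crystallizing component *i* satisfies

    ln(x_i γ_i) = −Δh_m,i/(R T)·(1 − T/T_m,i) − Δc_P,i/R·(1 − T_m,i/T + ln(T_m,i/T))

with the subcooled liquid as reference state. Δc_P = c_P(liquid) −
c_P(solid); it defaults to 0, since Δc_P values are rarely measured and the
term is small against the enthalpy term, giving the Schröder–van Laar form.
The sign convention (liquid minus solid) is a package convention; the
correction vanishes identically at T = T_m either way.

**Activity model.** Non-ideality is parameterized per branch by a
Redlich–Kister polynomial R·T·ln γ_i = a x_j² + b x_j³ + c x_j⁴ (0–3 terms,
J/mol). The coefficients are empirical dials with no physical
interpretation; negative values encode favored unlike-pair interactions.
Each branch carries an independent coefficient set and Gibbs–Duhem
cross-consistency between branches is deliberately **not** enforced — the
polynomial is used exactly as an empirical screening/fitting device, not as
a consistent g^E model. Positive coefficients (positive deviation) are
accepted but trigger a warning, since the screening studies restrict
themselves to γ ≤ 1.

**Units.** All internal quantities are SI: J/mol, J/(mol·K), K, mole
fraction. The screened RK range "0 to −30" is interpreted as kJ/mol
(−30 000 … 0 J/mol): values of order tens of J/mol would change ln γ by
~10⁻², which produces no visible depression and would make the non-ideality
study vacuous. CLI/config inputs accept `*_kJmol` keys and convert on read.

**Entropy conventions.** Two named melting-entropy values generate
enthalpies from temperatures (Δh_m = Δs_m·T_m): the Walden rule 54.4
J/(mol·K) (ordered crystals of rigid molecules, Δs_m/R ≈ 7) and a low value
20.0 J/(mol·K) (disordered crystals, Δs_m/R ≈ 2.4).

## Numerics

* **Closed-form liquidus.** With Δc_P = 0 the RK excess is
  temperature-independent, so T = (Δh_m + P(x_j))/(Δh_m/T_m − R ln x). Used
  everywhere it applies; validated against bracketed bisection on the
  residual to ≤ 1e−6 K. When Δh_m + P(x_j) ≤ 0 (over-strong negative
  deviation) no liquidus with T > 0 exists; this raises a typed
  `NoPhysicalLiquidusError`, which curve/sweep/screening layers catch and
  record as an explicit infeasibility flag rather than dropping the node.
* **Full-equation solver.** With Δc_P ≠ 0 the residual is solved by Brent's
  method on (0.01 K, T_m], expanding the upper bracket for
  positive-deviation cases; absolute tolerance 1e−8 K.
* **Eutectic location.** D(x) = T₁(x) − T₂(x) is scanned on a 2001-point
  grid, log-dense toward both pure ends (down to 1e−6 mole fraction),
  because ideal eutectics of dissimilar pairs sit within ~1e−3 of a pure
  side. Each bracketed sign change is refined by Brent to |D| ≤ 1e−8 K.
  Multiple intersections (possible under strong non-ideality) return the
  lowest-temperature root with a logged warning. The normalized depression
  uses the low-melting component as reference: (T_m,2 − T_e)/T_m,2.
* **RK fitting.** The objective is minimized in γ-space exactly as defined
  (OF = Σ(γ_cal − γ_exp)²), not in ln γ-space. The optimizer is a
  deterministic two-start scheme: Levenberg–Marquardt least squares
  initialized from (i) the exact linear least-squares solution in
  R·T·ln γ-space and (ii) the ideal point θ = 0; the lower objective wins.
  Tolerances 1e−15 (ftol/xtol/gtol), max 10 000 evaluations. On noiseless
  data the linear seed is already exact, so recovery is at machine
  precision.
* **Ideal-solubility fit.** Plain OLS of ln x₁ on 1/T (slope s, intercept
  c → Δh_m = −R·s, T_m = −s/c), pooled across systems or per system. No
  weighting and no exclusion of near-pure compositions is applied.
* **Enthalpy screening.** T_m,1 is held fixed while Δh_m,1 is screened over
  a grid; γ_exp is recomputed per assumption (reference-state shift), RK
  coefficients refitted, and γ₁ evaluated at the *experimental* eutectic
  point — x_e supplied by the caller (default: the lowest branch-1
  composition in the data) with T_e interpolated from the branch-1 table.
* **Output formatting.** All floats written by the CLI use 10 significant
  digits so that regression tests are stable across platforms.

## Synthetic data

The generator emulates literature-style binary SLE tables: two liquidus
branches, compositions drawn uniformly on each branch's feasible range
(default: branch 1 on [x₁_e + 0.02, 0.99], branch 2 mirrored; the 0.02
margin avoids branch ambiguity near the eutectic), exact forward-model
temperatures plus i.i.d. Gaussian noise on T. Noise is placed on
temperature, not composition, because liquidus temperatures are the
measured quantity in DSC-style experiments. Seeds are mandatory and echoed
into dataset metadata; the shared-component family generator spawns
per-partner seeds deterministically from one parent seed.

The canonical screening fixture is a choline-chloride-like solute: shared
component at T_m = 597 K with a true Δh_m of 4.3–5 kJ/mol, Walden-rule
partners between ~340 and ~415 K, branch-1 data on the solute-rich side
(x₁ ∈ [0.5, 0.99] for the screening fixture, 25 points, noiseless). With
that fixture the screening grid {1, 5, 10, 20, 40} kJ/mol reproduces the
expected pattern: near-exact refit and γ ≈ 1 at the true enthalpy, the
largest AAD at 1 kJ/mol, and γ drifting well below 1 by 40 kJ/mol. When the
data extend much closer to the eutectic (very wide composition span), the
two-term RK model also struggles at the *high* extreme and the 40 kJ/mol
AAD can rival the 1 kJ/mol one — the apparent-ideality conclusions are
unchanged, but "low AAD at high Δh_m" should not be over-interpreted for
wide-span data.

What the generator does **not** emulate: DSC thermogram artifacts
(heating-rate effects, metastable phases, decomposition), composition
errors, heteroscedastic noise, solid solubility, and compound formation.
Passing the recovery tests therefore shows the estimators are correct and
well-conditioned under the stated noise model, not that real systems are
free of these complications.

## Study conditions and problem sizes

The default sweep grids are chosen to exhibit every monotone trend of the
parameter study while running in seconds: RK grid {0, −6, −12, −18, −24,
−30} kJ/mol per branch; melting-temperature ratio 1.0–3.0 in steps of 0.25
at T_m,2 = 300 K; the four enthalpy cases at 600/300 K combine the Walden
and low entropy conventions per component ({32.64, 12.0} × {16.32, 6.0}
kJ/mol). Monte-Carlo recovery checks use 200 replicates at σ_T = 0.5 K and
25 points per branch, run at a = −5 and −20 kJ/mol. Dense-grid oracles in
the tests use 10⁶-point envelopes.

## Known limitations

* Binary systems only; no peritectics, solid solutions, congruently melting
  compounds, or ternaries.
* RK coefficients are temperature-independent; no Wilson/NRTL/UNIQUAC or
  equation-of-state alternatives.
* The eutectic is defined operationally as the minimum of the upper
  envelope max(T₁, T₂); systems whose branches touch tangentially (no sign
  change of D) are reported as having no eutectic.
* The γ-space objective is non-convex for 2–3 terms; the deterministic
  two-start scheme has proven sufficient on all tested data but is not a
  global optimizer.
* Melting-property back-fits inherit the ideal-solution assumption; the
  package itself demonstrates (shared-component family tests) that hidden
  non-ideality biases them.
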