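# desle

Solid–liquid equilibria (SLE) and eutectic-point modeling for deep eutectic
solvents (DESs) and other simple eutectic binaries.

DESs are mixtures whose eutectic temperature lies far below the melting
points of the pure constituents. Whether a candidate pair forms a deep
eutectic depends on two coupled ingredients: the **melting properties** of
the pure components (melting temperature T_m, melting enthalpy Δh_m, and
optionally the heat-capacity difference Δc_P) and the **non-ideality of the
liquid phase** (activity coefficients γ < 1 for favored unlike-pair
interactions). `desle` is a toolkit for exploring that interplay: it models
liquidus branches, locates eutectic points, back-fits melting properties
from solubility data, screens assumed melting enthalpies, and generates
synthetic SLE datasets with known ground truth for validating every stage.
It is aimed at thermodynamicists and solvent designers who want a small,
tested, scriptable alternative to spreadsheet SLE calculations.

## The model

The liquidus temperature of crystallizing component *i* at liquid mole
fraction x_i follows from equal chemical potential in pure solid and liquid
solution (subcooled-liquid reference state):

```
ln(x_i γ_i) = −Δh_m,i/(R T) · (1 − T/T_m,i) − Δc_P,i/R · (1 − T_m,i/T + ln(T_m,i/T))
```

With the commonly justified Δc_P = 0 this reduces to the Schröder–van Laar
form. Liquid-phase non-ideality is described by an empirical Redlich–Kister
(RK) polynomial in the mole fraction x_j of the other component,

```
R T ln γ_i = a(i) x_j² + b(i) x_j³ + c(i) x_j⁴
```

with coefficients in J/mol that act purely as a dial for the magnitude of
γ (negative = negative deviation from ideality). Because this excess term is
temperature-independent, the Δc_P = 0 liquidus has a closed form,
`T = (Δh_m + P(x_j)) / (Δh_m/T_m − R ln x)`, which the package cross-checks
against bracketed root finding. The eutectic point (x_e, T_e) is the
intersection of the two branches; the depression is reported normalized to
the low-melting component, ΔT_e = (T_m,2 − T_e)/T_m,2.

Three estimation workflows build on this:

* **ideal-solubility back-fit** — ln x₁ is linear in 1/T with slope
  −Δh_m,1/R and intercept Δh_m,1/(R T_m,1); pooled or per-system OLS
  recovers melting properties of components that cannot be measured
  directly (thermal decomposition, polymorphism);
* **RK regression** — coefficients minimizing
  OF = Σ (γ₁,cal − γ₁,exp)², with γ₁,exp obtained by inverting the liquidus
  equation point by point; quality reported as the average absolute
  deviation AAD = (1/N) Σ |T_cal − T_exp|;
* **melting-enthalpy screening** — refitting the RK model under a grid of
  assumed Δh_m values shows how the apparent ideality of a component is an
  artifact of the assumed reference state.

## Worked example

A hypothetical pair with T_m = 600 K / 300 K, Walden-rule enthalpies
(Δh_m = 54.4 · T_m → 32.64 and 16.32 kJ/mol) and a strongly non-ideal
high-melting component (a(1) = −30 kJ/mol):

```yaml
# system.yaml
system:
  name1: salt
  name2: acid
  comp1: {Tm_K: 600, dHm_kJmol: 32.64}
  comp2: {Tm_K: 300, dHm_kJmol: 16.32}
  rk1_kJmol: [-30]
```

```
$ desle eutectic --config system.yaml --out eutectic.json
x1_e = 0.307198375, Te = 284.0656703 K, norm_depression = 0.05311443247
```

Had both branches been ideal, the eutectic would sit at x₁ ≈ 0.0014 and
T_e ≈ 299.93 K — essentially the melting point of the low-melting component.
The strong negative deviation of Component 1 (γ₁ ≈ 0.0023 at the eutectic)
pulls the eutectic composition to x₁ ≈ 0.31 and depresses T_e by ~16 K: a
deep eutectic driven by non-ideality, the design heuristic the package
quantifies. The same library calls are available in Python:

```python
from desle import BinarySystem, MeltingProperties, RKCoefficients, eutectic_point

system = BinarySystem(
    props1=MeltingProperties(Tm=600.0, dHm=32_640.0),
    props2=MeltingProperties(Tm=300.0, dHm=16_320.0),
    coeffs1=RKCoefficients((-30_000.0,)),
)
print(eutectic_point(system))
# EutecticPoint(x1_e=0.3071983750393056, Te=284.06567025974016, ...)
```

Other subcommands: `liquidus` (tabulate a branch), `simulate` (synthetic
data), `fit-melting`, `fit-rk`, `screen`, `sweep` (the ideal and
non-ideality parameter studies). Every run writes a JSON manifest with the
config digest, seed and package version next to its output.

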