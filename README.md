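# gltkin

Steady-state kinetic analysis of Na⁺-coupled aspartate transport.

`gltkin` is for membrane-transport biochemists who measure initial uptake
rates of a substrate into proteoliposomes over a grid of co-ion and
substrate concentrations and want to turn those rates into mechanistic
rate constants. It implements, end to end, the classical-enzymology
workflow for 3 Na⁺ : 1 aspartate symporters of the SLC1A family (archaeal
Glt-type transporters and their EAAT relatives):

* **Schemes** — ordered, partially random and user-defined binding
  mechanisms as validated state graphs, with JSON serialization and
  enumeration of all strictly ordered 3 Na⁺/1 Asp variants.
* **Rate laws** — exact symbolic King–Altman derivation (directed
  spanning trees, cross-checked against the matrix-tree determinant and
  an independent numeric steady-state solver). For the canonical
  two-Na-then-Asp-then-Na cycle:

  ```
  v₀        a₁[Na]³[Asp]
  ──── = ─────────────────────────────────────────────────────────────
  vmax   a₁[Na]³[Asp] + a₂[Na]²[Asp] + a₃[Na][Asp] + a₄[Na]³ + a₅[Na]² + a₆[Na] + a₇
  ```

  with a₁…a₇ explicit monomial sums of the elementary rate constants,
  plus apparent-parameter rearrangements and asymptotic limits — notably
  lim₍[Na]→∞₎ K_M^Asp(app) = k_cat/k₃, which holds for every mechanism in
  which at least one sodium ion binds after aspartate.
* **Fitting** — Michaelis–Menten, Hill and hyperbolic saturation fits of
  rate tables; log-log regime slopes of the apparent K_M; derivation of
  k_cat, k₃ and k_cat/k₃ with delta-method errors; K_M-vs-K_D comparison
  against equilibrium binding data.
* **Synthetic assays** — a seeded generator of noisy rate tables and
  uptake time courses with mixed membrane orientations and one-sided
  (nanobody-style) inactivation, plus closed-loop parameter recovery.

## Worked example

The package bundles the measured uptake grid for the *Thermococcus
kodakarensis* transporter Glt_Tk (61 mean initial rates over 5–300 mM Na⁺
× 0.05–100 µM aspartate):

```python
from gltkin.data import load_table1
from gltkin import run_full_analysis

report = run_full_analysis(load_table1())
d = report.derived
print(f"kcat      = {d.kcat:.2f} s^-1")
print(f"kcat/k3   = {d.kcat_over_k3 * 1e6:.2f} uM")
print(f"k3        = {d.k3:.3g} M^-1 s^-1")
print(f"routes    = {report.k3_routes['relative_disagreement']:.1%} apart")
print(f"slope(low Na) = {report.slopes['low_na'][0]:.2f}")
```

prints

```
kcat      = 0.93 s^-1
kcat/k3   = 0.75 uM
k3        = 1.23e+06 M^-1 s^-1
routes    = 6.9% apart
slope(low Na) = -1.43
```

Reading: the maximal per-transporter turnover is ~0.9 s⁻¹; the apparent
aspartate K_M plateaus near 0.7 µM at saturating Na⁺, and that plateau
equals k_cat/k₃, so the aspartate association rate constant is
k₃ ≈ 1.3 × 10⁶ M⁻¹s⁻¹ — obtained **without** error-prone quantification
of active protein. Two independent routes to k₃ (the half-saturation of
v_max^Na(app) versus [Asp], and the K_M plateau itself) agree to within
7%. The low-sodium log-log slope of the K_M profile (−1.4, model
prediction −1) confirms the steep sodium dependence; the same analysis
run with an equilibrium-K_D table shows K_M ≫ K_D at 300 mM Na⁺,
ruling out rapid-equilibrium kinetics.

The same analysis is available from the shell:

```sh
gltkin analyze src/gltkin/data/glttk_table1.csv --out report.json
gltkin derive --order NA,NA,ASP,NA          # print the symbolic rate law
gltkin simulate --seed 7 --out sim.csv      # synthetic assay table
gltkin recover --n-seeds 20                 # closed-loop recovery study
```

Turnover numbers for related transporters follow from the same identity,
e.g. for the *Pyrococcus horikoshii* homolog with K_M plateau 120 nM and
independently measured k₃ = 1.2 × 10⁶ M⁻¹s⁻¹:

```python
from gltkin import derive_rate_constants
derive_rate_constants(km_limit=120e-9, k3=1.2e6).kcat   # 0.144 s^-1
```

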