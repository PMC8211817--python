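# Methods

## The kinetic model

`gltkin` analyses steady-state transport kinetics of Na⁺-coupled aspartate
symporters of the SLC1A family (archaeal Glt-type transporters and, by
extension, their EAAT homologs). The canonical mechanism is an ordered
five-state cycle

    E ⇌ ENa ⇌ ENaNa ⇌ ENaNaAsp ⇌ ENaNa·Asp·Na → E

in which two sodium ions bind before aspartate and one after, followed by a
single irreversible composite step (rate constant k_cat) that lumps
translocation, internal release and resetting of the empty transporter.
Binding steps are bimolecular (k₁, k₂, k₄ for Na⁺ and k₃ for aspartate, in
M⁻¹s⁻¹; the flux carries the external ligand concentration), unbinding
steps k₋₁…k₋₄ and turnover are unimolecular (s⁻¹). Zero-trans conditions
are assumed (no internal substrate at t = 0), which justifies the single
irreversible turnover arrow.

Key assumptions: states are distinguished by their bound-ligand content
(an optional site tag separates mechanistically distinct intermediates with
equal content, e.g. the two single-Na⁺ states of a random-order branch);
there is exactly one turnover edge; protomers operate independently, so
per-transporter rates add linearly over populations.

## Rate-law derivation (King–Altman / matrix-tree)

The steady-state population of each state is proportional to the sum of
directed-spanning-tree weights rooted at that state; each tree weight is
the product of its edge rates with concentration factors carried
symbolically. Trees are enumerated explicitly — feasible and transparent
for the ≤ 12-state graphs supported — and the per-root tree count is
cross-checked against the matrix-tree determinant, so a silent enumeration
bug cannot pass. The transport rate is

    v₀ / v_max = N([Na],[Asp]) / D([Na],[Asp]),

N collecting the trees rooted at the fully loaded state and D all trees,
grouped by powers of [Na] and [Asp]. For the canonical scheme D groups
into seven coefficient polynomials a₁…a₇ (e.g. a₁ = k₁k₂k₃k₄,
a₇ = k₋₁k₋₂k₋₃(k_cat + k₋₄)). Coefficients are stored as canonical sorted
monomial lists, so symbolic identities are tested as exact multiset
equalities rather than through CAS simplification heuristics.

v_max is treated as a free empirical scale (the plateau rate at saturating
ligands); the turnover constant cancels from the normalized fraction, which
is why N for the canonical scheme is simply a₁[Na]³[Asp].

Rearrangement gives the apparent parameters: at fixed [Na⁺] the rate is a
rectangular hyperbola in [Asp] with

    v_max^Asp(app) = v_max · a₁[Na]² / (a₁[Na]² + a₂[Na] + a₃)
    K_M^Asp(app)  = (a₄[Na]³ + a₅[Na]² + a₆[Na] + a₇) / (a₁[Na]³ + a₂[Na]² + a₃[Na])

while at fixed [Asp] the sodium dependence is cubic (sigmoidal, fitted
empirically with the Hill equation) with asymptote

    v_max^Na(app) = v_max · [Asp] / (k_cat/k₃ + [Asp]).

Asymptotic limits are computed by leading/trailing-term extraction on the
grouped polynomials, not numeric extrapolation: the high-[Na⁺] limit of
K_M^Asp(app) is a₄/a₁ = k_cat/k₃ and the low-[Na⁺] behaviour is
a₇/(a₃[Na]) (log-log slope −1). `check_limit_theorem` verifies, per
mechanism, whether the high-sodium limit equals k_cat over the aspartate
on-rate; symbolically this holds for every enumerated mechanism with at
least one Na⁺ binding after aspartate (and for the random-first-two-Na⁺
branch), and fails for the aspartate-last mechanism.

### Numeric oracle

`steady_state_oracle` solves the flux-balance equations directly on the
state graph, with no reference to spanning trees, using GTH
(Grassmann–Taksar–Heyman) elimination. GTH is subtraction-free, giving
componentwise *relative* accuracy even when the loaded-state occupancy is
twenty orders of magnitude below unity — a regime where a plain LU solve
of the balance system returns pure rounding noise. Symbolic and numeric
routes agree to better than 10⁻¹⁰ relative over random constants and
concentrations.

## Fitting

All fits are nonlinear least squares (`scipy.optimize.curve_fit`) with
non-negative bounds and a five-point multi-start (heuristic initial values:
v_max ← max observed rate, K ← log-interpolated half-max concentration,
n ← 1; starts scale K by 0.2/1/5 and vary n), keeping the lowest-SSR
solution, so clean-data recovery does not depend on starting points.
Standard errors are asymptotic (from the Jacobian). The default is
*unweighted* least squares on replicate-mean rates — the bundled reference
values were obtained from printed means, and replicate-level data are not
available — with 1/SEM² weighting as an option. Weighted and unweighted
fits coincide when all SEMs are equal.

The Hill half-saturation is parameterized directly as the concentration K
(not Kⁿ), matching how apparent sodium affinities are reported (mM). The
Hill coefficient is unconstrained-positive; values below 1 are legitimate
results at high aspartate.

Pipeline conventions (`run_paper_analysis`):

* the 1 mM Na⁺ row is excluded by default (near the assay noise floor,
  too few aspartate points);
* log-log regimes for the K_M^Asp(app) slope default to {5, 10, 25, 50} mM
  (low) and {100, 200, 300} mM (high), where the profile is respectively
  steep and flat;
* k_cat is taken as the plateau of the hyperbolic fit of v_max^Asp(app)
  versus [Na⁺], divided by 60 (rates are per-transporter min⁻¹);
* k₃ is derived twice — from the half-saturation of v_max^Na(app) versus
  [Asp] (route A, the primary estimate) and from k_cat over the mean
  high-regime K_M^Asp(app) plateau (route B) — and the report records
  their relative disagreement as an internal consistency check (< 7% on
  the bundled grid);
* uncertainties on derived constants are propagated by the delta method.

`compare_km_kd` matches a user-supplied equilibrium-K_D table to the
fitted K_M profile by nearest [Na⁺] (25% relative tolerance) and classes
each ratio as K_M≫K_D (> 3), ≈ (1/3–3) or ≪ (< 1/3); under
rapid-equilibrium kinetics all ratios would be 1, so structured departures
diagnose a steady-state mechanism.

## Synthetic assay generator

`synthetic_data` emulates the statistical structure of a radiolabel uptake
assay in proteoliposomes:

* **True rates** come from the derived rate law on a [Na⁺] × [Asp] grid
  (defaults: 5–300 mM × 0.05–100 µM, the measurable window of such
  assays), scaled by v_max = 60·k_cat min⁻¹.
* **Noise** is multiplicative lognormal with constant CV (default 0.15,
  n = 3 replicates) — printed SEMs of this assay type scale roughly with
  the mean. Reported values are replicate mean, SEM and n. Seeds are
  explicit; identical config + seed reproduces tables bit-for-bit.
* **Orientation mixture**: a fraction of transporters (default 0.5)
  reconstitutes right-side-out, the rest inside-out, with optionally
  different rate constants per orientation; total rate is the weighted sum.
  A membrane-impermeable binder ("sybody") can inactivate the external
  population only (`sybody="external"`) or both (`"both"`), emulating
  side-specific inhibition.
* **Time courses** accumulate substrate as A(t) = v₀·τ·(1 − e^(−t/τ))
  with τ = ∞ (exactly linear) by default; the exponential is a
  phenomenological stand-in for the departure from linearity at long
  times, not a mechanistic liposome-filling model — only the early window
  (default 20 s) from which initial rates are extracted (origin-anchored
  least-squares slope) is meaningful. Counter-transport, membrane
  potential and counting statistics are not simulated.

Default rate constants (chosen once for realism): k₁ = k₂ = 2×10³ M⁻¹s⁻¹,
k₋₁ = k₋₂ = 100 s⁻¹ (weak individual Na⁺ steps → apparent Hill n ≈ 1.7,
K_M^Na ≈ 50 mM), k₃ = 1.3×10⁶ M⁻¹s⁻¹, k₋₃ = 2 s⁻¹, k₄ = 5×10³ M⁻¹s⁻¹,
k₋₄ = 10 s⁻¹, k_cat = 0.9 s⁻¹, so k_cat/k₃ ≈ 0.69 µM and the apparent
aspartate K_M runs from tens of µM at 5 mM Na⁺ down to a sub-µM plateau.

### What closure tests do and do not show

`recover_parameters` closes the loop: simulate → fit → derive, comparing
recovered k_cat, k_cat/k₃ and k₃ to the generating constants. Two facts
matter when reading these results. First, the analysis pipeline fits Hill
and hyperbolic curves to a rate law that is neither, on a finite grid;
the extracted v_max^Na(app) therefore differs slightly from its [Na⁺]→∞
definition, leaving a ~5–9% upward bias in recovered k_cat/k₃ *even with
zero noise* on the default grid. The bias vanishes (< 2%) when the grids
extend deep into saturation, which the tests verify separately. Second,
truncating the sodium grid at 50 mM biases the recovered plateau high by
far more (> 20%), demonstrating why the saturating-sodium regime is
essential to the method. Passing recovery tests therefore validate the
pipeline's self-consistency under the generator's assumptions
(multiplicative noise, exact rate-law kinetics, complete grids); they do
not establish robustness to systematic errors real assays may have
(orientation-dependent kinetics, background binding, concentration
errors).

## Numerical and degenerate-input choices

* Concentrations are molar internally; mM/µM only at interfaces
  (tables, reports), avoiding unit slips in k₃ (M⁻¹s⁻¹) derivations.
* [Asp] = 0 gives rate 0 exactly; negative concentrations raise.
* Non-convergent fits (after multi-start) return a flagged result with
  NaN estimates rather than raising.
* Michaelis–Menten fits need ≥ 3 distinct concentrations, Hill fits ≥ 4
  (three free parameters); under-determined rows/columns of a sparse grid
  are skipped and listed in the report's `skipped` map instead of
  aborting the analysis.
* Rate-law derivation refuses graphs over 12 states (explicit tree
  enumeration would become the wrong tool well before cost became
  prohibitive: grouped output would be unreadable).
* Equality of symbolic limits is decided by `sympy.simplify` on the
  difference, on expressions built from positive symbols.

## Known limitations

* Apparent-parameter standard errors are asymptotic and computed from
  printed mean rates; replicate-level (or weighted) fitting generally
  gives different SEs, so reported uncertainties are indicative.
* The Hill equation is an empirical descriptor of the sigmoidal sodium
  dependence; its parameters (other than the asymptote's role in route A)
  carry no direct mechanistic meaning here.
* Reverse turnover and leak pathways are excluded by construction;
  proton/potassium-coupled cycles (EAAT-style) are out of scope.
* `v_max` is an empirical scale; absolute turnover numbers from it
  require accurate protein quantification, which is exactly the
  error-prone step the K_M-plateau route is designed to avoid.
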