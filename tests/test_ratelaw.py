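"""Symbolic rate-law derivation: coefficient identities, numeric agreement
with an independent steady-state solver, rearrangements and limits."""

import numpy as np
import pytest
import sympy as sp

from gltkin.ratelaw import (
    ASP_SYM,
    NA_SYM,
    VMAX_SYM,
    CoefficientPoly,
    RateLawError,
    apparent_parameter_expressions,
    asymptotic_km,
    check_limit_theorem,
    derive_rate_law,
    evaluate_rate,
    steady_state_oracle,
)
from gltkin.scheme import (
    APO,
    ASP,
    NA,
    BindingState,
    Edge,
    KineticScheme,
    build_canonical_scheme,
    build_ordered_scheme,
    build_random_first_two_na_scheme,
    enumerate_ordered_mechanisms,
)

# Denominator coefficients of the canonical two-Na-then-Asp-then-Na rate law,
# as exact monomial multisets, keyed by ([Na] power, [Asp] power).
CANONICAL_COEFFICIENTS = {
    (3, 1): {("k1", "k2", "k3", "k4")},
    (2, 1): {("k2", "k3", "k4", "kcat"), ("k1", "k3", "k4", "kcat"),
             ("k1", "k2", "k3", "kcat"), ("k1", "k2", "k3", "k-4")},
    (1, 1): {("k-1", "k3", "k4", "kcat")},
    (3, 0): {("k1", "k2", "k4", "kcat")},
    (2, 0): {("k1", "k-2", "k4", "kcat"), ("k1", "k2", "k-3", "kcat"),
             ("k1", "k2", "k-3", "k-4")},
    (1, 0): {("k1", "k-2", "k-3", "kcat"), ("k-1", "k-2", "k4", "kcat"),
             ("k1", "k-2", "k-3", "k-4")},
    (0, 0): {("k-1", "k-2", "k-3", "kcat"), ("k-1", "k-2", "k-3", "k-4")},
}


def _random_constants(rng, symbols):
    return {s: float(10 ** rng.uniform(-1, 2)) for s in symbols}


class TestDerivation:
    def test_canonical_denominator_coefficients(self, canonical_law):
        got = {key: {tuple(sorted(m)) for m in poly.monomials}
               for key, poly in canonical_law.denominator.items()}
        want = {key: {tuple(sorted(m)) for m in group}
                for key, group in CANONICAL_COEFFICIENTS.items()}
        assert got == want
        # multiset sizes: 1, 4, 1, 1, 3, 3, 2
        sizes = {k: len(v) for k, v in canonical_law.denominator.items()}
        assert sizes == {(3, 1): 1, (2, 1): 4, (1, 1): 1, (3, 0): 1,
                         (2, 0): 3, (1, 0): 3, (0, 0): 2}

    def test_canonical_numerator_is_a1_term(self, canonical_law):
        assert set(canonical_law.numerator) == {(3, 1)}
        assert canonical_law.numerator[(3, 1)].monomials == (
            ("k1", "k2", "k3", "k4"),)

    def test_two_state_toy_gives_briggs_haldane(self):
        e, es = BindingState(0, 0), BindingState(0, 1)
        toy = KineticScheme(
            states=(e, es),
            edges=(Edge(e, es, "k1", ASP, "k-1"),
                   Edge(es, e, "k-1", None, "k1")),
            turnover=Edge(es, e, "kcat"),
        )
        law = derive_rate_law(toy)
        s, k1, km1, kcat = sp.symbols("Asp k1 k-1 kcat", positive=True)
        expected = s / (s + (km1 + kcat) / k1)
        got = law.to_sympy().subs(VMAX_SYM, 1)
        assert sp.simplify(got - expected) == 0

    def test_state_limit_enforced(self):
        s = build_canonical_scheme()
        import gltkin.ratelaw as rl
        old = rl.MAX_STATES
        try:
            rl.MAX_STATES = 3
            with pytest.raises(RateLawError):
                derive_rate_law(s)
        finally:
            rl.MAX_STATES = old

    def test_coefficient_poly_positive_at_positive_constants(self):
        poly = CoefficientPoly((("k1", "k2"), ("k-1",)))
        assert poly.evaluate({"k1": 0.5, "k2": 3.0, "k-1": 0.1}) > 0


class TestOracleAgreement:
    def test_unit_constants_give_one_fifteenth(self, canonical_scheme,
                                               unit_constants):
        # a1..a7 = 1,4,1,1,3,3,2 at unit constants and 1 M concentrations
        got = steady_state_oracle(canonical_scheme, unit_constants, 1.0, 1.0)
        assert got == pytest.approx(1 / 15, rel=1e-12)

    def test_zero_substrate_gives_zero_rate(self, canonical_scheme,
                                            canonical_law, unit_constants):
        assert steady_state_oracle(canonical_scheme, unit_constants,
                                   1.0, 0.0) == pytest.approx(0.0, abs=1e-15)
        assert canonical_law.fraction(unit_constants, 1.0, 0.0) == 0.0

    def test_symbolic_matches_oracle_on_random_draws(self, canonical_scheme,
                                                     canonical_law):
        rng = np.random.default_rng(42)
        symbols = [e.symbol for e in canonical_scheme.all_edges()]
        worst = 0.0
        for _ in range(100):
            constants = _random_constants(rng, symbols)
            na = 10 ** rng.uniform(-4, 0)
            asp = 10 ** rng.uniform(-8, -2)
            sym = canonical_law.fraction(constants, na, asp)
            orc = steady_state_oracle(canonical_scheme, constants, na, asp)
            worst = max(worst, abs(sym - orc) / sym)
        assert worst < 1e-10

    def test_oracle_agreement_for_branched_scheme(self):
        scheme = build_random_first_two_na_scheme()
        law = derive_rate_law(scheme)
        rng = np.random.default_rng(7)
        symbols = [e.symbol for e in scheme.all_edges()]
        for _ in range(20):
            constants = _random_constants(rng, symbols)
            na, asp = 10 ** rng.uniform(-3, 0), 10 ** rng.uniform(-7, -3)
            sym = law.fraction(constants, na, asp)
            orc = steady_state_oracle(scheme, constants, na, asp)
            assert sym == pytest.approx(orc, rel=1e-10)


class TestEvaluation:
    def test_unit_constants_scaled_by_vmax(self, canonical_law,
                                           unit_constants):
        v = evaluate_rate(canonical_law, unit_constants, 1.0, 1.0, vmax=15.0)
        assert v == pytest.approx(1.0, rel=1e-12)

    def test_saturation_limit_reaches_vmax(self, canonical_law,
                                           default_constants):
        v = evaluate_rate(canonical_law, default_constants, 1e3, 1e3,
                          vmax=54.0)
        assert v == pytest.approx(54.0, rel=1e-3)

    def test_negative_concentration_rejected(self, canonical_law,
                                             unit_constants):
        with pytest.raises(RateLawError):
            evaluate_rate(canonical_law, unit_constants, -1.0, 1.0)

    def test_monotone_in_both_concentrations(self, canonical_law,
                                             default_constants):
        na = np.logspace(-4, 0, 25)
        asp = np.logspace(-8, -3, 25)
        for a in (1e-7, 1e-5, 1e-4):
            v = evaluate_rate(canonical_law, default_constants, na, a)
            assert np.all(np.diff(v) >= -1e-15) and np.all(v < 1.0)
        for n in (1e-3, 1e-2, 1e-1):
            v = evaluate_rate(canonical_law, default_constants, n, asp)
            assert np.all(np.diff(v) >= -1e-15) and np.all(v < 1.0)

    def test_common_rate_scaling_leaves_fraction_invariant(
            self, canonical_law, default_constants):
        scaled = {k: 17.3 * v for k, v in default_constants.items()}
        f1 = canonical_law.fraction(default_constants, 0.05, 1e-6)
        f2 = canonical_law.fraction(scaled, 0.05, 1e-6)
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestApparentParameters:
    def test_varied_na_gives_vmax_saturation_in_asp(self, canonical_law):
        app = apparent_parameter_expressions(canonical_law, NA)
        k3, kcat = sp.symbols("k3 kcat", positive=True)
        expected = VMAX_SYM * ASP_SYM / (kcat / k3 + ASP_SYM)
        assert sp.simplify(app.vmax_app - expected) == 0
        assert not app.saturating  # cubic in [Na]: no single half-saturation
        with pytest.raises(RateLawError):
            app.km_app_fn()

    def test_varied_asp_km_matches_coefficient_ratio(self, canonical_law):
        app = apparent_parameter_expressions(canonical_law, ASP)
        assert app.saturating
        polys = canonical_law.denominator

        def group(key):
            return polys[key].to_sympy()

        num = sum(group((p, 0)) * NA_SYM ** p for p in range(4))
        den = sum(group((p, 1)) * NA_SYM ** p for p in range(1, 4))
        assert sp.simplify(app.km_app - num / den) == 0

    def test_unit_constants_high_na_km_is_one_molar(self, canonical_law,
                                                    unit_constants):
        app = apparent_parameter_expressions(canonical_law, ASP)
        km = app.km_app.subs({sp.Symbol(s, positive=True): 1.0
                              for s in unit_constants})
        assert sp.limit(km, NA_SYM, sp.oo) == 1

    def test_expressions_consistent_with_rate_evaluation(
            self, canonical_law, default_constants):
        # vmax_app(Asp) and km_app(Na) reproduce the full rate law:
        # v(na, asp) = vmax_app_at_inf_na * asp... checked via the MM identity
        app = apparent_parameter_expressions(canonical_law, ASP)
        subs = {sp.Symbol(s, positive=True): v
                for s, v in default_constants.items()}
        km_fn = sp.lambdify(NA_SYM, app.km_app.subs(subs), "numpy")
        vmax_fn = sp.lambdify(NA_SYM,
                              app.vmax_app.subs(subs).subs(VMAX_SYM, 1),
                              "numpy")
        rng = np.random.default_rng(3)
        for _ in range(10):
            na = 10 ** rng.uniform(-3, 0)
            asp = 10 ** rng.uniform(-8, -3)
            direct = canonical_law.fraction(default_constants, na, asp)
            via_app = vmax_fn(na) * asp / (km_fn(na) + asp)
            assert direct == pytest.approx(via_app, rel=1e-10)


class TestAsymptoticLimits:
    def test_high_na_limit_is_kcat_over_k3(self, canonical_law):
        k3, kcat = sp.symbols("k3 kcat", positive=True)
        assert sp.simplify(asymptotic_km(canonical_law, "high_na")
                           - kcat / k3) == 0

    def test_low_na_limit_scales_as_inverse_na(self, canonical_law):
        low = asymptotic_km(canonical_law, "low_na")
        # a7 / (a3 [Na]): exactly one inverse power of [Na]
        assert sp.degree(sp.fraction(low)[1], NA_SYM) == 1
        a3 = canonical_law.denominator[(1, 1)].to_sympy()
        a7 = canonical_law.denominator[(0, 0)].to_sympy()
        assert sp.simplify(low - a7 / (a3 * NA_SYM)) == 0

    def test_vanishing_turnover_removes_the_plateau(self, canonical_law):
        # kcat -> 0 is the equilibrium-binding picture: the apparent K_M
        # keeps declining as 1/[Na] instead of levelling off
        app = apparent_parameter_expressions(canonical_law, ASP)
        km0 = sp.cancel(app.km_app.subs(sp.Symbol("kcat", positive=True), 0))
        assert sp.limit(km0, NA_SYM, sp.oo) == 0
        assert sp.limit(km0 * NA_SYM, NA_SYM, sp.oo).is_positive

    def test_small_kcat_approaches_equilibrium_dissociation(
            self, default_constants):
        # independent equilibrium oracle: with detailed-balance weights
        # w(E)=1, w(ENa)=K1 Na, ..., the aspartate-bound fraction is
        # MM-shaped with Kd_app = (1 + K1 Na + K1 K2 Na^2)
        #                         / (K1 K2 K3 Na^2 (1 + K4 Na))
        c = dict(default_constants, kcat=1e-9)
        law = derive_rate_law(build_canonical_scheme())
        app = apparent_parameter_expressions(law, ASP)
        subs = {sp.Symbol(s, positive=True): v for s, v in c.items()}
        km_fn = sp.lambdify(NA_SYM, app.km_app.subs(subs), "numpy")
        K1 = c["k1"] / c["k-1"]
        K2 = c["k2"] / c["k-2"]
        K3 = c["k3"] / c["k-3"]
        K4 = c["k4"] / c["k-4"]
        for na in (0.005, 0.05, 0.3):
            kd_app = (1 + K1 * na + K1 * K2 * na ** 2) / (
                K1 * K2 * K3 * na ** 2 * (1 + K4 * na))
            assert km_fn(na) == pytest.approx(kd_app, rel=1e-4)
        # ... but at the realistic turnover rate the steady-state K_M
        # deviates from the equilibrium K_D
        km_real = sp.lambdify(
            NA_SYM,
            app.km_app.subs({sp.Symbol(s, positive=True): v
                             for s, v in default_constants.items()}),
            "numpy")
        kd_300 = (1 + K1 * 0.3 + K1 * K2 * 0.3 ** 2) / (
            K1 * K2 * K3 * 0.3 ** 2 * (1 + K4 * 0.3))
        assert km_real(0.3) > 3 * kd_300


class TestLimitTheorem:
    @pytest.mark.parametrize("position,expected", [(1, True), (2, True),
                                                   (3, True), (4, False)])
    def test_ordered_mechanisms(self, position, expected):
        scheme = next(s for s in enumerate_ordered_mechanisms()
                      if s.meta["asp_position"] == position)
        holds, limit = check_limit_theorem(scheme)
        assert holds is expected
        if expected:
            on = f"k{position}"
            target = (sp.Symbol("kcat", positive=True)
                      / sp.Symbol(on, positive=True))
            assert sp.simplify(limit - target) == 0

    def test_asp_last_limit_retains_extra_constants(self):
        scheme = build_ordered_scheme((NA, NA, NA, ASP))
        holds, limit = check_limit_theorem(scheme)
        assert not holds
        syms = {str(s) for s in limit.free_symbols}
        assert not syms <= {"kcat", "k4"}

    def test_random_sodium_branch_still_satisfies_theorem(self):
        holds, limit = check_limit_theorem(build_random_first_two_na_scheme())
        assert holds
        target = (sp.Symbol("kcat", positive=True)
                  / sp.Symbol("k3", positive=True))
        assert sp.simplify(limit - target) == 0
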