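"""King-Altman derivation and evaluation of steady-state rate laws.

For a cyclic transporter scheme the steady-state population of each
state is proportional to the sum of directed-spanning-tree weights
rooted at that state (matrix-tree theorem); each tree weight is the
product of its edge rates, with binding edges carrying a factor of the
bound ligand's external concentration.  The initial transport rate is

    v0 = vmax * N([Na],[Asp]) / D([Na],[Asp])

where N collects the trees rooted at the fully loaded state, D collects
the trees rooted at every state, and both are grouped by the powers of
[Na] and [Asp].  For the canonical two-Na-then-Asp-then-Na scheme the
denominator groups into seven coefficient polynomials

    a1 [Na]^3 [Asp] + a2 [Na]^2 [Asp] + a3 [Na][Asp]
      + a4 [Na]^3 + a5 [Na]^2 + a6 [Na] + a7

with a1 = k1 k2 k3 k4 etc.  Coefficients are kept as canonical sorted
monomial lists so that symbolic identities can be checked as exact
multiset equalities; sympy is used only downstream, for rearrangements
(apparent parameters, asymptotic limits).

Trees are enumerated explicitly, which is transparent and exact for the
small graphs of interest (<= 12 states); the enumeration is cross-checked
against a determinant-based arborescence count.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import sympy as sp

from .scheme import APO, ASP, NA, KineticScheme, SchemeError

MAX_STATES = 12

#: sympy concentration symbols used in all exported expressions (molar)
NA_SYM = sp.Symbol("Na", positive=True)
ASP_SYM = sp.Symbol("Asp", positive=True)
VMAX_SYM = sp.Symbol("vmax", positive=True)


class RateLawError(ValueError):
    """Raised for schemes whose rate law cannot be derived or evaluated."""


Monomial = tuple[str, ...]


def monomial(symbols: Sequence[str]) -> Monomial:
    """Canonical (sorted) product of rate-constant symbols."""
    return tuple(sorted(symbols))


@dataclass(frozen=True)
class CoefficientPoly:
    """An implicit sum of rate-constant monomials, all with coefficient +1."""

    monomials: tuple[Monomial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "monomials", tuple(sorted(self.monomials)))

    def as_multiset(self) -> tuple[Monomial, ...]:
        return self.monomials

    def evaluate(self, constants: Mapping[str, float]) -> float:
        total = 0.0
        for mono in self.monomials:
            term = 1.0
            for s in mono:
                term *= constants[s]
            total += term
        return total

    def to_sympy(self) -> sp.Expr:
        return sp.Add(*[
            sp.Mul(*[sp.Symbol(s, positive=True) for s in mono])
            for mono in self.monomials
        ])

    def __len__(self) -> int:
        return len(self.monomials)


@dataclass
class RateLaw:
    """Grouped symbolic rate law v0/vmax = N/D of a kinetic scheme.

    ``numerator`` and ``denominator`` map ([Na] power, [Asp] power) to
    the coefficient polynomial of that concentration term.
    """

    numerator: dict[tuple[int, int], CoefficientPoly]
    denominator: dict[tuple[int, int], CoefficientPoly]
    kcat_symbol: str = "kcat"
    asp_on_symbols: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    # -- evaluation --------------------------------------------------------

    def fraction(self, constants: Mapping[str, float], na, asp):
        """v0/vmax at molar concentrations ``na`` and ``asp``."""
        na = np.asarray(na, dtype=float)
        asp = np.asarray(asp, dtype=float)
        if np.any(na < 0) or np.any(asp < 0):
            raise RateLawError("concentrations must be non-negative")

        def group_value(group):
            total = 0.0
            for (p_na, p_asp), poly in group.items():
                total = total + poly.evaluate(constants) * na ** p_na * asp ** p_asp
            return total

        out = group_value(self.numerator) / group_value(self.denominator)
        return out.item() if np.ndim(out) == 0 else out

    # -- sympy views -------------------------------------------------------

    def _group_sympy(self, group) -> sp.Expr:
        return sp.Add(*[
            poly.to_sympy() * NA_SYM ** p_na * ASP_SYM ** p_asp
            for (p_na, p_asp), poly in sorted(group.items())
        ])

    def numerator_sympy(self) -> sp.Expr:
        return self._group_sympy(self.numerator)

    def denominator_sympy(self) -> sp.Expr:
        return self._group_sympy(self.denominator)

    def to_sympy(self) -> sp.Expr:
        """Symbolic v0 = vmax * N/D."""
        return VMAX_SYM * self.numerator_sympy() / self.denominator_sympy()

    # -- export ------------------------------------------------------------

    def to_dict(self) -> dict:
        def group_d(group):
            return {
                f"Na^{p}|Asp^{q}": ["*".join(m) for m in poly.monomials]
                for (p, q), poly in sorted(group.items())
            }

        return {
            "asp_on_symbols": list(self.asp_on_symbols),
            "denominator": group_d(self.denominator),
            "kcat_symbol": self.kcat_symbol,
            "numerator": group_d(self.numerator),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def equation_string(self) -> str:
        def term(p, q, name):
            conc = ""
            if p:
                conc += f"[Na]^{p}" if p > 1 else "[Na]"
            if q:
                conc += f"[Asp]^{q}" if q > 1 else "[Asp]"
            return f"{name}{'*' if conc else ''}{conc}"

        names = {}
        for i, key in enumerate(sorted(self.denominator,
                                       key=lambda k: (-k[1], -k[0])), start=1):
            names[key] = f"a{i}"
        num = " + ".join(term(p, q, names[(p, q)])
                         for (p, q) in sorted(self.numerator,
                                              key=lambda k: (-k[1], -k[0])))
        den = " + ".join(term(p, q, names[(p, q)])
                         for (p, q) in sorted(self.denominator,
                                              key=lambda k: (-k[1], -k[0])))
        return f"v0/vmax = ({num}) / ({den})"


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def _spanning_trees_to_root(out_edges, nodes, root):
    """All arborescences converging on ``root``: one out-edge per non-root
    node such that every node reaches the root without cycles."""
    others = [n for n in nodes if n != root]
    for choice in itertools.product(*[out_edges[n] for n in others]):
        nxt = {e.source: e.target for e in choice}
        ok = True
        for start in others:
            seen = set()
            cur = start
            while cur != root:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = nxt[cur]
            if not ok:
                break
        if ok:
            yield choice


def _arborescence_count(scheme: KineticScheme, root) -> int:
    """Matrix-tree determinant count of arborescences into ``root``."""
    nodes = list(scheme.states)
    idx = {s: i for i, s in enumerate(nodes)}
    n = len(nodes)
    lap = sp.zeros(n, n)
    for e in scheme.all_edges():
        i, j = idx[e.source], idx[e.target]
        lap[i, i] += 1
        lap[i, j] -= 1
    r = idx[root]
    keep = [i for i in range(n) if i != r]
    return int(lap.extract(keep, keep).det())


def derive_rate_law(scheme: KineticScheme, cross_check: bool = True) -> RateLaw:
    """Symbolic steady-state rate law of ``scheme`` by the King-Altman method.

    Returns the rate law grouped by concentration powers.  The numerator
    collects the spanning trees rooted at the fully loaded state, whose
    steady-state occupancy (times kcat) is the transport rate; the
    turnover rate constant is absorbed into the empirical vmax scale, so
    the numerator of the canonical scheme is a1 [Na]^3 [Asp] with
    a1 = k1 k2 k3 k4.
    """
    if len(scheme.states) > MAX_STATES:
        raise RateLawError(f"scheme has more than {MAX_STATES} states")
    g = scheme.graph()
    if not nx.is_strongly_connected(g):
        raise RateLawError("scheme graph is not strongly connected")

    out_edges = {s: [] for s in scheme.states}
    for e in scheme.all_edges():
        out_edges[e.source].append(e)

    loaded = scheme.turnover.source
    numerator: dict[tuple[int, int], list[Monomial]] = {}
    denominator: dict[tuple[int, int], list[Monomial]] = {}
    for root in scheme.states:
        count = 0
        for tree in _spanning_trees_to_root(out_edges, scheme.states, root):
            count += 1
            p_na = sum(1 for e in tree if e.depends_on == NA)
            p_asp = sum(1 for e in tree if e.depends_on == ASP)
            mono = monomial([e.symbol for e in tree])
            denominator.setdefault((p_na, p_asp), []).append(mono)
            if root == loaded:
                numerator.setdefault((p_na, p_asp), []).append(mono)
        if cross_check and count != _arborescence_count(scheme, root):
            raise RateLawError(
                f"tree enumeration disagrees with matrix-tree count at {root!r}"
            )

    return RateLaw(
        numerator={k: CoefficientPoly(tuple(v)) for k, v in numerator.items()},
        denominator={k: CoefficientPoly(tuple(v)) for k, v in denominator.items()},
        kcat_symbol=scheme.kcat_symbol,
        asp_on_symbols=scheme.asp_binding_symbols(),
        meta=dict(scheme.meta),
    )


# ---------------------------------------------------------------------------
# numeric oracle and evaluation
# ---------------------------------------------------------------------------

def _stationary_gth(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of rate matrix ``q`` by GTH elimination.

    The Grassmann-Taksar-Heyman algorithm uses no subtractions, so every
    component of the result carries small *relative* error even when
    occupancies span many orders of magnitude — exactly the regime where
    a plain linear solve of the balance equations loses the small
    populations entirely.
    """
    w = q.astype(float).copy()
    n = w.shape[0]
    departure = np.empty(n)
    for k in range(n - 1, 0, -1):
        s = w[k, :k].sum()
        if s <= 0:
            raise RateLawError("singular steady-state system (absorbing state)")
        departure[k] = s
        w[:k, :k] += np.outer(w[:k, k], w[k, :k]) / s
        np.fill_diagonal(w[:k, :k], 0.0)
    p = np.zeros(n)
    p[0] = 1.0
    for k in range(1, n):
        p[k] = np.dot(p[:k], w[:k, k]) / departure[k]
    return p / p.sum()


def steady_state_oracle(scheme: KineticScheme,
                        constants: Mapping[str, float],
                        na: float, asp: float,
                        vmax_scale: float | None = None) -> float:
    """Steady-state rate fraction from the flux-balance equations.

    Solves d p / dt = 0 with populations summing to one, independently of
    the symbolic derivation (direct numeric elimination on the state
    graph's rate matrix), and returns kcat * p(fully loaded) divided by
    ``vmax_scale`` (default: kcat, so that the result is directly
    comparable to :meth:`RateLaw.fraction`).
    """
    for sym, val in constants.items():
        if not val > 0:
            raise RateLawError(f"constant {sym}={val} must be positive")
    states = list(scheme.states)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    q = np.zeros((n, n))
    conc = {NA: na, ASP: asp, None: 1.0}
    for e in scheme.all_edges():
        q[idx[e.source], idx[e.target]] += constants[e.symbol] * conc[e.depends_on]
    p = _stationary_gth(q)
    kcat = constants[scheme.kcat_symbol]
    scale = kcat if vmax_scale is None else vmax_scale
    return kcat * p[idx[scheme.turnover.source]] / scale


def evaluate_rate(rate_law: RateLaw, constants: Mapping[str, float],
                  na, asp, vmax: float = 1.0):
    """v0 = vmax * N/D at molar concentrations (scalar or array)."""
    return vmax * rate_law.fraction(constants, na, asp)


# ---------------------------------------------------------------------------
# apparent parameters and asymptotic limits
# ---------------------------------------------------------------------------

@dataclass
class ApparentExpressions:
    """Symbolic apparent saturation parameters for one varied ligand.

    ``vmax_app`` is the rate reached as the varied concentration grows
    without bound, as a function of the fixed ligand's concentration (in
    units of vmax).  ``km_app`` is the half-saturation concentration of
    the varied ligand; it exists in closed form only when the rate law is
    a degree-1 rational (rectangular hyperbola) in the varied ligand, in
    which case ``saturating`` is True.  Otherwise ``km_app`` is None and
    the raw rational expression is kept in ``rate_expr``.
    """

    varied: str
    vmax_app: sp.Expr
    km_app: sp.Expr | None
    saturating: bool
    rate_expr: sp.Expr

    def vmax_app_fn(self):
        other = ASP_SYM if self.varied == NA else NA_SYM
        return sp.lambdify(other, self.vmax_app.subs(VMAX_SYM, 1), "numpy")

    def km_app_fn(self):
        if self.km_app is None:
            raise RateLawError("no closed-form apparent K_M for this rate law")
        other = ASP_SYM if self.varied == NA else NA_SYM
        return sp.lambdify(other, self.km_app, "numpy")


def apparent_parameter_expressions(rate_law: RateLaw, varied: str,
                                   ) -> ApparentExpressions:
    """Rearranged apparent vmax / K_M expressions for one varied ligand.

    For the canonical scheme, varying aspartate gives

        vmax_app = vmax * a1 Na^2 / (a1 Na^2 + a2 Na + a3)
        K_M_app  = (a4 Na^3 + a5 Na^2 + a6 Na + a7) / (a1 Na^3 + a2 Na^2 + a3 Na)

    and varying sodium gives vmax_app = vmax * Asp / (kcat/k3 + Asp)
    (no closed-form half-saturation: the sodium dependence is cubic).
    """
    if varied not in (NA, ASP):
        raise RateLawError(f"varied ligand must be NA or ASP, got {varied!r}")
    v = NA_SYM if varied == NA else ASP_SYM
    num = sp.Poly(rate_law.numerator_sympy(), v)
    den = sp.Poly(rate_law.denominator_sympy(), v)
    rate_expr = VMAX_SYM * num.as_expr() / den.as_expr()

    d_num, d_den = num.degree(), den.degree()
    lead_ratio = sp.cancel(num.coeff_monomial(v ** d_num)
                           / den.coeff_monomial(v ** d_den))
    vmax_app = VMAX_SYM * (lead_ratio if d_num == d_den else sp.Integer(0))

    saturating = (
        d_num == 1 and d_den == 1
        and num.coeff_monomial(1) == 0
        and den.coeff_monomial(1) != 0
    )
    km_app = None
    if saturating:
        km_app = sp.cancel(den.coeff_monomial(1) / den.coeff_monomial(v))
    return ApparentExpressions(varied=varied, vmax_app=sp.simplify(vmax_app),
                               km_app=km_app, saturating=saturating,
                               rate_expr=rate_expr)


def _ratio_of_extreme_terms(expr: sp.Expr, high: bool) -> sp.Expr:
    """Leading (high) or trailing (low) term ratio of a rational in [Na]."""
    num, den = sp.fraction(sp.cancel(sp.together(expr)))
    pn = sp.Poly(num, NA_SYM)
    pd = sp.Poly(den, NA_SYM)

    def extreme(p):
        degs = [m[0] for m in p.monoms()]
        d = max(degs) if high else min(degs)
        return p.coeff_monomial(NA_SYM ** d) * NA_SYM ** d

    return sp.cancel(extreme(pn) / extreme(pd))


def asymptotic_km(rate_law: RateLaw, regime: str) -> sp.Expr:
    """Leading-order apparent aspartate K_M in the high- or low-[Na] regime.

    ``regime="high_na"`` extracts the ratio of highest [Na]-power terms
    (for the canonical scheme: a4/a1 = kcat/k3, a constant plateau);
    ``regime="low_na"`` the ratio of lowest-power terms (canonical:
    a7/(a3 [Na]), i.e. log-log slope -1 as [Na] -> 0).
    """
    if regime not in ("high_na", "low_na"):
        raise RateLawError(f"unknown regime {regime!r}")
    app = apparent_parameter_expressions(rate_law, ASP)
    if not app.saturating:
        raise RateLawError("rate law has no closed-form apparent aspartate K_M")
    return _ratio_of_extreme_terms(app.km_app, high=(regime == "high_na"))


def check_limit_theorem(scheme: KineticScheme) -> tuple[bool, sp.Expr]:
    """Does lim_{[Na]->oo} K_M_Asp(app) equal kcat over the Asp on-rate?

    Holds for every mechanism in which at least one sodium ion binds
    after aspartate (including random-order sodium branches); fails for
    the aspartate-last mechanism, whose limit retains additional rate
    constants.  Returns the verdict and the symbolic limit.
    """
    law = derive_rate_law(scheme)
    limit = asymptotic_km(law, "high_na")
    kcat = sp.Symbol(law.kcat_symbol, positive=True)
    holds = False
    for on_sym in law.asp_on_symbols:
        target = kcat / sp.Symbol(on_sym, positive=True)
        if sp.simplify(limit - target) == 0:
            holds = True
            break
    return holds, limit
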