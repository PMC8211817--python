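"""State graphs for ion/substrate binding mechanisms of coupled transport.

A transporter cycle is represented as a directed graph over *binding
states* — how many Na+ ions and aspartate molecules are bound — with
rate-constant-labelled edges.  Binding edges are bimolecular (their flux
carries a concentration factor for the ligand being bound, units
M^-1 s^-1); unbinding edges and the single irreversible turnover edge are
unimolecular (s^-1).  The turnover edge closes the cycle from the fully
loaded state back to the apo state and lumps every step of translocation,
internal release and resetting into one composite rate constant (kcat).

The builders in this module cover the mechanisms relevant to a
3 Na+ : 1 aspartate symporter: the four strictly ordered binding
sequences, partial-order (branched) variants where some sodium ions bind
randomly, and arbitrary user-defined lattices.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

NA = "NA"
ASP = "ASP"
LIGANDS = (NA, ASP)

#: maximum ligand stoichiometry of the canonical symporter
MAX_NA = 3
MAX_ASP = 1


class SchemeError(ValueError):
    """Raised when a kinetic scheme violates a structural invariant."""


@dataclass(frozen=True, order=True)
class BindingState:
    """A transporter state identified by its bound-ligand multiset.

    ``site`` is an optional tag distinguishing states whose multisets
    coincide but that are mechanistically distinct — e.g. the two
    single-Na+ intermediates of a random-order branch, where the ion
    occupies different sites.  States with empty tags compare by ligand
    counts alone.
    """

    na: int
    asp: int
    site: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.na <= MAX_NA):
            raise SchemeError(f"Na count {self.na} outside 0..{MAX_NA}")
        if not (0 <= self.asp <= MAX_ASP):
            raise SchemeError(f"Asp count {self.asp} outside 0..{MAX_ASP}")

    @property
    def n_bound(self) -> int:
        return self.na + self.asp

    @property
    def label(self) -> str:
        s = "E" + "Na" * self.na + "Asp" * self.asp
        return f"{s}({self.site})" if self.site else s

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


APO = BindingState(0, 0)
FULL = BindingState(MAX_NA, MAX_ASP)


@dataclass(frozen=True)
class Edge:
    """A single directed transition.

    ``depends_on`` names the ligand whose external concentration
    multiplies the rate ("NA" or "ASP") or is None for unimolecular
    steps.  ``partner`` is the symbol of the paired reverse edge; the
    turnover edge has ``partner=None``.
    """

    source: BindingState
    target: BindingState
    symbol: str
    depends_on: str | None = None
    partner: str | None = None

    def ligand_delta(self) -> tuple[int, int]:
        return (self.target.na - self.source.na, self.target.asp - self.source.asp)


@dataclass
class KineticScheme:
    """A validated binding/turnover state graph.

    ``rate_constants`` maps every edge symbol to a positive numeric value
    or to None for a purely symbolic scheme.  ``meta`` carries builder
    annotations (binding order, whether Na+ binds after aspartate, ...).
    """

    states: tuple[BindingState, ...]
    edges: tuple[Edge, ...]
    turnover: Edge
    rate_constants: dict[str, float | None] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(sorted(set(self.states)))
        self.edges = tuple(self.edges)
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        states = set(self.states)
        if APO not in states:
            raise SchemeError("apo state missing")
        by_symbol: dict[str, Edge] = {}
        for e in self.all_edges():
            if e.source not in states or e.target not in states:
                raise SchemeError(f"edge {e.symbol} references unknown state")
            if e.symbol in by_symbol:
                raise SchemeError(f"duplicate edge symbol {e.symbol!r}")
            by_symbol[e.symbol] = e

        if self.turnover.source != self._loaded_state() or self.turnover.target != APO:
            raise SchemeError(
                "turnover edge must run from the fully loaded state to apo"
            )
        if self.turnover.partner is not None:
            raise SchemeError("turnover edge must be irreversible")

        for e in self.edges:
            dna, dasp = e.ligand_delta()
            if abs(dna) + abs(dasp) != 1:
                raise SchemeError(
                    f"edge {e.symbol} changes more than one ligand ({dna},{dasp})"
                )
            binding = dna + dasp == 1
            if binding:
                expected = NA if dna == 1 else ASP
                if e.depends_on != expected:
                    raise SchemeError(
                        f"binding edge {e.symbol} must depend on [{expected}]"
                    )
            elif e.depends_on is not None:
                raise SchemeError(f"unbinding edge {e.symbol} must be unimolecular")
            if e.partner is None:
                raise SchemeError(f"edge {e.symbol} lacks a reverse partner")
            rev = by_symbol.get(e.partner)
            if rev is None or rev.source != e.target or rev.target != e.source:
                raise SchemeError(f"edge {e.symbol}: partner {e.partner!r} not paired")
            if rev.partner != e.symbol:
                raise SchemeError(f"partner symbols of {e.symbol} are not mutual")

        g = self.graph()
        if not nx.is_strongly_connected(g):
            raise SchemeError("scheme graph (with turnover) is not strongly connected")

        for sym, val in self.rate_constants.items():
            if val is not None and not val > 0:
                raise SchemeError(f"rate constant {sym}={val} must be positive")

    def _loaded_state(self) -> BindingState:
        return max(self.states, key=lambda s: (s.n_bound, s.na))

    # -- views -------------------------------------------------------------

    def all_edges(self) -> tuple[Edge, ...]:
        return self.edges + (self.turnover,)

    def graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.states)
        for e in self.all_edges():
            g.add_edge(e.source, e.target, symbol=e.symbol, depends_on=e.depends_on)
        return g

    @property
    def kcat_symbol(self) -> str:
        return self.turnover.symbol

    def asp_binding_symbols(self) -> tuple[str, ...]:
        """Symbols of all aspartate on-rate edges (usually a single one)."""
        return tuple(
            e.symbol for e in self.edges if e.depends_on == ASP
        )

    def is_numeric(self) -> bool:
        syms = {e.symbol for e in self.all_edges()}
        return all(self.rate_constants.get(s) is not None for s in syms)

    def numeric_constants(self) -> dict[str, float]:
        if not self.is_numeric():
            raise SchemeError("scheme has symbolic (unset) rate constants")
        return {s: float(self.rate_constants[s]) for s in
                (e.symbol for e in self.all_edges())}

    def with_constants(self, constants: Mapping[str, float]) -> "KineticScheme":
        merged = dict(self.rate_constants)
        merged.update(constants)
        return replace(self, rate_constants=merged)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def state_d(s: BindingState) -> dict:
            d = {"asp": s.asp, "na": s.na}
            if s.site:
                d["site"] = s.site
            return d

        def edge_d(e: Edge) -> dict:
            return {
                "depends_on": e.depends_on,
                "from": state_d(e.source),
                "partner": e.partner,
                "symbol": e.symbol,
                "to": state_d(e.target),
                "value": self.rate_constants.get(e.symbol),
            }

        return {
            "edges": [edge_d(e) for e in self.edges],
            "meta": self.meta,
            "states": [state_d(s) for s in self.states],
            "turnover": edge_d(self.turnover),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        def state(sd: dict) -> BindingState:
            return BindingState(sd["na"], sd["asp"], sd.get("site", ""))

        def edge(ed: dict) -> Edge:
            return Edge(state(ed["from"]), state(ed["to"]), ed["symbol"],
                        ed.get("depends_on"), ed.get("partner"))

        constants = {}
        for ed in list(d["edges"]) + [d["turnover"]]:
            constants[ed["symbol"]] = ed.get("value")
        return cls(
            states=tuple(state(sd) for sd in d["states"]),
            edges=tuple(edge(ed) for ed in d["edges"]),
            turnover=edge(d["turnover"]),
            rate_constants=constants,
            meta=dict(d.get("meta", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_constants(symbols: Iterable[str],
                     constants: Mapping[str, float] | None) -> dict[str, float | None]:
    out: dict[str, float | None] = {s: None for s in symbols}
    if constants:
        for sym, val in constants.items():
            if sym not in out:
                raise SchemeError(f"unknown rate-constant symbol {sym!r}")
            if val is not None and not val > 0:
                raise SchemeError(f"rate constant {sym}={val} must be positive")
            out[sym] = None if val is None else float(val)
    return out


def build_ordered_scheme(order: Sequence[str],
                         constants: Mapping[str, float] | None = None,
                         ) -> KineticScheme:
    """Linear chain apo -> ... -> fully loaded for a strict binding order.

    ``order`` lists the four binding events, e.g. ``("NA","NA","ASP","NA")``
    for the mechanism in which two sodium ions bind before aspartate and
    one after.  Forward symbols are k1..k4 in binding order, reverse
    symbols k-1..k-4, and the turnover edge is kcat.
    """
    order = tuple(order)
    if len(order) != MAX_NA + MAX_ASP or order.count(NA) != MAX_NA \
            or order.count(ASP) != MAX_ASP:
        raise SchemeError(
            f"order must contain exactly {MAX_NA} NA and {MAX_ASP} ASP, got {order}"
        )
    states = [APO]
    for lig in order:
        prev = states[-1]
        states.append(BindingState(prev.na + (lig == NA), prev.asp + (lig == ASP)))
    edges = []
    for i, lig in enumerate(order, start=1):
        fwd, rev = f"k{i}", f"k-{i}"
        edges.append(Edge(states[i - 1], states[i], fwd, depends_on=lig, partner=rev))
        edges.append(Edge(states[i], states[i - 1], rev, partner=fwd))
    turnover = Edge(states[-1], APO, "kcat")
    symbols = [e.symbol for e in edges] + ["kcat"]
    asp_pos = order.index(ASP) + 1
    return KineticScheme(
        states=tuple(states),
        edges=tuple(edges),
        turnover=turnover,
        rate_constants=_check_constants(symbols, constants),
        meta={
            "order": list(order),
            "asp_position": asp_pos,
            "na_after_asp": asp_pos < len(order),
        },
    )


def build_canonical_scheme(constants: Mapping[str, float] | None = None,
                           ) -> KineticScheme:
    """The two-Na-then-Asp-then-Na mechanism used throughout the analysis."""
    return build_ordered_scheme((NA, NA, ASP, NA), constants)


def build_partial_order_scheme(
    transitions: Sequence[tuple[BindingState, BindingState, str, str]],
    constants: Mapping[str, float] | None = None,
) -> KineticScheme:
    """Branched scheme from explicit (from, to, fwd_symbol, rev_symbol) steps.

    Each transition must add exactly one ligand (the reverse edge is
    created automatically); the fully loaded state must be reachable from
    apo and an aspartate-binding step must be present.  Passing the
    transitions of a single linear chain reproduces the ordered builder's
    graph.
    """
    states: set[BindingState] = {APO}
    edges: list[Edge] = []
    saw_asp = False
    for src, dst, fwd, rev in transitions:
        dna, dasp = dst.na - src.na, dst.asp - src.asp
        if (dna, dasp) == (1, 0):
            lig = NA
        elif (dna, dasp) == (0, 1):
            lig = ASP
            saw_asp = True
        else:
            raise SchemeError(
                f"transition {src.label}->{dst.label} must bind exactly one ligand"
            )
        states.update((src, dst))
        edges.append(Edge(src, dst, fwd, depends_on=lig, partner=rev))
        edges.append(Edge(dst, src, rev, partner=fwd))
    if not saw_asp:
        raise SchemeError("no aspartate-binding transition supplied")
    loaded = max(states, key=lambda s: (s.n_bound, s.na))
    if (loaded.na, loaded.asp) != (MAX_NA, MAX_ASP):
        raise SchemeError("fully loaded state {3xNA, ASP} missing from transitions")
    fwd_graph = nx.DiGraph((e.source, e.target) for e in edges if e.depends_on)
    if not nx.has_path(fwd_graph, APO, loaded):
        raise SchemeError("fully loaded state unreachable from apo by binding steps")
    turnover = Edge(loaded, APO, "kcat")
    symbols = [e.symbol for e in edges] + ["kcat"]
    return KineticScheme(
        states=tuple(states),
        edges=tuple(edges),
        turnover=turnover,
        rate_constants=_check_constants(symbols, constants),
        meta={"kind": "partial_order"},
    )


def enumerate_ordered_mechanisms(
    constants: Mapping[str, float] | None = None,
) -> list[KineticScheme]:
    """All four strictly ordered 3 Na+ / 1 Asp binding sequences.

    The aspartate molecule can occupy binding position 1, 2, 3 or 4;
    each scheme's ``meta["na_after_asp"]`` records whether at least one
    sodium ion binds after aspartate (true for positions 1-3), the
    condition under which the high-[Na+] limit of the apparent aspartate
    K_M collapses to kcat over the aspartate on-rate.
    """
    schemes = []
    for pos in range(4):
        order = [NA] * 4
        order[pos] = ASP
        schemes.append(build_ordered_scheme(order, constants))
    return schemes


def build_random_first_two_na_scheme(
    constants: Mapping[str, float] | None = None,
) -> KineticScheme:
    """Branched scheme in which the first two sodium ions bind in random order.

    The two single-Na+ intermediates are distinguished by site tags (the
    ion can occupy either of two sites); both branches converge on the
    doubly Na+-loaded state, after which aspartate (k3) and the last
    sodium ion (k4) bind as in the ordered mechanism.  Branch symbols are
    suffixed a/b.
    """
    ena_a = BindingState(1, 0, "a")
    ena_b = BindingState(1, 0, "b")
    enana = BindingState(2, 0)
    enanaasp = BindingState(2, 1)
    transitions = [
        (APO, ena_a, "k1a", "k-1a"),
        (APO, ena_b, "k1b", "k-1b"),
        (ena_a, enana, "k2a", "k-2a"),
        (ena_b, enana, "k2b", "k-2b"),
        (enana, enanaasp, "k3", "k-3"),
        (enanaasp, FULL, "k4", "k-4"),
    ]
    scheme = build_partial_order_scheme(transitions, constants)
    scheme.meta.update({"kind": "random_first_two_na", "na_after_asp": True})
    return scheme
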