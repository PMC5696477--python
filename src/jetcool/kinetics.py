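"""Kinetic trapping during supersonic-jet cooling.

Conversion barriers between conformers fall into three classes:

* low (<= 2 kcal/mol): crossed easily during the expansion — terminal-group
  rotations or beta/epsilon interconversion of extended backbones within the
  same side-chain structural type;
* medium (2-8 kcal/mol): side-chain swing / orientation changes, negligible
  on the cooling timescale;
* high (>= 8 kcal/mol): backbone refolding (folded<->folded of different kind,
  or folded<->extended), frozen out entirely.

Only low barriers carry flux during the rapid cooling, so the pre-expansion
(T_eff, default 450 K) equilibrium populations pool within connected
components of the low-barrier conversion graph. Each component (kinetic
basin) collapses onto its free-energy minimum at the post-expansion reference
temperature (T_ref, default 10 K) — the basin's sink. A sink is predicted
observable when its pooled population exceeds a threshold (default 8%).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .ensemble_io import BarrierRecord
from .structure import StructuralType

__all__ = [
    "LOW_BARRIER_MAX",
    "HIGH_BARRIER_MIN",
    "OBSERVABLE_THRESHOLD",
    "T_EFF_DEFAULT",
    "T_REF_DEFAULT",
    "BasinResult",
    "classify_barrier",
    "predict_barrier_class",
    "build_conversion_graph",
    "pool_populations",
    "observable_conformers",
]

LOW_BARRIER_MAX = 2.0  # kcal/mol, inclusive
HIGH_BARRIER_MIN = 8.0  # kcal/mol, inclusive
OBSERVABLE_THRESHOLD = 8.0  # percent, strict
T_EFF_DEFAULT = 450.0  # K, effective pre-expansion temperature
T_REF_DEFAULT = 10.0  # K, post-expansion reference for sink selection


def classify_barrier(
    dg: float, low_max: float = LOW_BARRIER_MAX, high_min: float = HIGH_BARRIER_MIN
) -> str:
    """Classify a conversion barrier (kcal/mol) as 'low', 'medium' or 'high'.

    Boundaries are inclusive: dg <= low_max is low, dg >= high_min is high.
    """
    if dg < 0:
        raise ValueError(f"barrier must be non-negative, got {dg}")
    if dg <= low_max:
        return "low"
    if dg >= high_min:
        return "high"
    return "medium"


def predict_barrier_class(a: StructuralType, b: StructuralType) -> str:
    """Barrier class predicted from two structural types alone.

    Empirical rules: backbone refolding is high; within the same fold class,
    conversion is low only between conformers of the same side-chain type
    (swing/orientation) — extended backbones may differ (beta<->epsilon) —
    and medium when the side-chain type differs. Explicit computed barriers
    always take precedence over this heuristic.
    """
    for t in (a, b):
        if t.terminus == "U":
            raise ValueError(f"cannot predict a barrier for untyped conformer {t.label}")
    if a.fold != b.fold:
        return "high"
    if a.folded and b.folded and a.backbone != b.backbone:
        return "high"
    if a.side_chain == b.side_chain:
        return "low"
    return "medium"


@dataclass(frozen=True)
class BasinResult:
    """A kinetic basin: a low-barrier connected component and its pooled population."""

    members: frozenset[str]
    sink: str
    pooled_population: float  # percent at T_eff
    observable: bool

    def __post_init__(self) -> None:
        if self.sink not in self.members:
            raise ValueError(f"sink {self.sink!r} is not a basin member")


def build_conversion_graph(
    ids,
    types: dict[str, StructuralType] | None = None,
    barriers: list[BarrierRecord] | None = None,
    low_max: float = LOW_BARRIER_MAX,
    high_min: float = HIGH_BARRIER_MIN,
) -> nx.Graph:
    """Graph whose edges are the low-barrier conformer conversions.

    For every unordered pair, an explicit barrier value (when given) decides
    the class; otherwise the type-based heuristic is consulted. Pairs with
    neither source of information get no edge.
    """
    g = nx.Graph()
    g.add_nodes_from(ids)
    explicit: dict[frozenset, float] = {}
    for rec in barriers or []:
        key = frozenset(rec.pair)
        explicit[key] = min(rec.dg_barrier, explicit.get(key, rec.dg_barrier))

    ids = list(g.nodes)
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            key = frozenset((u, v))
            if key in explicit:
                cls = classify_barrier(explicit[key], low_max, high_min)
            elif types is not None and u in types and v in types:
                try:
                    cls = predict_barrier_class(types[u], types[v])
                except ValueError:
                    continue
            else:
                continue
            if cls == "low":
                g.add_edge(u, v)
    return g


def pool_populations(
    graph: nx.Graph,
    pops_at_teff,
    g_at_tref=None,
    e_rel=None,
    observable_threshold: float = OBSERVABLE_THRESHOLD,
) -> list[BasinResult]:
    """Pool equilibrium populations over the low-barrier connected components.

    ``pops_at_teff`` maps conformer id -> equilibrium population (percent) at
    the effective pre-expansion temperature. ``g_at_tref`` maps id -> relative
    free energy at the low-temperature reference; the basin sink is its argmin
    within each component (ties broken by lower electronic energy via
    ``e_rel``, then lexicographic id). When ``g_at_tref`` is missing entirely,
    ``e_rel`` (or, failing that, the id ordering) decides the sink.

    Basins partition the node set and total population mass is conserved.
    """
    pops = dict(pops_at_teff)
    missing = [n for n in graph.nodes if n not in pops]
    if missing:
        raise KeyError(
            f"no population at T_eff for node(s): {', '.join(map(str, sorted(missing)))}"
        )
    g_ref = dict(g_at_tref) if g_at_tref is not None else {}
    e_ref = dict(e_rel) if e_rel is not None else {}
    inf = float("inf")

    basins = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        sink = min(
            members, key=lambda c: (g_ref.get(c, inf), e_ref.get(c, inf), str(c))
        )
        pooled = float(sum(pops[c] for c in members))
        basins.append(
            BasinResult(
                members=members,
                sink=sink,
                pooled_population=pooled,
                observable=pooled > observable_threshold,
            )
        )
    basins.sort(key=lambda b: -b.pooled_population)
    return basins


def observable_conformers(
    basins: list[BasinResult], threshold: float = OBSERVABLE_THRESHOLD
) -> list[tuple[str, float]]:
    """Sinks whose pooled population exceeds the threshold, descending."""
    out = [
        (b.sink, b.pooled_population)
        for b in basins
        if b.pooled_population > threshold
    ]
    out.sort(key=lambda t: -t[1])
    return out
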