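"""Minimal domain-edit scenarios between sigma70 core patterns.

Core patterns evolve through typed events: loss or gain of an essential
domain anywhere in the pattern, substitution between r4 and r4_2 (a variant
pair), formation of an ECF domain from an adjacent r2 + r4 (or r4_2) pair
(irreversible: ECF is a specialized adaptation, not a reversible fusion), and
gain/loss of a generic accessory token ``AD`` restricted to the pattern
termini (accessory insertions are a late, terminal-only development).

:func:`min_event_path` finds a minimum-total-cost event sequence between two
patterns by best-first (uniform-cost) search over the pattern space, with an
admissible alignment lower bound to keep distant pairs tractable and a
deterministic tie-break on the event-sequence key, so results are stable
across runs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Pattern",
    "EditEvent",
    "EditPath",
    "DEFAULT_COSTS",
    "FAMILY_PATTERNS",
    "DIVERSIFICATION_EDGES",
    "ECF_ORIGIN_EDGES",
    "apply_event",
    "enumerate_events",
    "min_event_path",
    "verify_scenario",
    "build_scenario_graph",
    "graph_to_dot",
    "graph_to_json",
    "family_size_comparison",
]

Pattern = tuple[str, ...]

ESSENTIAL_TOKENS = ("r1_2", "r2", "r3", "r4", "r4_2", "ECF")
AD_TOKEN = "AD"
#: tokens that can be gained at any position (ECF only forms via ecf_formation)
GAINABLE_TOKENS = ("r1_2", "r2", "r3", "r4", "r4_2")

DEFAULT_COSTS: dict[str, float] = {
    "loss": 1.0,
    "gain": 1.0,
    "substitution": 1.0,
    "ecf_formation": 1.0,
    "ad_gain": 1.0,
    "ad_loss": 1.0,
}


@dataclass(frozen=True, order=True, slots=True)
class EditEvent:
    """One architecture-transforming event.

    ``position`` indexes the pattern: the affected token for loss,
    substitution and ecf_formation (which consumes positions ``position`` and
    ``position + 1``), the insertion point for gains.  ``token`` is the token
    gained, lost, or produced by a substitution.  The dataclass ordering is
    the deterministic tie-break key used by the search.
    """

    kind: str
    position: int
    token: str = ""


@dataclass(frozen=True)
class EditPath:
    """A minimal event sequence transforming ``source`` into ``target``."""

    source: Pattern
    target: Pattern
    events: tuple[EditEvent, ...]
    cost: float

    def replay(self) -> Pattern:
        """Apply the events to ``source``; must reproduce ``target``."""
        p = self.source
        for e in self.events:
            p = apply_event(p, e)
        return p


def apply_event(pattern: Sequence[str], event: EditEvent) -> Pattern:
    """Apply one event to a pattern, validating applicability."""
    p = tuple(pattern)
    i = event.position
    if event.kind in ("loss", "ad_loss"):
        if not (0 <= i < len(p)):
            raise ValueError(f"loss position {i} out of range for {p}")
        if event.token and p[i] != event.token:
            raise ValueError(f"token {event.token} not at position {i} of {p}")
        if event.kind == "ad_loss" and p[i] != AD_TOKEN:
            raise ValueError(f"ad_loss at non-AD token {p[i]}")
        return p[:i] + p[i + 1 :]
    if event.kind in ("gain", "ad_gain"):
        if not (0 <= i <= len(p)):
            raise ValueError(f"gain position {i} out of range for {p}")
        token = event.token or (AD_TOKEN if event.kind == "ad_gain" else "")
        if not token:
            raise ValueError("gain requires a token")
        if event.kind == "ad_gain" and i not in (0, len(p)):
            raise ValueError("accessory domains are gained only at the termini")
        return p[:i] + (token,) + p[i:]
    if event.kind == "substitution":
        if not (0 <= i < len(p)):
            raise ValueError(f"substitution position {i} out of range for {p}")
        pair = {p[i], event.token}
        if pair != {"r4", "r4_2"}:
            raise ValueError(f"substitution only between r4 and r4_2, got {pair}")
        return p[:i] + (event.token,) + p[i + 1 :]
    if event.kind == "ecf_formation":
        if not (0 <= i < len(p) - 1):
            raise ValueError(f"ecf_formation needs positions {i},{i+1} in {p}")
        if p[i] != "r2" or p[i + 1] not in ("r4", "r4_2"):
            raise ValueError(
                f"ecf_formation requires adjacent r2 + r4/r4_2, got {p[i]},{p[i+1]}"
            )
        return p[:i] + ("ECF",) + p[i + 2 :]
    raise ValueError(f"unknown event kind {event.kind!r}")


def enumerate_events(pattern: Pattern, max_len: int = 8) -> list[EditEvent]:
    """All events applicable to a pattern, in deterministic (sorted) order.

    Gains are suppressed once the pattern reaches ``max_len`` tokens.
    """
    p = tuple(pattern)
    events: list[EditEvent] = []
    for i, t in enumerate(p):
        events.append(EditEvent("ad_loss" if t == AD_TOKEN else "loss", i, t))
        if t == "r4":
            events.append(EditEvent("substitution", i, "r4_2"))
        elif t == "r4_2":
            events.append(EditEvent("substitution", i, "r4"))
        if t == "r2" and i + 1 < len(p) and p[i + 1] in ("r4", "r4_2"):
            events.append(EditEvent("ecf_formation", i, "ECF"))
    if len(p) < max_len:
        for i in range(len(p) + 1):
            for t in GAINABLE_TOKENS:
                events.append(EditEvent("gain", i, t))
        for i in (0, len(p)):
            events.append(EditEvent("ad_gain", i, AD_TOKEN))
    return sorted(events)


def _alignment_lower_bound(
    source: Pattern, target: Pattern, costs: Mapping[str, float]
) -> float:
    """Admissible lower bound on the event cost from ``source`` to ``target``.

    A weighted alignment where deleting/inserting a token costs its loss/gain
    cost, aligning r4 to r4_2 costs the substitution, aligning an adjacent
    source (r2, r4/r4_2) pair to a target ECF costs the ecf_formation, and
    any other mismatch costs delete + insert.  It relaxes the terminal-only
    constraint on AD gains and the adjacency requirement of ecf_formation
    only in the safe direction, so it never exceeds the true cost.
    """

    def del_cost(t: str) -> float:
        return costs["ad_loss"] if t == AD_TOKEN else costs["loss"]

    def ins_cost(t: str) -> float:
        return costs["ad_gain"] if t == AD_TOKEN else costs["gain"]

    n, m = len(source), len(target)
    INF = float("inf")
    dp = [[INF] * (m + 1) for _ in range(n + 1)]
    dp[n][m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            best = INF
            if i < n:
                best = min(best, dp[i + 1][j] + del_cost(source[i]))
            if j < m:
                best = min(best, dp[i][j + 1] + ins_cost(target[j]))
            if i < n and j < m:
                s, t = source[i], target[j]
                if s == t:
                    sub = 0.0
                elif {s, t} == {"r4", "r4_2"}:
                    sub = costs["substitution"]
                else:
                    sub = del_cost(s) + ins_cost(t)
                best = min(best, dp[i + 1][j + 1] + sub)
            if (
                i + 1 < n
                and j < m
                and source[i] == "r2"
                and source[i + 1] in ("r4", "r4_2")
                and target[j] == "ECF"
            ):
                best = min(best, dp[i + 2][j + 1] + costs["ecf_formation"])
            dp[i][j] = best
    return dp[0][0]


def min_event_path(
    source: Sequence[str],
    target: Sequence[str],
    costs: Mapping[str, float] | None = None,
    max_len: int = 8,
) -> EditPath:
    """Minimum-total-cost event sequence from ``source`` to ``target``.

    Best-first search over the pattern space; among minimal-cost paths the
    one with the smallest event-sequence key is returned, making the result
    deterministic.  Raises ``ValueError`` if the target is unreachable under
    the configured event set / length bound.
    """
    src, tgt = tuple(source), tuple(target)
    if max(len(src), len(tgt)) > max_len:
        raise ValueError(f"patterns longer than the configured bound {max_len}")
    cost_table = dict(DEFAULT_COSTS)
    if costs:
        cost_table.update(costs)
    if src == tgt:
        return EditPath(src, tgt, (), 0.0)

    def h(p: Pattern) -> float:
        return _alignment_lower_bound(p, tgt, cost_table)

    # heap entries: (g + h, event key sequence, g, pattern, events)
    start_key: tuple = ()
    heap: list[tuple[float, tuple, float, Pattern, tuple[EditEvent, ...]]] = [
        (h(src), start_key, 0.0, src, ())
    ]
    best_seen: dict[Pattern, tuple[float, tuple]] = {src: (0.0, start_key)}
    while heap:
        f, key, g, pattern, events = heapq.heappop(heap)
        if pattern == tgt:
            return EditPath(src, tgt, events, g)
        if best_seen.get(pattern, (float("inf"), ())) < (g, key):
            continue
        for event in enumerate_events(pattern, max_len=max_len):
            try:
                nxt = apply_event(pattern, event)
            except ValueError:
                continue
            ng = g + cost_table[event.kind]
            nkey = key + ((event.kind, event.position, event.token),)
            prev = best_seen.get(nxt)
            if prev is None or (ng, nkey) < prev:
                best_seen[nxt] = (ng, nkey)
                heapq.heappush(
                    heap, (ng + h(nxt), nkey, ng, nxt, events + (event,))
                )
    raise ValueError(f"{tgt} unreachable from {src} under the configured events")


# ---------------------------------------------------------------------------
# the published diversification scenario

#: Core patterns of the 14 main families, with the generic ``AD`` token
#: standing for the accessory domain of the .3 families.
FAMILY_PATTERNS: dict[str, Pattern] = {
    "A.1": ("r1_2", "r2", "r3", "r4"),
    "A.5": ("r1_2", "r3", "r2", "r3", "r4"),
    "B.1": ("r1_2", "r2", "r4"),
    "C.1": ("r2", "r3", "r4"),
    "D.1": ("r2", "r3", "r4_2"),
    "E.1": ("r2", "r4"),
    "F.1": ("r2", "r4_2"),
    "F.3": ("r2", "r4_2", AD_TOKEN),
    "H.1": ("r2",),
    "H.3": ("r2", AD_TOKEN),
    "J.1": ("r4",),
    "K.1": ("r4_2",),
    "K.3": ("r4_2", AD_TOKEN),
    "L.1": ("ECF",),
}

#: Diversification of the ancestral A.1 family: every edge is a single event
#: (gain of a second r3 -> A.5; losses of r3 / r1_2 -> B.1 / C.1; r4 -> r4_2
#: substitutions; losses of r2 or r4; terminal AD acquisitions).  D.1 is
#: reachable both from C.1 (substitution) and from F.1 (r3 insertion); both
#: alternatives are retained.
DIVERSIFICATION_EDGES: list[tuple[str, str]] = [
    ("A.1", "A.5"),
    ("A.1", "B.1"),
    ("A.1", "C.1"),
    ("C.1", "D.1"),
    ("C.1", "E.1"),
    ("E.1", "F.1"),
    ("E.1", "H.1"),
    ("E.1", "J.1"),
    ("F.1", "K.1"),
    ("F.1", "F.3"),
    ("F.1", "D.1"),
    ("H.1", "H.3"),
    ("K.1", "K.3"),
]

#: Candidate origins of the ECF-only L.1 family: modification of adjacent
#: r2 + r4(/r4_2) in E.1/F.1 (one event), or domain loss followed by the same
#: modification from B.1/C.1/D.1 (two events).
ECF_ORIGIN_EDGES: list[tuple[str, str]] = [
    ("B.1", "L.1"),
    ("C.1", "L.1"),
    ("D.1", "L.1"),
    ("E.1", "L.1"),
    ("F.1", "L.1"),
]


def _pattern_of(family: str, patterns: Mapping[str, Pattern]) -> Pattern:
    try:
        return patterns[family]
    except KeyError:
        raise KeyError(f"family {family!r} has no registered core pattern") from None


def verify_scenario(
    edges: Iterable[tuple[str, str]],
    patterns: Mapping[str, Pattern] | None = None,
    costs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Minimal event cost of each scenario edge.

    One row per (source family, target family) with the minimal cost, whether
    it is a single event, and the event sequence found.
    """
    pats = FAMILY_PATTERNS if patterns is None else patterns
    rows = []
    for a, b in edges:
        path = min_event_path(_pattern_of(a, pats), _pattern_of(b, pats), costs=costs)
        rows.append(
            {
                "source": a,
                "target": b,
                "cost": path.cost,
                "single_event": path.cost == 1,
                "events": ";".join(
                    f"{e.kind}@{e.position}" + (f":{e.token}" if e.token else "")
                    for e in path.events
                ),
            }
        )
    return pd.DataFrame(rows, columns=["source", "target", "cost", "single_event", "events"])


def build_scenario_graph(
    edges: Iterable[tuple[str, str]] | None = None,
    root: str = "A.1",
    patterns: Mapping[str, Pattern] | None = None,
    costs: Mapping[str, float] | None = None,
) -> nx.DiGraph:
    """Scenario graph: families as nodes, minimal edit paths as edges.

    Checks that every node is reachable from ``root``.
    """
    pats = FAMILY_PATTERNS if patterns is None else patterns
    edge_list = list(edges) if edges is not None else list(DIVERSIFICATION_EDGES)
    g = nx.DiGraph(root=root)
    for fam in {root} | {x for e in edge_list for x in e}:
        g.add_node(fam, pattern="*".join(_pattern_of(fam, pats)))
    for a, b in edge_list:
        path = min_event_path(_pattern_of(a, pats), _pattern_of(b, pats), costs=costs)
        g.add_edge(
            a,
            b,
            cost=path.cost,
            events=[f"{e.kind}@{e.position}:{e.token}" for e in path.events],
        )
    unreachable = set(g.nodes) - ({root} | nx.descendants(g, root))
    if unreachable:
        raise ValueError(f"nodes unreachable from root {root}: {sorted(unreachable)}")
    return g


def graph_to_dot(g: nx.DiGraph) -> str:
    """Render a scenario graph in DOT format."""
    lines = ["digraph scenario {"]
    for node, data in sorted(g.nodes(data=True)):
        label = f"{node}\\n{data.get('pattern', '')}"
        lines.append(f'  "{node}" [label="{label}"];')
    for a, b, data in sorted(g.edges(data=True)):
        lines.append(f'  "{a}" -> "{b}" [label="{data.get("cost", "")}"];')
    lines.append("}")
    return "\n".join(lines)


def graph_to_json(g: nx.DiGraph) -> dict:
    """Node-link JSON representation of a scenario graph."""
    return nx.node_link_data(g, edges="edges")


def family_size_comparison(
    metrics: pd.DataFrame,
    family_a: str,
    family_b: str,
    alpha: float = 0.05,
):
    """Compare two families on protein length, essential span and coverage.

    ``metrics`` needs columns ``family``, ``protein_length``,
    ``essential_span_sum`` and ``coverage``.  Returns a dict metric ->
    :class:`sig70arch.cohort.GroupComparison`; families with fewer than 3
    proteins yield a warning string instead of a test.
    """
    from .cohort import compare_two_groups

    out: dict[str, object] = {}
    a = metrics[metrics["family"] == family_a]
    b = metrics[metrics["family"] == family_b]
    if len(a) < 3 or len(b) < 3:
        return {
            "warning": f"insufficient data: {family_a} n={len(a)}, {family_b} n={len(b)}"
        }
    for col in ("protein_length", "essential_span_sum", "coverage"):
        out[col] = compare_two_groups(
            a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float), alpha=alpha
        )
    return out
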