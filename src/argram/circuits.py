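"""Compile grammars to neural-circuit graphs and DOT renderings.

The mapping is one-to-one: each nonterminal becomes a soma; each terminal
becomes a port (dendritic input for sensors, axonal output for
actuators); each alternate contributes one synapse from the head's soma
to every symbol of the alternate, labeled with the alternate's
probability.  A rule that recurses directly on its own head yields an
autapse (a synapse from a soma onto itself); a synapse that closes a
longer cycle is flagged recurrent but categorizes as regular.  Quoted
terminals are projection ports — the describing circuit projecting onto
the described one — and render as dashed edges.

Edges with probability below .5 are marked inhibitory in metadata (low
probability of triggering); no further biophysics is modeled — the
circuits are structural.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .grammar import Grammar, SymbolKind, format_weight

__all__ = [
    "CircuitGraph",
    "circuit_graph",
    "circuit_stats",
    "grammar_to_dot",
    "circuit_to_dot",
    "circuit_to_json",
]

_PORT_KIND = {
    SymbolKind.SENSOR: "sensor_port",
    SymbolKind.ACTUATOR: "actuator_port",
    SymbolKind.QUOTED: "projection_port",
    SymbolKind.UNQUOTED: "projection_port",
    SymbolKind.WEIGHT_LITERAL: "projection_port",
}


@dataclass
class CircuitGraph:
    """Somata, terminal ports, and weighted synapse edges.

    ``graph`` is a :class:`networkx.MultiDiGraph`; soma nodes carry
    ``kind="soma"``, port nodes ``kind`` in ``{sensor_port,
    actuator_port, projection_port}``.  Edges carry ``weight``,
    ``alternate`` (index), ``autapse``, ``recurrent``, ``inhibitory`` and
    ``projection`` flags.
    """

    graph: nx.MultiDiGraph
    start: str

    @property
    def somata(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "soma"]

    def ports(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]


def circuit_graph(g: Grammar) -> CircuitGraph:
    """Compile a grammar to its neural circuit (bijective on nonterminals:
    one soma per rule head)."""
    graph = nx.MultiDiGraph()
    for rule in g.rules:
        graph.add_node(rule.head.name, kind="soma", label=rule.head.name)

    def port_id(name: str, kind: str) -> str:
        node = f"port:{name}"
        if node not in graph:
            graph.add_node(node, kind=kind, label=name)
        return node

    for rule in g.rules:
        source = rule.head.name
        for alt_index, alt in enumerate(rule.alternates):
            for sym in alt.symbols:
                if sym.kind is SymbolKind.NONTERMINAL:
                    target = sym.name
                else:
                    target = port_id(sym.name, _PORT_KIND[sym.kind])
                graph.add_edge(
                    source,
                    target,
                    weight=alt.weight,
                    alternate=alt_index,
                    autapse=(source == target),
                    recurrent=False,
                    inhibitory=alt.weight < 0.5 and len(rule.alternates) > 1,
                    projection=sym.kind
                    in (SymbolKind.QUOTED, SymbolKind.UNQUOTED, SymbolKind.WEIGHT_LITERAL),
                )

    _flag_recurrent_edges(graph, g)
    return CircuitGraph(graph=graph, start=g.start.name)


def _flag_recurrent_edges(graph: nx.MultiDiGraph, g: Grammar) -> None:
    """Mark back edges of a depth-first traversal from the start soma as
    recurrent (an autapse is the degenerate one-soma case)."""
    soma_names = [r.head.name for r in g.rules]
    color = {n: "white" for n in soma_names}

    def dfs(root: str) -> None:
        stack: list[tuple[str, list[str], int]] = []
        succ = lambda n: [
            v for _, v in graph.out_edges(n) if graph.nodes[v]["kind"] == "soma"
        ]
        color[root] = "gray"
        stack.append((root, _ordered_unique(succ(root)), 0))
        while stack:
            node, children, i = stack.pop()
            if i < len(children):
                stack.append((node, children, i + 1))
                child = children[i]
                if color[child] == "gray":
                    for key in graph[node].get(child, {}):
                        graph.edges[node, child, key]["recurrent"] = True
                elif color[child] == "white":
                    color[child] = "gray"
                    stack.append((child, _ordered_unique(succ(child)), 0))
            else:
                color[node] = "black"

    for name in soma_names:
        if color[name] == "white":
            dfs(name)


def _ordered_unique(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def circuit_stats(c: CircuitGraph) -> dict[str, int]:
    """Structural counts: somata, synapses, autapses, recurrent (regular,
    non-autapse) synapses, and sensor/actuator port counts."""
    autapses = 0
    recurrent = 0
    for u, v, d in c.graph.edges(data=True):
        if d["autapse"]:
            autapses += 1
        elif d["recurrent"]:
            recurrent += 1
    return {
        "somata": len(c.somata),
        "synapses": c.graph.number_of_edges(),
        "autapses": autapses,
        "recurrent": recurrent,
        "sensor_ports": len(c.ports("sensor_port")),
        "actuator_ports": len(c.ports("actuator_port")),
    }


# ---------------------------------------------------------------------------
# DOT emission
# ---------------------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def circuit_to_dot(c: CircuitGraph) -> str:
    """DOT text for the neural circuit: somata as inverted triangles,
    sensor/actuator ports as boxes, projections dashed.  Never truncated —
    the circuit, unlike the schema, carries recursion faithfully as
    recurrent edges."""
    lines = ["digraph circuit {", "  rankdir=TB;"]
    shape = {
        "soma": "invtriangle",
        "sensor_port": "box",
        "actuator_port": "box",
        "projection_port": "box",
    }
    for node, data in c.graph.nodes(data=True):
        attrs = [
            f"label={_dot_escape(data['label'])}",
            f"shape={shape[data['kind']]}",
            f"kind={_dot_escape(data['kind'])}",
        ]
        if data["kind"] != "soma":
            attrs.append("style=rounded")
        lines.append(f"  {_dot_escape(node)} [{', '.join(attrs)}];")
    for u, v, data in c.graph.edges(data=True):
        attrs = [f"label={_dot_escape(format_weight(data['weight']))}"]
        if data["projection"]:
            attrs.append("style=dashed")
        if data["recurrent"] or data["autapse"]:
            attrs.append("constraint=false")
        if data["inhibitory"]:
            attrs.append("color=gray")
        lines.append(f"  {_dot_escape(u)} -> {_dot_escape(v)} [{', '.join(attrs)}];")
    lines.append("}")
    return "\n".join(lines)


def grammar_to_dot(g: Grammar, depth: int = 2) -> str:
    """DOT text for the grammatical schema: the derivation tree with every
    alternate shown, recursion truncated once a nonterminal has been
    re-entered ``depth`` times on a path (depth 0 renders the start soma
    only).  Matches the figures' convention of cutting recursive schemas
    for clarity."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    lines = ["digraph schema {", "  rankdir=TB;"]
    counter = [0]

    def fresh(label: str, shape: str) -> str:
        node = f"n{counter[0]}"
        counter[0] += 1
        lines.append(
            f"  {_dot_escape(node)} [label={_dot_escape(label)}, shape={shape}];"
        )
        return node

    rule_map = g.rule_map

    def expand(name: str, counts: dict[str, int]) -> str:
        node = fresh(name, "ellipse")
        if counts.get(name, 0) >= depth:
            return node
        counts = dict(counts)
        counts[name] = counts.get(name, 0) + 1
        rule = rule_map[name]
        multi = len(rule.alternates) > 1
        for alt in rule.alternates:
            for sym in alt.symbols:
                if sym.kind is SymbolKind.NONTERMINAL:
                    child = expand(sym.name, counts)
                else:
                    child = fresh(sym.name, "box")
                label = format_weight(alt.weight) if multi else ""
                attr = f" [label={_dot_escape(label)}]" if label else ""
                lines.append(f"  {_dot_escape(node)} -> {_dot_escape(child)}{attr};")
        return node

    start = g.start.name
    if depth == 0:
        fresh(start, "ellipse")
    else:
        expand(start, {})
    lines.append("}")
    return "\n".join(lines)


def circuit_to_json(c: CircuitGraph) -> dict:
    """JSON-ready ``{nodes: [...], edges: [...]}`` graph export."""
    return {
        "nodes": [
            {"id": n, **{k: v for k, v in d.items()}}
            for n, d in c.graph.nodes(data=True)
        ],
        "edges": [
            {"source": u, "target": v, **{k: v2 for k, v2 in d.items()}}
            for u, v, d in c.graph.edges(data=True)
        ],
    }
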