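"""Adverse-outcome-pathway graph: taxonomy, validation and reachability.

The pathway is a directed acyclic graph whose nodes are a single dose root,
molecular initiating events (MIE), biomarkers (BM), acute- and chronic-phase
key events (KE) and a single adverse outcome (AO).  Acute-phase nodes respond
to every exposure; chronic-phase nodes respond only after a donor-specific
number of exposure repetitions.  All downstream modules take their parent
sets and topological order from this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx

from .errors import CycleError, RoleViolationError, UnknownNodeError

DOSE_NAME_DEFAULT = "DOSE"


class Role(str, Enum):
    DOSE = "DOSE"
    MIE = "MIE"
    ACUTE_KE = "ACUTE_KE"
    CHRONIC_KE = "CHRONIC_KE"
    BM = "BM"
    AO = "AO"


class Phase(str, Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"
    NONE = "none"


#: phase each role must carry
_ROLE_PHASE = {
    Role.DOSE: {Phase.NONE},
    Role.MIE: {Phase.ACUTE},
    Role.BM: {Phase.ACUTE},
    Role.ACUTE_KE: {Phase.ACUTE},
    Role.CHRONIC_KE: {Phase.CHRONIC},
    Role.AO: {Phase.CHRONIC},
}


@dataclass(frozen=True)
class NodeSpec:
    """One pathway node: a name, a role and an elicitation phase."""

    name: str
    role: Role
    phase: Phase

    @classmethod
    def make(cls, name: str, role: str | Role, phase: str | Phase) -> "NodeSpec":
        return cls(name=name, role=Role(role), phase=Phase(phase))


class AOPGraph:
    """Validated DAG of an adverse outcome pathway.

    Parameters
    ----------
    nodes
        Node specifications; order is preserved and fixes topological
        tie-breaking.
    edges
        ``(parent, child)`` pairs; order is preserved and fixes the order of
        each node's parent list.
    """

    def __init__(self, nodes: list[NodeSpec], edges: list[tuple[str, str]]):
        self.nodes = list(nodes)
        self.edges = [(str(p), str(c)) for p, c in edges]
        self._spec = {n.name: n for n in self.nodes}
        if len(self._spec) != len(self.nodes):
            raise RoleViolationError("duplicate node names")
        self._validate()
        self._g = nx.DiGraph()
        self._g.add_nodes_from(n.name for n in self.nodes)
        self._g.add_edges_from(self.edges)

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        names = set(self._spec)
        for p, c in self.edges:
            if p not in names or c not in names:
                raise UnknownNodeError(f"edge ({p}, {c}) references unknown node")
        for n in self.nodes:
            if n.phase not in _ROLE_PHASE[n.role]:
                raise RoleViolationError(
                    f"node {n.name}: role {n.role.value} cannot have phase {n.phase.value}"
                )
        dose = [n for n in self.nodes if n.role is Role.DOSE]
        ao = [n for n in self.nodes if n.role is Role.AO]
        if len(dose) != 1:
            raise RoleViolationError("exactly one DOSE node required")
        if len(ao) != 1:
            raise RoleViolationError("exactly one AO node required")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError("pathway graph contains a cycle")
        if g.in_degree(dose[0].name) != 0:
            raise RoleViolationError("DOSE must have no parents")
        if g.out_degree(ao[0].name) != 0:
            raise RoleViolationError("AO must have no children")
        reachable = nx.descendants(g, dose[0].name) | {dose[0].name}
        missing = names - reachable
        if missing:
            raise RoleViolationError(
                f"nodes not reachable from DOSE: {sorted(missing)}"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def dose_node(self) -> str:
        return next(n.name for n in self.nodes if n.role is Role.DOSE)

    @property
    def ao_node(self) -> str:
        return next(n.name for n in self.nodes if n.role is Role.AO)

    @property
    def biology_nodes(self) -> list[str]:
        """All nodes except the dose root, in input order."""
        return [n.name for n in self.nodes if n.role is not Role.DOSE]

    def spec(self, node: str) -> NodeSpec:
        try:
            return self._spec[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    def phase(self, node: str) -> Phase:
        return self.spec(node).phase

    def acute_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.phase is Phase.ACUTE]

    def chronic_nodes(self) -> list[str]:
        return [n.name for n in self.nodes if n.phase is Phase.CHRONIC]

    def parents(self, node: str) -> list[str]:
        """Parents of ``node`` in input edge order (deterministic)."""
        self.spec(node)
        return [p for p, c in self.edges if c == node]

    def biology_parents(self, node: str) -> list[str]:
        """Parents excluding the dose root."""
        dose = self.dose_node
        return [p for p in self.parents(node) if p != dose]

    def children(self, node: str) -> list[str]:
        self.spec(node)
        return [c for p, c in self.edges if p == node]

    def topological_order(self, include_dose: bool = True) -> list[str]:
        """Topological order, stable under the input node order."""
        priority = {n.name: i for i, n in enumerate(self.nodes)}
        order = list(
            nx.lexicographical_topological_sort(self._g, key=priority.get)
        )
        if not include_dose:
            order = [v for v in order if v != self.dose_node]
        return order

    # -- reachability -------------------------------------------------------
    def reachable_to_ao(
        self, active_edges: list[tuple[str, str]] | None = None
    ) -> set[str]:
        """Biology nodes with at least one directed path to AO.

        Only ``active_edges`` (a subset of the graph's edges) may be used;
        AO itself is always returned (it reaches itself by the empty path).
        """
        edges = self.edges if active_edges is None else list(active_edges)
        known = set(self._g.edges)
        for e in edges:
            if tuple(e) not in known:
                raise UnknownNodeError(f"edge {e} not in graph")
        sub = nx.DiGraph()
        sub.add_nodes_from(self._spec)
        sub.add_edges_from(edges)
        hits = nx.ancestors(sub, self.ao_node) | {self.ao_node}
        return hits - {self.dose_node}

    def lag_to_ao(self, node: str) -> int:
        """Shortest directed path length from ``node`` to AO."""
        self.spec(node)
        return nx.shortest_path_length(self._g, node, self.ao_node)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"name": n.name, "role": n.role.value, "phase": n.phase.value}
                for n in self.nodes
            ],
            "edges": [list(e) for e in self.edges],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "AOPGraph":
        nodes = [
            NodeSpec.make(d["name"], d["role"], d["phase"])
            for d in payload["nodes"]
        ]
        edges = [tuple(e) for e in payload["edges"]]
        return cls(nodes, edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AOPGraph)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"AOPGraph({len(self.biology_nodes)} biology nodes, {len(self.edges)} edges)"


def load_graph(source: str | Path | dict) -> AOPGraph:
    """Load and validate a graph from a JSON file path or a dict."""
    if isinstance(source, dict):
        return AOPGraph.from_dict(source)
    return AOPGraph.from_dict(json.loads(Path(source).read_text()))


def canonical_graph() -> AOPGraph:
    """The 20-node hypothetical pathway (19 biology nodes + dose root).

    Two MIEs produce receptor ligands BM1..BM4; the receptor KE1 triggers a
    signalling cascade BM5→BM6→BM7→BM8 whose product drives the chronic
    transduction product KE2 and the acute product KE3; chronic key events
    KE4..KE7 feed KE8 which elicits the adverse outcome.  This yields lag 1
    from KE8 to AO, lag 2 from KE4..KE7 and lag 3 from KE2/KE3.
    """
    nodes = [
        NodeSpec.make(DOSE_NAME_DEFAULT, Role.DOSE, Phase.NONE),
        NodeSpec.make("MIE1", Role.MIE, Phase.ACUTE),
        NodeSpec.make("MIE2", Role.MIE, Phase.ACUTE),
        *[NodeSpec.make(f"BM{i}", Role.BM, Phase.ACUTE) for i in range(1, 9)],
        NodeSpec.make("KE1", Role.ACUTE_KE, Phase.ACUTE),
        NodeSpec.make("KE2", Role.CHRONIC_KE, Phase.CHRONIC),
        NodeSpec.make("KE3", Role.ACUTE_KE, Phase.ACUTE),
        *[NodeSpec.make(f"KE{i}", Role.CHRONIC_KE, Phase.CHRONIC) for i in range(4, 9)],
        NodeSpec.make("AO", Role.AO, Phase.CHRONIC),
    ]
    edges = [
        (DOSE_NAME_DEFAULT, "MIE1"),
        (DOSE_NAME_DEFAULT, "MIE2"),
        ("MIE1", "BM1"),
        ("MIE1", "BM2"),
        ("MIE2", "BM3"),
        ("MIE2", "BM4"),
        ("BM1", "KE1"),
        ("BM2", "KE1"),
        ("BM3", "KE1"),
        ("BM4", "KE1"),
        ("KE1", "BM5"),
        ("BM5", "BM6"),
        ("BM6", "BM7"),
        ("BM7", "BM8"),
        ("BM8", "KE2"),
        ("BM8", "KE3"),
        ("KE2", "KE4"),
        ("KE2", "KE5"),
        ("KE2", "KE6"),
        ("KE3", "KE7"),
        ("KE4", "KE8"),
        ("KE5", "KE8"),
        ("KE6", "KE8"),
        ("KE7", "KE8"),
        ("KE8", "AO"),
    ]
    return AOPGraph(nodes, edges)


def mini_graph() -> AOPGraph:
    """A 5-biology-node chain used for fast tests and the tiny fixtures."""
    nodes = [
        NodeSpec.make(DOSE_NAME_DEFAULT, Role.DOSE, Phase.NONE),
        NodeSpec.make("MIE1", Role.MIE, Phase.ACUTE),
        NodeSpec.make("BM1", Role.BM, Phase.ACUTE),
        NodeSpec.make("KE1", Role.ACUTE_KE, Phase.ACUTE),
        NodeSpec.make("KE8", Role.CHRONIC_KE, Phase.CHRONIC),
        NodeSpec.make("AO", Role.AO, Phase.CHRONIC),
    ]
    edges = [
        (DOSE_NAME_DEFAULT, "MIE1"),
        ("MIE1", "BM1"),
        ("BM1", "KE1"),
        ("KE1", "KE8"),
        ("KE8", "AO"),
    ]
    return AOPGraph(nodes, edges)
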