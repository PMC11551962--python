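"""Graph data model for free-energy difference networks.

Two network modes are supported:

* ``complex`` mode — nodes are receptor–ligand complexes; RBFE edges join
  complexes sharing a receptor, RHFE edges join complexes sharing a ligand.
  Solving such a network (with at least one absolute anchor) yields standard
  binding free energies on both receptors simultaneously.
* ``selectivity`` mode — nodes are per-ligand binding selectivity free
  energies for one ordered receptor pair; RSFE (receptor swapping) edges
  constrain their differences.  Solving yields BSFEs from swap data plus one
  reference BSFE.

Every edge is directed with the convention ``value = x(head) - x(tail)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Tuple, Union

import networkx as nx

from .thermo import Measurement

__all__ = [
    "EdgeKind",
    "NetworkMode",
    "ComplexNode",
    "SelectivityNode",
    "Node",
    "Edge",
    "Anchor",
    "Finding",
    "Network",
    "NetworkStructureError",
]


class NetworkStructureError(ValueError):
    """The requested edge or anchor violates the network's structure."""


class EdgeKind(str, Enum):
    RBFE = "RBFE"
    RHFE = "RHFE"
    RSFE = "RSFE"


class NetworkMode(str, Enum):
    COMPLEX = "complex"
    SELECTIVITY = "selectivity"


@dataclass(frozen=True)
class ComplexNode:
    """Identity of a receptor–ligand complex."""

    receptor_id: str
    ligand_id: str

    def __str__(self) -> str:
        return f"{self.receptor_id}·{self.ligand_id}"


@dataclass(frozen=True)
class SelectivityNode:
    """A ligand's BSFE between an ordered receptor pair (from -> to)."""

    ligand_id: str
    receptor_from: str
    receptor_to: str

    def __post_init__(self) -> None:
        if self.receptor_from == self.receptor_to:
            raise NetworkStructureError(
                f"selectivity node needs two distinct receptors, got "
                f"{self.receptor_from!r} twice"
            )

    def __str__(self) -> str:
        return f"{self.ligand_id}[{self.receptor_from}→{self.receptor_to}]"


Node = Union[ComplexNode, SelectivityNode]


@dataclass(frozen=True)
class Edge:
    """A directed free-energy difference: ``value = x(head) - x(tail)``."""

    kind: EdgeKind
    tail: Node
    head: Node
    measurement: Measurement

    def __post_init__(self) -> None:
        if self.tail == self.head:
            raise NetworkStructureError(f"self-edge at node {self.tail}")


@dataclass(frozen=True)
class Anchor:
    """A node whose value sets the absolute scale of its component."""

    node: Node
    value: Measurement


@dataclass(frozen=True)
class Finding:
    """A structural validation finding. ``level`` is 'error' or 'warning'."""

    level: str
    code: str
    message: str


class Network:
    """Nodes, directed difference edges, and anchors — the solver's input.

    Nodes are created implicitly by the edge- and anchor-adding methods.
    Parallel edges (replicates, forward/reverse runs) are allowed and all
    enter the solver objective; they are never pre-averaged.
    """

    def __init__(
        self,
        mode: Union[NetworkMode, str] = NetworkMode.COMPLEX,
        receptor_pair: Optional[Tuple[str, str]] = None,
    ) -> None:
        self.mode = NetworkMode(mode)
        self.edges: List[Edge] = []
        self.anchors: List[Anchor] = []
        self._nodes: dict[Node, None] = {}  # insertion-ordered set
        if self.mode is NetworkMode.SELECTIVITY:
            if receptor_pair is None:
                raise NetworkStructureError(
                    "selectivity mode requires an ordered receptor_pair"
                )
            if receptor_pair[0] == receptor_pair[1]:
                raise NetworkStructureError(
                    "receptor_pair must name two distinct receptors"
                )
        self.receptor_pair = receptor_pair

    # -- node/edge construction -------------------------------------------

    @property
    def nodes(self) -> List[Node]:
        return list(self._nodes)

    def _register(self, *nodes: Node) -> None:
        for n in nodes:
            self._nodes.setdefault(n, None)

    def _require_mode(self, mode: NetworkMode, what: str) -> None:
        if self.mode is not mode:
            raise NetworkStructureError(
                f"{what} edges require a {mode.value}-mode network "
                f"(this network is {self.mode.value}-mode)"
            )

    def add_node(self, node: Node) -> Node:
        self._check_node_mode(node)
        self._register(node)
        return node

    def _check_node_mode(self, node: Node) -> None:
        if self.mode is NetworkMode.COMPLEX and not isinstance(node, ComplexNode):
            raise NetworkStructureError(f"complex-mode network got {node!r}")
        if self.mode is NetworkMode.SELECTIVITY:
            if not isinstance(node, SelectivityNode):
                raise NetworkStructureError(f"selectivity-mode network got {node!r}")
            if (node.receptor_from, node.receptor_to) != self.receptor_pair:
                raise NetworkStructureError(
                    f"node {node} does not match the network's receptor pair "
                    f"{self.receptor_pair}"
                )

    def add_edge(self, edge: Edge) -> Edge:
        """Add a pre-built edge after mode/endpoint checks."""
        self._check_node_mode(edge.tail)
        self._check_node_mode(edge.head)
        if edge.kind is EdgeKind.RBFE:
            if edge.tail.receptor_id != edge.head.receptor_id:  # type: ignore[union-attr]
                raise NetworkStructureError(
                    f"RBFE edge must stay on one receptor: {edge.tail} -> {edge.head}"
                )
        elif edge.kind is EdgeKind.RHFE:
            if edge.tail.ligand_id != edge.head.ligand_id:  # type: ignore[union-attr]
                raise NetworkStructureError(
                    f"RHFE edge must keep the ligand fixed: {edge.tail} -> {edge.head}"
                )
        elif edge.kind is EdgeKind.RSFE:
            if self.mode is not NetworkMode.SELECTIVITY:
                raise NetworkStructureError("RSFE edges belong to selectivity mode")
        self._register(edge.tail, edge.head)
        self.edges.append(edge)
        return edge

    def add_rbfe(
        self, receptor: str, ligand_from: str, ligand_to: str, m: Measurement
    ) -> Edge:
        """Relative binding free energy edge on one receptor.

        Constrains ``x(receptor·ligand_to) - x(receptor·ligand_from) = m``.
        """
        self._require_mode(NetworkMode.COMPLEX, "RBFE")
        return self.add_edge(
            Edge(
                EdgeKind.RBFE,
                ComplexNode(receptor, ligand_from),
                ComplexNode(receptor, ligand_to),
                m,
            )
        )

    def add_rhfe(
        self, ligand: str, receptor_from: str, receptor_to: str, m: Measurement
    ) -> Edge:
        """Receptor hopping edge: one ligand transferred between receptors.

        Constrains ``x(receptor_to·ligand) - x(receptor_from·ligand) = m``.
        """
        self._require_mode(NetworkMode.COMPLEX, "RHFE")
        return self.add_edge(
            Edge(
                EdgeKind.RHFE,
                ComplexNode(receptor_from, ligand),
                ComplexNode(receptor_to, ligand),
                m,
            )
        )

    def add_rsfe(self, ligand_1: str, ligand_2: str, m: Measurement) -> Edge:
        """Receptor swapping edge between two ligands' BSFE nodes.

        The swap starts from ligand_1 bound to the first-listed receptor of
        the network's pair and ligand_2 bound to the second, so the edge
        constrains ``BSFE(ligand_1) - BSFE(ligand_2) = m`` (tail = ligand_2,
        head = ligand_1).
        """
        self._require_mode(NetworkMode.SELECTIVITY, "RSFE")
        ra, rb = self.receptor_pair  # type: ignore[misc]
        return self.add_edge(
            Edge(
                EdgeKind.RSFE,
                SelectivityNode(ligand_2, ra, rb),
                SelectivityNode(ligand_1, ra, rb),
                m,
            )
        )

    def add_anchor(self, node: Node, value: Measurement) -> Anchor:
        self._check_node_mode(node)
        self._register(node)
        anchor = Anchor(node, value)
        self.anchors.append(anchor)
        return anchor

    # -- structure analysis -----------------------------------------------

    def as_undirected(self) -> nx.MultiGraph:
        """Undirected multigraph view (node objects as graph nodes)."""
        g = nx.MultiGraph()
        g.add_nodes_from(self._nodes)
        for i, e in enumerate(self.edges):
            g.add_edge(e.tail, e.head, key=i, edge=e)
        return g

    def components(self) -> List[set]:
        return [set(c) for c in nx.connected_components(self.as_undirected())]

    def validate(self) -> List[Finding]:
        """Structural checks; an empty list means the network is solvable.

        Errors are raised as data, not exceptions: anchor-less connected
        components, anchors on unknown nodes, and contradictory duplicate
        zero-uncertainty edges.
        """
        findings: List[Finding] = []
        anchored = {a.node for a in self.anchors}
        for a in self.anchors:
            if a.node not in self._nodes:
                findings.append(
                    Finding(
                        "error",
                        "anchor-unknown-node",
                        f"anchor on node {a.node} which is not in the network",
                    )
                )
        for comp in self.components():
            if not comp & anchored:
                names = ", ".join(sorted(str(n) for n in comp))
                findings.append(
                    Finding(
                        "error",
                        "component-without-anchor",
                        f"connected component without an anchor: {{{names}}}",
                    )
                )
        # contradictory exact (zero-uncertainty) parallel edges admit no solution
        exact: dict[tuple, float] = {}
        for e in self.edges:
            if e.measurement.uncertainty == 0:
                key = (e.tail, e.head)
                rkey = (e.head, e.tail)
                if key in exact and exact[key] != e.measurement.value:
                    findings.append(
                        Finding(
                            "error",
                            "contradictory-exact-edges",
                            f"zero-uncertainty edges {e.tail} -> {e.head} disagree: "
                            f"{exact[key]} vs {e.measurement.value}",
                        )
                    )
                elif rkey in exact and exact[rkey] != -e.measurement.value:
                    findings.append(
                        Finding(
                            "error",
                            "contradictory-exact-edges",
                            f"zero-uncertainty edges between {e.tail} and {e.head} "
                            f"disagree under reversal",
                        )
                    )
                exact.setdefault(key, e.measurement.value)
        return findings

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Network(mode={self.mode.value}, nodes={len(self._nodes)}, "
            f"edges={len(self.edges)}, anchors={len(self.anchors)})"
        )
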