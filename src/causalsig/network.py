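"""Signed directed regulatory networks.

The substrate for causal reasoning: a directed graph whose edges carry a
regulatory sign (+1 activation, -1 inhibition) and a mechanism label, and
whose nodes carry a molecular-function annotation (transcription factor,
kinase, phosphatase, RNA, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

NODE_FUNCTIONS = frozenset({"TF", "kinase", "phosphatase", "RNA", "other"})
MECHANISMS = frozenset(
    {"transcription-regulation", "phosphorylation", "binding", "other"}
)


@dataclass
class RegulatoryNetwork:
    """A signed directed molecular-interaction network.

    Wraps a :class:`networkx.DiGraph`; every node has a ``function``
    attribute drawn from :data:`NODE_FUNCTIONS` and every edge has
    ``sign`` (+1/-1) and ``mechanism`` attributes.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, node: str, function: str = "other") -> None:
        if function not in NODE_FUNCTIONS:
            raise ValueError(f"unknown molecular function: {function!r}")
        self.graph.add_node(node, function=function)

    def add_edge(
        self,
        source: str,
        target: str,
        sign: int,
        mechanism: str = "other",
    ) -> None:
        if source == target:
            raise ValueError(f"self-loop not allowed: {source!r}")
        if sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        if mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism: {mechanism!r}")
        for endpoint in (source, target):
            if endpoint not in self.graph:
                self.graph.add_node(endpoint, function="other")
        self.graph.add_edge(source, target, sign=sign, mechanism=mechanism)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def function_of(self, node: str) -> str:
        if node not in self.graph:
            raise KeyError(f"unknown node: {node!r}")
        return self.graph.nodes[node].get("function", "other")

    def nodes_with_function(self, function: str) -> list[str]:
        if function not in NODE_FUNCTIONS:
            raise ValueError(f"unknown molecular function: {function!r}")
        return sorted(
            n for n, d in self.graph.nodes(data=True)
            if d.get("function", "other") == function
        )

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    # ------------------------------------------------------------------ IO

    def write_sif(self, edge_path: str | Path, node_path: str | Path) -> None:
        """Write SIF-like edge TSV (source, sign:mechanism, target) and a
        node-annotation TSV (node, function)."""
        with open(edge_path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                sign = "+" if d["sign"] > 0 else "-"
                fh.write(f"{u}\t{sign}:{d['mechanism']}\t{v}\n")
        with open(node_path, "w") as fh:
            for n in sorted(self.graph.nodes):
                fh.write(f"{n}\t{self.function_of(n)}\n")

    @classmethod
    def read_sif(
        cls, edge_path: str | Path, node_path: str | Path | None = None
    ) -> "RegulatoryNetwork":
        net = cls()
        if node_path is not None:
            with open(node_path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    node, function = line.split("\t")
                    net.add_node(node, function)
        with open(edge_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                source, label, target = line.split("\t")
                sign_char, _, mechanism = label.partition(":")
                sign = 1 if sign_char == "+" else -1
                net.add_edge(source, target, sign, mechanism or "other")
        return net
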