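"""Gene Ontology handling: DAG parsing, depths, branch sub-networks.

The ontology is read from OBO 1.2 text (via ``obonet``) and reduced to
its ``is_a`` skeleton. Term depth is the length of the shortest ``is_a``
path to the namespace root (configurable to longest-path). A branch —
e.g. immune system process, GO:0002376 — is its root plus all ``is_a``
descendants; the branch sub-network of the integrated PIN keeps proteins
annotated inside the branch and the interactions among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd

from interopin.errors import FormatError, LookupError_
from interopin.integrate import IntegratedPIN
from interopin.subnet import NodeInfo, SubNetwork

IMMUNE_BRANCH_ROOT = "GO:0002376"


@dataclass
class GOGraph:
    """An ``is_a``-only GO DAG. Edges point child -> parent."""

    graph: nx.DiGraph
    roots: dict[str, str] = field(default_factory=dict)  # namespace -> root term

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise FormatError("ontology is_a graph contains a cycle")
        for term in self.graph.nodes:
            if self.graph.out_degree(term) == 0:
                ns = self.graph.nodes[term].get("namespace", "")
                self.roots.setdefault(ns, term)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name_of(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace_of(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        if term not in self.graph:
            raise LookupError_(f"unknown GO term {term!r}")
        return set(nx.descendants(self.graph, term))


def parse_obo(path: str | Path) -> GOGraph:
    """Load an OBO 1.2 file, keeping non-obsolete terms and is_a edges only."""
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        g.add_node(term, name=data.get("name", term), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return GOGraph(graph=g)


def term_depth(go: GOGraph, term: str, mode: str = "shortest") -> int:
    """Depth of ``term``: is_a path length to its namespace root (root = 0).

    GO "level" conventions vary; the default is the shortest path, with
    ``mode="longest"`` available.
    """
    if term not in go.graph:
        raise LookupError_(f"unknown GO term {term!r}")
    root = go.roots.get(go.namespace_of(term))
    if term == root:
        return 0
    if mode == "shortest":
        return nx.shortest_path_length(go.graph, term, root)
    if mode == "longest":
        best = -1
        for path in nx.all_simple_paths(go.graph, term, root):
            best = max(best, len(path) - 1)
        if best < 0:
            raise LookupError_(f"{term!r} does not reach root {root!r}")
        return best
    raise ValueError(f"unknown depth mode {mode!r}")


def branch_members(go: GOGraph, branch_root: str = IMMUNE_BRANCH_ROOT) -> set[str]:
    """The branch root plus all its is_a descendants."""
    if branch_root not in go.graph:
        raise LookupError_(f"unknown GO term {branch_root!r}")
    # edges point child -> parent, so descendants of the branch root are
    # exactly the nodes that can reach it.
    return {branch_root} | set(nx.ancestors(go.graph, branch_root))


@dataclass
class AnnotationTable:
    """Protein -> GO term annotations (biological process by convention)."""

    term_sets: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "AnnotationTable":
        table = cls()
        for protein, term in rows:
            table.term_sets.setdefault(protein, set()).add(term)
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["protein", "go_term"]:
            raise FormatError(f"{path}: expected columns protein, go_term")
        return cls.from_rows(zip(df["protein"], df["go_term"]))

    def terms_of(self, protein: str) -> set[str]:
        return set(self.term_sets.get(protein, set()))

    def is_classified(self, protein: str) -> bool:
        return bool(self.term_sets.get(protein))

    def validate_against(self, go: GOGraph) -> None:
        unknown = {t for ts in self.term_sets.values() for t in ts} - go.terms
        if unknown:
            raise LookupError_(f"annotation terms absent from ontology: {sorted(unknown)[:5]}")


def extract_branch_subnetwork(
    pin: IntegratedPIN, annotations: AnnotationTable, branch: set[str]
) -> SubNetwork:
    """Induced sub-network on proteins annotated within a GO branch.

    Isolated branch proteins are retained as nodes (the branch defines
    membership; connectivity is reported separately).
    """
    members = {
        pid
        for pid in pin.nodes
        if annotations.terms_of(pid) & branch
    }
    sub = SubNetwork(organism_id="branch")
    for pid in sorted(members):
        node = pin.nodes[pid]
        sub.nodes[pid] = NodeInfo(
            unigenes=set(node.unigenes), label=node.label, e_value=node.e_value
        )
    for edge in sorted(pin.edges):
        if edge[0] in members and edge[1] in members:
            sub.edges.add(edge)
    return sub


def connected_components(net: SubNetwork) -> list[tuple[set[str], int]]:
    """Connected components as (node set, edge count), largest first.

    Ordering is deterministic: by size descending, then by the
    lexicographically smallest node.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    comps = [
        (set(c), g.subgraph(c).number_of_edges()) for c in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: (-len(c[0]), min(c[0])))
    return comps


def level_summary(
    annotations: AnnotationTable, go: GOGraph, level: int = 1, namespace: str | None = None
) -> dict[str, int]:
    """Count annotated proteins per ontology term at a given depth.

    Each protein's terms are mapped up through their ancestor closure to
    the terms at depth ``level`` (children of the root for level 1); a
    protein annotated under several branches counts toward each.
    """
    level_terms = {t for t in go.terms if term_depth(go, t) == level}
    if namespace is not None:
        level_terms = {t for t in level_terms if go.namespace_of(t) == namespace}
    counts: dict[str, int] = {t: 0 for t in sorted(level_terms)}
    for protein in sorted(annotations.term_sets):
        closure: set[str] = set()
        for term in annotations.term_sets[protein]:
            if term not in go.graph:
                raise LookupError_(f"annotation term {term!r} absent from ontology")
            closure |= {term} | go.ancestors(term)
        for t in closure & level_terms:
            counts[t] += 1
    return counts


def pathway_membership_summary(
    net: SubNetwork,
    pathway_table: pd.DataFrame,
    category: str | None = "signaling",
) -> tuple[int, float, dict[str, int]]:
    """Fraction of sub-network proteins annotated to pathways of a category.

    Returns (member count, fraction of nodes, per-pathway node counts).
    ``pathway_table`` has columns protein, pathway, category.
    """
    df = pathway_table
    if category is not None:
        df = df[df["category"] == category]
    members_of: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        members_of.setdefault(row["pathway"], set()).add(row["protein"])
    nodes = set(net.nodes)
    in_any = set()
    per_pathway: dict[str, int] = {}
    for pathway in sorted(members_of):
        hit = members_of[pathway] & nodes
        if hit:
            per_pathway[pathway] = len(hit)
            in_any |= hit
    fraction = len(in_any) / len(nodes) if nodes else 0.0
    return len(in_any), fraction, per_pathway
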