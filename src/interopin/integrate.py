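"""Ordered iterative integration of sub-networks with cumulative scoring.

The per-organism sub-networks are merged one at a time into a growing
integrated network. In each round the already-integrated network is the
*target* (closer relatives, integrated earlier) and the incoming
sub-network is the *query*. Nodes are merged on cross-organism orthology;
each round contributes, to every edge present in target and/or query,

* an edge-match score: 3 if the interaction exists in both networks,
  2 if only in the target, 1 if only in the query; and
* a protein-match score per endpoint: 2 if the target and query proteins
  are orthologous and share a unigene, 1 if orthologous but associated
  with different unigenes, 0 if the node has no ortholog in the other
  network this round.

The final confidence score of an edge is the sum of its ledger over all
rounds; with seven sub-networks (six rounds) it ranges from 1 (an edge
appearing only in the last query, endpoints unmatched) to 42 (an edge
present throughout with fully matching endpoints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from interopin.errors import ConfigurationError, DuplicateOrganismError, InteropinError
from interopin.subnet import NodeInfo, SubNetwork, canonical_edge

MAX_ROUND_SCORE = 7  # 3 (edge both) + 2 + 2 (both endpoints fully matched)


@dataclass(frozen=True)
class RoundScore:
    """One round's contribution to an edge: endpoint protein scores and edge score.

    ``protein_a`` / ``protein_b`` follow the canonical (sorted) order of the
    edge's endpoint ids. ``edge == 0`` only for rounds before the edge
    first existed (padding).
    """

    protein_a: int
    protein_b: int
    edge: int

    @property
    def total(self) -> int:
        return self.protein_a + self.protein_b + self.edge


@dataclass
class ScoreLedger:
    """Per-round score components of one integrated edge."""

    rounds: list[RoundScore] = field(default_factory=list)

    @property
    def final_score(self) -> int:
        return sum(r.total for r in self.rounds)

    def packed(self) -> str:
        return ";".join(f"{r.protein_a},{r.protein_b},{r.edge}" for r in self.rounds)


@dataclass
class MergedNode:
    """A node of the integrated network: one protein class across organisms."""

    primary_id: str
    member_ids: dict[str, str]  # organism -> protein id
    unigenes: set[str]
    label: str = ""
    e_value: float = math.inf

    def members(self) -> set[str]:
        return set(self.member_ids.values())


@dataclass
class IntegrationRoundStats:
    """Per-round integration statistics.

    ``n1``/``n2``: query nodes merged into the target / total query nodes;
    ``m1``/``m2``: query edges whose merged endpoints already formed a
    target edge / total query edges; final counts describe the network
    after the round.
    """

    round_no: int
    query_organism: str
    n1: int
    n2: int
    m1: int
    m2: int
    final_node_count: int
    final_edge_count: int

    @property
    def node_ratio(self) -> float | None:
        return self.n1 / self.n2 if self.n2 else None

    @property
    def edge_ratio(self) -> float | None:
        return self.m1 / self.m2 if self.m2 else None

    @staticmethod
    def _pct(x: float | None) -> str:
        return "" if x is None else f"{100.0 * x:.2f}%"


@dataclass
class IntegratedPIN:
    """The growing/final integrated network with per-edge score ledgers."""

    nodes: dict[str, MergedNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], ScoreLedger] = field(default_factory=dict)
    organisms: list[str] = field(default_factory=list)
    rounds_completed: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def unigenes(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out |= node.unigenes
        return out

    def final_scores(self) -> dict[tuple[str, str], int]:
        return {e: l.final_score for e, l in self.edges.items()}

    def member_index(self) -> dict[str, str]:
        """Map every member protein id to its merged node's primary id."""
        idx: dict[str, str] = {}
        for primary, node in self.nodes.items():
            for member in node.member_ids.values():
                idx[member] = primary
        return idx


class OrthologTable:
    """Cross-organism orthology between reference proteins.

    Stores unordered pairs of organism-qualified protein ids; lookup by
    protein returns all its orthologs. This relation is an explicit input
    (e.g. from reciprocal-best-hit analysis) — it cannot be derived from
    unigene sharing, because orthologous proteins may map to different
    unigenes and still count as a (score-1) match.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):  # noqa: D107
        self._adj: dict[str, set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            return
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def orthologs_of(self, protein: str) -> set[str]:
        return self._adj.get(protein, set())

    def are_orthologs(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, set())

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            {canonical_edge(a, b) for a, bs in self._adj.items() for b in bs}
        )

    def __len__(self) -> int:
        return len(self.pairs())


def order_subnetworks(
    subnets: Sequence[SubNetwork],
    phylo_ranks: dict[str, int],
    sizes: dict[str, int] | None = None,
) -> list[str]:
    """Integration order: genetic closeness first, then sub-network size.

    Organisms are sorted by ascending phylogenetic closeness rank (1 =
    closest relative of the focal organism); among equal ranks the larger
    sub-network (edge count by default) is integrated earlier.
    """
    for sub in subnets:
        if sub.organism_id not in phylo_ranks:
            raise ConfigurationError(f"no phylogenetic rank for {sub.organism_id!r}")
    if sizes is None:
        sizes = {s.organism_id: s.n_edges for s in subnets}
    return [
        s.organism_id
        for s in sorted(
            subnets,
            key=lambda s: (phylo_ranks[s.organism_id], -sizes.get(s.organism_id, 0), s.organism_id),
        )
    ]


def score_protein_match(
    target_node: MergedNode, query_node: MergedNode, orthologs: OrthologTable
) -> int:
    """Protein-match score for one round: 2, 1 or 0.

    2 — the nodes are orthologous and share at least one unigene;
    1 — orthologous but associated with disjoint unigene sets;
    0 — no ortholog relation between any member proteins.
    """
    related = any(
        orthologs.are_orthologs(m, q)
        for m in sorted(target_node.members())
        for q in sorted(query_node.members())
    )
    if not related:
        return 0
    return 2 if target_node.unigenes & query_node.unigenes else 1


def score_edge_match(in_target: bool, in_query: bool) -> int:
    """Edge-match score for one round: both 3, target-only 2, query-only 1."""
    if in_target and in_query:
        return 3
    if in_target:
        return 2
    if in_query:
        return 1
    raise InteropinError("edge exists in neither the target nor the query network")


def _subnet_node_as_merged(organism: str, pid: str, info: NodeInfo) -> MergedNode:
    return MergedNode(
        primary_id=pid,
        member_ids={organism: pid},
        unigenes=set(info.unigenes),
        label=info.label or pid,
        e_value=info.e_value,
    )


def pin_from_subnetwork(sub: SubNetwork) -> IntegratedPIN:
    """Seed the integration with the first (closest-relative) sub-network."""
    pin = IntegratedPIN(organisms=[sub.organism_id])
    for pid in sorted(sub.nodes):
        pin.nodes[pid] = _subnet_node_as_merged(sub.organism_id, pid, sub.nodes[pid])
    for edge in sorted(sub.edges):
        pin.edges[canonical_edge(*edge)] = ScoreLedger()
    return pin


def _match_query_nodes(
    pin: IntegratedPIN, query: SubNetwork, orthologs: OrthologTable
) -> dict[str, str]:
    """Greedy one-to-one matching of query nodes onto target nodes.

    Candidate pairs are every (target node, query node) related by at
    least one ortholog pair between member proteins; they are consumed in
    order of increasing summed homology E-value, ties broken
    lexicographically by query then target id, each node used at most
    once. Losers enter the network as new nodes.
    """
    member_idx = pin.member_index()
    candidates: list[tuple[float, str, str]] = []
    for qid in sorted(query.nodes):
        qinfo = query.nodes[qid]
        targets = {
            member_idx[o] for o in sorted(orthologs.orthologs_of(qid)) if o in member_idx
        }
        for primary in sorted(targets):
            cost = pin.nodes[primary].e_value + qinfo.e_value
            candidates.append((cost, qid, primary))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    assigned_q: set[str] = set()
    assigned_t: set[str] = set()
    match: dict[str, str] = {}
    for cost, qid, primary in candidates:
        if qid in assigned_q or primary in assigned_t:
            continue
        match[qid] = primary
        assigned_q.add(qid)
        assigned_t.add(primary)
    return match


def integrate_round(
    pin: IntegratedPIN, query: SubNetwork, orthologs: OrthologTable
) -> tuple[IntegratedPIN, IntegrationRoundStats]:
    """Merge one query sub-network into the target and score the round."""
    if query.organism_id in pin.organisms:
        raise DuplicateOrganismError(f"{query.organism_id!r} already integrated")

    match = _match_query_nodes(pin, query, orthologs)

    # Per-node protein score for this round, computed BEFORE unigene union.
    node_score: dict[str, int] = {}
    for qid, primary in match.items():
        qnode = _subnet_node_as_merged(query.organism_id, qid, query.nodes[qid])
        node_score[primary] = score_protein_match(pin.nodes[primary], qnode, orthologs)

    # Merge matched query nodes; introduce the rest as new nodes.
    new_ids: dict[str, str] = {}  # query node -> integrated node id
    for qid in sorted(query.nodes):
        info = query.nodes[qid]
        if qid in match:
            primary = match[qid]
            node = pin.nodes[primary]
            node.member_ids[query.organism_id] = qid
            node.unigenes |= info.unigenes
            node.e_value = min(node.e_value, info.e_value)
            new_ids[qid] = primary
        else:
            if qid in pin.nodes:  # same id reused across organisms is not expected
                raise DuplicateOrganismError(f"node id collision on {qid!r}")
            pin.nodes[qid] = _subnet_node_as_merged(query.organism_id, qid, info)
            node_score[qid] = 0
            new_ids[qid] = qid

    target_edges = set(pin.edges)
    query_edges_mapped = {
        canonical_edge(new_ids[a], new_ids[b]) for a, b in query.edges
    }
    m1 = len(query_edges_mapped & target_edges)

    round_index = pin.rounds_completed  # 0-based position in the ledger
    for edge in sorted(target_edges | query_edges_mapped):
        in_t = edge in target_edges
        in_q = edge in query_edges_mapped
        escore = score_edge_match(in_t, in_q)
        pa = node_score.get(edge[0], 0)
        pb = node_score.get(edge[1], 0)
        ledger = pin.edges.get(edge)
        if ledger is None:
            ledger = ScoreLedger(rounds=[RoundScore(0, 0, 0)] * round_index)
            pin.edges[edge] = ledger
        ledger.rounds.append(RoundScore(pa, pb, escore))

    pin.organisms.append(query.organism_id)
    pin.rounds_completed += 1
    stats = IntegrationRoundStats(
        round_no=pin.rounds_completed,
        query_organism=query.organism_id,
        n1=len(match),
        n2=query.n_proteins,
        m1=m1,
        m2=query.n_edges,
        final_node_count=pin.n_nodes,
        final_edge_count=pin.n_edges,
    )
    return pin, stats


def integrate_all(
    subnets: Sequence[SubNetwork], orthologs: OrthologTable
) -> tuple[IntegratedPIN, list[IntegrationRoundStats]]:
    """Fold :func:`integrate_round` over the ordered sub-networks."""
    if len(subnets) < 2:
        raise ConfigurationError("integration needs at least two sub-networks")
    pin = pin_from_subnetwork(subnets[0])
    stats: list[IntegrationRoundStats] = []
    for query in subnets[1:]:
        pin, st = integrate_round(pin, query, orthologs)
        stats.append(st)
    return pin, stats


def score_distribution(
    pin: IntegratedPIN, n_bins: int = 6
) -> list[tuple[int, int, int]]:
    """Histogram of final scores over equal-width bins spanning [1, 7R].

    With six rounds the default six bins are 1-7, 8-14, ..., 36-42.
    Returns (lo, hi, count) triples; counts sum to the edge count.
    """
    rounds = pin.rounds_completed
    hi_max = MAX_ROUND_SCORE * rounds
    width = hi_max // n_bins if n_bins and hi_max % n_bins == 0 else max(1, -(-hi_max // n_bins))
    bins = [(lo, min(lo + width - 1, hi_max)) for lo in range(1, hi_max + 1, width)]
    counts = [0] * len(bins)
    for edge, ledger in pin.edges.items():
        s = ledger.final_score
        if not 1 <= s <= hi_max:
            raise InteropinError(f"edge {edge} score {s} outside [1, {hi_max}]")
        counts[(s - 1) // width] += 1
    return [(lo, hi, c) for (lo, hi), c in zip(bins, counts)]


def extract_high_score(pin: IntegratedPIN, min_score: int = 40) -> SubNetwork:
    """Sub-network of edges whose final score reaches ``min_score``."""
    sub = SubNetwork(organism_id="high_score")
    for edge, ledger in sorted(pin.edges.items()):
        if ledger.final_score >= min_score:
            sub.edges.add(edge)
            for pid in edge:
                node = pin.nodes[pid]
                sub.nodes[pid] = NodeInfo(
                    unigenes=set(node.unigenes), label=node.label, e_value=node.e_value
                )
    return sub


def write_pin(pin: IntegratedPIN, edges_path: str | Path, nodes_path: str | Path) -> None:
    with open(edges_path, "w") as fh:
        fh.write("protein_a\tprotein_b\tfinal_score\tledger\n")
        for (a, b), ledger in sorted(pin.edges.items()):
            fh.write(f"{a}\t{b}\t{ledger.final_score}\t{ledger.packed()}\n")
    with open(nodes_path, "w") as fh:
        fh.write("primary_id\tlabel\tmembers\tunigenes\n")
        for pid in sorted(pin.nodes):
            node = pin.nodes[pid]
            members = ";".join(f"{o}:{p}" for o, p in sorted(node.member_ids.items()))
            fh.write(f"{pid}\t{node.label}\t{members}\t{';'.join(sorted(node.unigenes))}\n")


def read_pin(edges_path: str | Path, nodes_path: str | Path) -> IntegratedPIN:
    """Re-load a PIN written by :func:`write_pin` (ledgers included)."""
    pin = IntegratedPIN()
    organisms: set[str] = set()
    with open(nodes_path) as fh:
        fh.readline()
        for line in fh:
            pid, label, members, unigenes = line.rstrip("\n").split("\t")
            member_ids = dict(m.split(":", 1) for m in members.split(";") if m)
            organisms |= set(member_ids)
            pin.nodes[pid] = MergedNode(
                primary_id=pid,
                member_ids=member_ids,
                unigenes={u for u in unigenes.split(";") if u},
                label=label,
            )
    with open(edges_path) as fh:
        fh.readline()
        for line in fh:
            a, b, _final, packed = line.rstrip("\n").split("\t")
            rounds = [
                RoundScore(*(int(x) for x in part.split(",")))
                for part in packed.split(";")
                if part
            ]
            pin.edges[canonical_edge(a, b)] = ScoreLedger(rounds=rounds)
            pin.rounds_completed = max(pin.rounds_completed, len(rounds))
    pin.organisms = sorted(organisms)
    return pin


def write_round_stats(stats: Sequence[IntegrationRoundStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "round\tquery_organism\tn1\tn2\tn1/n2\tm1\tm2\tm1/m2\t"
            "final_node\tfinal_edge\n"
        )
        for st in stats:
            fh.write(
                f"{st.round_no}\t{st.query_organism}\t{st.n1}\t{st.n2}\t"
                f"{IntegrationRoundStats._pct(st.node_ratio)}\t{st.m1}\t{st.m2}\t"
                f"{IntegrationRoundStats._pct(st.edge_ratio)}\t"
                f"{st.final_node_count}\t{st.final_edge_count}\n"
            )
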