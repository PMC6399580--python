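"""GO DAG handling, branch extraction, components — with brute-force oracles."""

from __future__ import annotations

import random

import pytest

from conftest import SEVEN_ORGS, full_ortholog_table, one_edge_subnet, make_subnet
from interopin.errors import LookupError_
from interopin.integrate import integrate_all
from interopin.ontology import (
    AnnotationTable,
    branch_members,
    connected_components,
    extract_branch_subnetwork,
    level_summary,
    parse_obo,
    pathway_membership_summary,
    term_depth,
)
from interopin.subnet import NodeInfo, SubNetwork

import pandas as pd


def write_obo(tmp_path, stanzas: list[tuple[str, str, list[str], bool]]):
    lines = ["format-version: 1.2", ""]
    for tid, name, parents, obsolete in stanzas:
        lines += ["[Term]", f"id: {tid}", f"name: {name}", "namespace: biological_process"]
        for p in parents:
            lines.append(f"is_a: {p} ! x")
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path = tmp_path / "toy.obo"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def diamond_go(tmp_path):
    # root <- a <- c, root <- b <- c (diamond), plus a deeper chain under b
    return parse_obo(
        write_obo(
            tmp_path,
            [
                ("GO:1", "root", [], False),
                ("GO:2", "a", ["GO:1"], False),
                ("GO:3", "b", ["GO:1"], False),
                ("GO:4", "b-child", ["GO:3"], False),
                ("GO:5", "diamond", ["GO:2", "GO:4"], False),
                ("GO:6", "gone", ["GO:1"], True),
            ],
        )
    )


class TestParseAndDepth:
    def test_chain_loads_terms_and_edges(self, tmp_path):
        go = parse_obo(
            write_obo(tmp_path, [("GO:1", "root", [], False), ("GO:2", "A", ["GO:1"], False), ("GO:3", "B", ["GO:2"], False)])
        )
        assert go.terms == {"GO:1", "GO:2", "GO:3"}
        assert go.graph.number_of_edges() == 2

    def test_obsolete_terms_are_excluded(self, diamond_go):
        assert "GO:6" not in diamond_go.terms

    def test_diamond_keeps_both_parent_edges(self, diamond_go):
        assert diamond_go.parents("GO:5") == {"GO:2", "GO:4"}

    def test_depth_via_brute_force_path_enumeration(self, diamond_go):
        def all_path_lengths(term, target):
            if term == target:
                return [0]
            return [1 + d for p in diamond_go.parents(term) for d in all_path_lengths(p, target)]

        for term in sorted(diamond_go.terms):
            assert term_depth(diamond_go, term) == min(all_path_lengths(term, "GO:1"))
        assert term_depth(diamond_go, "GO:5") == 2  # shortest of 2 and 3
        assert term_depth(diamond_go, "GO:5", mode="longest") == 3
        assert term_depth(diamond_go, "GO:1") == 0

    def test_unknown_term_raises(self, diamond_go):
        with pytest.raises(LookupError_):
            term_depth(diamond_go, "GO:404")


class TestBranch:
    def test_leaf_branch_is_itself(self, diamond_go):
        assert branch_members(diamond_go, "GO:5") == {"GO:5"}

    def test_subtree_and_diamond_counted_once(self, diamond_go):
        assert branch_members(diamond_go, "GO:3") == {"GO:3", "GO:4", "GO:5"}
        assert branch_members(diamond_go, "GO:1") == diamond_go.terms

    def test_branch_is_a_fixed_point(self, diamond_go):
        branch = branch_members(diamond_go, "GO:3")
        for member in branch:
            assert branch_members(diamond_go, member) <= branch


def seven_org_pin():
    subs = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS]
    pin, _ = integrate_all(subs, full_ortholog_table(SEVEN_ORGS, ["A", "B"]))
    return pin


class TestBranchSubnetwork:
    def test_edges_need_both_endpoints_in_branch(self):
        subs = [
            make_subnet("o1", [("o1.P1", "o1.P2"), ("o1.P1", "o1.P3")],
                        {"o1.P1": {"u1"}, "o1.P2": {"u2"}, "o1.P3": {"u3"}}),
            one_edge_subnet("o2", {"u1"}, {"u2"}),
        ]
        pin, _ = integrate_all(subs, full_ortholog_table([], []))
        ann = AnnotationTable.from_rows([("o1.P1", "GO:3"), ("o1.P3", "GO:4")])
        net = extract_branch_subnetwork(pin, ann, {"GO:3", "GO:4"})
        assert set(net.nodes) == {"o1.P1", "o1.P3"}
        assert net.edges == {("o1.P1", "o1.P3")}

    def test_no_branch_proteins_gives_empty(self):
        pin = seven_org_pin()
        net = extract_branch_subnetwork(pin, AnnotationTable(), {"GO:3"})
        assert net.counts == (0, 0, 0)

    def test_counts_match_brute_force_filter(self, small_bundle, tmp_path):
        from interopin.homology import select_homologs
        from interopin.subnet import extract_subnetwork, filter_confidence
        from interopin.ontology import GOGraph

        hmap = select_homologs(small_bundle.homology_hits, organisms=small_bundle.organisms)
        subs = [
            extract_subnetwork(filter_confidence(i), hmap) for i in small_bundle.interactomes
        ]
        pin, _ = integrate_all(subs, small_bundle.orthologs())
        (tmp_path / "go.obo").write_text(small_bundle.go_obo)
        go = parse_obo(tmp_path / "go.obo")
        ann = AnnotationTable.from_rows(
            zip(small_bundle.go_annotations["protein"], small_bundle.go_annotations["go_term"])
        )
        branch = branch_members(go, "GO:0002376")
        net = extract_branch_subnetwork(pin, ann, branch)
        # oracle: exhaustive filter over all PIN nodes and edges
        oracle_nodes = {p for p in pin.nodes if ann.terms_of(p) & branch}
        oracle_edges = {e for e in pin.edges if e[0] in oracle_nodes and e[1] in oracle_nodes}
        assert set(net.nodes) == oracle_nodes
        assert net.edges == oracle_edges
        assert net.edges <= set(pin.edges)
        assert len(oracle_nodes) >= 5  # the generator guarantees a populated branch


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


class TestComponents:
    def test_path_plus_pair(self):
        net = make_subnet("x", [("a", "b"), ("b", "c"), ("d", "e")], {})
        comps = connected_components(net)
        assert [(len(n), e) for n, e in comps] == [(3, 2), (2, 1)]

    def test_empty_network(self):
        assert connected_components(SubNetwork(organism_id="x")) == []

    def test_matches_union_find_oracle_on_random_graph(self):
        rnd = random.Random(5)
        nodes = [f"n{i}" for i in range(50)]
        edges = sorted(
            {tuple(sorted(rnd.sample(nodes, 2))) for _ in range(60)}
        )
        net = SubNetwork(organism_id="x")
        for n in nodes:
            net.nodes[n] = NodeInfo(unigenes=set(), label=n)
        net.edges = set(edges)
        uf = UnionFind(nodes)
        for a, b in edges:
            uf.union(a, b)
        oracle: dict[str, set[str]] = {}
        for n in nodes:
            oracle.setdefault(uf.find(n), set()).add(n)
        comps = connected_components(net)
        assert sorted(map(frozenset, oracle.values()), key=lambda s: (-len(s), min(s))) == [
            frozenset(n) for n, _ in comps
        ]
        # partition and edge conservation
        assert sum(len(n) for n, _ in comps) == len(nodes)
        assert sum(e for _, e in comps) == len(edges)


class TestLevelSummary:
    def test_counts_match_brute_force_closure(self, diamond_go):
        ann = AnnotationTable.from_rows(
            [("p1", "GO:5"), ("p2", "GO:4"), ("p3", "GO:2"), ("p3", "GO:5")]
        )
        counts = level_summary(ann, diamond_go, level=1)

        def closure(term):
            out = {term}
            for p in diamond_go.parents(term):
                out |= closure(p)
            return out

        level1 = {t for t in diamond_go.terms if term_depth(diamond_go, t) == 1}
        oracle = {t: 0 for t in level1}
        for protein in ["p1", "p2", "p3"]:
            cl = set().union(*(closure(t) for t in ann.terms_of(protein)))
            for t in cl & level1:
                oracle[t] += 1
        assert counts == oracle
        # the diamond term reaches level 1 through both parents
        assert counts["GO:2"] == 2 and counts["GO:3"] == 3

    def test_protein_under_single_branch_counts_once(self, diamond_go):
        counts = level_summary(AnnotationTable.from_rows([("p1", "GO:4")]), diamond_go, level=1)
        assert counts == {"GO:2": 0, "GO:3": 1}


class TestPathwayMembership:
    def make_net(self, n):
        net = SubNetwork(organism_id="x")
        for i in range(n):
            net.nodes[f"p{i}"] = NodeInfo(unigenes=set(), label=f"p{i}")
        return net

    def test_fraction_of_members(self):
        net = self.make_net(93)
        table = pd.DataFrame(
            [(f"p{i}", "Ras", "signaling") for i in range(36)],
            columns=["protein", "pathway", "category"],
        )
        count, fraction, per = pathway_membership_summary(net, table)
        assert count == 36
        assert round(100 * fraction, 1) == 38.7
        assert per == {"Ras": 36}

    def test_empty_table(self):
        net = self.make_net(5)
        table = pd.DataFrame(columns=["protein", "pathway", "category"])
        assert pathway_membership_summary(net, table) == (0, 0.0, {})

    def test_all_members(self):
        net = self.make_net(4)
        table = pd.DataFrame(
            [(f"p{i}", "MAPK", "signaling") for i in range(4)],
            columns=["protein", "pathway", "category"],
        )
        count, fraction, _ = pathway_membership_summary(net, table)
        assert (count, fraction) == (4, 1.0)
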