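"""Ordered integration and the cumulative per-edge confidence score."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import SEVEN_ORGS, full_ortholog_table, make_subnet, one_edge_subnet
from interopin.errors import ConfigurationError, DuplicateOrganismError, InteropinError
from interopin.integrate import (
    MergedNode,
    OrthologTable,
    extract_high_score,
    integrate_all,
    integrate_round,
    order_subnetworks,
    pin_from_subnetwork,
    read_pin,
    score_distribution,
    score_edge_match,
    score_protein_match,
    write_pin,
)
from interopin.subnet import NodeInfo, SubNetwork


def node(pid: str, org: str, unigenes: set[str]) -> MergedNode:
    return MergedNode(primary_id=pid, member_ids={org: pid}, unigenes=unigenes)


class TestComponentScores:
    def test_protein_match_shared_unigene_scores_two(self):
        ortho = OrthologTable([("o1.A", "o2.A")])
        assert score_protein_match(node("o1.A", "o1", {"u1"}), node("o2.A", "o2", {"u1", "u2"}), ortho) == 2

    def test_protein_match_disjoint_unigenes_scores_one(self):
        ortho = OrthologTable([("o1.A", "o2.A")])
        assert score_protein_match(node("o1.A", "o1", {"u1"}), node("o2.A", "o2", {"u2"}), ortho) == 1

    def test_protein_match_without_orthology_scores_zero(self):
        assert score_protein_match(node("o1.A", "o1", {"u1"}), node("o2.A", "o2", {"u1"}), OrthologTable()) == 0

    @pytest.mark.parametrize(
        "in_target,in_query,expected", [(True, True, 3), (True, False, 2), (False, True, 1)]
    )
    def test_edge_match_scores(self, in_target, in_query, expected):
        assert score_edge_match(in_target, in_query) == expected

    def test_edge_in_neither_network_is_a_contract_violation(self):
        with pytest.raises(InteropinError):
            score_edge_match(False, False)


class TestOrder:
    def test_rank_dominates(self):
        subs = [make_subnet("A", [("A.x", "A.y")], {}), make_subnet("B", [("B.x", "B.y")], {})]
        assert order_subnetworks(subs, {"A": 1, "B": 2}) == ["A", "B"]

    def test_size_breaks_rank_ties(self):
        a = make_subnet("A", [("A.x", "A.y")], {})
        b = make_subnet("B", [("B.x", "B.y"), ("B.y", "B.z")], {})
        assert order_subnetworks([a, b], {"A": 1, "B": 1}) == ["B", "A"]

    def test_seven_reference_organisms_order(self):
        # closeness ranks mirror the arthropod-first phylogeny; rodent sizes
        # differ enough that the larger rodent sub-network goes first.
        sizes = {
            "Dmel": 56330, "Agam": 18931, "Cele": 23132,
            "Mmus": 49131, "Rnor": 41107, "Hsap": 74523, "Scer": 20444,
        }
        ranks = {"Dmel": 1, "Agam": 2, "Cele": 3, "Mmus": 4, "Rnor": 4, "Hsap": 5, "Scer": 6}
        subs = [make_subnet(o, [(f"{o}.x", f"{o}.y")], {}) for o in sizes]
        assert order_subnetworks(subs, ranks, sizes) == [
            "Dmel", "Agam", "Cele", "Mmus", "Rnor", "Hsap", "Scer",
        ]

    def test_missing_rank_is_a_configuration_error(self):
        subs = [make_subnet("A", [("A.x", "A.y")], {})]
        with pytest.raises(ConfigurationError):
            order_subnetworks(subs, {})


class TestRound:
    def test_fully_matching_round_scores_seven(self):
        target = pin_from_subnetwork(one_edge_subnet("o1", {"u1"}, {"u2"}))
        query = one_edge_subnet("o2", {"u1"}, {"u2"})
        ortho = full_ortholog_table(["o1", "o2"], ["A", "B"])
        pin, st_ = integrate_round(target, query, ortho)
        assert pin.edges[("o1.A", "o1.B")].final_score == 3 + 2 + 2
        assert (st_.n1, st_.n2, st_.m1, st_.m2) == (2, 2, 1, 1)

    def test_disjoint_round_scores_target_two_query_one(self):
        target = pin_from_subnetwork(make_subnet("o1", [("o1.A", "o1.B")], {"o1.A": {"u1"}, "o1.B": {"u2"}}))
        query = make_subnet("o2", [("o2.C", "o2.D")], {"o2.C": {"u3"}, "o2.D": {"u4"}})
        pin, st_ = integrate_round(target, query, OrthologTable())
        assert pin.edges[("o1.A", "o1.B")].final_score == 2
        assert pin.edges[("o2.C", "o2.D")].final_score == 1
        assert (st_.n1, st_.m1) == (0, 0)

    def test_edgeless_round_reports_blank_ratio(self):
        target = pin_from_subnetwork(make_subnet("o1", [], {}))
        target.nodes["o1.A"] = node("o1.A", "o1", {"u1"})
        query = SubNetwork(organism_id="o2")
        query.nodes["o2.A"] = NodeInfo(unigenes={"u1"})
        pin, st_ = integrate_round(target, query, OrthologTable([("o1.A", "o2.A")]))
        assert st_.m2 == 0 and st_.edge_ratio is None
        assert st_.n1 == 1

    def test_duplicate_organism_rejected(self):
        target = pin_from_subnetwork(one_edge_subnet("o1", {"u1"}, {"u2"}))
        with pytest.raises(DuplicateOrganismError):
            integrate_round(target, one_edge_subnet("o1", {"u1"}, {"u2"}), OrthologTable())


class TestIntegrateAll:
    def test_maximum_score_is_42_for_six_full_rounds(self):
        subs = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS]
        ortho = full_ortholog_table(SEVEN_ORGS, ["A", "B"])
        pin, stats = integrate_all(subs, ortho)
        assert pin.n_edges == 1
        assert next(iter(pin.final_scores().values())) == 42
        assert len(stats) == 6

    def test_minimum_score_is_1_for_last_round_unmatched_query_edge(self):
        subs = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS[:6]]
        last = make_subnet("o7", [("o7.X", "o7.Y")], {"o7.X": {"u8"}, "o7.Y": {"u9"}})
        ortho = full_ortholog_table(SEVEN_ORGS, ["A", "B"])
        pin, _ = integrate_all(subs + [last], ortho)
        assert pin.edges[("o7.X", "o7.Y")].final_score == 1

    def test_never_matched_first_round_edge_scores_12(self):
        first = make_subnet("o1", [("o1.X", "o1.Y")], {"o1.X": {"u8"}, "o1.Y": {"u9"}})
        rest = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS[1:]]
        pin, _ = integrate_all([first] + rest, full_ortholog_table(SEVEN_ORGS[1:], ["A", "B"]))
        assert pin.edges[("o1.X", "o1.Y")].final_score == 2 * 6

    def test_score1_merge_unions_disjoint_unigene_sets(self):
        subs = [one_edge_subnet("o1", {"u1"}, {"u2"}), one_edge_subnet("o2", {"u3"}, {"u4"})]
        pin, _ = integrate_all(subs, full_ortholog_table(["o1", "o2"], ["A", "B"]))
        assert pin.nodes["o1.A"].unigenes == {"u1", "u3"}
        assert pin.edges[("o1.A", "o1.B")].final_score == 3 + 1 + 1

    def test_needs_at_least_two_subnetworks(self):
        with pytest.raises(ConfigurationError):
            integrate_all([one_edge_subnet("o1", {"u1"}, {"u2"})], OrthologTable())

    def test_order_asymmetry_is_the_target_query_edge_scores(self):
        a = make_subnet("oA", [("oA.X", "oA.Y")], {"oA.X": {"u1"}, "oA.Y": {"u2"}})
        b = make_subnet("oB", [("oB.P", "oB.Q")], {"oB.P": {"u3"}, "oB.Q": {"u4"}})
        pin_ab, _ = integrate_all([a, b], OrthologTable())
        pin_ba, _ = integrate_all([b, a], OrthologTable())
        # the unmatched target-only edge gets 2, the query-only edge 1 — swapped
        assert pin_ab.edges[("oA.X", "oA.Y")].final_score == 2
        assert pin_ab.edges[("oB.P", "oB.Q")].final_score == 1
        assert pin_ba.edges[("oA.X", "oA.Y")].final_score == 1
        assert pin_ba.edges[("oB.P", "oB.Q")].final_score == 2


def random_instance(seed: int, n_orgs: int):
    """A random multi-organism instance for property tests."""
    rnd = random.Random(seed)
    orgs = [f"g{i}" for i in range(n_orgs)]
    n_prot = rnd.randint(2, 6)
    names = [f"N{j}" for j in range(n_prot)]
    subs = []
    for org in orgs:
        edges = []
        for i in range(n_prot):
            for j in range(i + 1, n_prot):
                if rnd.random() < 0.5:
                    edges.append((f"{org}.{names[i]}", f"{org}.{names[j]}"))
        if not edges:
            edges = [(f"{org}.{names[0]}", f"{org}.{names[1]}")]
        unigenes = {f"{org}.{n}": {f"u{rnd.randint(0, n_prot)}"} for n in names}
        subs.append(make_subnet(org, edges, unigenes))
    ortho = OrthologTable()
    for n in names:
        for i in range(n_orgs):
            for j in range(i + 1, n_orgs):
                if rnd.random() < 0.7:
                    ortho.add(f"{orgs[i]}.{n}", f"{orgs[j]}.{n}")
    return subs, ortho


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_orgs=st.integers(2, 5))
    def test_final_scores_bounded_by_rounds(self, seed, n_orgs):
        """Every final score lies in [1, 7R] after R integration rounds."""
        subs, ortho = random_instance(seed, n_orgs)
        pin, stats = integrate_all(subs, ortho)
        rounds = n_orgs - 1
        scores = pin.final_scores().values()
        assert scores and all(1 <= s <= 7 * rounds for s in scores)
        # per-round component ranges and padding semantics
        for ledger in pin.edges.values():
            assert len(ledger.rounds) == rounds
            seen = False
            for r in ledger.rounds:
                assert r.protein_a in (0, 1, 2) and r.protein_b in (0, 1, 2)
                assert r.edge in (0, 1, 2, 3)
                if r.edge:
                    seen = True
                else:
                    assert not seen  # zero edge scores only before first existence
        # Table-3-style final counts are non-decreasing
        nodes = [s.final_node_count for s in stats]
        edges = [s.final_edge_count for s in stats]
        assert nodes == sorted(nodes) and edges == sorted(edges)
        assert all(s.n1 <= s.n2 and s.m1 <= s.m2 for s in stats)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_integration_is_deterministic(self, seed):
        subs, ortho = random_instance(seed, 4)
        pin1, st1 = integrate_all(subs, ortho)
        subs2, ortho2 = random_instance(seed, 4)
        pin2, st2 = integrate_all(subs2, ortho2)
        assert pin1.final_scores() == pin2.final_scores()
        assert [s.__dict__ for s in st1] == [s.__dict__ for s in st2]


class TestDistributionAndHighScore:
    def make_pin(self, scores):
        subs, ortho = random_instance(3, 7)
        pin, _ = integrate_all(subs, ortho)
        return pin

    def test_six_bins_partition_1_to_42(self):
        subs = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS]
        pin, _ = integrate_all(subs, full_ortholog_table(SEVEN_ORGS, ["A", "B"]))
        hist = score_distribution(pin)
        assert [(lo, hi) for lo, hi, _ in hist] == [
            (1, 7), (8, 14), (15, 21), (22, 28), (29, 35), (36, 42)
        ]
        assert [c for _, _, c in hist] == [0, 0, 0, 0, 0, 1]

    def test_histogram_totals_conserved_on_random_instance(self):
        subs, ortho = random_instance(42, 7)
        pin, _ = integrate_all(subs, ortho)
        hist = score_distribution(pin)
        assert sum(c for _, _, c in hist) == pin.n_edges

    def test_high_score_extraction_thresholds(self):
        subs = [one_edge_subnet(o, {"u1"}, {"u2"}) for o in SEVEN_ORGS]
        pin, _ = integrate_all(subs, full_ortholog_table(SEVEN_ORGS, ["A", "B"]))
        assert extract_high_score(pin, 40).n_edges == 1
        assert extract_high_score(pin, 1).n_edges == pin.n_edges
        assert extract_high_score(pin, 43).n_edges == 0


def test_pin_tsv_round_trip(tmp_path):
    subs, ortho = random_instance(7, 4)
    pin, _ = integrate_all(subs, ortho)
    write_pin(pin, tmp_path / "e.tsv", tmp_path / "n.tsv")
    back = read_pin(tmp_path / "e.tsv", tmp_path / "n.tsv")
    assert back.final_scores() == pin.final_scores()
    assert {p: n.unigenes for p, n in back.nodes.items()} == {
        p: n.unigenes for p, n in pin.nodes.items()
    }
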