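"""Shared fixtures: small synthetic bundles and hand-built toy networks."""

from __future__ import annotations

import pytest

from interopin.integrate import OrthologTable
from interopin.subnet import NodeInfo, SubNetwork
from interopin.synthetic import FixtureConfig, generate_fixture


def make_subnet(org: str, edges: list[tuple[str, str]], unigenes: dict[str, set[str]]) -> SubNetwork:
    """Build a sub-network from an edge list and per-node unigene sets."""
    sub = SubNetwork(organism_id=org)
    for a, b in edges:
        sub.edges.add(tuple(sorted((a, b))))
        for p in (a, b):
            if p not in sub.nodes:
                sub.nodes[p] = NodeInfo(unigenes=set(unigenes.get(p, set())), label=p)
    return sub


def one_edge_subnet(org: str, a_unigenes: set[str], b_unigenes: set[str]) -> SubNetwork:
    return make_subnet(org, [(f"{org}.A", f"{org}.B")],
                       {f"{org}.A": a_unigenes, f"{org}.B": b_unigenes})


def full_ortholog_table(orgs: list[str], locals_: list[str]) -> OrthologTable:
    """All-vs-all orthology for the given local protein names across organisms."""
    table = OrthologTable()
    for name in locals_:
        for i in range(len(orgs)):
            for j in range(i + 1, len(orgs)):
                table.add(f"{orgs[i]}.{name}", f"{orgs[j]}.{name}")
    return table


SEVEN_ORGS = [f"o{i}" for i in range(1, 8)]


@pytest.fixture(scope="session")
def small_bundle():
    """A small but structurally complete synthetic fixture."""
    return generate_fixture(
        FixtureConfig(
            n_organisms=5,
            n_proteins_per_organism=60,
            n_unigenes=120,
            edge_density=0.08,
            ortholog_overlap=0.8,
            n_go_terms=40,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on a small fixture, shared across tests."""
    from interopin.pipeline import RunConfig, run_pipeline
    from interopin.synthetic import FixtureConfig

    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        out_dir=str(out),
        fixture=FixtureConfig(
            n_organisms=5,
            n_proteins_per_organism=60,
            n_unigenes=120,
            edge_density=0.08,
            n_go_terms=40,
        ),
        seed=11,
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest, out
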