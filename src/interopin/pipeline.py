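"""End-to-end orchestration: fixture -> homology -> sub-networks -> PIN
-> branch sub-network -> age dating -> neighbour annotation.

One :class:`RunConfig` drives a reproducible run; every stage writes its
standard TSV outputs into the run directory and the run closes with a
JSON manifest recording parameters, the seed, per-stage counts and
SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from interopin import annotate as annotate_mod
from interopin import evoage, homology, integrate, ontology, subnet, synthetic
from interopin.errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: str = "pin_run"
    fixture: synthetic.FixtureConfig = field(default_factory=synthetic.FixtureConfig)
    input_dir: str | None = None  # pre-existing fixture directory; else generate
    e_threshold: float = 1e-10
    min_combined: int = 900
    high_score_cutoff: int = 40
    branch_term: str = ontology.IMMUNE_BRANCH_ROOT
    go_level: int = 1
    vote_fraction: float = 0.5
    min_support: int = 2
    min_pathway_proteins: int = 10
    order: list[str] | str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fixture = synthetic.FixtureConfig(**data.pop("fixture", {}))
        cfg = cls(fixture=fixture, **data)
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        fx = synthetic.FixtureConfig(**{**asdict(self.fixture), "seed": seed})
        cfg = RunConfig(**{**{k: v for k, v in asdict(self).items() if k != "fixture"}, "fixture": fx})
        cfg.seed = seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute all stages; return (and write) the run manifest."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "parameters": {
            "e_threshold": config.e_threshold,
            "min_combined": config.min_combined,
            "high_score_cutoff": config.high_score_cutoff,
            "branch_term": config.branch_term,
            "go_level": config.go_level,
            "vote_fraction": config.vote_fraction,
            "min_support": config.min_support,
            "min_pathway_proteins": config.min_pathway_proteins,
            "seed": config.seed,
        },
        "stages": {},
    }
    stages: dict[str, object] = manifest["stages"]  # type: ignore[assignment]

    # stage 1: inputs
    if config.input_dir is not None:
        bundle = synthetic.read_fixture(config.input_dir)
        fixture_dir = Path(config.input_dir)
    else:
        fx = synthetic.FixtureConfig(**{**asdict(config.fixture), "seed": config.seed})
        bundle = synthetic.generate_fixture(fx)
        fixture_dir = out / "fixture"
        synthetic.write_fixture(bundle, fixture_dir)
    stages["inputs"] = {
        "organisms": bundle.organisms,
        "n_hits": len(bundle.homology_hits),
        "n_ortholog_pairs": len(bundle.ortholog_table),
    }
    logger.info("inputs: %d organisms, %d BLAST hits", len(bundle.organisms), len(bundle.homology_hits))

    # stage 2: homology map
    hmap = homology.select_homologs(
        bundle.homology_hits, e_threshold=config.e_threshold, organisms=bundle.organisms
    )
    homology.write_homology_map(hmap, out / "homology_map.tsv")
    stages["homology"] = {"n_selected_pairs": hmap.n_pairs()}

    # stage 3: per-organism sub-networks
    id_map = {
        row["protein"]: (row["accession"], row["name"]) for _, row in bundle.id_map.iterrows()
    }
    subnets: dict[str, subnet.SubNetwork] = {}
    stat_rows = []
    for inter in bundle.interactomes:
        filtered = subnet.filter_confidence(inter, config.min_combined)
        sub = subnet.extract_subnetwork(filtered, hmap)
        subnet.label_nodes(sub, id_map)
        subnets[inter.organism_id] = sub
        subnet.write_subnetwork(sub, out / f"subnet_{inter.organism_id}.tsv")
        stat_rows.append(
            {
                "organism": inter.organism_id,
                "unigenes": sub.n_unigenes,
                "proteins": sub.n_proteins,
                "interactions": sub.n_edges,
            }
        )
    pd.DataFrame(stat_rows).to_csv(out / "subnet_stats.tsv", sep="\t", index=False)
    stages["subnetworks"] = {r["organism"]: (r["unigenes"], r["proteins"], r["interactions"]) for r in stat_rows}

    # stage 4: ordered integration
    ranks = bundle.phylo_ranks()
    if config.order == "auto":
        order = integrate.order_subnetworks(list(subnets.values()), ranks)
    else:
        order = list(config.order)
        if set(order) != set(subnets):
            raise ConfigurationError("explicit order must list every organism exactly once")
    orthologs = bundle.orthologs()
    ordered = [subnets[o] for o in order]
    pin, round_stats = integrate.integrate_all(ordered, orthologs)
    integrate.write_pin(pin, out / "pin_edges.tsv", out / "pin_nodes.tsv")
    integrate.write_round_stats(round_stats, out / "integration_stats.tsv")
    histogram = integrate.score_distribution(pin)
    with open(out / "score_histogram.tsv", "w") as fh:
        fh.write("score_lo\tscore_hi\tn_interactions\n")
        for lo, hi, c in histogram:
            fh.write(f"{lo}\t{hi}\t{c}\n")
    high = integrate.extract_high_score(pin, config.high_score_cutoff)
    subnet.write_subnetwork(high, out / "high_score_subnet.tsv")
    stages["integration"] = {
        "order": order,
        "final_nodes": pin.n_nodes,
        "final_edges": pin.n_edges,
        "final_unigenes": len(pin.unigenes),
        "histogram": [[lo, hi, c] for lo, hi, c in histogram],
        "high_score_edges": high.n_edges,
        "rounds": [
            {
                "round": st.round_no,
                "query": st.query_organism,
                "n1": st.n1,
                "n2": st.n2,
                "m1": st.m1,
                "m2": st.m2,
                "final_node": st.final_node_count,
                "final_edge": st.final_edge_count,
            }
            for st in round_stats
        ],
    }
    logger.info("integrated PIN: %d nodes, %d edges", pin.n_nodes, pin.n_edges)

    # stage 5: GO branch sub-network
    go = ontology.parse_obo(fixture_dir / "go.obo")
    annotations = ontology.AnnotationTable.from_rows(
        zip(bundle.go_annotations["protein"], bundle.go_annotations["go_term"])
    )
    annotations.validate_against(go)
    branch = ontology.branch_members(go, config.branch_term)
    branch_net = ontology.extract_branch_subnetwork(pin, annotations, branch)
    subnet.write_subnetwork(branch_net, out / "immune_subnet.tsv")
    components = ontology.connected_components(branch_net)
    with open(out / "components.tsv", "w") as fh:
        fh.write("component\tn_proteins\tn_interactions\tmembers\n")
        for i, (nodes, n_edges) in enumerate(components, start=1):
            fh.write(f"{i}\t{len(nodes)}\t{n_edges}\t{';'.join(sorted(nodes))}\n")
    levels = ontology.level_summary(annotations, go, level=config.go_level)
    pd.DataFrame(
        [(t, go.name_of(t), c) for t, c in sorted(levels.items())],
        columns=["term", "name", "n_proteins"],
    ).to_csv(out / "level_summary.tsv", sep="\t", index=False)
    n_members, fraction, per_pathway = ontology.pathway_membership_summary(
        branch_net, bundle.pathways, category="signaling"
    )
    stages["branch"] = {
        "term": config.branch_term,
        "branch_terms": len(branch),
        "n_proteins": branch_net.n_proteins,
        "n_interactions": branch_net.n_edges,
        "largest_component": [len(components[0][0]), components[0][1]] if components else [0, 0],
        "signaling_members": n_members,
        "signaling_pct": round(100 * fraction, 1),
        "per_pathway": per_pathway,
    }

    # stage 6: evolutionary age groups
    grouping = evoage.AgeGrouping.from_table(bundle.age_groups)
    origins = evoage.assign_origins(
        bundle.protein_presence(), bundle.edge_presence(), grouping, branch_net.edges
    )
    origins.to_frame().to_csv(out / "origins.tsv", sep="\t", index=False)
    age_matrix = evoage.pathway_age_distribution(
        origins, bundle.pathways, min_proteins=config.min_pathway_proteins
    )
    age_matrix.to_csv(out / "pathway_age_matrix.tsv", sep="\t", index=False)
    stages["evoage"] = {
        "dated_proteins": len(origins.protein_group),
        "dated_interactions": len(origins.edge_origin),
        "pathways_analyzed": list(age_matrix["pathway"]) if len(age_matrix) else [],
    }

    # stage 7: neighbour annotation
    result = annotate_mod.neighbor_annotate(
        pin, annotations, vote_fraction=config.vote_fraction, min_support=config.min_support
    )
    annotate_mod.propagate_to_unigenes(result, pin, annotations)
    with open(out / "new_annotations.tsv", "w") as fh:
        fh.write("entity\tentity_type\tterm\tsupport\n")
        for pid in sorted(result.protein_terms):
            for term, support in sorted(result.protein_terms[pid].items()):
                fh.write(f"{pid}\tprotein\t{term}\t{support}\n")
        for u in sorted(result.unigene_terms):
            for term in sorted(result.unigene_terms[u]):
                fh.write(f"{u}\tunigene\t{term}\t\n")
    coverage = annotate_mod.coverage_report(pin, result)
    pd.DataFrame(coverage.summary_rows()).to_csv(out / "coverage.tsv", sep="\t", index=False)
    depth_hist = annotate_mod.depth_histogram(result, go)
    with open(out / "depth_histogram.tsv", "w") as fh:
        fh.write("entity_type\tdepth\tcount\n")
        for kind in ("protein", "unigene"):
            for depth in sorted(depth_hist[kind]):
                fh.write(f"{kind}\t{depth}\t{depth_hist[kind][depth]}\n")
    stages["annotation"] = {
        "newly_annotated_proteins": coverage.n_proteins_newly_annotated,
        "newly_annotated_unigenes": coverage.n_unigenes_newly_annotated,
        "protein_recovery_pct": round(100 * coverage.protein_recovery_fraction, 1),
        "unigene_recovery_pct": round(100 * coverage.unigene_recovery_fraction, 1),
    }

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    manifest["wall_seconds"] = round(time.monotonic() - t0, 2)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
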