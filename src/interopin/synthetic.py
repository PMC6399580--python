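"""Synthetic input fixtures with the statistical structure the pipeline assumes.

Generates, from one seed, a mutually consistent set of inputs: several
reference organisms with overlapping heavy-tailed interactomes in the
STRING ``protein.links`` dialect, BLAST tabular homology hits whose
E-values straddle the selection cutoff, a small biological-process GO DAG
containing an immune-system-process branch, an ID-mapping table, a
cross-organism ortholog table chained across consecutive organisms, an
ortholog presence/absence matrix over organisms partitioned into ordered
age groups, and a pathway-membership table.

Proteins are indexed consistently across organisms (``<taxid>.P<j>``);
ortholog chains between consecutive organisms run over a random shared
subset of indices, so full, partial and broken chains all occur and the
integration exercises protein-match scores 2, 1 and 0. Unigene-to-protein
hits are generated per index in one of four modes: one unigene shared by
all organisms' copies (score-2 matches), two unigenes split across a cut
in the organism chain (score-1 matches), two unigenes on the same protein
(the many-unigenes-per-protein case), or hits that all fail the E-value
cutoff (exercising the homolog filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from interopin.errors import ConfigurationError
from interopin.homology import BlastHit, parse_blast_tab
from interopin.integrate import OrthologTable
from interopin.subnet import ReferenceInteractome, parse_links

BACKBONE_FRACTION = 0.6  # share of each organism's edges drawn from the common backbone
ANNOTATED_FRACTION = 0.45  # fraction of protein indices given prior GO annotations
HIGH_SCORE_FRACTION = 0.8  # links rows at combined_score >= 900

LEVEL1_TERMS = [
    ("GO:0002376", "immune system process"),
    ("GO:0008152", "metabolic process"),
    ("GO:0009987", "cellular process"),
    ("GO:0065007", "biological regulation"),
    ("GO:0032502", "developmental process"),
    ("GO:0050896", "response to stimulus"),
]
ROOT_TERM = ("GO:0008150", "biological_process")

SIGNALING_PATHWAYS = ["Ras", "Rap1", "MAPK", "NF-kappaB", "HIF-1", "PI3K-Akt"]
METABOLIC_PATHWAYS = ["Glycolysis", "Oxidative phosphorylation"]


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and scale of one synthetic fixture."""

    n_organisms: int = 7
    n_proteins_per_organism: int = 200
    n_unigenes: int = 400
    edge_density: float = 0.05
    ortholog_overlap: float = 0.8
    e_value_range: tuple[float, float] = (1e-180, 1e-3)
    n_go_terms: int = 60
    n_age_groups: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_organisms", "n_proteins_per_organism", "n_unigenes", "n_go_terms", "n_age_groups"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("edge_density", "ortholog_overlap"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name}={v} outside (0, 1]")
        if self.n_go_terms < len(LEVEL1_TERMS) + 5:
            raise ConfigurationError(
                f"n_go_terms must be >= {len(LEVEL1_TERMS) + 5} to host the branch structure"
            )
        n_shared = round(self.ortholog_overlap * self.n_proteins_per_organism)
        if n_shared > self.n_proteins_per_organism:
            raise ConfigurationError("ortholog_overlap requires more shared proteins than exist")
        lo, hi = self.e_value_range
        if not 0 < lo < hi:
            raise ConfigurationError(f"invalid e_value_range ({lo}, {hi})")


@dataclass
class FixtureBundle:
    """All generated inputs, in memory."""

    config: FixtureConfig
    organisms: list[str]  # taxids, closest relative first (integration rank order)
    interactomes: list[ReferenceInteractome]
    homology_hits: list[BlastHit]
    go_obo: str
    go_annotations: pd.DataFrame  # protein, go_term
    id_map: pd.DataFrame  # protein, accession, name
    ortholog_table: pd.DataFrame  # protein_a, protein_b
    presence: pd.DataFrame  # entity, entity_type, one column per organism (0/1)
    age_groups: pd.DataFrame  # organism, group
    pathways: pd.DataFrame  # protein, pathway, category

    def phylo_ranks(self) -> dict[str, int]:
        return {org: i + 1 for i, org in enumerate(self.organisms)}

    def orthologs(self) -> OrthologTable:
        return OrthologTable(zip(self.ortholog_table["protein_a"], self.ortholog_table["protein_b"]))

    def protein_presence(self) -> pd.DataFrame:
        df = self.presence[self.presence["entity_type"] == "protein"]
        return df.set_index("entity")[self.organisms].astype(bool)

    def edge_presence(self) -> pd.DataFrame:
        df = self.presence[self.presence["entity_type"] == "interaction"]
        return df.set_index("entity")[self.organisms].astype(bool)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FixtureBundle):
            return NotImplemented
        return (
            self.organisms == other.organisms
            and self.interactomes == other.interactomes
            and self.homology_hits == other.homology_hits
            and self.go_obo == other.go_obo
            and self.go_annotations.equals(other.go_annotations)
            and self.id_map.equals(other.id_map)
            and self.ortholog_table.equals(other.ortholog_table)
            and self.presence.equals(other.presence)
            and self.age_groups.equals(other.age_groups)
            and self.pathways.equals(other.pathways)
        )


def _pid(taxid: str, j: int) -> str:
    return f"{taxid}.P{j:04d}"


def _sample_weighted_edges(
    rng: np.random.Generator, n: int, n_edges: int, exclude: set[tuple[int, int]] | None = None
) -> list[tuple[int, int]]:
    """Sample distinct undirected index pairs with heavy-tailed endpoint weights.

    Preferential weighting (w_i ~ rank^-0.7) yields hub-dominated degree
    sequences like those of curated interactomes.
    """
    exclude = exclude or set()
    n_edges = min(n_edges, n * (n - 1) // 2 - len(exclude))
    w = (np.arange(1, n + 1, dtype=float)) ** -0.7
    w /= w.sum()
    edges: set[tuple[int, int]] = set()
    attempts = 0
    max_attempts = 50 * max(n_edges, 1) + 1000
    while len(edges) < n_edges and attempts < max_attempts:
        a, b = rng.choice(n, size=2, p=w)
        attempts += 1
        if a == b:
            continue
        pair = (int(min(a, b)), int(max(a, b)))
        if pair in exclude or pair in edges:
            continue
        edges.add(pair)
    if len(edges) < n_edges:  # dense corner: fill uniformly
        all_pairs = [
            (a, b)
            for a in range(n)
            for b in range(a + 1, n)
            if (a, b) not in exclude and (a, b) not in edges
        ]
        idx = rng.choice(len(all_pairs), size=n_edges - len(edges), replace=False)
        edges.update(all_pairs[i] for i in sorted(idx))
    return sorted(edges)


def _make_go_dag(rng: np.random.Generator, n_terms: int) -> tuple[str, list[str], set[str]]:
    """Build OBO text; return (obo text, non-root term ids, immune-branch ids)."""
    terms: list[tuple[str, str, list[str]]] = [(ROOT_TERM[0], ROOT_TERM[1], [])]
    for tid, name in LEVEL1_TERMS:
        terms.append((tid, name, [ROOT_TERM[0]]))
    immune = {LEVEL1_TERMS[0][0]}
    n_extra = n_terms - len(terms)
    for k in range(n_extra):
        tid = f"GO:09{k:05d}"
        if k < 5:  # guarantee a non-trivial immune branch
            parent_pool = sorted(immune)
        else:
            parent_pool = [t[0] for t in terms[1:]]
        parents = [parent_pool[int(rng.integers(len(parent_pool)))]]
        if rng.random() < 0.2 and len(terms) > 2:  # diamond: a second parent
            others = [t[0] for t in terms[1:] if t[0] != parents[0]]
            parents.append(others[int(rng.integers(len(others)))])
        if any(p in immune for p in parents):
            immune.add(tid)
        terms.append((tid, f"synthetic process {k}", parents))

    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for tid, name, parents in terms:
        lines += [f"[Term]", f"id: {tid}", f"name: {name}", "namespace: biological_process"]
        for p in parents:
            lines += [f"is_a: {p} ! parent"]
        lines.append("")
    # one obsolete stanza, to be skipped by parsers
    lines += ["[Term]", "id: GO:0999999", "name: obsolete synthetic term", "is_obsolete: true", ""]
    non_root = [t[0] for t in terms[1:]]
    return "\n".join(lines) + "\n", non_root, immune


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Generate one deterministic fixture bundle from the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_org = config.n_organisms
    n_prot = config.n_proteins_per_organism
    taxids = [str(9001 + i) for i in range(n_org)]

    # --- ortholog chains over consecutive organisms -----------------------
    n_shared = round(config.ortholog_overlap * n_prot)
    shared: list[set[int]] = []
    for i in range(max(n_org - 1, 0)):
        idx = rng.choice(n_prot, size=n_shared, replace=False)
        shared.append({int(x) for x in idx})
    ortho_rows = [
        (_pid(taxids[i], j), _pid(taxids[i + 1], j))
        for i in range(n_org - 1)
        for j in sorted(shared[i])
    ]

    # --- interactomes: shared backbone + per-organism edges ---------------
    total_target = config.edge_density * n_prot * (n_prot - 1) / 2
    n_backbone = round(total_target * BACKBONE_FRACTION)
    n_extra = round(total_target * (1 - BACKBONE_FRACTION))
    backbone = _sample_weighted_edges(rng, n_prot, n_backbone)
    backbone_set = set(backbone)
    interactomes: list[ReferenceInteractome] = []
    org_edges: list[list[tuple[int, int]]] = []
    for i, taxid in enumerate(taxids):
        extra = _sample_weighted_edges(rng, n_prot, n_extra, exclude=backbone_set)
        edges = sorted(backbone_set | set(extra))
        # connect isolated indices so every protein appears in the links file
        used = {x for e in edges for x in e}
        for j in range(n_prot):
            if j not in used and n_prot > 1:
                other = int(rng.integers(n_prot - 1))
                if other >= j:
                    other += 1
                edges.append((min(j, other), max(j, other)))
        edges = sorted(set(edges))
        inter = ReferenceInteractome(organism_id=taxid)
        for a, b in edges:
            if rng.random() < HIGH_SCORE_FRACTION:
                score = int(rng.integers(900, 1000))
            else:
                score = int(rng.integers(400, 900))
            inter.add_edge(_pid(taxid, a), _pid(taxid, b), score)
        interactomes.append(inter)
        org_edges.append(edges)

    # --- unigene hits straddling the E-value cutoff -----------------------
    lo, hi = config.e_value_range
    log_lo = math.log10(max(lo, 1e-180))
    log_hi = math.log10(hi)

    def passing_e() -> float:
        return float(f"{10 ** rng.uniform(log_lo, min(-12.0, log_hi)):.2e}")

    def failing_e() -> float:
        return float(f"{10 ** rng.uniform(max(-9.0, log_lo), log_hi):.2e}")

    unigene_counter = 0

    def next_unigene() -> str:
        nonlocal unigene_counter
        name = f"u{unigene_counter % config.n_unigenes:05d}"
        unigene_counter += 1
        return name

    def make_hit(unigene: str, taxid: str, j: int, e: float, bit_penalty: float = 0.0) -> BlastHit:
        length = int(rng.integers(80, 500))
        pident = float(f"{rng.uniform(30, 95):.2f}")
        bit = max(25.0, float(f"{60 - 2 * math.log10(e) + rng.normal(0, 2) - bit_penalty:.1f}"))
        qs = int(rng.integers(1, 100))
        return BlastHit(
            query_id=unigene,
            subject_id=_pid(taxid, j),
            percent_identity=pident,
            alignment_length=length,
            mismatches=int(length * (100 - pident) / 100),
            gap_opens=int(rng.integers(0, 5)),
            q_start=qs,
            q_end=qs + 3 * length,
            s_start=1,
            s_end=length,
            e_value=e,
            bit_score=bit,
        )

    hits_by_block: dict[tuple[str, str], list[BlastHit]] = {}

    def add_hit(hit: BlastHit) -> None:
        hits_by_block.setdefault((hit.query_id, hit.subject_organism), []).append(hit)

    modes = rng.choice(
        ["shared", "split", "multi", "none"], size=n_prot, p=[0.6, 0.15, 0.1, 0.15]
    )
    for j in range(n_prot):
        mode = str(modes[j])
        if mode == "shared":
            u = next_unigene()
            for taxid in taxids:
                add_hit(make_hit(u, taxid, j, passing_e()))
        elif mode == "split" and n_org > 1:
            u1, u2 = next_unigene(), next_unigene()
            cut = int(rng.integers(1, n_org))
            for i, taxid in enumerate(taxids):
                add_hit(make_hit(u1 if i < cut else u2, taxid, j, passing_e()))
        elif mode == "multi":
            u1, u2 = next_unigene(), next_unigene()
            for taxid in taxids:
                add_hit(make_hit(u1, taxid, j, passing_e()))
                add_hit(make_hit(u2, taxid, j, passing_e(), bit_penalty=10.0))
        else:  # none / degenerate single organism split
            u = next_unigene()
            n_orgs_hit = int(rng.integers(1, min(3, n_org) + 1))
            for i in sorted(rng.choice(n_org, size=n_orgs_hit, replace=False)):
                add_hit(make_hit(u, taxids[int(i)], j, failing_e()))
        # decoy secondary hits at worse E-values exercise the first-hit rule
        if rng.random() < 0.25 and n_prot > 1:
            other = int(rng.integers(n_prot - 1))
            if other >= j:
                other += 1
            taxid = taxids[int(rng.integers(n_org))]
            block = [h for (q, o), hs in hits_by_block.items() if o == taxid for h in hs if any(
                h2.subject_id == _pid(taxid, j) for h2 in hs)]
            if block:
                u = block[0].query_id
                add_hit(make_hit(u, taxid, other, failing_e(), bit_penalty=30.0))

    homology_hits: list[BlastHit] = []
    for key in sorted(hits_by_block):
        block = sorted(hits_by_block[key], key=lambda h: -h.bit_score)
        homology_hits.extend(block)

    # --- GO DAG, annotations ---------------------------------------------
    go_obo, non_root_terms, immune_terms = _make_go_dag(rng, config.n_go_terms)
    immune_sorted = sorted(immune_terms)
    ann_rows: list[tuple[str, str]] = []
    for j in range(n_prot):
        force_immune = j < 8
        if not force_immune and rng.random() > ANNOTATED_FRACTION:
            continue
        n_terms = int(rng.integers(1, 4))
        chosen = {non_root_terms[int(k)] for k in rng.choice(len(non_root_terms), size=n_terms)}
        if force_immune:
            chosen.add(immune_sorted[int(rng.integers(len(immune_sorted)))])
        for taxid in taxids:
            for t in sorted(chosen):
                ann_rows.append((_pid(taxid, j), t))
    go_annotations = pd.DataFrame(ann_rows, columns=["protein", "go_term"])

    # --- id map -----------------------------------------------------------
    id_rows = []
    for i, taxid in enumerate(taxids):
        for j in range(n_prot):
            if rng.random() < 0.7:
                id_rows.append((_pid(taxid, j), f"ACC{taxid}{j:04d}", f"prot{j}_{taxid}"))
    id_map = pd.DataFrame(id_rows, columns=["protein", "accession", "name"])

    # --- age groups (nested-clade: first organism nearest => latest group) -
    k = config.n_age_groups
    group_of_org = {
        taxids[i]: f"G{k - (i * k) // max(n_org, 1)}" for i in range(n_org)
    }
    age_groups = pd.DataFrame(
        [(t, group_of_org[t]) for t in taxids], columns=["organism", "group"]
    )

    # --- presence matrix (protein and interolog rows) ----------------------
    def chain_run(i0: int, j: int) -> set[int]:
        run = {i0}
        i = i0
        while i - 1 >= 0 and j in shared[i - 1]:
            i -= 1
            run.add(i)
        i = i0
        while i < n_org - 1 and j in shared[i]:
            i += 1
            run.add(i)
        return run

    presence_rows: list[dict[str, object]] = []
    runs_from_first: dict[int, set[int]] = {}
    for i, taxid in enumerate(taxids):
        for j in range(n_prot):
            run = chain_run(i, j)
            if i == 0:
                runs_from_first[j] = run
            row: dict[str, object] = {"entity": _pid(taxid, j), "entity_type": "protein"}
            for ii, t in enumerate(taxids):
                row[t] = int(ii in run)
            presence_rows.append(row)
    for a, b in backbone:  # interolog rows keyed by the first organism's ids
        ra, rb = runs_from_first[a], runs_from_first[b]
        ea, eb = sorted((_pid(taxids[0], a), _pid(taxids[0], b)))
        row = {"entity": f"{ea}|{eb}", "entity_type": "interaction"}
        for ii, t in enumerate(taxids):
            row[t] = int(ii in ra and ii in rb)
        presence_rows.append(row)
    for i, taxid in enumerate(taxids):
        extra_only = sorted(set(org_edges[i]) - backbone_set)
        for a, b in extra_only:
            ea, eb = sorted((_pid(taxid, a), _pid(taxid, b)))
            row = {"entity": f"{ea}|{eb}", "entity_type": "interaction"}
            for ii, t in enumerate(taxids):
                row[t] = int(ii == i)
            presence_rows.append(row)
    presence = pd.DataFrame(presence_rows, columns=["entity", "entity_type", *taxids])

    # --- pathways -----------------------------------------------------------
    pathway_rows: list[tuple[str, str, str]] = []
    sig_size = max(12, n_prot // 10)
    for name in SIGNALING_PATHWAYS:
        members = sorted(int(x) for x in rng.choice(n_prot, size=min(sig_size, n_prot), replace=False))
        for j in members:
            for taxid in taxids:
                pathway_rows.append((_pid(taxid, j), name, "signaling"))
    for name, size in zip(METABOLIC_PATHWAYS, (8, 6)):
        members = sorted(int(x) for x in rng.choice(n_prot, size=min(size, n_prot), replace=False))
        for j in members:
            for taxid in taxids:
                pathway_rows.append((_pid(taxid, j), name, "metabolic"))
    pathways = pd.DataFrame(pathway_rows, columns=["protein", "pathway", "category"])

    ortholog_table = pd.DataFrame(ortho_rows, columns=["protein_a", "protein_b"])
    return FixtureBundle(
        config=config,
        organisms=taxids,
        interactomes=interactomes,
        homology_hits=homology_hits,
        go_obo=go_obo,
        go_annotations=go_annotations,
        id_map=id_map,
        ortholog_table=ortholog_table,
        presence=presence,
        age_groups=age_groups,
        pathways=pathways,
    )


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> list[dict[str, object]]:
    """Write the bundle in the standard dialects; return a file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[dict[str, object]] = []

    def record(path: Path, fmt: str, rows: int) -> None:
        manifest.append({"path": str(path), "format": fmt, "rows": rows})

    for inter in bundle.interactomes:
        path = directory / f"{inter.organism_id}.protein.links.txt"
        with open(path, "w") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for (a, b), score in sorted(inter.edges.items()):
                fh.write(f"{a} {b} {score}\n")
        record(path, "string-links", len(inter.edges))

    path = directory / "hits.outfmt6.tsv"
    with open(path, "w") as fh:
        for hit in bundle.homology_hits:
            fh.write("\t".join(hit.to_row()) + "\n")
    record(path, "blast-outfmt6", len(bundle.homology_hits))

    path = directory / "go.obo"
    path.write_text(bundle.go_obo)
    record(path, "obo", bundle.go_obo.count("[Term]"))

    for name, df in (
        ("go_annotations.tsv", bundle.go_annotations),
        ("idmap.tsv", bundle.id_map),
        ("orthologs.tsv", bundle.ortholog_table),
        ("presence.tsv", bundle.presence),
        ("age_groups.tsv", bundle.age_groups),
        ("pathways.tsv", bundle.pathways),
    ):
        path = directory / name
        df.to_csv(path, sep="\t", index=False)
        record(path, "tsv", len(df))
    return manifest


def read_fixture(directory: str | Path) -> FixtureBundle:
    """Re-parse a written fixture directory into an in-memory bundle."""
    directory = Path(directory)
    link_files = sorted(directory.glob("*.protein.links.txt"))
    interactomes = [parse_links(p) for p in link_files]
    age_groups = pd.read_csv(directory / "age_groups.tsv", sep="\t", dtype=str)
    organisms = list(age_groups["organism"])
    presence = pd.read_csv(directory / "presence.tsv", sep="\t", dtype={"entity": str, "entity_type": str})
    interactomes.sort(key=lambda x: organisms.index(x.organism_id))
    return FixtureBundle(
        config=FixtureConfig(n_organisms=len(interactomes)),
        organisms=organisms,
        interactomes=interactomes,
        homology_hits=parse_blast_tab(directory / "hits.outfmt6.tsv"),
        go_obo=(directory / "go.obo").read_text(),
        go_annotations=pd.read_csv(directory / "go_annotations.tsv", sep="\t", dtype=str),
        id_map=pd.read_csv(directory / "idmap.tsv", sep="\t", dtype=str),
        ortholog_table=pd.read_csv(directory / "orthologs.tsv", sep="\t", dtype=str),
        presence=presence,
        age_groups=age_groups,
        pathways=pd.read_csv(directory / "pathways.tsv", sep="\t", dtype=str),
    )
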