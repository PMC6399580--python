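"""Per-organism interaction sub-networks from a reference interactome.

A reference interactome (STRING ``protein.links`` dialect: integer combined
scores 0-999, i.e. confidence probability x 1000) is confidence-filtered
and intersected with the homology map: only interactions whose BOTH
endpoint proteins are homologous to at least one unigene survive. Each
surviving node carries its unigene set; nodes without any surviving edge
are dropped (the result is a network, not a catalogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from interopin.errors import FormatError, IdentifierMismatchError, MappingError
from interopin.homology import HomologyMap

DEFAULT_MIN_COMBINED = 900  # STRING "highest confidence" 0.9


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceInteractome:
    """One organism's proteins and confidence-scored undirected interactions."""

    organism_id: str
    proteins: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, combined_score: int) -> None:
        if a == b:
            raise FormatError(f"self-loop on {a}")
        if not 0 <= combined_score <= 999:
            raise FormatError(f"combined_score {combined_score} outside 0-999")
        self.proteins.add(a)
        self.proteins.add(b)
        self.edges[canonical_edge(a, b)] = combined_score

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceInteractome):
            return NotImplemented
        return (
            self.organism_id == other.organism_id
            and self.proteins == other.proteins
            and self.edges == other.edges
        )


@dataclass
class NodeInfo:
    """A sub-network node: its unigene associations and display label."""

    unigenes: set[str]
    label: str = ""
    e_value: float = float("inf")  # best homology E-value; merge tie-break


@dataclass
class SubNetwork:
    """An organism-tagged network whose nodes carry unigene associations."""

    organism_id: str
    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_proteins(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_unigenes(self) -> int:
        return len(set().union(*(n.unigenes for n in self.nodes.values()), set()))

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_unigenes, self.n_proteins, self.n_edges)


def parse_links(path: str | Path, organism_id: str | None = None) -> ReferenceInteractome:
    """Parse a STRING ``protein.links`` file (space-separated, header line).

    The organism id defaults to the taxid prefix of the first protein id
    (STRING ids are ``<taxid>.<local id>``).
    """
    inter: ReferenceInteractome | None = None
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["protein1", "protein2", "combined_score"]:
            raise FormatError(f"{path}: unexpected links header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            a, b, score = parts[0], parts[1], int(parts[2])
            if inter is None:
                inter = ReferenceInteractome(organism_id or a.split(".", 1)[0])
            inter.add_edge(a, b, score)
    if inter is None:
        inter = ReferenceInteractome(organism_id or Path(path).name.split(".", 1)[0])
    return inter


def write_links(inter: ReferenceInteractome, path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for (a, b), score in sorted(inter.edges.items()):
            fh.write(f"{a} {b} {score}\n")
    return len(inter.edges)


def filter_confidence(
    interactome: ReferenceInteractome, min_combined: int = DEFAULT_MIN_COMBINED
) -> ReferenceInteractome:
    """Keep only edges with ``combined_score >= min_combined``.

    The default 900 corresponds to STRING's highest-confidence limit 0.9.
    The protein set is left untouched.
    """
    kept = {e: s for e, s in interactome.edges.items() if s >= min_combined}
    return ReferenceInteractome(
        organism_id=interactome.organism_id,
        proteins=set(interactome.proteins),
        edges=kept,
    )


def extract_subnetwork(
    interactome: ReferenceInteractome, homology: HomologyMap
) -> SubNetwork:
    """Keep interactions whose BOTH endpoints are homologous to unigenes.

    Nodes are the proteins that carry at least one mapped unigene and at
    least one surviving edge; each node records its unigene set and the
    best homology E-value among them.
    """
    org = interactome.organism_id
    if homology.forward and org not in homology.forward:
        raise IdentifierMismatchError(
            f"homology map covers organisms {homology.organisms()}, not {org!r}"
        )
    mapped = homology.inverse.get(org, {})
    sub = SubNetwork(organism_id=org)
    for (a, b) in sorted(interactome.edges):
        if a in mapped and b in mapped:
            sub.edges.add((a, b))
            for p in (a, b):
                if p not in sub.nodes:
                    sub.nodes[p] = NodeInfo(
                        unigenes=set(mapped[p]),
                        label=p,
                        e_value=homology.best_evalue(org, p),
                    )
    return sub


def read_id_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read ``idmap.tsv`` rows (protein, accession, name)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein\t"):
            raise FormatError(f"{path}: missing idmap header")
        for line in fh:
            protein, accession, name = line.rstrip("\n").split("\t")
            if protein in out and out[protein] != (accession, name):
                raise MappingError(f"conflicting idmap rows for {protein}")
            out[protein] = (accession, name)
    return out


def label_nodes(subnetwork: SubNetwork, id_map: dict[str, tuple[str, str]]) -> SubNetwork:
    """Label nodes with accession/name when mapped, else the internal id.

    Mirrors the convention of falling back to the database-internal
    (STRING) identifier for proteins without an accession.
    """
    for pid, info in subnetwork.nodes.items():
        if pid in id_map:
            accession, name = id_map[pid]
            info.label = f"{accession}|{name}" if name else accession
        else:
            info.label = pid
    return subnetwork


def write_subnetwork(sub: SubNetwork, path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(sub.edges):
            fh.write(f"{a}\t{b}\n")
    return len(sub.edges)
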