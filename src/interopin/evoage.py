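"""Evolutionary age-group dating of proteins and interactions.

Organisms are partitioned into ordered phylostrata (age groups G1..Gk,
G1 the earliest-diverging outgroup, Gk the nearest relatives). A protein
is dated to the earliest group containing an organism where an ortholog
is present; an interaction's origin is the LATEST group among the edge's
own appearance group and the two endpoint protein groups — the
interaction cannot predate its last-appearing component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from interopin.errors import ConfigurationError, UndatedError
from interopin.subnet import canonical_edge

logger = logging.getLogger(__name__)


@dataclass
class AgeGrouping:
    """Ordered age groups and the organism -> group assignment."""

    groups: list[str]  # ordered, earliest (G1) first
    organism_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.organism_group.values()) - set(self.groups)
        if unknown:
            raise ConfigurationError(f"organisms assigned to unknown groups {sorted(unknown)}")

    @classmethod
    def from_table(cls, df: pd.DataFrame, groups: Sequence[str] | None = None) -> "AgeGrouping":
        mapping = dict(zip(df["organism"].astype(str), df["group"].astype(str)))
        if groups is None:
            groups = sorted(set(mapping.values()))
        return cls(groups=list(groups), organism_group=mapping)

    def index(self, group: str) -> int:
        return self.groups.index(group)

    def group_of(self, organism: str) -> str:
        if organism not in self.organism_group:
            raise ConfigurationError(f"organism {organism!r} has no age group")
        return self.organism_group[organism]


def protein_age(presence_row: Mapping[str, bool], grouping: AgeGrouping) -> str:
    """Earliest age group among the organisms where the entity is present."""
    present = [org for org, flag in presence_row.items() if flag]
    if not present:
        raise UndatedError("all-absent presence row cannot be dated")
    return min((grouping.group_of(o) for o in present), key=grouping.index)


def interaction_origin(edge_group: str, group_a: str, group_b: str, grouping: AgeGrouping) -> str:
    """Origin of an interaction: the latest of edge and endpoint groups."""
    return max((edge_group, group_a, group_b), key=grouping.index)


@dataclass
class OriginAssignment:
    """Dated proteins and interactions."""

    groups: list[str] = field(default_factory=list)  # ordered, earliest first
    protein_group: dict[str, str] = field(default_factory=dict)
    edge_origin: dict[tuple[str, str], str] = field(default_factory=dict)
    edge_components: dict[tuple[str, str], tuple[str, str, str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_a": a,
                "protein_b": b,
                "edge_group": self.edge_components[(a, b)][0],
                "group_a": self.edge_components[(a, b)][1],
                "group_b": self.edge_components[(a, b)][2],
                "origin": self.edge_origin[(a, b)],
            }
            for (a, b) in sorted(self.edge_origin)
        ]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "edge_group", "group_a", "group_b", "origin"])


def assign_origins(
    protein_presence: pd.DataFrame,
    edge_presence: pd.DataFrame,
    grouping: AgeGrouping,
    edges: Iterable[tuple[str, str]],
) -> OriginAssignment:
    """Date every protein and interaction from presence/absence rows.

    ``protein_presence`` is indexed by protein id; ``edge_presence`` by
    ``"a|b"`` with canonically ordered endpoints; columns are organisms
    (booleans). An edge without its own presence row falls back to the
    intersection of its endpoints' rows (the interolog can exist only
    where both partners do).
    """
    out = OriginAssignment(groups=list(grouping.groups))
    cols = list(protein_presence.columns)
    for protein in protein_presence.index:
        row = protein_presence.loc[protein]
        try:
            out.protein_group[protein] = protein_age(dict(zip(cols, row.astype(bool))), grouping)
        except UndatedError:
            logger.warning("protein %s has an all-absent presence row; left undated", protein)
    for a, b in sorted(canonical_edge(a, b) for a, b in edges):
        if a not in out.protein_group or b not in out.protein_group:
            logger.warning("edge %s|%s has an undatable endpoint; skipped", a, b)
            continue
        key = f"{a}|{b}"
        if key in edge_presence.index:
            row = edge_presence.loc[key].astype(bool)
        else:
            row = protein_presence.loc[a].astype(bool) & protein_presence.loc[b].astype(bool)
        try:
            edge_group = protein_age(dict(zip(cols, row)), grouping)
        except UndatedError:
            logger.warning("edge %s|%s present nowhere; skipped", a, b)
            continue
        ga, gb = out.protein_group[a], out.protein_group[b]
        out.edge_components[(a, b)] = (edge_group, ga, gb)
        out.edge_origin[(a, b)] = interaction_origin(edge_group, ga, gb, grouping)
    return out


def pathway_age_distribution(
    origins: OriginAssignment,
    pathway_table: pd.DataFrame,
    pathways: Sequence[str] | None = None,
    min_proteins: int = 10,
) -> pd.DataFrame:
    """Interaction counts and fractions per pathway and age group.

    A pathway's interactions are the dated edges with BOTH endpoints in
    the pathway. By default pathways with more than ``min_proteins``
    member proteins (among dated proteins) are analysed; pathways with no
    qualifying interaction are excluded with a warning. Fractions within
    a pathway sum to 1.
    """
    members_of: dict[str, set[str]] = {}
    for _, row in pathway_table.iterrows():
        members_of.setdefault(row["pathway"], set()).add(row["protein"])
    dated = set(origins.protein_group)
    if pathways is None:
        pathways = sorted(
            p for p, ms in members_of.items() if len(ms & dated) > min_proteins
        )
    groups = _group_order(origins)
    rows = []
    for pathway in pathways:
        members = members_of.get(pathway, set())
        counts = {g: 0 for g in groups}
        total = 0
        for (a, b), origin in origins.edge_origin.items():
            if a in members and b in members:
                counts[origin] += 1
                total += 1
        if total == 0:
            logger.warning("pathway %s has no dated interactions; excluded", pathway)
            continue
        row: dict[str, object] = {"pathway": pathway, "n_interactions": total}
        for g in groups:
            row[f"count_{g}"] = counts[g]
            row[f"frac_{g}"] = counts[g] / total
        rows.append(row)
    return pd.DataFrame(rows)


def _group_order(origins: OriginAssignment) -> list[str]:
    if origins.groups:
        return list(origins.groups)
    return sorted(set(origins.edge_origin.values()) | set(origins.protein_group.values()))
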