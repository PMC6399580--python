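"""Neighbour-based (guilt-by-association) functional annotation.

Proteins without a biological-process GO annotation are assigned the
terms their annotated direct neighbours in the network agree on: a term
is assigned when its support (number of annotated neighbours carrying it)
reaches ``max(min_support, ceil(vote_fraction * annotated neighbours))``.
New protein annotations are then propagated to unigenes by union over a
unigene's proteins. Existing annotations are never altered — the
procedure is a monotone extension.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from interopin.errors import ConfigurationError
from interopin.integrate import IntegratedPIN
from interopin.ontology import AnnotationTable, GOGraph, term_depth


@dataclass
class AnnotationResult:
    """Outcome of neighbour annotation and unigene propagation."""

    protein_terms: dict[str, dict[str, int]] = field(default_factory=dict)  # new terms w/ support
    still_unclassified_proteins: set[str] = field(default_factory=set)
    unigene_terms: dict[str, set[str]] = field(default_factory=dict)
    still_unclassified_unigenes: set[str] = field(default_factory=set)
    previously_unclassified_proteins: set[str] = field(default_factory=set)
    previously_unclassified_unigenes: set[str] = field(default_factory=set)

    def annotated_proteins(self) -> set[str]:
        return set(self.protein_terms)

    def annotated_unigenes(self) -> set[str]:
        return set(self.unigene_terms)


def _adjacency(pin: IntegratedPIN) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {pid: set() for pid in pin.nodes}
    for a, b in pin.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def neighbor_annotate(
    pin: IntegratedPIN,
    annotations: AnnotationTable,
    vote_fraction: float = 0.5,
    min_support: int = 2,
    iterative: bool = False,
    closure: bool = False,
    go: GOGraph | None = None,
) -> AnnotationResult:
    """Annotate unclassified proteins from their annotated neighbours.

    Single pass by default: assignments are decided from the prior
    annotation state only. With ``iterative=True`` passes repeat, feeding
    new annotations back in, until a fixed point. With ``closure=True``
    each neighbour votes with the ancestor closure of its terms
    (requires ``go``).
    """
    if not 0 < vote_fraction <= 1:
        raise ConfigurationError(f"vote_fraction {vote_fraction} outside (0, 1]")
    if closure and go is None:
        raise ConfigurationError("closure voting requires the ontology graph")

    adj = _adjacency(pin)
    known: dict[str, set[str]] = {
        pid: annotations.terms_of(pid) for pid in pin.nodes if annotations.is_classified(pid)
    }
    result = AnnotationResult(
        previously_unclassified_proteins={pid for pid in pin.nodes if pid not in known}
    )

    frontier = set(result.previously_unclassified_proteins)
    while True:
        newly: dict[str, dict[str, int]] = {}
        for pid in sorted(frontier):
            annotated_neighbors = [n for n in adj[pid] if n in known]
            if not annotated_neighbors:
                continue
            votes: Counter[str] = Counter()
            for n in annotated_neighbors:
                terms = known[n]
                if closure and go is not None:
                    expanded: set[str] = set()
                    for t in terms:
                        expanded |= {t} | go.ancestors(t)
                    terms = expanded
                votes.update(terms)
            threshold = max(min_support, math.ceil(vote_fraction * len(annotated_neighbors)))
            assigned = {t: c for t, c in votes.items() if c >= threshold}
            if assigned:
                newly[pid] = assigned
        if not newly:
            break
        for pid, terms in newly.items():
            merged = result.protein_terms.setdefault(pid, {})
            for t, c in terms.items():
                merged[t] = max(merged.get(t, 0), c)
            known[pid] = set(merged)
        frontier -= set(newly)
        if not iterative:
            break

    result.still_unclassified_proteins = (
        result.previously_unclassified_proteins - set(result.protein_terms)
    )
    return result


def propagate_to_unigenes(
    result: AnnotationResult,
    pin: IntegratedPIN,
    annotations: AnnotationTable,
) -> AnnotationResult:
    """Let unclassified unigenes inherit their proteins' terms (by union).

    A unigene counts as previously classified if any of its proteins was
    annotated before neighbour voting; otherwise it inherits the union of
    the terms (prior or new) of its proteins, or stays unclassified.
    """
    unigene_proteins: dict[str, set[str]] = {}
    for pid, node in pin.nodes.items():
        for u in node.unigenes:
            unigene_proteins.setdefault(u, set()).add(pid)

    prior_terms = {pid: annotations.terms_of(pid) for pid in pin.nodes}
    for unigene in sorted(unigene_proteins):
        proteins = unigene_proteins[unigene]
        if any(prior_terms[p] for p in proteins):
            continue  # previously classified via its proteins
        result.previously_unclassified_unigenes.add(unigene)
        inherited: set[str] = set()
        for p in proteins:
            inherited |= set(result.protein_terms.get(p, ()))
        if inherited:
            result.unigene_terms[unigene] = inherited
        else:
            result.still_unclassified_unigenes.add(unigene)
    return result


@dataclass
class CoverageReport:
    """Annotation coverage before/after, per entity class."""

    n_proteins_total: int
    n_proteins_previously_unclassified: int
    n_proteins_newly_annotated: int
    n_unigenes_total: int
    n_unigenes_previously_unclassified: int
    n_unigenes_newly_annotated: int

    @property
    def protein_recovery_fraction(self) -> float:
        d = self.n_proteins_previously_unclassified
        return self.n_proteins_newly_annotated / d if d else 0.0

    @property
    def unigene_recovery_fraction(self) -> float:
        d = self.n_unigenes_previously_unclassified
        return self.n_unigenes_newly_annotated / d if d else 0.0

    @property
    def protein_remaining_unclassified_fraction(self) -> float:
        if not self.n_proteins_total:
            return 0.0
        return (
            self.n_proteins_previously_unclassified - self.n_proteins_newly_annotated
        ) / self.n_proteins_total

    @property
    def unigene_remaining_unclassified_fraction(self) -> float:
        if not self.n_unigenes_total:
            return 0.0
        return (
            self.n_unigenes_previously_unclassified - self.n_unigenes_newly_annotated
        ) / self.n_unigenes_total

    def summary_rows(self) -> list[dict[str, object]]:
        return [
            {
                "entity": "protein",
                "total": self.n_proteins_total,
                "previously_unclassified": self.n_proteins_previously_unclassified,
                "newly_annotated": self.n_proteins_newly_annotated,
                "recovery_pct": round(100 * self.protein_recovery_fraction, 1),
                "remaining_unclassified_pct": round(
                    100 * self.protein_remaining_unclassified_fraction, 1
                ),
            },
            {
                "entity": "unigene",
                "total": self.n_unigenes_total,
                "previously_unclassified": self.n_unigenes_previously_unclassified,
                "newly_annotated": self.n_unigenes_newly_annotated,
                "recovery_pct": round(100 * self.unigene_recovery_fraction, 1),
                "remaining_unclassified_pct": round(
                    100 * self.unigene_remaining_unclassified_fraction, 1
                ),
            },
        ]


def coverage_report(pin: IntegratedPIN, result: AnnotationResult) -> CoverageReport:
    """Fractions of previously unclassified proteins/unigenes now annotated."""
    return CoverageReport(
        n_proteins_total=pin.n_nodes,
        n_proteins_previously_unclassified=len(result.previously_unclassified_proteins),
        n_proteins_newly_annotated=len(result.protein_terms),
        n_unigenes_total=len(pin.unigenes),
        n_unigenes_previously_unclassified=len(result.previously_unclassified_unigenes),
        n_unigenes_newly_annotated=len(result.unigene_terms),
    )


def depth_histogram(
    result: AnnotationResult, go: GOGraph
) -> dict[str, dict[int, int]]:
    """Counts of newly annotated proteins and unigenes per GO term depth.

    An entity with terms at several depths is counted at each distinct
    depth once.
    """
    series: dict[str, dict[int, int]] = {"protein": {}, "unigene": {}}
    for kind, terms_by_entity in (
        ("protein", {p: set(ts) for p, ts in result.protein_terms.items()}),
        ("unigene", result.unigene_terms),
    ):
        for entity in sorted(terms_by_entity):
            depths = {term_depth(go, t) for t in terms_by_entity[entity]}
            for d in depths:
                series[kind][d] = series[kind].get(d, 0) + 1
    return series
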