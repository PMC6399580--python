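"""Unigene-to-reference-protein homology from BLAST tabular output.

Unigenes (assembled transcripts) are aligned against reference proteomes
with BLASTX; the tabular (outfmt 6) hits are parsed here and reduced to a
per-organism homology map with the first-passing-hit rule: for each
unigene and organism, the first hit in aligner output order whose E-value
is strictly below the threshold (default 1e-10) names the homologous
protein. The inverse map (protein -> unigenes) is many-to-many: one
reference protein may be homologous to several unigenes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from interopin.errors import FormatError

logger = logging.getLogger(__name__)

DEFAULT_E_THRESHOLD = 1e-10

BLAST_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular (outfmt 6) output.

    ``subject_id`` is organism-qualified in the STRING style
    (``<taxid>.<local id>``); the organism is the part before the first dot.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"negative E-value {self.e_value} for {self.query_id}")

    @property
    def subject_organism(self) -> str:
        return self.subject_id.split(".", 1)[0]

    def to_row(self) -> list[str]:
        return [
            self.query_id,
            self.subject_id,
            f"{self.percent_identity:.2f}",
            str(self.alignment_length),
            str(self.mismatches),
            str(self.gap_opens),
            str(self.q_start),
            str(self.q_end),
            str(self.s_start),
            str(self.s_end),
            f"{self.e_value:.2e}",
            f"{self.bit_score:.1f}",
        ]


@dataclass
class HomologyMap:
    """Per-organism unigene<->protein correspondences.

    ``forward[org][unigene] = (protein, e_value)`` — at most one protein per
    unigene per organism. ``inverse[org][protein]`` is the set of unigenes
    selecting that protein.
    """

    e_threshold: float = DEFAULT_E_THRESHOLD
    forward: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)
    inverse: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, organism: str, unigene: str, protein: str, e_value: float) -> None:
        fwd = self.forward.setdefault(organism, {})
        if unigene in fwd:
            return
        fwd[unigene] = (protein, e_value)
        self.inverse.setdefault(organism, {}).setdefault(protein, set()).add(unigene)

    def organisms(self) -> list[str]:
        return sorted(self.forward)

    def unigenes_of(self, organism: str, protein: str) -> set[str]:
        return set(self.inverse.get(organism, {}).get(protein, set()))

    def protein_of(self, organism: str, unigene: str) -> str | None:
        entry = self.forward.get(organism, {}).get(unigene)
        return entry[0] if entry else None

    def best_evalue(self, organism: str, protein: str) -> float:
        """Smallest E-value among the unigene hits selecting ``protein``."""
        fwd = self.forward.get(organism, {})
        evs = [ev for u in self.unigenes_of(organism, protein) for p, ev in [fwd[u]] if p == protein]
        return min(evs) if evs else math.inf

    def n_pairs(self) -> int:
        return sum(len(m) for m in self.forward.values())


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a BLAST outfmt-6 file, preserving row order.

    Raises :class:`FormatError` naming the line for rows without exactly
    12 tab-separated fields.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def select_homologs(
    hits: Iterable[BlastHit],
    e_threshold: float = DEFAULT_E_THRESHOLD,
    organisms: Iterable[str] | None = None,
) -> HomologyMap:
    """Reduce ordered hits to a homology map with the first-passing-hit rule.

    For each (unigene, organism) pair the FIRST hit in input order with
    ``e_value`` strictly below ``e_threshold`` is selected — not the best
    one; the aligner emits hits best-first, and that order is trusted. A
    warning is logged if bit scores are not non-increasing within a
    query-organism block. Hits to organisms outside ``organisms`` (when
    given) are ignored, with a logged count.
    """
    allowed = set(organisms) if organisms is not None else None
    hmap = HomologyMap(e_threshold=e_threshold)
    last_bit: dict[tuple[str, str], float] = {}
    n_foreign = 0
    disorder_warned = False
    for hit in hits:
        org = hit.subject_organism
        if allowed is not None and org not in allowed:
            n_foreign += 1
            continue
        key = (hit.query_id, org)
        prev = last_bit.get(key)
        if prev is not None and hit.bit_score > prev and not disorder_warned:
            logger.warning(
                "bit scores not non-increasing within block %s/%s; "
                "keeping file order for the first-hit rule",
                hit.query_id,
                org,
            )
            disorder_warned = True
        last_bit[key] = hit.bit_score
        if hit.e_value < e_threshold:
            hmap.add(org, hit.query_id, hit.subject_id, hit.e_value)
    if n_foreign:
        logger.info("ignored %d hits to organisms outside the configured list", n_foreign)
    return hmap


def write_homology_map(hmap: HomologyMap, path: str | Path) -> int:
    """Write ``homology_map.tsv`` (organism, unigene, protein, e_value)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("organism\tunigene\tprotein\te_value\n")
        for org in hmap.organisms():
            for unigene in sorted(hmap.forward[org]):
                protein, ev = hmap.forward[org][unigene]
                fh.write(f"{org}\t{unigene}\t{protein}\t{ev:.3e}\n")
                n += 1
    return n


def read_homology_map(path: str | Path) -> HomologyMap:
    hmap = HomologyMap()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("organism\t"):
            raise FormatError(f"{path}: missing homology_map header")
        for line in fh:
            org, unigene, protein, ev = line.rstrip("\n").split("\t")
            hmap.add(org, unigene, protein, float(ev))
    return hmap
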