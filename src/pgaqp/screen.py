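"""Candidate-locus discovery from protein-vs-genome homology hits.

High-scoring pairs (HSPs) from a tblastn-style search are filtered on
bit score and e-value, clustered into genomic hot-spots, reduced to one
representative hit per hot-spot, and reconciled with an existing gene
annotation. Hot-spots with no annotation overlap are flagged NOVEL and
handed to de-novo annotation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .io import AnnotatedGene, log

NOVEL = "NOVEL"


@dataclass(frozen=True)
class HspRecord:
    """One homology hit; subject coordinates 1-based, sstart <= send."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.sstart > self.send:
            raise ValueError("HspRecord requires sstart <= send")
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("scores must be non-negative")


@dataclass(frozen=True)
class Hotspot:
    """A cluster of overlapping/nearby HSPs taken as one candidate locus."""

    subject_id: str
    start: int
    end: int
    members: tuple[HspRecord, ...]
    representative: HspRecord


def filter_hsps(
    hsps: Sequence[HspRecord],
    min_bitscore: float = 100.0,
    max_evalue: float = 1e-5,
) -> list[HspRecord]:
    """Keep hits with bitscore >= min_bitscore and evalue <= max_evalue.

    Both thresholds are inclusive; input order is preserved.
    """
    return [h for h in hsps if h.bitscore >= min_bitscore and h.evalue <= max_evalue]


def cluster_hotspots(hsps: Sequence[HspRecord], merge_gap: int = 2000) -> list[Hotspot]:
    """Merge HSPs on the same subject into positional hot-spots.

    Two HSPs share a hot-spot iff they are connected by a chain of pairs
    whose subject intervals overlap or lie within ``merge_gap`` bp.
    Strand is ignored: hot-spots are positional and candidate loci are
    re-annotated downstream. The representative is the member of maximal
    bitscore (ties: lower sstart, then lexicographic query_id).
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    by_subject: dict[str, list[HspRecord]] = {}
    for h in hsps:
        by_subject.setdefault(h.subject_id, []).append(h)

    hotspots: list[Hotspot] = []
    for subject in by_subject:
        members = sorted(by_subject[subject], key=lambda h: (h.sstart, h.send))
        block: list[HspRecord] = []
        block_end = None
        for h in members:
            if block and h.sstart > block_end + merge_gap:
                hotspots.append(_mk_hotspot(subject, block))
                block = []
                block_end = None
            block.append(h)
            block_end = h.send if block_end is None else max(block_end, h.send)
        if block:
            hotspots.append(_mk_hotspot(subject, block))
    return sorted(hotspots, key=lambda hs: (hs.subject_id, hs.start))


def _mk_hotspot(subject: str, block: list[HspRecord]) -> Hotspot:
    rep = min(block, key=lambda h: (-h.bitscore, h.sstart, h.query_id))
    return Hotspot(
        subject_id=subject,
        start=min(h.sstart for h in block),
        end=max(h.send for h in block),
        members=tuple(block),
        representative=rep,
    )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def map_to_annotation(
    hotspots: Sequence[Hotspot], genes: Sequence[AnnotatedGene]
) -> list[tuple[Hotspot, str]]:
    """Map each hot-spot to the annotated gene with maximal bp overlap.

    Zero overlap maps to ``NOVEL`` (an unannotated region, as for the
    paper-scale chromosome-5 case). Ties go to the longer overlapping
    gene, then lexicographic gene_id.
    """
    out: list[tuple[Hotspot, str]] = []
    for hs in hotspots:
        best_id = NOVEL
        best = (0, 0, "")
        for g in genes:
            if g.seq_id != hs.subject_id:
                continue
            ov = _overlap(hs.start, hs.end, g.start, g.end)
            if ov == 0:
                continue
            key = (ov, g.end - g.start + 1, "")
            # ties: bigger overlap, then longer gene, then lexicographically
            # smaller id wins
            if (key[0], key[1]) > (best[0], best[1]) or (
                (key[0], key[1]) == (best[0], best[1])
                and (best_id == NOVEL or g.gene_id < best_id)
            ):
                best = key
                best_id = g.gene_id
        if best_id == NOVEL:
            log.info("hot-spot %s:%d-%d maps to no annotated gene (NOVEL)",
                     hs.subject_id, hs.start, hs.end)
        out.append((hs, best_id))
    return out
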