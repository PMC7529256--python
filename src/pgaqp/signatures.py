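"""Extraction of MIP diagnostic residues from aquaporin proteins.

An aquaporin is recognized by a small set of diagnostic features: two
NPA-class motifs on loops B and E, six transmembrane helices, the four
ar/R selectivity-filter residues (helix 2, helix 5, loop E x2), the five
Froger positions P1-P5, and a handful of regulatory residues on PIPs.
Motif variants are restricted to the seven triplets observed in the
family inventory (NPA, NPS, NPT, NPV, NPI, NPL, TPA); anything else is
not treated as a motif.

Positions of the ar/R, Froger and regulatory residues are transferred by
alignment column from curated reference isoforms rather than located by a
conserved-domain service, which keeps extraction deterministic and
testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils import ProtParamData

from .io import log

NPA_VARIANTS = ("NPA", "NPS", "NPT", "NPV", "NPI", "NPL", "TPA")
GAP = "-"

REGULATORY_SITES = (
    "nter_Lys3", "nter_Glu6", "loopB_Ser", "loopD_His", "cter_Ser280", "cter_Ser283",
)


@dataclass(frozen=True)
class NpaScan:
    """Result of scanning a protein for NPA-class triplets."""

    npa_lb: str
    npa_le: str
    lb_pos: int  # 1-based position of the motif's first residue
    le_pos: int
    n_motifs: int  # total NPA-class triplets seen in the sequence

    @property
    def spacing(self) -> int:
        """Residues strictly between the two motifs."""
        return self.le_pos - self.lb_pos - 3


@dataclass(frozen=True)
class ReferenceIsoform:
    """A curated reference with known signature positions (all 1-based)."""

    id: str
    family: str
    subfamily: str
    sequence: str
    npa_lb_pos: int
    npa_le_pos: int
    arR_pos: tuple[int, int, int, int]
    froger_pos: tuple[int, int, int, int, int]
    regulatory_pos: dict = field(default_factory=dict)

    @property
    def spacing(self) -> int:
        return self.npa_le_pos - self.npa_lb_pos - 3

    def __post_init__(self) -> None:
        for positions in (self.arR_pos, self.froger_pos):
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"{self.id}: curated positions not increasing")
            if positions[-1] > len(self.sequence) or positions[0] < 1:
                raise ValueError(f"{self.id}: curated position out of range")


@dataclass
class SignatureProfile:
    """The full diagnostic-residue profile of one protein."""

    protein_id: str
    npa_lb: str | None = None
    npa_le: str | None = None
    inter_npa_spacing: int | None = None
    n_npa_motifs: int = 0
    arR: tuple[str, str, str, str] | None = None
    froger: tuple[str, str, str, str, str] | None = None
    pre_p4: str | None = None  # residue immediately before the P4 column
    pre_p5: str | None = None
    tm_segments: tuple[tuple[int, int], ...] = ()
    n_terminus_in: bool | None = None
    regulatory: dict = field(default_factory=dict)


def find_npa_motifs(
    protein: str, reference_spacing: int | None = None
) -> NpaScan | None:
    """Locate the loop-B / loop-E NPA-class motif pair.

    Scans for the seven allowed triplet variants. With exactly two hits
    the pair is (earliest, latest); with more, the non-overlapping ordered
    pair whose spacing is closest to ``reference_spacing`` wins (ties:
    earliest pair). Fewer than two hits returns None — the caller decides
    what a zero- or single-motif protein means (see
    :func:`pgaqp.models.flag_non_aqp`, which accepts the motif count).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    hits = [
        (i + 1, protein[i : i + 3])
        for i in range(len(protein) - 2)
        if protein[i : i + 3] in NPA_VARIANTS
    ]
    if len(hits) < 2:
        return None
    if len(hits) == 2 or reference_spacing is None:
        (p1, m1), (p2, m2) = hits[0], hits[-1]
    else:
        best = None
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                pa, pb = hits[a][0], hits[b][0]
                if pb - pa < 3:
                    continue
                key = (abs((pb - pa - 3) - reference_spacing), pa, pb)
                if best is None or key < best[0]:
                    best = (key, hits[a], hits[b])
        if best is None:
            return None
        (p1, m1), (p2, m2) = best[1], best[2]
    return NpaScan(npa_lb=m1, npa_le=m2, lb_pos=p1, le_pos=p2, n_motifs=len(hits))


def predict_tm(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 5,
) -> tuple[tuple[tuple[int, int], ...], bool]:
    """Transmembrane segments from Kyte-Doolittle hydropathy.

    A window of ``window`` residues whose mean hydropathy reaches
    ``threshold`` marks a candidate core; overlapping/adjacent cores fuse,
    cores closer than ``merge_gap`` residues merge, and each segment is
    trimmed symmetrically to at most 23 residues (never below the window
    length). Returns (segments, n_terminus_in) with 1-based inclusive
    segment coordinates; an even segment count puts the N-terminus inside
    (cytoplasmic), as both termini cross back for each helix pair.
    """
    n = len(protein)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    kd = ProtParamData.kd
    vals = [kd[a] if a in kd else 0.0 for a in protein]
    prefix = [0.0]
    for v in vals:
        prefix.append(prefix[-1] + v)

    cores: list[list[int]] = []
    for i in range(n - window + 1):
        if (prefix[i + window] - prefix[i]) / window >= threshold:
            start, end = i + 1, i + window  # 1-based inclusive
            if cores and start <= cores[-1][1] + 1 + merge_gap:
                cores[-1][1] = max(cores[-1][1], end)
            else:
                cores.append([start, end])

    segments: list[tuple[int, int]] = []
    for start, end in cores:
        length = end - start + 1
        if length > 23:
            excess = length - 23
            start += excess // 2
            end -= excess - excess // 2
        segments.append((start, end))
    return tuple(segments), len(segments) % 2 == 0


# ---------------------------------------------------------------------------
# Alignment-column transfer
# ---------------------------------------------------------------------------

class TransferError(ValueError):
    """Query too diverged from the reference for reliable column transfer."""


def _align_to_reference(query: str, reference: str):
    from .classify import _aligner  # shared aligner configuration

    aln = _aligner().align(reference, query)[0]
    ref_blocks, query_blocks = aln.aligned
    # map: 0-based reference index -> 0-based query index (or None at a gap)
    mapping: dict[int, int] = {}
    matches = 0
    columns = 0
    prev_r = prev_q = 0
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        columns += max(rs - prev_r, qs - prev_q)
        for k in range(re - rs):
            mapping[rs + k] = qs + k
            if reference[rs + k] == query[qs + k]:
                matches += 1
        columns += re - rs
        prev_r, prev_q = re, qe
    columns += max(len(reference) - prev_r, len(query) - prev_q)
    identity = 100.0 * matches / columns if columns else 0.0
    return mapping, identity


def _transfer(
    query: str, reference: ReferenceIsoform, positions: Sequence[int]
) -> tuple[list[str], list[int | None], float]:
    mapping, identity = _align_to_reference(query, reference.sequence)
    if identity < 20.0:
        raise TransferError(
            f"alignment identity {identity:.1f}% to {reference.id} below 20%; "
            "column transfer unreliable"
        )
    residues: list[str] = []
    qpos: list[int | None] = []
    for p in positions:
        qi = mapping.get(p - 1)
        if qi is None:
            residues.append(GAP)
            qpos.append(None)
        else:
            residues.append(query[qi])
            qpos.append(qi + 1)
    return residues, qpos, identity


def extract_arR(
    protein: str, reference: ReferenceIsoform
) -> tuple[str, str, str, str]:
    """The ar/R selectivity filter (H2, H5, LE1, LE2) by column transfer."""
    residues, _, _ = _transfer(protein, reference, reference.arR_pos)
    return tuple(residues)  # type: ignore[return-value]


def extract_froger(
    protein: str, reference: ReferenceIsoform
) -> tuple[tuple[str, str, str, str, str], str | None, str | None]:
    """Froger residues P1-P5 plus the residues preceding the P4/P5 columns.

    A gap in the query at a curated column is reported as '-' (observed in
    the inventory at P1). The preceding residues feed the CO2-permeability
    rule, which requires an isoleucine before P4 and P5 in PIPs.
    """
    pos = reference.froger_pos
    wanted = list(pos) + [pos[3] - 1, pos[4] - 1]
    residues, _, _ = _transfer(protein, reference, wanted)
    froger = tuple(residues[:5])
    pre_p4 = residues[5] if residues[5] != GAP else None
    pre_p5 = residues[6] if residues[6] != GAP else None
    return froger, pre_p4, pre_p5  # type: ignore[return-value]


def check_regulatory_residues(
    protein: str, reference: ReferenceIsoform
) -> dict[str, bool]:
    """Presence of the PIP gating/trafficking residues by column transfer.

    Sites (named after their AtPIP2-1 archetypes): N-terminal Lys3 and
    Glu6 (methylation/trafficking), loop-B Ser (S121, open-pore
    phosphorylation), loop-D His (H199, pH gating), C-terminal Ser280 and
    Ser283 (phosphorylation/trafficking). A site is present when the
    query residue in the reference's column equals the reference residue.
    """
    if not reference.regulatory_pos:
        raise ValueError(f"{reference.id}: no curated regulatory positions")
    names = [s for s in REGULATORY_SITES if s in reference.regulatory_pos]
    positions = [reference.regulatory_pos[s] for s in names]
    residues, _, _ = _transfer(protein, reference, positions)
    return {
        name: res == reference.sequence[reference.regulatory_pos[name] - 1]
        for name, res in zip(names, residues)
    }


def extract_signature(
    protein_id: str,
    protein: str,
    reference: ReferenceIsoform,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    tm_merge_gap: int = 5,
) -> SignatureProfile:
    """Full signature profile of one protein against one curated reference."""
    profile = SignatureProfile(protein_id=protein_id)
    scan = find_npa_motifs(protein, reference_spacing=reference.spacing)
    if scan is not None:
        profile.npa_lb = scan.npa_lb
        profile.npa_le = scan.npa_le
        profile.inter_npa_spacing = scan.spacing
        profile.n_npa_motifs = scan.n_motifs
    else:
        profile.n_npa_motifs = sum(
            1 for i in range(len(protein) - 2) if protein[i : i + 3] in NPA_VARIANTS
        )
    try:
        profile.arR = extract_arR(protein, reference)
        profile.froger, profile.pre_p4, profile.pre_p5 = extract_froger(
            protein, reference
        )
        if reference.regulatory_pos:
            profile.regulatory = check_regulatory_residues(protein, reference)
    except TransferError as exc:
        log.warning("%s: %s", protein_id, exc)
    if len(protein) >= tm_window:
        profile.tm_segments, profile.n_terminus_in = predict_tm(
            protein, tm_window, tm_threshold, tm_merge_gap
        )
    return profile
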