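"""Structural annotation of candidate loci.

Candidate loci found by the homology screen are extracted with flanking
sequence, turned into gene models (from an existing annotation or a
best-ORF de-novo call), validated against the pseudo-gene rules (missing
start codon, early stop in the first exon), translated, and summarized as
protein records with average-mass molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io import AnnotatedGene, GenomeSequence, log
from .screen import Hotspot

STOP_CODONS = {"TAA", "TAG", "TGA"}
AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class ModelError(ValueError):
    """An ill-formed gene model or CDS."""


@dataclass
class GeneModel:
    """A candidate gene with exon chain and assembled CDS."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: str
    status: str = "candidate"  # annotated | de_novo | pseudo | non_aqp | candidate
    pseudo_reason: str = "none"  # none | no_start | early_stop


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mw_kda(self) -> float:
        return protein_mw(self.sequence)


def extract_locus(
    genome: GenomeSequence, hotspot: Hotspot, flank: int = 1000
) -> tuple[str, int]:
    """Extract the hot-spot envelope plus ``flank`` bp on each side.

    Returns (subsequence, offset) where offset is the 1-based genome
    coordinate of the first returned base, so position p in the genome is
    p - offset + 1 within the slice. The window is clipped to sequence
    bounds.
    """
    if hotspot.subject_id != genome.id:
        raise ValueError(f"hotspot is on {hotspot.subject_id}, not {genome.id}")
    n = len(genome.residues)
    if hotspot.start < 1 or hotspot.end > n:
        raise ValueError("hotspot outside sequence bounds")
    lo = max(1, hotspot.start - flank)
    hi = min(n, hotspot.end + flank)
    return genome.residues[lo - 1 : hi], lo


def assemble_cds(genome: GenomeSequence, gene: AnnotatedGene) -> str:
    """Concatenate exon sequence 5'->3' (reverse-complemented for '-')."""
    parts = [genome.residues[s - 1 : e] for s, e in gene.exons]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def model_from_annotation(genome: GenomeSequence, gene: AnnotatedGene) -> GeneModel:
    return GeneModel(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        start=gene.start,
        end=gene.end,
        strand=gene.strand,
        exons=gene.exons,
        cds=assemble_cds(genome, gene),
        status="annotated",
    )


def validate_model(model: GeneModel) -> GeneModel:
    """Apply the pseudo-gene rules to an assembled model.

    A model is a pseudo-gene if its CDS does not begin with ATG
    (``no_start``) or an in-frame stop codon falls strictly inside the
    first exon's CDS contribution (``early_stop``); otherwise the status
    is left unchanged.
    """
    if not model.exons:
        raise ModelError(f"{model.gene_id}: empty exon chain")
    cds = model.cds.upper()
    if len(cds) < 3:
        raise ModelError(f"{model.gene_id}: CDS shorter than one codon")
    if cds[:3] != "ATG":
        return replace(model, status="pseudo", pseudo_reason="no_start")
    # first exon in transcript order: last genomic exon for '-' strand
    first_exon = model.exons[0] if model.strand == "+" else model.exons[-1]
    first_len = first_exon[1] - first_exon[0] + 1
    for i in range(1, len(cds) // 3):
        codon_end = (i + 1) * 3
        if codon_end > first_len or codon_end >= len(cds):
            break
        if cds[i * 3 : codon_end] in STOP_CODONS:
            return replace(model, status="pseudo", pseudo_reason="early_stop")
    return model


def translate(cds: str, protein_id: str = "protein") -> ProteinRecord:
    """Translate a CDS that ends in a stop codon; internal stops are errors."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ModelError(f"{protein_id}: CDS length {len(cds)} not divisible by 3")
    if len(cds) < 6:
        raise ModelError(f"{protein_id}: CDS too short to encode a protein")
    if cds[-3:] not in STOP_CODONS:
        raise ModelError(f"{protein_id}: CDS lacks a terminal stop codon")
    aa = str(Seq(cds).translate())
    if "*" in aa[:-1]:
        pos = aa.index("*")
        raise ModelError(f"{protein_id}: premature stop at codon {pos + 1}")
    return ProteinRecord(protein_id=protein_id, sequence=aa[:-1])


def protein_mw(sequence: str) -> float:
    """Average-mass molecular weight in kDa.

    Sum of average residue masses plus one water; unmodified termini.
    Report tables round to 2 decimals, matching the kDa convention of the
    packaged inventory.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(sequence):
        if aa not in AA20:
            raise ValueError(f"ambiguous or invalid residue {aa!r} at position {i + 1}")
    return ProteinAnalysis(sequence).molecular_weight() / 1000.0


def flag_non_aqp(protein: ProteinRecord, npa_scan) -> tuple[str, bool]:
    """Classify a protein as aqp / non_aqp from its NPA-motif scan.

    ``npa_scan`` is the result of :func:`pgaqp.signatures.find_npa_motifs`
    (None when no motif was found) or a raw motif count. A protein with no
    NPA-class motif at all is not an aquaporin; a single motif keeps the
    aqp call but is flagged low-confidence.

    Returns (label, low_confidence).
    """
    if npa_scan is None:
        n = 0
    elif isinstance(npa_scan, int):
        n = npa_scan
    else:
        n = npa_scan.n_motifs
    if n == 0:
        return "non_aqp", False
    if n == 1:
        log.warning("%s: single NPA-class motif; low-confidence aqp call",
                    protein.protein_id)
        return "aqp", True
    return "aqp", False


# ---------------------------------------------------------------------------
# De-novo annotation (NOVEL hot-spots)
# ---------------------------------------------------------------------------

def find_orfs(seq: str, min_aa: int = 80) -> list[tuple[int, int, str]]:
    """ATG..stop open reading frames on both strands of ``seq``.

    Returns (start, end, strand) in 1-based coordinates of ``seq``, stop
    codon included; ORFs shorter than ``min_aa`` codons are dropped.
    """
    out: list[tuple[int, int, str]] = []
    n = len(seq)
    for strand, s in (("+", seq.upper()), ("-", str(Seq(seq).reverse_complement()).upper())):
        for frame in range(3):
            i = frame
            while i + 3 <= len(s):
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= len(s) and s[j : j + 3] not in STOP_CODONS:
                        j += 3
                    if j + 3 <= len(s) and (j + 3 - i) // 3 - 1 >= min_aa:
                        if strand == "+":
                            out.append((i + 1, j + 3, "+"))
                        else:
                            out.append((n - (j + 3) + 1, n - i, "-"))
                        i = j
                    i += 3
                else:
                    i += 3
    return out


def denovo_model(
    locus_seq: str,
    offset: int,
    seq_id: str,
    panel_proteins: Sequence,
    gene_id: str = "denovo",
    min_aa: int = 80,
) -> GeneModel | None:
    """Single-exon de-novo gene call for an unannotated hot-spot.

    Among ATG..stop ORFs in the extracted locus, picks the one whose
    translation aligns best to any reference-panel protein. Multi-exon
    de-novo chaining is not attempted (the published workflow resolved
    those loci with external gene finders plus manual curation).
    """
    from .classify import pairwise_align  # local import: avoid cycle

    best = None
    for s, e, strand in find_orfs(locus_seq, min_aa=min_aa):
        cds = locus_seq[s - 1 : e]
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        try:
            prot = translate(cds, f"{gene_id}_orf")
        except ModelError:
            continue
        score = max(
            pairwise_align(prot.sequence, ref.sequence)[0] for ref in panel_proteins
        )
        if best is None or score > best[0]:
            best = (score, s, e, strand, cds)
    if best is None:
        return None
    _, s, e, strand, cds = best
    g_start, g_end = offset + s - 1, offset + e - 1
    return GeneModel(
        gene_id=gene_id,
        seq_id=seq_id,
        start=g_start,
        end=g_end,
        strand=strand,
        exons=((g_start, g_end),),
        cds=cds,
        status="de_novo",
    )
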