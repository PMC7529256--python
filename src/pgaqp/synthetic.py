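"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study's raw inputs at desk scale: a reference
panel of curated aquaporin-like proteins, genomes with planted aquaporin
genes (functional, pseudo, and non-aquaporin decoys), tblastn-style HSP
tables over those genomes, pressure-chamber sap-flux series with a known
true hydraulic conductivity and azide-inhibition fraction, and qPCR Ct
tables with known fold changes. Every generator is bit-reproducible
under a fixed seed, and the returned truth objects are sufficient to
score discovery recall, signature recovery, Lpr recovery and fold-change
recovery without any external data.

Panel proteins are built from an explicit six-helix template: hydrophobic
21-residue transmembrane blocks separated by polar loops, with the NPA
motifs, ar/R filter, Froger positions and (for PIPs) regulatory residues
planted at recorded coordinates. Back-translation uses one fixed codon
per amino acid so planted CDS are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .expression import CtRecord
from .hydraulics import PressureFluxSeries, WATER_DENSITY_G_PER_M3
from .io import AnnotatedGene, GenomeSequence, log
from .screen import HspRecord
from .signatures import NPA_VARIANTS, ReferenceIsoform

HYDROPHOBIC = "LIVFA"
POLAR = "GSTDEQKR"

#: one fixed codon per amino acid (deterministic back-translation)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
STOP = "TAA"


def back_translate(protein: str) -> str:
    """Protein -> CDS with the fixed codon table, terminal stop appended."""
    return "".join(CODON[a] for a in protein) + STOP


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

#: subfamily templates: arR tetrad, Froger P1-P5, NPA variants, inter-NPA
#: spacing, H2/H5 live inside helices 2/5 so they may be any residue class
_TEMPLATES = {
    "PIP1": dict(arR="FHTR", froger="QSAFW", npa=("NPA", "NPA"), spacing=112, pre45="I"),
    "PIP2": dict(arR="FHTR", froger="QSAFW", npa=("NPA", "NPA"), spacing=112, pre45="I"),
    "TIP1": dict(arR="HIAV", froger="TSAYW", npa=("NPA", "NPA"), spacing=106, pre45="V"),
    "TIP2": dict(arR="HIGR", froger="TSAYW", npa=("NPA", "NPA"), spacing=106, pre45="V"),
    "NIP1": dict(arR="WVAR", froger="FTAYV", npa=("NPA", "NPA"), spacing=104, pre45="V"),
    "NIP2": dict(arR="GSGR", froger="LTAYF", npa=("NPA", "NPA"), spacing=108, pre45="V"),
    "SIP1": dict(arR="VVPN", froger="MAAYW", npa=("NPT", "NPA"), spacing=103, pre45="V"),
    "XIP1": dict(arR="VTAR", froger="VCAFW", npa=("NPA", "NPV"), spacing=110, pre45="V"),
}

_TM_LEN = 21
_LOOP = "GSTDEQKR"  # cyclic polar filler, no N or P => no spurious NPA-class hit

# A-rich helix pattern (mean hydropathy ~2.4): hydrophobic enough for a
# 19-window call, mild enough that cores do not bleed across the loops
_TM_PAT = "AAVALAAFA"


def _polar(n: int, phase: int = 0) -> str:
    return "".join(_LOOP[(phase + i) % len(_LOOP)] for i in range(n))


def _tm(n: int = _TM_LEN, phase: int = 0) -> str:
    return "".join(_TM_PAT[(phase + i) % len(_TM_PAT)] for i in range(n))


def _build_reference(subfamily: str, member: int, rng: np.random.Generator) -> ReferenceIsoform:
    t = _TEMPLATES[subfamily]
    arR, froger, (npa_lb, npa_le), spacing, pre45 = (
        t["arR"], t["froger"], t["npa"], t["spacing"], t["pre45"]
    )
    budget = spacing - (3 * _TM_LEN + 16 + 16)  # loops B-post + E-pre
    b_post_len, e_pre_len = budget - budget // 2, budget // 2

    seq: list[str] = []
    pos: dict[str, int] = {}

    def add(chunk: str) -> int:
        start = len(seq) + 1
        seq.extend(chunk)
        return start

    def add_one(name: str, residue: str) -> None:
        pos[name] = add(residue)

    add("MSKDVE")  # Lys3 / Glu6 archetypes
    pos["nter_Lys3"], pos["nter_Glu6"] = 3, 6
    add(_polar(4, phase=1))
    add(_tm(phase=0))                                   # TM1
    add(_polar(16, phase=2))                            # loop A
    tm2 = _tm(phase=1)
    add(tm2[:10])
    add_one("H2", arR[0])
    add(tm2[11:])                                       # TM2, H2 at centre
    add(_polar(12, phase=3))
    pos["npa_lb"] = add(npa_lb)                         # loop B
    add_one("loopB_Ser", "S")
    add(_polar(b_post_len - 1, phase=4))
    add(_tm(phase=2))                                   # TM3
    add(_polar(16, phase=5))                            # loop C
    add(_tm(phase=3))                                   # TM4
    add(_polar(7, phase=6))
    add_one("loopD_His", "H")
    add(_polar(8, phase=7))                             # loop D (16)
    tm5 = _tm(phase=4)
    add(tm5[:10])
    add_one("H5", arR[1])
    add(tm5[11:])                                       # TM5, H5 at centre
    add(_polar(e_pre_len, phase=0))
    pos["npa_le"] = add(npa_le)                         # loop E
    add("G")
    add_one("LE1", arR[2])
    add_one("LE2", arR[3])
    add("ES")
    add_one("P1", froger[0])
    add("DG")
    add(_tm(phase=5))                                   # TM6
    add("KG")
    add_one("P2", froger[1])
    add("D")
    add_one("P3", froger[2])
    add("G")
    add(pre45)
    add_one("P4", froger[3])
    add(pre45)
    add_one("P5", froger[4])
    add("G")
    add_one("cter_Ser280", "S")
    add("RD")
    add_one("cter_Ser283", "S")
    add("GKTE")

    ref = ReferenceIsoform(
        id=f"REF_{subfamily}_{member}",
        family=subfamily[:3],
        subfamily=subfamily,
        sequence="".join(seq),
        npa_lb_pos=pos["npa_lb"],
        npa_le_pos=pos["npa_le"],
        arR_pos=(pos["H2"], pos["H5"], pos["LE1"], pos["LE2"]),
        froger_pos=(pos["P1"], pos["P2"], pos["P3"], pos["P4"], pos["P5"]),
        regulatory_pos={
            k: pos[k]
            for k in ("nter_Lys3", "nter_Glu6", "loopB_Ser", "loopD_His",
                      "cter_Ser280", "cter_Ser283")
        },
    )
    if member > 1:  # neutral variation at free positions for extra members
        mutated = mutate_protein(ref.sequence, curated_positions(ref), 0.04, rng)
        ref = ReferenceIsoform(
            id=ref.id, family=ref.family, subfamily=ref.subfamily, sequence=mutated,
            npa_lb_pos=ref.npa_lb_pos, npa_le_pos=ref.npa_le_pos,
            arR_pos=ref.arR_pos, froger_pos=ref.froger_pos,
            regulatory_pos=ref.regulatory_pos,
        )
    return ref


def curated_positions(ref: ReferenceIsoform) -> frozenset[int]:
    """1-based positions that carry signature information (kept unmutated)."""
    protected = set(range(ref.npa_lb_pos, ref.npa_lb_pos + 3))
    protected |= set(range(ref.npa_le_pos, ref.npa_le_pos + 3))
    protected |= set(ref.arR_pos)
    protected |= set(ref.froger_pos)
    protected |= {p - 1 for p in (ref.froger_pos[3], ref.froger_pos[4])}
    protected |= set(ref.regulatory_pos.values())
    return frozenset(protected)


def mutate_protein(
    sequence: str,
    protected: frozenset[int],
    rate: float,
    rng: np.random.Generator,
) -> str:
    """Substitute a ``rate`` fraction of unprotected residues, class-preserving.

    Hydrophobic residues stay hydrophobic and polar stay polar, so mutated
    derivatives keep six predicted helices and realistic loops.
    """
    out = list(sequence)
    # position 1 (the start methionine) is always kept
    candidates = [i for i in range(1, len(sequence)) if (i + 1) not in protected]
    n_mut = int(round(rate * len(candidates)))
    for i in rng.choice(len(candidates), size=n_mut, replace=False):
        p = candidates[int(i)]
        pool = HYDROPHOBIC if sequence[p] in HYDROPHOBIC else POLAR
        choices = [c for c in pool if c != sequence[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_reference_panel(
    n_per_family: int = 2, seed: int = 0
) -> list[ReferenceIsoform]:
    """Curated reference isoforms covering PIP, TIP, NIP, SIP and XIP.

    Each family contributes ``n_per_family`` members drawn by cycling over
    its subfamily templates; member 1 of each subfamily is the unmodified
    template, further members vary neutrally at non-curated positions.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    for sub in _TEMPLATES:
        by_family.setdefault(sub[:3], []).append(sub)
    panel: list[ReferenceIsoform] = []
    for family in ("PIP", "TIP", "NIP", "SIP", "XIP"):
        subs = by_family[family]
        for i in range(n_per_family):
            panel.append(_build_reference(subs[i % len(subs)], i // len(subs) + 1, rng))
    return panel


# ---------------------------------------------------------------------------
# Genome planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGeneTruth:
    gene_id: str
    family: str
    status: str  # functional | pseudo | decoy
    seq_id: str
    start: int
    end: int
    strand: str
    exon_count: int
    source_reference: str
    mutation_rate: float
    protein: str  # the (mutated) protein the locus encodes
    pseudo_reason: str = "none"  # no_start | early_stop for pseudo entries
    expected_arR: tuple[str, ...] | None = None
    expected_froger: tuple[str, ...] | None = None
    expected_spacing: int | None = None


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_decoy_protein(n_aa: int, rng: np.random.Generator) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    seq = ["M"] + [aa[int(i)] for i in rng.integers(0, 20, size=n_aa - 1)]
    prot = "".join(seq)
    # scrub any NPA-class triplet so decoys carry no motif at all
    out = list(prot)
    for i in range(len(out) - 2):
        if "".join(out[i : i + 3]) in NPA_VARIANTS:
            out[i + 1] = "G"
    return "".join(out)


def _split_exons(cds: str, n_exons: int, rng: np.random.Generator) -> list[str]:
    """Split a CDS at codon boundaries into n_exons pieces, each >= 12 nt."""
    n_codons = len(cds) // 3
    min_codons = 4
    if n_exons * min_codons > n_codons:
        n_exons = max(1, n_codons // min_codons)
    while True:
        cuts = sorted(rng.choice(np.arange(1, n_codons), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *[int(c) for c in cuts], n_codons]
        if all(b - a >= min_codons for a, b in zip(bounds, bounds[1:])):
            return [cds[a * 3 : b * 3] for a, b in zip(bounds, bounds[1:])]


def plant_genome(
    panel: Sequence[ReferenceIsoform],
    n_genes: int = 12,
    n_pseudo: int = 3,
    n_decoys: int = 3,
    seed: int = 0,
    n_sequences: int = 2,
    sequence_length: int = 2_000_000,
    min_spacing: int = 5_000,
    mutation_rate: float = 0.05,
) -> tuple[list[GenomeSequence], list[AnnotatedGene], list[PlantedGeneTruth]]:
    """Random genome with planted aquaporin genes, pseudo-genes and decoys.

    Functional genes are back-translated from class-preserving mutated
    panel proteins and split into 1-5 exons; pseudo-genes violate exactly
    one rule (missing start codon, or an in-frame stop inside the first
    exon); decoys encode proteins with no NPA-class motif. Returns the
    genome, the truth annotation (gene + exon features) and the planted
    truth table.
    """
    if min(n_genes, n_pseudo, n_decoys) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = n_genes + n_pseudo + n_decoys

    # build gene payloads first so we know their sizes
    payloads = []  # (gene_id, status, reason, family, source, protein, exon_seqs, introns)
    for idx in range(n_total):
        status = ("functional" if idx < n_genes
                  else "pseudo" if idx < n_genes + n_pseudo else "decoy")
        gene_id = f"synth_{status}_{idx + 1:02d}"
        reason = "none"
        if status == "decoy":
            protein = _random_decoy_protein(int(rng.integers(220, 300)), rng)
            family, source = "none", "none"
        else:
            # round-robin over the panel: families stay balanced and every
            # subfamily template is represented once counts reach panel size
            ref = panel[idx % len(panel)]
            protein = mutate_protein(ref.sequence, curated_positions(ref), mutation_rate, rng)
            family, source = ref.family, ref.id
        cds = back_translate(protein)
        n_exons = int(rng.integers(1, 6))
        exon_seqs = _split_exons(cds, n_exons, rng)
        if status == "pseudo":
            reason = "no_start" if rng.random() < 0.5 else "early_stop"
            first = list(exon_seqs[0])
            if reason == "no_start":
                first[0:3] = "CTG"
            else:
                codon_i = int(rng.integers(1, len(first) // 3 - 1))
                first[codon_i * 3 : codon_i * 3 + 3] = "TGA"
            exon_seqs[0] = "".join(first)
        introns = []
        for _ in range(len(exon_seqs) - 1):
            ilen = int(rng.integers(100, 801))
            introns.append("GT" + _random_dna(ilen - 4, rng) + "AG")
        payloads.append((gene_id, status, reason, family, source, protein, exon_seqs, introns))

    # place loci round-robin over sequences with >= min_spacing gaps
    per_seq = [[] for _ in range(n_sequences)]
    for i, p in enumerate(payloads):
        per_seq[i % n_sequences].append(p)

    genome: list[GenomeSequence] = []
    annotation: list[AnnotatedGene] = []
    truths: list[PlantedGeneTruth] = []
    for s in range(n_sequences):
        seq_id = f"chr{s + 1}"
        items = per_seq[s]
        total_gene = sum(
            sum(len(e) for e in p[6]) + sum(len(i) for i in p[7]) for p in items
        )
        slack = sequence_length - total_gene - (len(items) + 1) * min_spacing
        if slack < 0:
            raise ValueError(
                f"sequence_length {sequence_length} too small to place "
                f"{len(items)} loci at {min_spacing} bp spacing"
            )
        extra = rng.multinomial(slack, [1 / (len(items) + 1)] * (len(items) + 1)) if items else [sequence_length]
        chunks: list[str] = []
        cursor = 0  # 0-based length so far
        for k, p in enumerate(items):
            gap = min_spacing + int(extra[k])
            chunks.append(_random_dna(gap, rng))
            cursor += gap
            gene_id, status, reason, family, source, protein, exon_seqs, introns = p
            region_parts = []
            local_exons = []  # (start, end) 1-based within region, transcript order
            lpos = 0
            for j, ex in enumerate(exon_seqs):
                local_exons.append((lpos + 1, lpos + len(ex)))
                region_parts.append(ex)
                lpos += len(ex)
                if j < len(introns):
                    region_parts.append(introns[j])
                    lpos += len(introns[j])
            region = "".join(region_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            g_start = cursor + 1
            L = len(region)
            if strand == "-":
                chunks.append(str(Seq(region).reverse_complement()))
                exons = sorted(
                    (g_start + L - e, g_start + L - s0) for s0, e in local_exons
                )
            else:
                chunks.append(region)
                exons = [(g_start + s0 - 1, g_start + e - 1) for s0, e in local_exons]
            cursor += L
            gene = AnnotatedGene(
                gene_id=gene_id, seq_id=seq_id, start=g_start, end=cursor,
                strand=strand, exons=tuple(exons),
            )
            annotation.append(gene)
            ref = next((r for r in panel if r.id == source), None)
            truths.append(
                PlantedGeneTruth(
                    gene_id=gene_id, family=family, status=status, seq_id=seq_id,
                    start=g_start, end=cursor, strand=strand,
                    exon_count=len(exon_seqs), source_reference=source,
                    mutation_rate=mutation_rate if status != "decoy" else 0.0,
                    protein=protein, pseudo_reason=reason,
                    expected_arR=(
                        tuple(protein[q - 1] for q in ref.arR_pos) if ref else None
                    ),
                    expected_froger=(
                        tuple(protein[q - 1] for q in ref.froger_pos) if ref else None
                    ),
                    expected_spacing=ref.spacing if ref else None,
                )
            )
        tail = sequence_length - cursor
        if tail > 0:
            chunks.append(_random_dna(tail, rng))
        genome.append(GenomeSequence(seq_id, "".join(chunks)))
    return genome, annotation, truths


# ---------------------------------------------------------------------------
# HSP simulation
# ---------------------------------------------------------------------------

def simulate_hsps(
    genome: Sequence[GenomeSequence],
    annotation: Sequence[AnnotatedGene],
    truths: Sequence[PlantedGeneTruth],
    spurious_rate: float = 0.0,
    redundancy: float = 0.0,
    seed: int = 0,
) -> list[HspRecord]:
    """tblastn-style HSP table over a planted genome.

    Every planted exon yields one primary HSP with bitscore >= 100;
    ``redundancy`` adds Poisson-distributed overlapping HSPs of strictly
    lower bitscore; ``spurious_rate`` (per Mb) adds background hits that
    fail the published filter (bitscore < 100 or e-value > 1e-5).
    """
    rng = np.random.default_rng(seed)
    by_id = {t.gene_id: t for t in truths}
    out: list[HspRecord] = []
    for gene in annotation:
        truth = by_id[gene.gene_id]
        qcursor = 1
        for s, e in gene.exons:
            aa_len = max(1, (e - s + 1) // 3)
            bit = float(rng.uniform(120, 400))
            primary = HspRecord(
                query_id=truth.source_reference if truth.source_reference != "none" else "REF_PIP1_1",
                subject_id=gene.seq_id,
                pident=round(100.0 * (1 - truth.mutation_rate), 2),
                aln_length=aa_len,
                qstart=qcursor, qend=qcursor + aa_len - 1,
                sstart=s, send=e, strand=gene.strand,
                evalue=float(10.0 ** -rng.uniform(20, 80)),
                bitscore=round(bit, 1),
            )
            qcursor += aa_len
            out.append(primary)
            for _ in range(int(rng.poisson(redundancy))):
                half = (e - s) // 2
                ss = s + min(int(rng.integers(0, 31)), half)
                ee = e - min(int(rng.integers(0, 31)), half)
                out.append(
                    HspRecord(
                        query_id=f"REF_ALT_{int(rng.integers(1, 9))}",
                        subject_id=gene.seq_id,
                        pident=round(float(rng.uniform(40, 90)), 2),
                        aln_length=max(10, (ee - ss + 1) // 3),
                        qstart=1, qend=max(10, (ee - ss + 1) // 3),
                        sstart=ss, send=ee, strand=gene.strand,
                        evalue=float(10.0 ** -rng.uniform(10, 40)),
                        bitscore=round(max(1.0, primary.bitscore - float(rng.uniform(5, 50))), 1),
                    )
                )
    total_mb = sum(len(g.residues) for g in genome) / 1e6
    n_spurious = int(rng.poisson(spurious_rate * total_mb))
    for _ in range(n_spurious):
        g = genome[int(rng.integers(len(genome)))]
        length = int(rng.integers(60, 301))
        ss = int(rng.integers(1, len(g.residues) - length))
        if rng.random() < 0.5:
            bit, ev = float(rng.uniform(30, 99.9)), float(10.0 ** -rng.uniform(2, 10))
        else:
            bit, ev = float(rng.uniform(100, 200)), float(10.0 ** -rng.uniform(0.5, 4.9))
            ev = max(ev, 1.01e-5)
        out.append(
            HspRecord(
                query_id=f"REF_BG_{int(rng.integers(1, 999))}",
                subject_id=g.id, pident=round(float(rng.uniform(20, 50)), 2),
                aln_length=length // 3, qstart=1, qend=length // 3,
                sstart=ss, send=ss + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                evalue=ev, bitscore=round(bit, 1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pressure-flux and Ct simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydraulicsTruth:
    genotype: str
    true_lpr: float  # m^3 m^-2 s^-1 MPa^-1
    azide_inhibition: float  # fraction of Lpr removed by azide
    noise_sd: float  # relative sd of sap-mass measurements
    n_plants: int

    def __post_init__(self) -> None:
        if not 0 <= self.azide_inhibition <= 1:
            raise ValueError("azide_inhibition must lie in [0, 1]")
        if self.n_plants < 2:
            raise ValueError("n_plants must be >= 2")


def simulate_pressure_flux(
    truth: HydraulicsTruth,
    pressures: Sequence[float] = (0.1, 0.2, 0.3),
    collection_s: float = 300.0,
    root_area: float = 0.05,
    seed: int = 0,
) -> list[PressureFluxSeries]:
    """Sap-mass series for n_plants untreated plus n_plants azide-treated plants.

    Expected sap mass at pressure P is
    true_lpr * (1 - inhibition if treated) * root_area * P * t * density,
    with multiplicative Gaussian noise of sd ``noise_sd``; negative draws
    are truncated at 0 and logged.
    """
    if len(set(pressures)) < 2:
        raise ValueError("need >= 2 distinct pressures")
    if root_area <= 0:
        raise ValueError("root_area must be positive")
    rng = np.random.default_rng(seed)
    series: list[PressureFluxSeries] = []
    for treatment in ("none", "azide"):
        eff_lpr = truth.true_lpr * (
            1 - truth.azide_inhibition if treatment == "azide" else 1
        )
        for plant in range(truth.n_plants):
            points = []
            for p in pressures:
                expected = eff_lpr * root_area * p * collection_s * WATER_DENSITY_G_PER_M3
                mass = expected * (1 + rng.normal(0, truth.noise_sd)) if truth.noise_sd > 0 else expected
                if mass < 0:
                    log.warning("truncating negative simulated sap mass to 0")
                    mass = 0.0
                points.append((float(p), float(mass), float(collection_s)))
            series.append(
                PressureFluxSeries(
                    plant_id=f"{truth.genotype}_{treatment}_{plant + 1:02d}",
                    genotype=truth.genotype,
                    treatment=treatment,
                    points=tuple(points),
                    root_surface_area=root_area,
                )
            )
    return series


@dataclass(frozen=True)
class ExpressionTruth:
    gene: str
    genotype: str
    fold_change_vs_calibrator: float
    ct_noise_sd: float

    def __post_init__(self) -> None:
        if self.fold_change_vs_calibrator <= 0:
            raise ValueError("fold change must be positive")


def simulate_ct(
    truths: Sequence[ExpressionTruth],
    n_reps: int = 3,
    seed: int = 0,
    reference_ct: float = 20.0,
    base_dct: float = 5.0,
) -> list[CtRecord]:
    """Ct tables realizing known fold changes under the ddCt generative model.

    Ct_target = Ct_reference + base_dct - log2(fold) + noise, so a
    calibrator with fold 1 sits at dCt = base_dct and the ddCt inversion
    recovers each truth's fold exactly at zero noise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[CtRecord] = []
    for t in truths:
        for rep in range(1, n_reps + 1):
            ct_ref = reference_ct + (rng.normal(0, t.ct_noise_sd) if t.ct_noise_sd else 0.0)
            ct_tgt = (
                ct_ref + base_dct - math.log2(t.fold_change_vs_calibrator)
                + (rng.normal(0, t.ct_noise_sd) if t.ct_noise_sd else 0.0)
            )
            out.append(CtRecord(t.gene, t.genotype, rep, ct_tgt, ct_ref))
    return out
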