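"""End-to-end discovery: screen -> annotate -> signatures -> classify.

Chains the stage modules over one genome + HSP table + annotation and
returns one result row per hot-spot, carrying the gene model, its
validation status, the signature profile, the family assignment and the
substrate prediction. This is the engine behind the CLI subcommands and
the synthetic benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import classify as _classify
from . import models as _models
from . import screen as _screen
from . import signatures as _signatures
from .io import AnnotatedGene, GenomeSequence, log
from .signatures import ReferenceIsoform, SignatureProfile


@dataclass
class LocusResult:
    hotspot: _screen.Hotspot
    mapped_gene: str  # annotated gene id or NOVEL
    model: _models.GeneModel | None = None
    protein: _models.ProteinRecord | None = None
    signature: SignatureProfile | None = None
    assignment: _classify.FamilyAssignment | None = None
    permeability: _classify.PermeabilityPrediction | None = None
    low_confidence: bool = False


def run_discovery(
    genome: Sequence[GenomeSequence],
    hsps: Sequence[_screen.HspRecord],
    annotation: Sequence[AnnotatedGene],
    panel: Sequence[ReferenceIsoform],
    min_bitscore: float = 100.0,
    max_evalue: float = 1e-5,
    merge_gap: int = 2000,
    flank: int = 1000,
    identity_floor: float = 25.0,
) -> list[LocusResult]:
    genomes = {g.id: g for g in genome}
    kept = _screen.filter_hsps(hsps, min_bitscore, max_evalue)
    log.info("screen: %d/%d HSPs pass the filter", len(kept), len(hsps))
    hotspots = _screen.cluster_hotspots(kept, merge_gap)
    mapped = _screen.map_to_annotation(hotspots, annotation)
    genes = {g.gene_id: g for g in annotation}
    existing_names: set[str] = set()

    results: list[LocusResult] = []
    for hs, gene_id in mapped:
        res = LocusResult(hotspot=hs, mapped_gene=gene_id)
        results.append(res)
        g = genomes[hs.subject_id]
        if gene_id != _screen.NOVEL:
            model = _models.model_from_annotation(g, genes[gene_id])
        else:
            locus_seq, offset = _models.extract_locus(g, hs, flank)
            model = _models.denovo_model(
                locus_seq, offset, g.id, panel, gene_id=f"novel_{hs.subject_id}_{hs.start}"
            )
            if model is None:
                log.warning("no de-novo model at %s:%d-%d", hs.subject_id, hs.start, hs.end)
                continue
        model = _models.validate_model(model)
        res.model = model
        if model.status == "pseudo":
            continue
        try:
            protein = _models.translate(model.cds, model.gene_id)
        except _models.ModelError as exc:
            log.warning("%s: translation failed (%s)", model.gene_id, exc)
            continue
        res.protein = protein

        scan = _signatures.find_npa_motifs(protein.sequence)
        label, res.low_confidence = _models.flag_non_aqp(protein, scan)
        if label == "non_aqp":
            model.status = "non_aqp"
            continue

        # nearest reference guides both signature transfer and naming
        best_ref = max(
            panel,
            key=lambda r: _classify.pairwise_align(protein.sequence, r.sequence)[0],
        )
        res.signature = _signatures.extract_signature(
            protein.protein_id, protein.sequence, best_ref
        )
        res.assignment = _classify.assign_family(
            protein.protein_id, protein.sequence, panel,
            signature=res.signature, identity_floor=identity_floor,
            existing_names=existing_names,
        )
        res.permeability = _classify.predict_permeability(
            res.signature, res.assignment.family, res.assignment.subfamily
        )
    return results
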