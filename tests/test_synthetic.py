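"""Generator contracts: determinism, planted truth self-consistency, noise models."""

import math

import numpy as np
import pytest

from pgaqp import (
    HydraulicsTruth,
    ExpressionTruth,
    aqp_contribution,
    compute_lpr,
    ddct_relative_expression,
    filter_hsps,
    find_npa_motifs,
    fit_conductance,
    make_reference_panel,
    plant_genome,
    simulate_ct,
    simulate_hsps,
    simulate_pressure_flux,
    translate,
)
from pgaqp.models import model_from_annotation, validate_model
from pgaqp.signatures import NPA_VARIANTS


class TestReferencePanel:
    def test_same_seed_gives_identical_panel(self):
        a = make_reference_panel(2, seed=9)
        b = make_reference_panel(2, seed=9)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_all_five_families_covered(self, panel):
        assert {r.family for r in panel} == {"PIP", "TIP", "NIP", "SIP", "XIP"}

    def test_pip_members_carry_fhtr(self, panel):
        for r in panel:
            if r.family == "PIP":
                assert tuple(r.sequence[p - 1] for p in r.arR_pos) == ("F", "H", "T", "R")

    def test_nip2_members_have_spacing_108_and_gsgr(self, panel):
        nip2 = [r for r in panel if r.subfamily == "NIP2"]
        assert nip2
        for r in nip2:
            assert r.spacing == 108
            assert tuple(r.sequence[p - 1] for p in r.arR_pos) == ("G", "S", "G", "R")

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            make_reference_panel(0)


class TestPlantGenome:
    def test_empty_planting(self, panel):
        genome, annotation, truths = plant_genome(panel, 0, 0, 0, seed=1)
        assert annotation == [] and truths == []
        assert len(genome) == 2 and len(genome[0].residues) == 2_000_000

    def test_same_seed_reproducible(self, panel):
        g1, a1, t1 = plant_genome(panel, 4, 1, 1, seed=5, sequence_length=200_000)
        g2, a2, t2 = plant_genome(panel, 4, 1, 1, seed=5, sequence_length=200_000)
        assert [s.residues for s in g1] == [s.residues for s in g2]
        assert a1 == a2 and t1 == t2

    def test_truth_exons_translate_to_planted_proteins(self, planted):
        """Re-extracting and translating each functional gene recovers its protein."""
        genome, annotation, truths = planted
        genomes = {g.id: g for g in genome}
        by_id = {t.gene_id: t for t in truths}
        checked = 0
        for gene in annotation:
            truth = by_id[gene.gene_id]
            if truth.status != "functional":
                continue
            model = model_from_annotation(genomes[gene.seq_id], gene)
            assert translate(model.cds, gene.gene_id).sequence == truth.protein
            checked += 1
        assert checked == 12

    def test_pseudo_genes_violate_exactly_their_planted_rule(self, planted):
        genome, annotation, truths = planted
        genomes = {g.id: g for g in genome}
        by_id = {t.gene_id: t for t in truths}
        n_pseudo = 0
        for gene in annotation:
            truth = by_id[gene.gene_id]
            if truth.status != "pseudo":
                continue
            model = validate_model(model_from_annotation(genomes[gene.seq_id], gene))
            assert (model.status, model.pseudo_reason) == ("pseudo", truth.pseudo_reason)
            n_pseudo += 1
        assert n_pseudo == 3

    def test_decoys_carry_no_npa_motif(self, planted):
        _, _, truths = planted
        decoys = [t for t in truths if t.status == "decoy"]
        assert len(decoys) == 3
        for t in decoys:
            assert all(
                t.protein[i : i + 3] not in NPA_VARIANTS
                for i in range(len(t.protein) - 2)
            )

    def test_impossible_placement_raises(self, panel):
        with pytest.raises(ValueError, match="too small"):
            plant_genome(panel, 40, 0, 0, seed=1, sequence_length=50_000)


class TestSimulateHsps:
    def test_noise_free_count_equals_exon_count(self, planted, planted_hsps):
        _, annotation, _ = planted
        assert len(planted_hsps) == sum(len(g.exons) for g in annotation)

    def test_primaries_pass_filter(self, planted_hsps):
        assert len(filter_hsps(planted_hsps)) == len(planted_hsps)

    def test_spurious_hits_all_fail_the_filter(self, planted, panel):
        genome, annotation, truths = planted
        noisy = simulate_hsps(genome, annotation, truths, spurious_rate=5.0,
                              redundancy=0.0, seed=3)
        clean = simulate_hsps(genome, annotation, truths, spurious_rate=0.0,
                              redundancy=0.0, seed=3)
        n_spurious = len(noisy) - len(clean)
        assert n_spurious > 0
        assert len(filter_hsps(noisy)) == len(clean)

    def test_redundant_hits_score_below_their_primary(self, planted):
        genome, annotation, truths = planted
        hsps = simulate_hsps(genome, annotation, truths, spurious_rate=0.0,
                             redundancy=2.0, seed=3)
        # primaries sit exactly on exon coordinates; extras overlap them
        exon_coords = {
            (g.seq_id, s, e): None for g in annotation for s, e in g.exons
        }
        primaries: dict = {}
        extras = []
        for h in hsps:
            key = (h.subject_id, h.sstart, h.send)
            if key in exon_coords and key not in primaries:
                primaries[key] = h.bitscore  # generator emits primaries first
            else:
                extras.append(h)
        assert len(primaries) == len(exon_coords) and extras
        for h in extras:
            overlapping = [
                b for (s, ss, se), b in primaries.items()
                if s == h.subject_id and ss <= h.send and h.sstart <= se
            ]
            assert overlapping and h.bitscore < max(overlapping)

    def test_same_seed_identical_table(self, planted):
        genome, annotation, truths = planted
        a = simulate_hsps(genome, annotation, truths, 1.0, 1.0, seed=4)
        b = simulate_hsps(genome, annotation, truths, 1.0, 1.0, seed=4)
        assert a == b


class TestSimulatePressureFlux:
    truth = HydraulicsTruth("G1", true_lpr=1e-7, azide_inhibition=0.0,
                            noise_sd=0.0, n_plants=2)

    def test_noise_free_inversion_recovers_true_lpr(self):
        series = simulate_pressure_flux(self.truth, seed=0)
        for s in series:
            lpr = compute_lpr(fit_conductance(s), s.root_surface_area)
            assert lpr == pytest.approx(1e-7, rel=1e-9)

    def test_full_inhibition_zeroes_treated_masses(self):
        truth = HydraulicsTruth("G1", 1e-7, 1.0, 0.0, 2)
        series = simulate_pressure_flux(truth, seed=0)
        for s in series:
            if s.treatment == "azide":
                assert all(m == 0.0 for _, m, _ in s.points)

    def test_mean_contribution_near_truth_under_noise(self):
        truth = HydraulicsTruth("G1", 1e-7, azide_inhibition=0.8,
                                noise_sd=0.05, n_plants=15)
        series = simulate_pressure_flux(truth, seed=12)
        untreated = [
            compute_lpr(fit_conductance(s), s.root_surface_area)
            for s in series if s.treatment == "none"
        ]
        mean_untreated = float(np.mean(untreated))
        contribs = [
            aqp_contribution(
                compute_lpr(fit_conductance(s), s.root_surface_area), mean_untreated
            )
            for s in series if s.treatment == "azide"
        ]
        se = float(np.std(contribs, ddof=1) / math.sqrt(len(contribs)))
        assert abs(float(np.mean(contribs)) - 80.0) < 3 * max(se, 0.5)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            simulate_pressure_flux(self.truth, pressures=(0.2, 0.2))
        with pytest.raises(ValueError):
            HydraulicsTruth("G", 1e-7, 1.5, 0.0, 3)


class TestSimulateCt:
    def test_zero_noise_zero_fold_change_gives_ddct_zero(self):
        records = simulate_ct([ExpressionTruth("g", "A", 1.0, 0.0)], n_reps=4, seed=0)
        summaries = ddct_relative_expression(records, ("g", "A"))
        assert summaries[0].mean == pytest.approx(1.0)

    def test_fold_four_recovered_exactly_without_noise(self):
        records = simulate_ct(
            [ExpressionTruth("g", "A", 1.0, 0.0), ExpressionTruth("g", "B", 4.0, 0.0)],
            n_reps=3, seed=0,
        )
        summaries = {(s.gene, s.genotype): s for s in ddct_relative_expression(records, ("g", "A"))}
        assert summaries[("g", "B")].mean == pytest.approx(4.0)

    def test_noisy_folds_recovered_within_three_se(self):
        truths = [ExpressionTruth("g", "CAL", 1.0, 0.2)] + [
            ExpressionTruth("g", f"G{f}", f, 0.2) for f in (0.5, 2.0, 8.0)
        ]
        records = simulate_ct(truths, n_reps=8, seed=5)
        summaries = {s.genotype: s for s in ddct_relative_expression(records, ("g", "CAL"))}
        for f in (0.5, 2.0, 8.0):
            s = summaries[f"G{f}"]
            assert abs(s.mean - f) < 3 * s.se
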