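# Methods

This note documents the models, parameters, numerical choices and known
limitations of `pgaqp`, stage by stage in the order the pipeline runs.

## Packaged inventory registries

Two TSVs ship with the package: the 33-gene aquaporin inventory of the
pearl-millet genome (gene/transcript/protein lengths, MW, chromosome
coordinates) and the per-isoform conserved-domain residues (NPA loop-B
and loop-E triplets, ar/R tetrad, Froger P1–P5). Values are stored
verbatim. Two published internal inconsistencies are deliberately
preserved rather than corrected:

* one PIP1 row prints a protein length one residue short of
  `transcript/3 − 1`; the inventory-wide length identity is asserted
  for every row *except* that one (`LENGTH_RULE_EXCEPTIONS`);
* the printed 11,899 bp chromosome-3 PIP2 cluster is exactly
  `end(PgPIP2-5) − start(PgPIP2-6)`; the third PIP2 gene said to lie in
  that window is ~285 kb away by its own printed coordinates. We
  therefore compute cluster spans as `max(end) − min(start)` (no +1)
  over proximity clusters (same chromosome and subfamily, gaps
  ≤ 100 kb), which reproduces both printed spans (11,899 and
  141,812 bp) from the table's coordinates alone.

The inventory ID column is not monotone for TIP rows; registries key by
gene name, never by ID.

## Homology screen

HSPs are kept when `bitscore ≥ 100` **and** `evalue ≤ 1e-5`, both
inclusive. Hot-spots are connected components of HSPs on one subject
sequence whose intervals overlap or lie within `merge_gap` bp
(default 2000). The published workflow states no clustering distance;
2 kb was chosen once to bridge the introns of 1–5-exon genes and is a
config/CLI flag. Strand is ignored during clustering — hot-spots are
positional and loci are re-annotated downstream. The representative is
the member of maximal bit score (ties: lower subject start, then
lexicographic query id). Hot-spot → gene mapping maximizes bp overlap
(ties: longer gene, then lexicographic id); zero overlap maps to
`NOVEL`.

## Structural annotation

Loci are extracted with a ±1000 bp flank (clipped at sequence bounds;
the applied offset is returned for coordinate back-mapping). CDS are
assembled from the exon chain (reverse-complemented on the minus
strand). Pseudo-gene rules, applied in order: no `ATG` at CDS position
1 → `no_start`; an in-frame stop whose codon lies entirely within the
first exon's CDS contribution, excluding the terminal stop →
`early_stop`. Translation uses the standard genetic code, requires a
terminal stop, and treats internal stops and frame violations as
errors. Protein MW is the sum of average residue masses plus one water
(Biopython's average-mass table), reported in kDa; report tables round
to two decimals, matching the inventory convention. Ambiguity codes
(B, Z, X) are rejected with the offending position named.

De-novo annotation of `NOVEL` hot-spots picks, among ATG→stop ORFs
(both strands, ≥ 80 codons) in the extracted locus, the one whose
translation aligns best to any reference-panel protein. This replaces
an external gene finder plus manual curation and is deliberately
limited to single-exon calls; multi-exon de-novo chaining is out of
scope (in the published data the large majority of hot-spots fall in
already-annotated genes, and the synthetic truth annotation is
complete).

Proteins with zero NPA-class motifs are non-AQP; a single motif keeps
the AQP call with a low-confidence flag — the rejection rule concerns
absence of signatures, not partial presence.

## Signature extraction

The motif alphabet is fixed to the seven triplets observed in the
inventory (NPA, NPS, NPT, NPV, NPI, NPL, TPA); anything else is not a
motif, which prevents spurious matches while covering every printed
polymorphism. With more than two candidate triplets, the pair whose
spacing is closest to the family reference spacing wins (ties:
earliest pair). Inter-NPA spacing counts residues strictly between the
two triplets, so the "exactly 108 residues" silicon criterion is
checkable verbatim.

Transmembrane prediction is a Kyte–Doolittle sliding-window scan
(window 19, threshold 1.6, merge gap 5 — all exposed in config;
external TM predictors are not re-implementable exactly). Qualifying
windows fuse into cores; segments are center-trimmed to ≤ 23 residues
and never shortened below the window length. An even segment count
reports the N-terminus as cytoplasmic.

ar/R, Froger and PIP regulatory residues (N-terminal Lys3/Glu6, loop-B
Ser, loop-D His, C-terminal Ser280/Ser283, named after their AtPIP2-1
archetypes) are read off by **alignment-column transfer**: the query is
globally aligned to a curated reference and the query residues in the
reference's curated columns are reported, with `-` where the query has
a gap (as the inventory prints for one Froger P1). Transfer refuses to
run below 20% alignment identity. The residues immediately preceding
the P4 and P5 columns are captured for the CO₂ rule.

## Classification and permeability

Global alignment uses BLOSUM62 with affine gap costs (open 10,
extend 1); identity is exact matches over all alignment columns. A
protein inherits family and subfamily from its best-scoring reference;
it is `unclassified` only when identity falls below 25% (config) *and*
its ar/R-or-Froger residues match none observed for that family in the
inventory. The 25% floor sits below typical cross-family MIP identity.
Proposed names take the lowest unused numeric suffix within the
subfamily — names are assignment-relative, and collisions are resolved
mechanically.

The permeability rule table fires every matching rule independently;
substrates are the union over fired rules and restrictions lose any
substrate granted by another rule. The silicon rule requires **both**
G-S-G-R and spacing 108, exactly as the two conditions are conjoined in
the literature. The nitrate rule ("same ar/R motif and similar Froger
residues as OsPIP1-3") has no published definition of "similar"; we
require subfamily PIP1, the exact F-H-T-R tetrad and ≥ 4/5 Froger
agreement with (Q,S,A,F,W) — recorded here as an assumption.

Nearest-reference classification replaces a bootstrap ML phylogeny:
deterministic, desk-scale, and faithful to the published naming logic
(families and closest homologs).

## Hydraulics

Sap mass converts to volumetric flow at 1 g/ml (dilute xylem sap). L₀
is the free-intercept OLS slope of flow vs pressure — the published
protocol equilibrates at 0.4 MPa before collecting, and a free
intercept absorbs residual exudation; a through-origin mode is a flag.
Lpr = L₀ / root surface area. The contribution statistic is evaluated
per azide-treated plant against the untreated genotype mean; negative
values are reported as-is (the formula imposes no clipping) and logged.
Group summaries are mean ± sd/√n; single-observation groups report
se = 0 with a degenerate flag. LSD letters use the one-way-ANOVA pooled
mean square, `t(1−α/2, df_error)·√(MSE·(1/nᵢ+1/nⱼ))` per pair, and a
greedy descending-mean line display (the conventional agricolae-style
output); ties break by group name, making the letter partition
invariant to input order.

## ΔΔCt expression

Amplification efficiency is fixed at 2 (perfect doubling), the ΔΔCt
method's assumption; an efficiency-corrected mode is behind a flag.
ΔΔCt subtracts the calibrator group's *mean* ΔCt (replicates are not
paired across genes), so the calibrator's mean relative expression is 1
by construction. Calibrator uncertainty is not propagated into other
groups' standard errors.

## Synthetic data: what it emulates, and what it does not

The generators realize the study's raw inputs at desk scale with known
truth. Defaults (chosen once, to mirror the study's scale while staying
fast): genome of 2 sequences × 2 Mb; 12 functional + 3 pseudo + 3 decoy
loci at ≥ 5 kb spacing with 1–5 exons (the inventory's observed range);
5% class-preserving protein mutation; pressure design 0.1/0.2/0.3 MPa
× 300 s; hydraulics truth Lpr 1e-7 m³ m⁻² s⁻¹ MPa⁻¹ (the reported
magnitude) with 80% azide inhibition (the reported contribution scale),
5% multiplicative sap-mass noise, 15 plants per arm (the reported
10–15); Ct noise 0.2 cycles with 6–8 biological replicates.

Panel proteins follow an explicit six-helix template: 21-residue
A-rich hydrophobic helices separated by ≥ 15-residue polar loops, with
all curated residues planted at recorded positions and family-specific
inter-NPA spacings (NIP2 exactly 108). Source references for planted
genes rotate round-robin over the panel so every family is always
represented. Back-translation uses one fixed codon per amino acid —
reproducibility over codon realism. Pseudo-genes violate exactly one
rule; decoys are protein-coding with every NPA-class triplet scrubbed.
Sap-mass noise is multiplicative Gaussian truncated at zero (masses
are positive); azide inhibition is treated as instantaneous and
constant, since no exposure-duration kinetics are published.

Not emulated: realistic intergenic composition and repeats, codon usage,
splice-site signals, sequencing reads, alignment score noise in HSPs,
plant-to-plant root-area variation, and primer efficiency variation.
Passing the benchmark therefore demonstrates the pipeline's logic
(filtering, clustering, validation rules, residue transfer, rule
engine, estimators) — not robustness to assembly artifacts or
biological edge cases absent from the generator.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full benchmark at
its default scale (18 loci on 4 Mb, 15 plants per treatment arm, 8 qPCR
replicates), 200 classification draws, and exhaustive alignment
enumeration up to length 6; the complete suite finishes in a few
seconds on one CPU.

## Known limitations

* Multi-exon de-novo annotation is not attempted (see above).
* Signature positions in the output are artifact-defined; the
  inventory prints residues only, so positions cannot be checked
  against it.
* The published cohort contributions (84.64% / 76.40%) and lysimeter
  WUE values rest on per-plant raw data that is not machine-readable
  here; the package covers the estimator's correctness through
  recovery experiments instead.
* The LSD letter display assumes separability is monotone in mean
  distance (exact for balanced groups); severely unbalanced designs may
  need a clique-based display.
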