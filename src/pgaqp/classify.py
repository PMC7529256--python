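"""Family assignment and substrate-permeability inference.

Classification follows nearest-reference logic: each accepted aquaporin
protein is globally aligned to a curated reference panel covering the
five higher-plant families (PIP, TIP, NIP, SIP, XIP) and inherits the
family and subfamily of its best-scoring reference, cross-checked
against the signature residues observed for that family in the packaged
inventory. Substrate permeability is then inferred from the ar/R
selectivity filter and related features through a small rule table
assembled from published structure-function associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .io import log
from .registries import load_table2_registry
from .signatures import ReferenceIsoform, SignatureProfile

FAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


def pairwise_align(a: str, b: str) -> tuple[float, float, int]:
    """Optimal global alignment (BLOSUM62, affine gaps: open 10, extend 1).

    Returns (score, identity_pct, n_columns); identity is exact matches
    over alignment columns, gap columns included.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires two non-empty sequences")
    aln = _aligner().align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_a = prev_b = 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        columns += max(as_ - prev_a, bs - prev_b) + (ae - as_)
        matches += sum(1 for k in range(ae - as_) if a[as_ + k] == b[bs + k])
        prev_a, prev_b = ae, be
    columns += max(len(a) - prev_a, len(b) - prev_b)
    identity = 100.0 * matches / columns if columns else 0.0
    return float(aln.score), identity, columns


@dataclass
class FamilyAssignment:
    protein_id: str
    family: str  # PIP/TIP/NIP/SIP/XIP/unclassified
    subfamily: str
    proposed_name: str
    nearest_reference: str
    identity_pct: float
    signature_consistent: bool


@lru_cache(maxsize=1)
def _family_signature_sets() -> dict[str, dict[str, set]]:
    """Observed ar/R tetrads and Froger P2-P5 quadruplets per family."""
    sets: dict[str, dict[str, set]] = {}
    for e in load_table2_registry():
        fam = e.isoform[2:5]
        d = sets.setdefault(fam, {"arR": set(), "froger": set()})
        d["arR"].add(e.arR)
        d["froger"].add(e.froger[1:])
    return sets


def signature_consistent_with(family: str, signature: SignatureProfile | None) -> bool:
    """Is the extracted signature within the family's observed residue sets?"""
    if signature is None or family not in _family_signature_sets():
        return False
    sets = _family_signature_sets()[family]
    arr_ok = signature.arR is not None and tuple(signature.arR) in sets["arR"]
    froger_ok = (
        signature.froger is not None and tuple(signature.froger[1:]) in sets["froger"]
    )
    return arr_ok or froger_ok


def assign_family(
    protein_id: str,
    sequence: str,
    panel: Sequence[ReferenceIsoform],
    signature: SignatureProfile | None = None,
    identity_floor: float = 25.0,
    existing_names: set[str] | None = None,
    name_prefix: str = "Aqp",
) -> FamilyAssignment:
    """Nearest-reference family assignment with a signature cross-check.

    The protein inherits family/subfamily from the panel member with
    maximal global-alignment score. An assignment is demoted to
    ``unclassified`` only when identity to the nearest reference falls
    below ``identity_floor`` AND the signature is inconsistent with the
    family's observed residue sets. The proposed name takes the lowest
    numeric suffix within the subfamily not colliding with
    ``existing_names`` (the set is updated in place).
    """
    if not panel:
        raise ValueError("empty reference panel")
    covered = {r.family for r in panel}
    missing = set(FAMILIES) - covered
    if missing:
        raise ValueError(f"reference panel missing families: {sorted(missing)}")

    best_ref = None
    best = (float("-inf"), 0.0)
    for ref in panel:
        score, identity, _ = pairwise_align(sequence, ref.sequence)
        if score > best[0]:
            best = (score, identity)
            best_ref = ref
    assert best_ref is not None
    identity = best[1]

    consistent = signature_consistent_with(best_ref.family, signature)
    if identity < identity_floor and not consistent:
        return FamilyAssignment(
            protein_id=protein_id,
            family="unclassified",
            subfamily="",
            proposed_name="",
            nearest_reference=best_ref.id,
            identity_pct=identity,
            signature_consistent=False,
        )

    if existing_names is None:
        existing_names = set()
    k = 1
    while f"{name_prefix}{best_ref.subfamily}-{k}" in existing_names:
        k += 1
    name = f"{name_prefix}{best_ref.subfamily}-{k}"
    existing_names.add(name)
    return FamilyAssignment(
        protein_id=protein_id,
        family=best_ref.family,
        subfamily=best_ref.subfamily,
        proposed_name=name,
        nearest_reference=best_ref.id,
        identity_pct=identity,
        signature_consistent=consistent,
    )


# ---------------------------------------------------------------------------
# Substrate-permeability rules
# ---------------------------------------------------------------------------

@dataclass
class PermeabilityPrediction:
    protein_id: str
    substrates: frozenset[str]
    restricted: frozenset[str]
    rules_fired: tuple[str, ...]


#: ar/R-tetrad rules: id -> (tetrad matcher, substrates, restricted)
OSPIP13_FROGER = ("Q", "S", "A", "F", "W")


def _arR_matches(arR: tuple[str, ...], pattern: tuple[str, ...]) -> bool:
    return all(a in alts.split("/") for a, alts in zip(arR, pattern))


ARR_RULES: tuple[tuple[str, tuple[str, ...], frozenset, frozenset], ...] = (
    ("FHTR_water_h2o2", ("F", "H", "T", "R"), frozenset({"water", "H2O2"}), frozenset()),
    ("HIGR_water_nh3_urea_h2o2", ("H", "I", "G", "R"),
     frozenset({"water", "NH3", "urea", "H2O2"}), frozenset()),
    ("HIAV_nh3_urea_h2o2_no_water", ("H", "I", "A", "V"),
     frozenset({"NH3", "urea", "H2O2"}), frozenset({"water"})),
    ("WVAR_water_nh3_h2o2", ("W", "V", "A", "R"),
     frozenset({"water", "NH3", "H2O2"}), frozenset()),
    ("AxxR_restricted_water_nh3", ("A", "I/A", "G/A", "R"),
     frozenset(), frozenset({"water", "NH3"})),
)


def predict_permeability(
    signature: SignatureProfile, family: str, subfamily: str = ""
) -> PermeabilityPrediction:
    """Fire every matching substrate rule for one signature.

    Rules (each an independent published association):
      * F-H-T-R -> water, H2O2
      * H-I-G-R -> water, NH3, urea, H2O2
      * H-I-A-V -> NH3, urea, H2O2; water restricted
      * W-V-A-R -> water, NH3, H2O2
      * A-(I|A)-(G|A)-R -> water and NH3 restricted
      * G-S-G-R AND exactly 108 residues between the NPA motifs -> silicon
      * PIP with Ile immediately before the P4 and P5 Froger columns -> CO2
      * PIP1 with the F-H-T-R filter and >= 4/5 Froger match to the
        OsPIP1-3 pattern (Q,S,A,F,W) -> NO3

    ``substrates`` is the union over fired rules; ``restricted`` is the
    union of restrictions minus anything another rule granted.
    """
    substrates: set[str] = set()
    restricted: set[str] = set()
    fired: list[str] = []
    arR = tuple(signature.arR) if signature.arR is not None else None

    if arR is not None:
        for rule_id, pattern, subs, restr in ARR_RULES:
            if _arR_matches(arR, pattern):
                substrates |= subs
                restricted |= restr
                fired.append(rule_id)
        if arR == ("G", "S", "G", "R") and signature.inter_npa_spacing == 108:
            substrates.add("silicon")
            fired.append("GSGR_spacing108_silicon")

    if family == "PIP" and signature.pre_p4 == "I" and signature.pre_p5 == "I":
        substrates.add("CO2")
        fired.append("PIP_ile_pre_p4p5_co2")

    if (
        family == "PIP"
        and subfamily == "PIP1"
        and arR == ("F", "H", "T", "R")
        and signature.froger is not None
        and sum(a == b for a, b in zip(signature.froger, OSPIP13_FROGER)) >= 4
    ):
        substrates.add("NO3")
        fired.append("PIP1_ospip13_like_no3")

    return PermeabilityPrediction(
        protein_id=signature.protein_id,
        substrates=frozenset(substrates),
        restricted=frozenset(restricted - substrates),
        rules_fired=tuple(fired),
    )
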