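"""Packaged registries of the published pearl-millet aquaporin inventory.

Two small TSV tables ship with the package: the 33-gene family inventory
(gene coordinates, transcript/protein lengths, molecular weights) and the
per-isoform conserved-domain residues (dual NPA motifs, ar/R selectivity
filter, Froger positions P1-P5). Values are stored verbatim as printed;
known internal inconsistencies of the source tables are preserved, not
corrected (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

GAP = "-"

#: rows whose printed protein length deviates from transcript_length/3 - 1
LENGTH_RULE_EXCEPTIONS = frozenset({"PgPIP1-4"})


@dataclass(frozen=True)
class Table1Entry:
    gene_name: str
    glean_id: str
    gene_length: int
    transcript_length: int
    protein_length: int
    protein_mw: float
    chromosome: str
    start: int
    end: int

    @property
    def family(self) -> str:
        """PIP/TIP/NIP/SIP, derived from the gene-name prefix."""
        return self.gene_name[2:5]

    @property
    def subfamily(self) -> str:
        """e.g. PIP2 from PgPIP2-1."""
        return self.gene_name[2:].split("-")[0]


@dataclass(frozen=True)
class Table2Entry:
    isoform: str
    npa_lb: str
    npa_le: str
    arR: tuple[str, str, str, str]
    froger: tuple[str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.npa_lb) != 3 or len(self.npa_le) != 3:
            raise ValueError(f"{self.isoform}: NPA triplets must have length 3")
        if len(self.arR) != 4 or len(self.froger) != 5:
            raise ValueError(f"{self.isoform}: arR must be 4 residues, Froger 5")
        if any(r == GAP for r in self.froger[1:]):
            raise ValueError(f"{self.isoform}: only Froger P1 may be a gap")


def _read_packaged(name: str) -> list[list[str]]:
    text = resources.files("pgaqp").joinpath("data", name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def load_table1_registry() -> list[Table1Entry]:
    """The 33-gene inventory, in printed row order, keyed by gene_name."""
    return [
        Table1Entry(
            gene_name=r["gene_name"],
            glean_id=r["glean_id"],
            gene_length=int(r["gene_length"]),
            transcript_length=int(r["transcript_length"]),
            protein_length=int(r["protein_length"]),
            protein_mw=float(r["protein_mw"]),
            chromosome=r["chromosome"],
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for r in _read_packaged("table1.tsv")
    ]


def load_table2_registry() -> list[Table2Entry]:
    """The per-isoform conserved-domain residues (33 rows)."""
    return [
        Table2Entry(
            isoform=r["isoform"],
            npa_lb=r["npa_lb"],
            npa_le=r["npa_le"],
            arR=(r["arR_H2"], r["arR_H5"], r["arR_LE1"], r["arR_LE2"]),
            froger=(
                r["froger_P1"], r["froger_P2"], r["froger_P3"],
                r["froger_P4"], r["froger_P5"],
            ),
        )
        for r in _read_packaged("table2.tsv")
    ]


@dataclass(frozen=True)
class TandemCluster:
    """Genes of one subfamily lying close together on one chromosome."""

    chromosome: str
    subfamily: str
    genes: tuple[str, ...]
    start: int
    end: int

    @property
    def span_bp(self) -> int:
        """Extent of the cluster, max(end) - min(start) of member genes."""
        return self.end - self.start


def tandem_clusters(
    entries: list[Table1Entry], max_gap: int = 100_000
) -> list[TandemCluster]:
    """Find same-subfamily gene clusters by chromosomal proximity.

    Genes of one subfamily on one chromosome are merged into a cluster when
    the gap between consecutive gene spans is at most ``max_gap``; clusters
    of a single gene are dropped. Candidate tandem-duplication regions in
    the inventory surface this way.
    """
    by_key: dict[tuple[str, str], list[Table1Entry]] = {}
    for e in entries:
        by_key.setdefault((e.chromosome, e.subfamily), []).append(e)

    clusters: list[TandemCluster] = []
    for (chrom, subfam), group in sorted(by_key.items()):
        group = sorted(group, key=lambda e: e.start)
        block: list[Table1Entry] = []
        for e in group:
            if block and e.start - max(b.end for b in block) > max_gap:
                if len(block) > 1:
                    clusters.append(_mk_cluster(chrom, subfam, block))
                block = []
            block.append(e)
        if len(block) > 1:
            clusters.append(_mk_cluster(chrom, subfam, block))
    return clusters


def _mk_cluster(chrom: str, subfam: str, block: list[Table1Entry]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        subfamily=subfam,
        genes=tuple(e.gene_name for e in block),
        start=min(e.start for e in block),
        end=max(e.end for e in block),
    )
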