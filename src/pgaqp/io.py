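"""Readers and writers for the formats the pipeline consumes and produces.

Coordinates are 1-based inclusive throughout (BLAST tabular / GFF3
convention); any conversion is localized to the reader or writer touching
the foreign format.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

log = logging.getLogger("pgaqp")

DEFAULT_CONFIG: dict = {
    "screen": {"min_bitscore": 100.0, "max_evalue": 1e-5, "merge_gap": 2000},
    "annotate": {"flank": 1000},
    "signatures": {"tm_window": 19, "tm_threshold": 1.6, "tm_merge_gap": 5},
    "classify": {"identity_floor": 25.0},
    "hydraulics": {"free_intercept": True, "alpha": 0.05},
    "expression": {"efficiency": 2.0},
}


def setup_logging(level: str = "INFO") -> None:
    """Stage-tagged logging to stderr (idempotent)."""
    root = logging.getLogger("pgaqp")
    if not root.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        root.addHandler(h)
    root.setLevel(level.upper())


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config file over the built-in defaults (shallow per stage)."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for stage, values in user.items():
            cfg.setdefault(stage, {}).update(values or {})
    return cfg


class ParseError(ValueError):
    """A malformed input file; message carries file and line context."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One nucleotide (or protein) sequence record."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse a FASTA file into records, uppercasing residues, order preserved."""
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []
    name_line = 0

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{name_line}: record '{name}' has no sequence")
        records.append(GenomeSequence(name, seq.upper()))

    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{i}: empty FASTA header")
                name_line = i
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}:{i}: sequence before first header")
                chunks.append(line)
    flush(-1)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST 12-column tabular
# ---------------------------------------------------------------------------

BLAST_COLUMNS = (
    "query_id subject_id pident aln_length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tab(path: str | Path) -> list:
    """Read 12-column tabular BLAST output into :class:`~pgaqp.screen.HspRecord`.

    Subject coordinates are normalized so sstart <= send, with the original
    orientation kept as a strand flag.
    """
    from .screen import HspRecord  # local import: avoid cycle

    out: list[HspRecord] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}:{i}: expected 12 columns, got {len(fields)}")
            try:
                pident = float(fields[2])
                aln_length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-numeric field ({exc})") from None
            strand = "+" if sstart <= send else "-"
            if strand == "-":
                sstart, send = send, sstart
            out.append(
                HspRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=pident,
                    aln_length=aln_length,
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                    strand=strand,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return out


def write_blast_tab(hsps: Sequence, path: str | Path) -> None:
    """Write HSPs back to the 12-column dialect (minus-strand coords re-swapped)."""
    with open(path, "w") as fh:
        for h in hsps:
            s, e = (h.send, h.sstart) if h.strand == "-" else (h.sstart, h.send)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.pident, h.aln_length, 0, 0,
                        h.qstart, h.qend, s, e, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (gene/exon features only — all this pipeline emits or consumes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedGene:
    """A gene with its exon chain, 1-based inclusive genome coordinates."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            prev_end = e


def read_gff3(path: str | Path) -> list[AnnotatedGene]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{i}: expected 9 GFF3 columns")
            seq_id, _, ftype, start, end, _, strand, _, attrs = f
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{i}: gene without ID attribute")
                genes[gid] = {
                    "seq_id": seq_id,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent not in genes:
                    raise ParseError(f"{path}:{i}: exon with unknown Parent")
                genes[parent]["exons"].append((int(start), int(end)))
    return [
        AnnotatedGene(
            gene_id=gid,
            seq_id=g["seq_id"],
            start=g["start"],
            end=g["end"],
            strand=g["strand"],
            exons=tuple(sorted(g["exons"])),
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def write_gff3(genes: Iterable[AnnotatedGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\tpgaqp\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\tpgaqp\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{j};Parent={g.gene_id}\n"
                )
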