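"""Back-splice junction calling from chimeric read alignments.

Circular RNAs are produced by back-splicing: a downstream splice donor is
joined to an upstream acceptor, so a read spanning the junction aligns as a
chimera whose two segments sit in *reversed* genomic order relative to
linear splicing. This module parses tab-delimited chimeric-junction records
(columns 1-9 compatible with the STAR chimeric-junction layout), calls
back-splice junctions per sample, annotates them against gene models by
exon-boundary matching, and merges per-sample calls into a cohort count
matrix.

Coordinate conventions
----------------------
The chimeric dialect is 1-based: ``pos_a`` is the first base after the end
of the donor segment (reading in transcript direction) and ``pos_b`` is the
last base before the start of the acceptor segment. Internally junctions
use 0-based half-open ``[start, end)`` intervals, serialized as
``chrom:start|end:strand``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError
from .genes import GeneModel

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class ChimericRecord:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    junction_type: int
    read_name: str = ""
    anchor_a: int = 0
    anchor_b: int = 0


@dataclass
class BackspliceJunction:
    """A called circRNA back-splice junction with per-sample read support."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    gene_id: str = UNANNOTATED
    counts: dict = field(default_factory=dict)

    @property
    def junction_id(self) -> str:
        return format_junction_id(self.chrom, self.start, self.end, self.strand)


def format_junction_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}|{end}:{strand}"


def parse_junction_id(junction_id: str) -> tuple[str, int, int, str]:
    """Invert :func:`format_junction_id`; raises ParseError on malformed IDs."""
    try:
        chrom, coords, strand = junction_id.rsplit(":", 2)
        start_s, end_s = coords.split("|")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"malformed junction ID {junction_id!r}") from exc
    if strand not in ("+", "-") or start >= end or start < 0:
        raise ParseError(f"malformed junction ID {junction_id!r}")
    return chrom, start, end, strand


def parse_chimeric_file(path) -> list[ChimericRecord]:
    """Parse a chimeric-junction TSV into records, preserving line order.

    Lines starting with ``#`` are skipped. At least 7 columns are required
    (chromA, posA, strandA, chromB, posB, strandB, junction_type); columns
    8-9 are anchor lengths and column 10 the read name when present. Extra
    columns are ignored.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"expected >=7 columns, got {len(f)}", lineno)
            if f[2] not in ("+", "-") or f[5] not in ("+", "-"):
                raise ParseError(f"bad strand {f[2]!r}/{f[5]!r}", lineno)
            try:
                pos_a, pos_b = int(f[1]), int(f[4])
                jtype = int(f[6])
                anchor_a = int(f[7]) if len(f) > 7 else 0
                anchor_b = int(f[8]) if len(f) > 8 else 0
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", lineno) from exc
            if pos_a < 1 or pos_b < 1:
                raise ParseError("positions must be >= 1", lineno)
            records.append(
                ChimericRecord(
                    chrom_a=f[0],
                    pos_a=pos_a,
                    strand_a=f[2],
                    chrom_b=f[3],
                    pos_b=pos_b,
                    strand_b=f[5],
                    junction_type=jtype,
                    read_name=f[9] if len(f) > 9 else "",
                    anchor_a=anchor_a,
                    anchor_b=anchor_b,
                )
            )
    return records


def is_backsplice(rec: ChimericRecord) -> bool:
    """True iff the record is evidence for a back-splice junction.

    Both segments must be on the same chromosome and strand, with the
    acceptor upstream of the donor *in transcript orientation*: on ``+``
    the acceptor coordinate is genomically left of the donor
    (``pos_b < pos_a``), on ``-`` the reverse.
    """
    if rec.chrom_a != rec.chrom_b or rec.strand_a != rec.strand_b:
        return False
    if rec.strand_a == "+":
        return rec.pos_b < rec.pos_a
    return rec.pos_b > rec.pos_a


def backsplice_coords(rec: ChimericRecord) -> tuple[str, int, int, str]:
    """Genomic interval (0-based half-open) of the circRNA a record supports."""
    if rec.strand_a == "+":
        # acceptor starts circ: start = pos_b (1-based pos_b is the base
        # before the acceptor start => 0-based start); donor ends it.
        return rec.chrom_a, rec.pos_b, rec.pos_a - 1, "+"
    return rec.chrom_a, rec.pos_a, rec.pos_b - 1, "-"


def call_backsplice(records, min_reads: int = 1) -> list[BackspliceJunction]:
    """Group back-splice evidence and emit junctions with >= min_reads support.

    The default ``min_reads=1`` matches the species definition (a circRNA
    counts as detected whenever its read count exceeds zero); pass 2 for a
    CIRCexplorer-style stricter call.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    support = Counter(
        backsplice_coords(r) for r in records if is_backsplice(r)
    )
    junctions = [
        BackspliceJunction(chrom, start, end, strand)
        for (chrom, start, end, strand), n in support.items()
        if n >= min_reads
    ]
    for j in junctions:
        j.counts["__count__"] = support[(j.chrom, j.start, j.end, j.strand)]
    return sorted(junctions, key=lambda j: (j.chrom, j.start, j.end, j.strand))


def annotate_junctions(
    junctions, gene_models, tolerance_nt: int = 0
) -> list[BackspliceJunction]:
    """Assign a parental gene to each junction by exon-boundary matching.

    A junction is annotated to gene G iff its start matches an exon start
    of G and its end matches an exon end of G, both within ``tolerance_nt``
    and on the same chromosome and strand; otherwise it stays
    "unannotated". Distinct junctions within one gene are kept separate —
    circRNA isoforms of the same gene are never merged.
    """
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in gene_models:
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    for j in junctions:
        j.gene_id = UNANNOTATED
        hits = []
        for g in by_loc.get((j.chrom, j.strand), []):
            start_ok = any(
                abs(j.start - s) <= tolerance_nt for s in g.exon_starts
            )
            end_ok = any(abs(j.end - e) <= tolerance_nt for e in g.exon_ends)
            if start_ok and end_ok:
                hits.append(g.gene_id)
        if hits:
            j.gene_id = sorted(hits)[0]
    return junctions


def merge_samples(per_sample: dict) -> pd.DataFrame:
    """Merge per-sample junction lists into a junction x sample count matrix.

    ``per_sample`` maps sample_id -> list of BackspliceJunction (as emitted
    by :func:`call_backsplice`). Junctions absent from a sample get 0.
    """
    sample_ids = list(per_sample)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample IDs")
    data: dict[str, dict[str, int]] = {}
    for sample, junctions in per_sample.items():
        for j in junctions:
            jid = j.junction_id
            count = j.counts.get("__count__", j.counts.get(sample, 0))
            data.setdefault(jid, {})[sample] = count
    mat = pd.DataFrame(data).T.reindex(columns=sample_ids)
    if mat.empty:
        mat = pd.DataFrame(index=pd.Index([], name="junction_id"), columns=sample_ids)
    mat = mat.fillna(0).astype(int).sort_index()
    mat.index.name = "junction_id"
    mat.columns.name = "sample_id"
    return mat
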