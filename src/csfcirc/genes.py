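"""Gene models on a genome: a minimal exon-aware representation with BED12 I/O.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError


@dataclass(frozen=True)
class GeneModel:
    """A multi-exon transcript model.

    exons are (start, end) pairs, 0-based half-open, sorted by start and
    non-overlapping; `start`/`end` bound the whole transcript.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon [{s},{e}) outside gene bounds for {self.gene_id}"
                )

    @property
    def exon_starts(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.exons)

    @property
    def exon_ends(self) -> tuple[int, ...]:
        return tuple(e for _, e in self.exons)


def read_bed12(path) -> list[GeneModel]:
    """Read gene models from a BED12 file (one transcript per line)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"expected 12 BED12 columns, got {len(fields)}", lineno
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if len(sizes) != block_count or len(offsets) != block_count:
                raise ParseError("block count mismatch", lineno)
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            try:
                models.append(
                    GeneModel(name, chrom, start, end, strand, exons)
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return models


def write_bed12(models, path) -> None:
    with open(path, "w") as fh:
        for g in models:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )
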