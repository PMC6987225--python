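"""Sequence and gene-annotation I/O plus strand/windowing primitives.

Coordinates are 0-based half-open everywhere in memory; human-readable
reports convert to 1-based inclusive at the output boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

Interval = tuple[int, int]


class SequenceError(ValueError):
    """Raised for malformed sequences or annotations."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence over the strict alphabet {A, C, G, T}.

    Ambiguity codes are rejected rather than skipped because every 6-bp
    window of the sequence enters the binding partition function.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, b in enumerate(self.bases):
            if b not in VALID_BASES:
                raise SequenceError(
                    f"record {self.id!r}: invalid base {b!r} at position {pos + 1}"
                )

    @property
    def n(self) -> int:
        """Sequence length N in bp."""
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement of a strict-alphabet sequence."""
    for b in bases:
        if b not in VALID_BASES:
            raise SequenceError(f"invalid base {b!r} in reverse_complement input")
    return bases.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Lowercase (softmasked) bases are uppercased; any non-ACGT character,
    including hard-mask ``N``, raises :class:`SequenceError` naming the
    record and 1-based position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def iter_windows(record: "SequenceRecord | str", k: int) -> Iterator[tuple[int, str]]:
    """Yield ``(position, k-mer)`` for every k-bp window on one strand.

    Positions are 0-based offsets of the window's first base; exactly
    ``N - k + 1`` windows are produced in increasing order.
    """
    bases = record.bases if isinstance(record, SequenceRecord) else record
    n = len(bases)
    if k > n:
        raise SequenceError(f"window size {k} exceeds sequence length {n}")
    if k < 1:
        raise SequenceError("window size must be >= 1")
    for i in range(n - k + 1):
        yield i, bases[i : i + k]


def _merge(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge half-open intervals; rejects malformed ones."""
    for s, e in intervals:
        if s < 0 or e <= s:
            raise SequenceError(f"malformed interval [{s}, {e})")
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(span: Interval, holes: list[Interval]) -> list[Interval]:
    """Subtract merged `holes` from `span`, returning the remainder."""
    out: list[Interval] = []
    cursor = span[0]
    for s, e in holes:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


@dataclass
class GeneModel:
    """Interval structure of an extended gene on one reference sequence.

    The extended region is the transcript span padded by a flank (2 kb by
    default) on both sides.  The regulatory region (RR) is everything in
    the extended span that is not CDS — by this definition UTRs, introns
    and the flanks all count as regulatory.
    """

    gene_id: str
    seq_ref: str
    span: Interval
    cds: list[Interval] = field(default_factory=list)
    exons: list[Interval] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        self.cds = _merge(self.cds)
        self.exons = _merge(self.exons)
        s0, s1 = self.span
        if s0 < 0 or s1 <= s0:
            raise SequenceError(f"gene {self.gene_id!r}: malformed span {self.span}")
        for s, e in self.cds + self.exons:
            if s < s0 or e > s1:
                raise SequenceError(
                    f"gene {self.gene_id!r}: interval [{s},{e}) outside span {self.span}"
                )
        # CDS must lie within exons when exons are annotated
        if self.exons:
            for s, e in self.cds:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise SequenceError(
                        f"gene {self.gene_id!r}: CDS [{s},{e}) not contained in any exon"
                    )

    @property
    def regulatory(self) -> list[Interval]:
        """Extended span minus CDS (half-open intervals)."""
        return _subtract(self.span, self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def regulatory_length(self) -> int:
        return sum(e - s for s, e in self.regulatory)


def read_annotation(path: str | Path, fmt: str = "GFF3", flank: int = 2000) -> GeneModel:
    """Read a single-gene annotation into a :class:`GeneModel`.

    GFF3: only ``gene``, ``mRNA``, ``exon`` and ``CDS`` features are
    consumed (others are ignored with a logged notice).  When several
    mRNAs exist, the CDS set of the transcript with the longest total CDS
    is used.  BED dialect: 6 columns ``(ref, start, end, feature, score,
    strand)`` with the name column naming the feature type (transcript,
    exon or CDS), one gene per file.

    The extended span is the transcript span padded by ``flank`` bp on
    both sides, clipped at 0 on the left.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.upper()
    if fmt == "GFF3":
        return _read_gff3(path, flank)
    if fmt == "BED":
        return _read_bed(path, flank)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gff3(path: Path, flank: int) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known = {"gene", "mRNA", "exon", "CDS"}
    for ftype in db.featuretypes():
        if ftype not in known:
            logger.info("ignoring GFF3 feature type %r", ftype)

    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise SequenceError(f"{path}: expected exactly one gene, found {len(genes)}")
    gene = genes[0]

    mrnas = list(db.children(gene, featuretype="mRNA"))
    if mrnas:
        def cds_len(m):  # GFF is 1-based inclusive: length = end - start + 1
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        best = max(mrnas, key=cds_len)
        cds = [(c.start - 1, c.end) for c in db.children(best, featuretype="CDS")]
        exons = [(e.start - 1, e.end) for e in db.children(best, featuretype="exon")]
        tspan = (best.start - 1, best.end)
    else:
        cds = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        exons = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
        tspan = (gene.start - 1, gene.end)

    for s, e in cds:
        if s < tspan[0] or e > tspan[1]:
            raise SequenceError(f"{path}: CDS [{s},{e}) outside transcript {tspan}")
    span = (max(0, tspan[0] - flank), tspan[1] + flank)
    return GeneModel(
        gene_id=gene.id,
        seq_ref=gene.seqid,
        span=span,
        cds=cds,
        exons=exons,
        strand=gene.strand if gene.strand in "+-" else "+",
    )


def _read_bed(path: Path, flank: int) -> GeneModel:
    tspan = None
    cds: list[Interval] = []
    exons: list[Interval] = []
    ref = None
    strand = "+"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise SequenceError(f"{path}: BED line needs >= 4 columns: {line!r}")
            ref = ref or cols[0]
            start, end = int(cols[1]), int(cols[2])
            feature = cols[3]
            if len(cols) >= 6 and cols[5] in "+-":
                strand = cols[5]
            if feature.lower() == "transcript":
                tspan = (start, end)
            elif feature.lower() == "exon":
                exons.append((start, end))
            elif feature.lower() == "cds":
                cds.append((start, end))
            else:
                logger.info("ignoring BED feature %r", feature)
    if tspan is None:
        if not exons:
            raise SequenceError(f"{path}: no transcript or exon features")
        merged = _merge(exons)
        tspan = (merged[0][0], merged[-1][1])
    for s, e in cds:
        if s < tspan[0] or e > tspan[1]:
            raise SequenceError(f"{path}: CDS [{s},{e}) outside transcript {tspan}")
    span = (max(0, tspan[0] - flank), tspan[1] + flank)
    return GeneModel(
        gene_id=ref or "gene", seq_ref=ref or "seq", span=span, cds=cds,
        exons=exons, strand=strand,
    )
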