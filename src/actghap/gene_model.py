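"""Transcript models and the region partition driving level assignment.

A gene is represented by one transcript model (MANE-style: a single
standardized transcript per gene).  The exonic sequence is partitioned
into 5'UTR, CDS and 3'UTR blocks; the gaps between exons are introns;
two fixed-length flanks abut the gene body.  All internal coordinates
are 0-based half-open; GFF3 I/O converts at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils

STRANDS = ("+", "-")

#: default flank used for the upstream/downstream fields and the
#: haplotype extraction window (bp)
DEFAULT_FLANK = 5000

#: wider flank reserved for cross-assembly anchoring contexts; not used
#: in core paths
ANCHOR_FLANK = 7000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript of one gene on one assembly."""

    gene_symbol: str
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    assembly: str = ""

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        self.validate()

    @property
    def coding_flag(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: empty exon list")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping/unsorted exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )
        for iv in self.cds:
            if not any(
                exon.start <= iv.start and iv.end <= exon.end
                for exon in self.exons
            ):
                raise ValueError(
                    f"{self.transcript_id}: CDS {iv.start}-{iv.end} "
                    "not contained in a single exon"
                )
        total = sum(iv.length for iv in self.cds)
        if total and total % 3 != 0:
            warnings.warn(
                f"{self.transcript_id}: CDS length {total} is not a "
                "multiple of 3",
                stacklevel=2,
            )


@dataclass
class RegionPartition:
    """Disjoint region partition of one gene window.

    ``utr5``/``utr3`` hold the exonic non-coding blocks (for non-coding
    genes every exon block is listed under ``utr5`` so that the T-level
    sequence covers the whole transcript).  ``upstream``/``downstream``
    are strand-aware: ``upstream`` is the 5' flank in transcript
    orientation.
    """

    utr5: list[GenomicInterval]
    cds: list[GenomicInterval]
    introns: list[GenomicInterval]
    utr3: list[GenomicInterval]
    upstream: GenomicInterval
    downstream: GenomicInterval
    gene_body: GenomicInterval
    strand: str

    @property
    def window(self) -> GenomicInterval:
        """Full analysis window (gene body plus both flanks)."""
        start = min(self.upstream.start, self.downstream.start)
        end = max(self.upstream.end, self.downstream.end)
        return GenomicInterval(self.gene_body.contig, start, end, self.strand)

    def region_at(self, pos: int) -> Optional[str]:
        """Region label covering ``pos``: one of cds/utr5/utr3/intron/
        upstream/downstream, or None outside the window."""
        for label, ivs in (
            ("cds", self.cds),
            ("utr5", self.utr5),
            ("utr3", self.utr3),
            ("intron", self.introns),
        ):
            if any(iv.contains(pos) for iv in ivs):
                return label
        if self.upstream.contains(pos):
            return "upstream"
        if self.downstream.contains(pos):
            return "downstream"
        return None

    def ordered_regions(self) -> list[tuple[str, GenomicInterval]]:
        """All labelled intervals in genomic order (tiles the window)."""
        out = [("upstream", self.upstream), ("downstream", self.downstream)]
        out += [("utr5", iv) for iv in self.utr5]
        out += [("cds", iv) for iv in self.cds]
        out += [("utr3", iv) for iv in self.utr3]
        out += [("intron", iv) for iv in self.introns]
        return sorted(out, key=lambda it: it[1].start)

    def to_bed(self) -> list[tuple[str, int, int, str, int, str]]:
        """BED6 rows (contig, start, end, label, score, strand)."""
        return [
            (iv.contig, iv.start, iv.end, label, 0, self.strand)
            for label, iv in self.ordered_regions()
        ]


def _subtract(exon: GenomicInterval, blocks: list[GenomicInterval]) -> list[GenomicInterval]:
    """Pieces of ``exon`` not covered by ``blocks`` (blocks sorted, disjoint)."""
    pieces = []
    cursor = exon.start
    for b in blocks:
        if b.end <= exon.start or b.start >= exon.end:
            continue
        if b.start > cursor:
            pieces.append(
                GenomicInterval(exon.contig, cursor, b.start, exon.strand)
            )
        cursor = max(cursor, b.end)
    if cursor < exon.end:
        pieces.append(GenomicInterval(exon.contig, cursor, exon.end, exon.strand))
    return pieces


def partition_regions(model: TranscriptModel, flank: int = DEFAULT_FLANK) -> RegionPartition:
    """Partition the gene window of ``model`` into disjoint regions.

    The exonic non-coding blocks genomically left of the CDS are 5'UTR
    on the + strand and 3'UTR on the - strand (and vice versa on the
    right).  Flanks have length exactly ``flank`` and abut the gene
    body.
    """
    if not model.exons:
        raise ValueError("empty exon list")
    contig, strand = model.contig, model.strand
    gene_body = GenomicInterval(contig, model.start, model.end, strand)
    if gene_body.start - flank < 0:
        raise ValueError(
            f"{model.transcript_id}: flank {flank} extends past contig start"
        )

    introns = [
        GenomicInterval(contig, prev.end, cur.start, strand)
        for prev, cur in zip(model.exons, model.exons[1:])
        if cur.start > prev.end
    ]

    noncoding: list[GenomicInterval] = []
    for exon in model.exons:
        noncoding.extend(_subtract(exon, model.cds))

    if model.coding_flag:
        cds_start = model.cds[0].start
        cds_end = model.cds[-1].end
        left = [iv for iv in noncoding if iv.end <= cds_start]
        right = [iv for iv in noncoding if iv.start >= cds_end]
        mid = [iv for iv in noncoding if iv not in left and iv not in right]
        if mid:  # exonic non-coding strictly inside the CDS span: impossible
            raise ValueError(
                f"{model.transcript_id}: exonic non-coding block inside CDS span"
            )
        utr5, utr3 = (left, right) if strand == "+" else (right, left)
    else:
        utr5, utr3 = noncoding, []

    left_flank = GenomicInterval(contig, gene_body.start - flank, gene_body.start, strand)
    right_flank = GenomicInterval(contig, gene_body.end, gene_body.end + flank, strand)
    upstream, downstream = (
        (left_flank, right_flank) if strand == "+" else (right_flank, left_flank)
    )
    return RegionPartition(
        utr5=utr5,
        cds=list(model.cds),
        introns=introns,
        utr3=utr3,
        upstream=upstream,
        downstream=downstream,
        gene_body=gene_body,
        strand=strand,
    )


_TRANSCRIPT_TYPES = {
    "mRNA",
    "ncRNA",
    "lnc_RNA",
    "transcript",
    "snoRNA",
    "snRNA",
    "miRNA",
    "pseudogenic_transcript",
}


def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def read_gff(path: str, assembly_name: str = "") -> list[TranscriptModel]:
    """Read transcript models from a GFF3 file.

    Expects gene / (mRNA|ncRNA|transcript) / exon / CDS features with
    ``Parent`` links and 1-based closed coordinates.  Returns one model
    per transcript, ordered by (contig, start, transcript_id).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for tx in db.all_features():
        if tx.featuretype not in _TRANSCRIPT_TYPES:
            continue
        parents = list(db.parents(tx, featuretype="gene"))
        if not parents:
            raise ValueError(
                f"transcript {tx.id}: no parent gene feature"
            )
        gene = parents[0]
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, tx.strand)
            for e in db.children(tx, featuretype="exon")
        ]
        cds = [
            GenomicInterval(c.seqid, c.start - 1, c.end, tx.strand)
            for c in db.children(tx, featuretype="CDS")
        ]
        if not exons:
            raise ValueError(f"transcript {tx.id}: no exon features")
        model = TranscriptModel(
            gene_symbol=_attr(gene, "Name", "gene_name") or gene.id,
            transcript_id=_attr(tx, "ID", "transcript_id") or tx.id,
            gene_id=gene.id,
            contig=tx.seqid,
            strand=tx.strand,
            exons=exons,
            cds=cds,
            assembly=assembly_name,
        )
        models.append(model)
    models.sort(key=lambda m: (m.contig, m.start, m.transcript_id))
    return models
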