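"""Readers and writers for the standard formats the pipeline touches:
FASTA, GFF3, SAM/BAM, calibration/variant/catalog/expression TSV, the
per-gene catalog JSON, and the haplotype-dictionary BAM.

All user-facing text formats carry 1-based coordinates; everything in
memory is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_model import RegionPartition, TranscriptModel
from .nomenclature import (
    ACTGCode,
    ClusterEntry,
    HaplotypeCatalog,
    apply_variants,
    format_code,
)
from .variant_engine import ContigAlignment, RawVariant

SCHEMA_VERSION = "1"

# auxiliary tags used in the haplotype-dictionary BAM
TAG_A = "XA"  # A-level id
TAG_C = "XC"  # C-level id
TAG_T = "XT"  # T-level id
TAG_G = "XG"  # G-level id
TAG_CODE = "XH"  # formatted composite code string
TAG_POPS = "XP"  # population counts, "POP=count" semicolon-joined
TAG_COUNT = "XN"  # global haplotype count


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def write_gff3(path, models: Sequence[TranscriptModel]) -> None:
    """Emit gene/mRNA-or-ncRNA/exon/CDS features, 1-based closed."""
    lines = ["##gff-version 3"]
    for m in models:
        gid, tid = m.gene_id, m.transcript_id
        lines.append(
            "\t".join(
                [
                    m.contig,
                    "actghap",
                    "gene",
                    str(m.start + 1),
                    str(m.end),
                    ".",
                    m.strand,
                    ".",
                    f"ID={gid};Name={m.gene_symbol}",
                ]
            )
        )
        ttype = "mRNA" if m.coding_flag else "ncRNA"
        lines.append(
            "\t".join(
                [
                    m.contig,
                    "actghap",
                    ttype,
                    str(m.start + 1),
                    str(m.end),
                    ".",
                    m.strand,
                    ".",
                    f"ID={tid};Parent={gid}",
                ]
            )
        )
        for i, e in enumerate(m.exons, 1):
            lines.append(
                "\t".join(
                    [
                        m.contig,
                        "actghap",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        m.strand,
                        ".",
                        f"ID={tid}.exon{i};Parent={tid}",
                    ]
                )
            )
        for i, c in enumerate(m.cds, 1):
            lines.append(
                "\t".join(
                    [
                        m.contig,
                        "actghap",
                        "CDS",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        m.strand,
                        "0",
                        f"ID={tid}.cds{i};Parent={tid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(path, partition: RegionPartition) -> None:
    rows = [
        "\t".join(map(str, row)) for row in partition.to_bed()
    ]
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# SAM/BAM


def _sam_header(reference_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": int(length)}
                for name, length in reference_lengths.items()
            ],
            "PG": [{"ID": "actghap", "PN": "actghap"}],
        }
    )


def write_sam(
    path,
    alignments: Sequence[ContigAlignment],
    reference_lengths: Mapping[str, int],
) -> None:
    """Write alignments as SAM (or BAM if the path ends in .bam)."""
    header = _sam_header(reference_lengths)
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for aln in sorted(alignments, key=lambda a: (a.contig, a.ref_start, a.name)):
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.name
            rec.reference_name = aln.contig
            rec.reference_start = aln.ref_start
            rec.query_sequence = aln.query
            rec.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
            rec.mapping_quality = 60
            rec.flag = 0
            out.write(rec)


def read_alignments(path) -> list[ContigAlignment]:
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        return [
            ContigAlignment.from_pysam(rec)
            for rec in fh.fetch(until_eof=True)
            if not rec.is_unmapped
        ]


# ---------------------------------------------------------------------------
# catalog serialization


def catalog_to_dict(catalog: HaplotypeCatalog) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "gene": catalog.gene,
        "transcript_id": catalog.transcript_id,
        "version": catalog.version,
        "populations": dict(catalog.populations),
        "assemblies": dict(catalog.assemblies),
        "levels": {
            level: [
                {
                    "id": e.hap_id,
                    "sequence": e.sequence,
                    "count": e.count,
                    "members": list(e.members),
                    "pop_counts": dict(e.pop_counts),
                    "assemblies": list(e.assemblies),
                }
                for e in entries
            ]
            for level, entries in catalog.levels.items()
        },
    }


def catalog_from_dict(data: dict) -> HaplotypeCatalog:
    levels = {
        level: [
            ClusterEntry(
                level=level,
                hap_id=e["id"],
                sequence=e["sequence"],
                count=e["count"],
                members=tuple(e["members"]),
                pop_counts=dict(e["pop_counts"]),
                assemblies=tuple(e["assemblies"]),
            )
            for e in entries
        ]
        for level, entries in data["levels"].items()
    }
    return HaplotypeCatalog(
        gene=data["gene"],
        transcript_id=data["transcript_id"],
        version=data["version"],
        levels=levels,
        populations=data.get("populations", {}),
        assemblies=data.get("assemblies", {}),
    )


def write_catalog_json(path, catalog: HaplotypeCatalog) -> None:
    Path(path).write_text(json.dumps(catalog_to_dict(catalog), indent=1))


def read_catalog_json(path) -> HaplotypeCatalog:
    return catalog_from_dict(json.loads(Path(path).read_text()))


def catalog_to_frame(catalog: HaplotypeCatalog) -> pd.DataFrame:
    """Catalog TSV rows: one per (level, id) cluster."""
    import hashlib

    rows = []
    pops = sorted(set(catalog.populations.values()))
    for level in sorted(catalog.levels):
        for e in catalog.levels[level]:
            row = {
                "gene": catalog.gene,
                "level": level,
                "id": e.hap_id,
                "sequence_hash": hashlib.sha1(e.sequence.encode()).hexdigest()[:12],
                "count": e.count,
                "assemblies": ",".join(e.assemblies),
            }
            for pop in pops:
                row[f"n_{pop}"] = e.pop_counts.get(pop, 0)
            rows.append(row)
    return pd.DataFrame(rows)


def write_level_fasta(path, catalog: HaplotypeCatalog, level: str) -> None:
    """Per-level FASTA export; record ids are formatted codes."""
    records = {}
    for e in catalog.levels.get(level, []):
        code = ACTGCode(prefix=catalog.gene, **{level.lower(): e.hap_id})
        records[format_code(code)] = e.sequence
    write_fasta(path, records)


# ---------------------------------------------------------------------------
# haplotype-dictionary BAM


def write_haplotype_dict_bam(
    catalog: HaplotypeCatalog,
    model: TranscriptModel,
    reference: str,
    path,
    body_haplotypes: Sequence[dict],
    window,
) -> None:
    """One alignment record per distinct gene-body haplotype.

    ``body_haplotypes`` rows need keys: ids (level->int), variants
    (list of RawVariant), count, pop_counts.  Each record is aligned to
    the reference window with a CIGAR reconstructed from its variants
    and carries the level ids, the formatted code, population counts
    and the global count as auxiliary tags (documented constants
    TAG_A..TAG_COUNT; echoed as @CO header lines).
    """
    from .synthetic import PanelHaplotype, haplotype_alignment

    header_dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.contig, "LN": len(reference)}],
        "PG": [{"ID": "actghap", "PN": "actghap"}],
        "CO": [
            f"{TAG_A}/{TAG_C}/{TAG_T}/{TAG_G}: per-level haplotype ids",
            f"{TAG_CODE}: composite haplotype code; {TAG_POPS}: population "
            f"counts; {TAG_COUNT}: global count",
        ],
    }
    header = pysam.AlignmentHeader.from_dict(header_dict)
    mode = "wb" if str(path).endswith(".bam") else "w"
    records = []
    for bh in body_haplotypes:
        ids = bh["ids"]
        code = ACTGCode(
            prefix=catalog.gene,
            a=ids.get("A", 0),
            c=ids.get("C", 0),
            t=ids.get("T", 0),
            g=ids.get("G", 0),
            version=catalog.version or None,
        )
        name = format_code(code).replace(":", "_")
        variants = tuple(bh["variants"])
        seq, _ = apply_variants(reference, window, variants)
        hap = PanelHaplotype(name, 0, variants, seq)
        aln = haplotype_alignment(hap, reference, window)
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_name = model.contig
        rec.reference_start = aln.ref_start
        rec.query_sequence = aln.query
        rec.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
        rec.mapping_quality = 60
        rec.flag = 0
        rec.set_tag(TAG_A, ids.get("A", 0), "i")
        rec.set_tag(TAG_C, ids.get("C", 0), "i")
        rec.set_tag(TAG_T, ids.get("T", 0), "i")
        rec.set_tag(TAG_G, ids.get("G", 0), "i")
        rec.set_tag(TAG_CODE, format_code(code), "Z")
        rec.set_tag(
            TAG_POPS,
            ";".join(f"{k}={v}" for k, v in sorted(bh["pop_counts"].items())) or ".",
            "Z",
        )
        rec.set_tag(TAG_COUNT, int(bh["count"]), "i")
        records.append(rec)
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in sorted(records, key=lambda r: (r.reference_start, r.query_name)):
            out.write(rec)
    if mode == "wb":
        pysam.index(str(path))


# ---------------------------------------------------------------------------
# simple TSV tables


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    """Samples x genes matrix with a 'sample' index column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(path, expression: Mapping[str, Mapping[str, float]]) -> None:
    """``expression``: gene -> sample -> value."""
    frame = pd.DataFrame(expression)
    frame.index.name = "sample"
    frame.sort_index().to_csv(path, sep="\t")


def read_diplotype_tsv(path) -> pd.DataFrame:
    """Columns: sample, gene, level, hap1_id, hap2_id."""
    return pd.read_csv(path, sep="\t")


def write_diplotype_tsv(path, rows: Sequence[dict]) -> None:
    pd.DataFrame(
        rows, columns=["sample", "gene", "level", "hap1_id", "hap2_id"]
    ).to_csv(path, sep="\t", index=False)
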