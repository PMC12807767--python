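"""Variant calling from contig alignments, level classification, and the
homopolymer-calibrated binomial variant quality (VQV) filter.

A variant supported by ``s`` of ``c`` contigs overlapping its locus,
under a per-contig error probability ``p``, gets

    VQV = -10 * log10( Pr[X >= s] ),  X ~ Binomial(c, p)

so VQV 100 corresponds to a tail probability of 1e-10 and VQV 50 to
1e-5.  The error probability comes from a homopolymer-context quality
table: the lower of the reference-context and alternate-context QVs is
converted with the Phred rule p = 10**(-QV/10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .gene_model import GenomicInterval, RegionPartition, TranscriptModel, DEFAULT_FLANK

LEVELS = ("A", "C", "T", "G", "U", "D")

#: retention thresholds: protein/coding levels demand tail <= 1e-10,
#: the non-coding levels tail <= 1e-5
DEFAULT_THRESHOLDS: dict[str, float] = {
    "A": 100.0,
    "C": 100.0,
    "T": 50.0,
    "G": 50.0,
    "U": 50.0,
    "D": 50.0,
}

CONSEQUENCE_FLAGS = frozenset(
    {
        "missense",
        "synonymous",
        "inframe_indel",
        "frameshift",
        "start_loss",
        "stop_gain",
        "stop_loss",
        "splice_unmodeled",
    }
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawVariant:
    """Normalized variant: left-aligned, parsimony-trimmed, with one
    anchor base retained for indels (VCF convention)."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    source_haplotype: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele (anchor base required)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class HomopolymerContext:
    base: str
    run_length_ref: int
    run_length_alt: int

    def __post_init__(self) -> None:
        if self.run_length_ref < 1 or self.run_length_alt < 1:
            raise ValueError("run lengths must be >= 1")


@dataclass(frozen=True)
class ClassifiedVariant:
    contig: str
    pos: int
    ref: str
    alt: str
    source_haplotype: str
    level: str
    flags: frozenset[str] = frozenset()
    vqv: Optional[float] = None
    retained: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if not self.flags <= CONSEQUENCE_FLAGS:
            raise ValueError(f"unknown flags {self.flags - CONSEQUENCE_FLAGS}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def raw(self) -> RawVariant:
        return RawVariant(
            self.contig, self.pos, self.ref, self.alt, self.source_haplotype
        )


class QVCalibration:
    """Per-contig homopolymer quality table.

    Maps (contig id, base, run length) to a Phred-scaled QV.  Run
    lengths beyond the largest tabulated bin are clamped to it; a row
    with contig id ``"*"`` acts as a global fallback.
    """

    FALLBACK = "*"

    def __init__(self, table: Mapping[tuple[str, str, int], float]):
        self._table: dict[tuple[str, str, int], float] = {}
        for (contig, base, run), qv in table.items():
            if qv < 0:
                raise ValueError(f"negative QV for {(contig, base, run)}")
            self._table[(contig, base.upper(), int(run))] = float(qv)
        self._bins: dict[tuple[str, str], list[int]] = {}
        for contig, base, run in self._table:
            self._bins.setdefault((contig, base), []).append(run)
        for bins in self._bins.values():
            bins.sort()

    def lookup(self, contig_id: str, base: str, run_length: int) -> float:
        """QV at the nearest tabulated run-length bin at or below
        ``run_length`` (clamped into the table's range)."""
        base = base.upper()
        for cid in (contig_id, self.FALLBACK):
            bins = self._bins.get((cid, base))
            if not bins:
                continue
            below = [b for b in bins if b <= run_length]
            run = below[-1] if below else bins[0]
            return self._table[(cid, base, run)]
        raise ValueError(
            f"no calibration row for contig {contig_id!r}, base {base!r}"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"contig_id": c, "base": b, "run_length": r, "qv": q}
            for (c, b, r), q in sorted(self._table.items())
        ]
        return pd.DataFrame(rows, columns=["contig_id", "base", "run_length", "qv"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QVCalibration":
        table = {
            (str(row.contig_id), str(row.base), int(row.run_length)): float(row.qv)
            for row in frame.itertuples()
        }
        return cls(table)

    @classmethod
    def read_tsv(cls, path) -> "QVCalibration":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments


_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class ContigAlignment:
    """Minimal gapped alignment of one haplotype contig to the reference."""

    name: str
    contig: str
    ref_start: int
    cigar: list[tuple[str, int]]  # ops from MIDSH=X
    query: str

    def __post_init__(self) -> None:
        for op, n in self.cigar:
            if op not in _CIGAR_OPS or n <= 0:
                raise ValueError(f"bad cigar element {(op, n)}")

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            n for op, n in self.cigar if op in "M=XDN"
        )

    @classmethod
    def from_pysam(cls, rec) -> "ContigAlignment":
        cigar = [( _CIGAR_OPS[op], n) for op, n in rec.cigartuples]
        return cls(
            name=rec.query_name,
            contig=rec.reference_name,
            ref_start=rec.reference_start,
            cigar=cigar,
            query=rec.query_sequence,
        )


def normalize_variant(
    reference: str, pos: int, ref: str, alt: str, source: str = "", contig: str = ""
) -> RawVariant:
    """Parsimony-trim and left-align one variant against ``reference``
    (a full contig sequence; ``pos`` is 0-based on it)."""
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    raise ValueError("cannot left-extend at contig start")
                pos -= 1
                b = reference[pos]
                ref, alt = b + ref, b + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return RawVariant(contig, pos, ref, alt, source)


def trim_to_gene_window(
    aln: ContigAlignment, model: TranscriptModel, flank: int = DEFAULT_FLANK
) -> ContigAlignment:
    """Clip an alignment (coordinates and CIGAR) to the gene window
    ``[gene_start - flank, gene_end + flank)``."""
    wstart, wend = model.start - flank, model.end + flank
    if aln.ref_end <= wstart or aln.ref_start >= wend:
        raise ValueError(
            f"{aln.name}: alignment {aln.ref_start}-{aln.ref_end} does not "
            f"overlap window {wstart}-{wend}"
        )
    out: list[tuple[str, int]] = []
    query_parts: list[str] = []
    rpos, qpos = aln.ref_start, 0
    new_start = max(aln.ref_start, wstart)
    for op, n in aln.cigar:
        if op in "SH":
            if op == "S":
                qpos += n
            continue
        consumes_ref = op in "M=XDN"
        consumes_query = op in "M=XI"
        if consumes_ref and not consumes_query:  # D/N
            keep = min(rpos + n, wend) - max(rpos, wstart)
            if keep > 0:
                out.append((op, keep))
            rpos += n
        elif consumes_query and not consumes_ref:  # I
            if wstart < rpos < wend:
                out.append((op, n))
                query_parts.append(aln.query[qpos : qpos + n])
            qpos += n
        else:  # M/=/X
            lo, hi = max(rpos, wstart), min(rpos + n, wend)
            if hi > lo:
                out.append((op, hi - lo))
                qoff = qpos + (lo - rpos)
                query_parts.append(aln.query[qoff : qoff + (hi - lo)])
            rpos += n
            qpos += n
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ContigAlignment(
        name=aln.name,
        contig=aln.contig,
        ref_start=new_start,
        cigar=merged,
        query="".join(query_parts),
    )


def call_variants_from_alignment(
    aln: ContigAlignment, reference: str, window: GenomicInterval
) -> list[RawVariant]:
    """Emit every mismatch, insertion and deletion inside ``window``.

    The alignment must span the window end-to-end (incomplete contigs
    are the caller's exclusion criterion).  Indels are left-aligned and
    anchored; variants whose normalized position falls outside the
    window are dropped.
    """
    if aln.ref_start > window.start or aln.ref_end < window.end:
        raise ValueError(
            f"{aln.name}: alignment {aln.ref_start}-{aln.ref_end} does not "
            f"span window {window.start}-{window.end}"
        )
    variants: list[RawVariant] = []
    rpos, qpos = aln.ref_start, 0

    def emit(pos: int, ref: str, alt: str) -> None:
        v = normalize_variant(
            reference, pos, ref, alt, source=aln.name, contig=window.contig
        )
        if window.start <= v.pos < window.end:
            variants.append(v)

    for op, n in aln.cigar:
        if op in "SH":
            if op == "S":
                qpos += n
            continue
        if op in "M=X":
            for i in range(n):
                rb = reference[rpos + i]
                qb = aln.query[qpos + i]
                if rb != qb and window.start <= rpos + i < window.end:
                    variants.append(
                        RawVariant(window.contig, rpos + i, rb, qb, aln.name)
                    )
            rpos += n
            qpos += n
        elif op == "I":
            anchor = rpos - 1
            emit(anchor, reference[anchor], reference[anchor] + aln.query[qpos : qpos + n])
            qpos += n
        elif op in "DN":
            anchor = rpos - 1
            emit(
                anchor,
                reference[anchor : rpos + n],
                reference[anchor],
            )
            rpos += n
    variants.sort(key=lambda v: (v.pos, v.ref, v.alt))
    return variants


# ---------------------------------------------------------------------------
# consequence classification


def _splice_cds(model: TranscriptModel, reference: str) -> str:
    seq = "".join(reference[iv.start : iv.end] for iv in model.cds)
    return revcomp(seq) if model.strand == "-" else seq


def _genomic_to_cds_index(model: TranscriptModel, pos: int) -> Optional[int]:
    """Index of genomic position ``pos`` in the spliced CDS (transcript
    orientation), or None outside the CDS."""
    offset = 0
    total = sum(iv.length for iv in model.cds)
    for iv in model.cds:
        if iv.contains(pos):
            idx = offset + (pos - iv.start)
            return idx if model.strand == "+" else total - 1 - idx
        offset += iv.length
    return None


_CODON_TABLE = {}


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    if codon not in _CODON_TABLE:
        _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE[codon]


def classify(
    variant: RawVariant,
    partition: RegionPartition,
    model: TranscriptModel,
    reference: str,
) -> ClassifiedVariant:
    """Assign the variant's level (A/C/T/G/U/D) and consequence flags.

    CDS SNVs are translated in transcript frame: protein-changing
    variants (missense, start-loss, stop-gain, stop-loss) and all CDS
    indels are level A; synonymous changes are level C.  UTR -> T,
    intron -> G, flanks -> U/D.
    """
    # first altered base: SNVs change pos itself, anchored indels change
    # from pos+1 (a left-aligned insertion sits between pos and pos+1)
    locus = variant.pos if len(variant.ref) == len(variant.alt) else variant.pos + 1
    region = partition.region_at(locus)
    if region is None:
        raise ValueError(
            f"variant at {variant.contig}:{variant.pos} outside gene window"
        )
    flags: set[str] = set()
    if region == "utr5" or region == "utr3":
        level = "T"
    elif region == "intron":
        level = "G"
    elif region == "upstream":
        level = "U"
    elif region == "downstream":
        level = "D"
    else:  # cds
        level, flags = _classify_cds(variant, model, reference)
        if variant.is_indel:
            # indel whose span leaves the CDS: consequence not modelled
            last = variant.pos + len(variant.ref) - 1
            if len(variant.ref) > 1 and partition.region_at(last) != "cds":
                flags.add("splice_unmodeled")
    return ClassifiedVariant(
        contig=variant.contig,
        pos=variant.pos,
        ref=variant.ref,
        alt=variant.alt,
        source_haplotype=variant.source_haplotype,
        level=level,
        flags=frozenset(flags),
    )


def _classify_cds(
    variant: RawVariant, model: TranscriptModel, reference: str
) -> tuple[str, set[str]]:
    if variant.is_indel:
        shift = abs(len(variant.ref) - len(variant.alt)) % 3
        return "A", ({"frameshift"} if shift else {"inframe_indel"})
    cds_seq = _splice_cds(model, reference)
    flags: set[str] = set()
    changed = False
    protein_changed = False
    for off in range(len(variant.ref)):
        idx = _genomic_to_cds_index(model, variant.pos + off)
        if idx is None:
            continue
        ref_b = variant.ref[off]
        alt_b = variant.alt[off]
        if model.strand == "-":
            ref_b, alt_b = revcomp(ref_b), revcomp(alt_b)
        codon_i = idx // 3
        codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            continue
        alt_codon = codon[: idx % 3] + alt_b + codon[idx % 3 + 1 :]
        ref_aa = _translate_codon(codon)
        alt_aa = _translate_codon(alt_codon)
        changed = True
        if codon_i == 0 and alt_codon != "ATG":
            flags.add("start_loss")
            protein_changed = True
        elif ref_aa == "*" and alt_aa != "*":
            flags.add("stop_loss")
            protein_changed = True
        elif ref_aa != "*" and alt_aa == "*":
            flags.add("stop_gain")
            protein_changed = True
        elif ref_aa != alt_aa:
            flags.add("missense")
            protein_changed = True
    if not changed:
        raise ValueError(
            f"variant at {variant.contig}:{variant.pos} not resolvable in CDS"
        )
    if protein_changed:
        return "A", flags
    return "C", {"synonymous"}


# ---------------------------------------------------------------------------
# homopolymer context and VQV


def _run_length(seq: str, pos: int, base: str) -> int:
    """Maximal run of ``base`` in ``seq`` containing or abutting ``pos``."""
    n = len(seq)
    if pos < 0 or pos >= n:
        return 0
    i = pos
    if seq[i] != base:
        # run may start right of an anchor position
        if i + 1 < n and seq[i + 1] == base:
            i += 1
        else:
            return 0
    lo = i
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < n and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def homopolymer_context(reference: str, variant: RawVariant) -> HomopolymerContext:
    """Homopolymer run lengths around the variant locus in the reference
    and the variant-applied contexts.  Non-homopolymer events (SNVs,
    multi-base mixed indels) use run length 1."""
    ref, alt = variant.ref, variant.alt
    if not variant.is_indel:
        return HomopolymerContext(ref[0], 1, 1)
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    inserted = longer[len(shorter):] if longer.startswith(shorter) else longer[1:]
    base = inserted[0]
    if any(b != base for b in inserted):
        return HomopolymerContext(base, 1, 1)
    run_ref = max(1, _run_length(reference, variant.pos, base))
    # alt context computed on the locally edited sequence
    lo = max(0, variant.pos - 60)
    local = reference[lo : variant.pos] + alt + reference[variant.pos + len(ref) : variant.pos + len(ref) + 60]
    run_alt = max(1, _run_length(local, variant.pos - lo, base))
    return HomopolymerContext(base, max(1, run_ref), run_alt)


def contig_error_probability(
    calib: QVCalibration, ctx: HomopolymerContext, contig_id: str
) -> float:
    """Phred-decode the lower of the reference- and alternate-context
    QVs into a per-contig error probability in (0, 1]."""
    qv_ref = calib.lookup(contig_id, ctx.base, ctx.run_length_ref)
    qv_alt = calib.lookup(contig_id, ctx.base, ctx.run_length_alt)
    return 10.0 ** (-min(qv_ref, qv_alt) / 10.0)


def vqv(supporting: int, covering: int, p_err: float) -> float:
    """Variant-level quality: -10*log10 Pr[X >= supporting] for
    X ~ Binomial(covering, p_err)."""
    if not 0 <= supporting <= covering:
        raise ValueError(f"supporting {supporting} not in [0, {covering}]")
    if not 0.0 < p_err <= 1.0:
        raise ValueError(f"p_err {p_err} not in (0, 1]")
    if supporting == 0:
        return 0.0
    tail = float(stats.binom.sf(supporting - 1, covering, p_err))
    if tail > 0.0:
        return max(0.0, -10.0 * math.log10(tail))
    # underflow: evaluate the tail in log space
    ks = np.arange(supporting, covering + 1)
    log_tail = logsumexp(stats.binom.logpmf(ks, covering, p_err))
    return max(0.0, -10.0 * log_tail / math.log(10.0))


def filter_variants(
    variants: Sequence[ClassifiedVariant],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> list[ClassifiedVariant]:
    """Set the ``retained`` flag: keep a variant iff its VQV meets its
    level's threshold (inclusive).  Variants with no VQV pass through
    (no-filter mode)."""
    out = []
    for v in variants:
        if v.level not in thresholds:
            raise ValueError(f"no VQV threshold configured for level {v.level}")
        retained = True if v.vqv is None else v.vqv >= thresholds[v.level]
        out.append(replace(v, retained=retained))
    return out


# ---------------------------------------------------------------------------
# panel-level support aggregation


def aggregate_panel(
    per_copy_variants: Mapping[str, Sequence[RawVariant]],
) -> tuple[dict[tuple, set[str]], int]:
    """Collect support across haploid copies.

    Returns (mapping variant key -> set of supporting copy ids, covering)
    where covering is the number of copies in the panel (all copies are
    required to span the window end-to-end upstream of this call).
    """
    support: dict[tuple, set[str]] = {}
    for copy_id, variants in per_copy_variants.items():
        for v in variants:
            support.setdefault(v.key, set()).add(copy_id)
    return support, len(per_copy_variants)


def score_variant(
    variant: RawVariant,
    supporting: int,
    covering: int,
    calib: QVCalibration,
    reference: str,
    contig_id: Optional[str] = None,
) -> float:
    """VQV of one variant given its panel support and the QV table."""
    ctx = homopolymer_context(reference, variant)
    p = contig_error_probability(
        calib, ctx, contig_id if contig_id is not None else QVCalibration.FALLBACK
    )
    return vqv(supporting, covering, p)


def variants_to_frame(variants: Sequence[ClassifiedVariant]) -> pd.DataFrame:
    """Tabular report (POS is 1-based in the output)."""
    rows = [
        {
            "CHROM": v.contig,
            "POS": v.pos + 1,
            "REF": v.ref,
            "ALT": v.alt,
            "LEVEL": v.level,
            "FLAGS": ",".join(sorted(v.flags)),
            "VQV": v.vqv,
            "RETAINED": v.retained,
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=["CHROM", "POS", "REF", "ALT", "LEVEL", "FLAGS", "VQV", "RETAINED"],
    )
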