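"""Per-level haplotype sequences, frequency-ranked identifier catalogs,
and the structured code format (``GENE:a1c1t1g1`` and friends).

Within each level, identical sequences are clustered and numbered from
1 in descending global frequency (ties broken by lexicographic order of
the sequence, so assignment is independent of input order).  Identifier
0 marks a non-applicable level: non-coding genes carry ``a0c0``, a
disrupted coding sequence (start-loss / stop-gain / stop-loss /
frameshift) carries ``a0`` while its C-level stays defined, and an
intronless transcript carries ``g0``.  Reference assemblies enter the
panel as ordinary rows, so their haplotypes live in the same ranked
space as the population's.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Seq import Seq

from .gene_model import GenomicInterval, RegionPartition, TranscriptModel
from .variant_engine import ClassifiedVariant, RawVariant, revcomp

DISRUPTION_FLAGS = frozenset({"start_loss", "stop_gain", "stop_loss", "frameshift"})

#: levels that appear in composite code strings, in rendering order
CODE_LEVELS = ("a", "c", "t", "g")


# ---------------------------------------------------------------------------
# haplotype window construction


def apply_variants(
    reference: str,
    window: GenomicInterval,
    variants: Sequence[RawVariant],
    breakpoints: Sequence[int] = (),
) -> tuple[str, dict[int, int]]:
    """Apply normalized variants to the reference window.

    Returns the haplotype window sequence plus a map from each requested
    reference breakpoint to its offset in the haplotype sequence, which
    lets callers slice the haplotype at region boundaries without
    re-aligning.  Variants must be non-overlapping and lie inside the
    window.
    """
    variants = sorted(variants, key=lambda v: v.pos)
    for a, b in zip(variants, variants[1:]):
        if a.pos + len(a.ref) > b.pos:
            raise ValueError(
                f"overlapping variants at {a.pos} and {b.pos}"
            )
    marks: dict[int, int] = {}
    bps = sorted(set(breakpoints))
    bi = 0
    out: list[str] = []
    out_len = 0
    cur = window.start

    def copy_to(target: int) -> None:
        nonlocal cur, out_len, bi
        while bi < len(bps) and bps[bi] <= target:
            if bps[bi] >= cur:
                marks[bps[bi]] = out_len + (bps[bi] - cur)
                bi += 1
            else:
                bi += 1
        if target > cur:
            out.append(reference[cur:target])
            out_len += target - cur
            cur = target

    for v in variants:
        if v.pos < window.start or v.pos + len(v.ref) > window.end:
            raise ValueError(
                f"variant at {v.pos} outside window {window.start}-{window.end}"
            )
        copy_to(v.pos)
        out.append(v.alt)
        out_len += len(v.alt)
        cur = v.pos + len(v.ref)
        is_insertion = len(v.ref) == 1 and len(v.alt) > 1
        while bi < len(bps) and bps[bi] <= cur:
            if len(v.ref) == len(v.alt):
                # substitution: positions map 1:1
                marks[bps[bi]] = out_len - len(v.alt) + (bps[bi] - v.pos)
            elif is_insertion and bps[bi] == cur:
                # a boundary right after the anchor keeps the inserted
                # bases in the downstream region (matches classify())
                marks[bps[bi]] = out_len - (len(v.alt) - 1)
            else:
                # breakpoints inside a deleted span collapse onto the
                # end of the emitted allele
                marks[bps[bi]] = out_len
            bi += 1
    copy_to(window.end)
    return "".join(out), marks


# ---------------------------------------------------------------------------
# level sequences


@dataclass
class LevelSequences:
    """The derived per-level sequences of one phased haplotype.

    ``None`` marks an absent level (rendered as id 0): protein and CDS
    for non-coding genes, protein when translation is disrupted, introns
    for intronless transcripts, exonic non-coding when the annotation
    has no UTR at all.
    """

    a_seq: Optional[str]
    c_seq: Optional[str]
    t_seq: Optional[str]
    g_seq: Optional[str]
    u_seq: Optional[str]
    d_seq: Optional[str]
    source: str
    transcript_id: str = ""
    disruption_flags: frozenset[str] = frozenset()
    window_seq: Optional[str] = None

    def get(self, level: str) -> Optional[str]:
        return getattr(self, f"{level.lower()}_seq")

    @property
    def levels_present(self) -> list[str]:
        return [lv for lv in "ACTGUD" if self.get(lv) is not None]


def translate_cds(c_seq: str) -> tuple[Optional[str], frozenset[str]]:
    """Translate a spliced CDS; detect disruptions.

    Returns (protein or None, disruption flags).  The protein is the
    translation up to (excluding) the terminal stop.  A CDS that does
    not start with ATG is a start-loss; a length not divisible by 3 is
    a frameshift; an in-frame stop before the last codon is a
    stop-gain; a missing terminal stop is a stop-loss.  Any disruption
    yields protein None.
    """
    flags: set[str] = set()
    if len(c_seq) < 6 or not c_seq.upper().startswith("ATG"):
        flags.add("start_loss")
    if len(c_seq) % 3 != 0:
        flags.add("frameshift")
    usable = c_seq[: len(c_seq) - len(c_seq) % 3]
    aa = str(Seq(usable).translate()) if usable else ""
    stop_at = aa.find("*")
    if stop_at == -1:
        flags.add("stop_loss")
    elif stop_at != len(aa) - 1:
        flags.add("stop_gain")
    if flags:
        return None, frozenset(flags)
    return aa[:-1], frozenset()


def _splice(pieces: Sequence[str], strand: str) -> str:
    """Join genomic-order pieces into a transcript-orientation sequence."""
    seq = "".join(pieces)
    return revcomp(seq) if strand == "-" else seq


def derive_level_sequences(
    haplotype: Union[Sequence[RawVariant], Sequence[ClassifiedVariant]],
    model: TranscriptModel,
    partition: RegionPartition,
    reference: str,
) -> LevelSequences:
    """Derive the per-level sequences of one haplotype.

    ``haplotype`` is the haplotype's variant set relative to the
    reference (classified variants must be retained — filter first; raw
    variants are accepted as no-filter mode).  The reference is the
    full contig sequence the partition's coordinates refer to.
    """
    source = ""
    variants: list[RawVariant] = []
    for v in haplotype:
        if isinstance(v, ClassifiedVariant):
            if v.retained is False:
                raise ValueError(
                    f"non-retained variant at {v.pos}; filter before deriving"
                )
            variants.append(v.raw)
        else:
            variants.append(v)
        source = source or v.source_haplotype

    regions = partition.ordered_regions()
    breakpoints = sorted(
        {iv.start for _, iv in regions} | {iv.end for _, iv in regions}
    )
    window = partition.window
    hap_seq, marks = apply_variants(reference, window, variants, breakpoints)

    pieces: dict[str, list[str]] = defaultdict(list)
    for label, iv in regions:  # genomic order
        pieces[label].append(hap_seq[marks[iv.start] : marks[iv.end]])

    strand = model.strand
    u_seq = _splice(pieces["upstream"], strand)
    d_seq = _splice(pieces["downstream"], strand)
    g_seq = _splice(pieces["intron"], strand) if partition.introns else None

    has_utr = bool(partition.utr5 or partition.utr3)
    if has_utr:
        utr5 = _splice(pieces["utr5"], strand) if partition.utr5 else ""
        utr3 = _splice(pieces["utr3"], strand) if partition.utr3 else ""
        t_seq = utr5 + utr3
    else:
        t_seq = None

    if model.coding_flag:
        c_seq = _splice(pieces["cds"], strand)
        a_seq, flags = translate_cds(c_seq)
    else:
        c_seq, a_seq, flags = None, None, frozenset()

    return LevelSequences(
        a_seq=a_seq,
        c_seq=c_seq,
        t_seq=t_seq,
        g_seq=g_seq,
        u_seq=u_seq,
        d_seq=d_seq,
        source=source,
        transcript_id=model.transcript_id,
        disruption_flags=flags,
        window_seq=hap_seq,
    )


# ---------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class ClusterEntry:
    level: str
    hap_id: int
    sequence: str
    count: int
    members: tuple[str, ...]
    pop_counts: Mapping[str, int] = field(default_factory=dict)
    assemblies: tuple[str, ...] = ()


@dataclass
class HaplotypeCatalog:
    """Frequency-ranked haplotype clusters of one gene, per level."""

    gene: str
    transcript_id: str
    version: str
    levels: dict[str, list[ClusterEntry]]
    populations: Mapping[str, str] = field(default_factory=dict)
    assemblies: Mapping[str, str] = field(default_factory=dict)

    def id_for(self, level: str, sequence: str) -> Optional[int]:
        for entry in self.levels.get(level, []):
            if entry.sequence == sequence:
                return entry.hap_id
        return None

    def entry(self, level: str, hap_id: int) -> ClusterEntry:
        for e in self.levels.get(level, []):
            if e.hap_id == hap_id:
                return e
        raise KeyError(f"{self.gene}: no {level}-level haplotype {hap_id}")

    def entry_for_assembly(self, level: str, assembly: str) -> Optional[ClusterEntry]:
        for e in self.levels.get(level, []):
            if assembly in e.assemblies:
                return e
        return None

    def size(self, level: str) -> int:
        return len(self.levels.get(level, []))


def build_catalog(
    panel: Sequence[LevelSequences],
    populations: Optional[Mapping[str, str]] = None,
    assemblies: Optional[Mapping[str, str]] = None,
    version: str = "v1",
    gene: str = "",
) -> HaplotypeCatalog:
    """Cluster identical per-level sequences over the panel and assign
    ids 1..K in descending count (ties: lexicographically smaller
    sequence first).  Absent sequences are excluded from clustering and
    map to id 0 at code-assignment time.  Reference assemblies are
    ordinary panel rows (one haplotype each).
    """
    populations = dict(populations or {})
    assemblies = dict(assemblies or {})
    tx_ids = {ls.transcript_id for ls in panel if ls.transcript_id}
    if len(tx_ids) > 1:
        raise ValueError(f"mixed transcript models in panel: {sorted(tx_ids)}")
    transcript_id = next(iter(tx_ids), "")

    levels: dict[str, list[ClusterEntry]] = {}
    for level in "ACTGUD":
        members: dict[str, list[str]] = defaultdict(list)
        for ls in panel:
            seq = ls.get(level)
            if seq is not None:
                members[seq].append(ls.source)
        if not members:
            continue
        ranked = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        entries = []
        for hap_id, (seq, mem) in enumerate(ranked, start=1):
            pop_counts = Counter(
                populations[m] for m in mem if m in populations
            )
            asm = tuple(sorted({assemblies[m] for m in mem if m in assemblies}))
            entries.append(
                ClusterEntry(
                    level=level,
                    hap_id=hap_id,
                    sequence=seq,
                    count=len(mem),
                    members=tuple(sorted(mem)),
                    pop_counts=dict(pop_counts),
                    assemblies=asm,
                )
            )
        levels[level] = entries
    return HaplotypeCatalog(
        gene=gene or transcript_id,
        transcript_id=transcript_id,
        version=version,
        levels=levels,
        populations=populations,
        assemblies=assemblies,
    )


# ---------------------------------------------------------------------------
# codes


@dataclass(frozen=True)
class ACTGCode:
    """Structured haplotype identifier.

    ``None`` for a level means "not part of this code" (partial depth);
    0 means "level not applicable".  The r-form (regulatory regions) is
    mutually exclusive with the a/c/t/g fields.
    """

    prefix: str
    a: Optional[int] = None
    c: Optional[int] = None
    t: Optional[int] = None
    g: Optional[int] = None
    u: Optional[int] = None
    d: Optional[int] = None
    r: Optional[int] = None
    version: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("empty prefix")
        fields = [self.a, self.c, self.t, self.g, self.u, self.d]
        if self.r is not None:
            if any(f is not None for f in fields):
                raise ValueError("r-form codes carry no a/c/t/g fields")
            if self.r < 1:
                raise ValueError("r id must be >= 1")
        else:
            if all(f is None for f in fields):
                raise ValueError("code has no level fields")
            if any(f is not None and f < 0 for f in fields):
                raise ValueError("negative level id")


def assign_code(
    sample_level_seqs: LevelSequences,
    catalog: HaplotypeCatalog,
    prefix: Optional[str] = None,
    strict: bool = True,
) -> ACTGCode:
    """Look the sample's per-level sequences up in the catalog.

    Absent levels get id 0.  A sequence not in the catalog raises in
    strict mode, otherwise receives the provisional id K+1.
    """
    ids: dict[str, Optional[int]] = {}
    for level in "ACTGUD":
        seq = sample_level_seqs.get(level)
        if seq is None:
            ids[level.lower()] = 0
            continue
        hap_id = catalog.id_for(level, seq)
        if hap_id is None:
            if strict:
                raise ValueError(
                    f"{catalog.gene}: novel {level}-level sequence for "
                    f"{sample_level_seqs.source!r}"
                )
            hap_id = catalog.size(level) + 1
        ids[level.lower()] = hap_id
    return ACTGCode(
        prefix=prefix or catalog.gene,
        a=ids["a"],
        c=ids["c"],
        t=ids["t"],
        g=ids["g"],
        u=ids["u"],
        d=ids["d"],
        version=catalog.version or None,
    )


def format_code(code: ACTGCode, style: str = "full") -> str:
    """Render a code: ``full`` keeps every set a/c/t/g field, ``short``
    drops leading zero levels (a0c0t1g1 -> t1g1), ``with_version``
    appends the version field.  u/d ids never enter the string."""
    if style not in ("full", "short", "with_version"):
        raise ValueError(f"unknown style {style!r}")
    if code.r is not None:
        body = f"r{code.r}"
    else:
        parts = [
            (letter, getattr(code, letter))
            for letter in CODE_LEVELS
            if getattr(code, letter) is not None
        ]
        if style == "short":
            while len(parts) > 1 and parts[0][1] == 0:
                parts = parts[1:]
        body = "".join(f"{letter}{val}" for letter, val in parts)
    text = f"{code.prefix}:{body}"
    if style == "with_version" and code.version:
        text += f":{code.version}"
    return text


_PREFIX_RE = re.compile(r"[A-Za-z0-9_.\-]")


def parse_code(text: str) -> ACTGCode:
    """Parse full, short, partial-depth, versioned and r-form codes.

    Malformed input raises ValueError naming the position of the first
    offending character.
    """

    def fail(i: int, why: str) -> ValueError:
        return ValueError(f"invalid code {text!r}: {why} at position {i}")

    colon = text.find(":")
    if colon <= 0:
        raise fail(max(colon, 0), "missing or empty prefix before ':'")
    prefix = text[:colon]
    for i, ch in enumerate(prefix):
        if not _PREFIX_RE.match(ch):
            raise fail(i, f"bad prefix character {ch!r}")
    rest = text[colon + 1 :]
    vcolon = rest.find(":")
    version = None
    if vcolon != -1:
        version = rest[vcolon + 1 :]
        if not re.fullmatch(r"v[A-Za-z0-9_.]+", version):
            raise fail(colon + 1 + vcolon + 1, "bad version field")
        rest = rest[:vcolon]
    if not rest:
        raise fail(colon + 1, "empty level body")

    base = colon + 1
    if rest[0] == "r":
        m = re.fullmatch(r"r(\d+)", rest)
        if not m:
            raise fail(base + 1, "r must be followed by digits only")
        return ACTGCode(prefix=prefix, r=int(m.group(1)), version=version)

    order = "actgud"
    ids: dict[str, int] = {}
    i = 0
    min_next = 0
    while i < len(rest):
        letter = rest[i]
        if letter not in order:
            raise fail(base + i, f"unexpected character {letter!r}")
        if order.index(letter) < min_next:
            raise fail(base + i, f"level {letter!r} out of order or repeated")
        min_next = order.index(letter) + 1
        j = i + 1
        while j < len(rest) and rest[j].isdigit():
            j += 1
        if j == i + 1:
            raise fail(base + i + 1, f"level {letter!r} lacks a numeric id")
        ids[letter] = int(rest[i + 1 : j])
        i = j
    return ACTGCode(prefix=prefix, version=version, **ids)


# ---------------------------------------------------------------------------
# cross-assembly comparison


@dataclass(frozen=True)
class AssemblyRankPair:
    gene: str
    level: str
    rank_on_assembly_1: int
    rank_on_assembly_2: int

    def __post_init__(self) -> None:
        if self.rank_on_assembly_1 < 1 or self.rank_on_assembly_2 < 1:
            raise ValueError("ranks must be >= 1")


def cross_assembly_ranks(
    catalog: HaplotypeCatalog,
    assembly_1: str,
    assembly_2: str,
    levels: Sequence[str] = ("A", "C", "T", "G"),
) -> list[AssemblyRankPair]:
    """Global id rank carried by each reference assembly, per level.

    One pair per level where both assemblies have an assigned id (a gene
    carrying a1 on one assembly and a5 on the other yields (1, 5))."""
    registered = set(catalog.assemblies.values())
    for asm in (assembly_1, assembly_2):
        if asm not in registered:
            raise ValueError(f"assembly {asm!r} not registered in catalog")
    pairs = []
    for level in levels:
        e1 = catalog.entry_for_assembly(level, assembly_1)
        e2 = catalog.entry_for_assembly(level, assembly_2)
        if e1 is not None and e2 is not None:
            pairs.append(
                AssemblyRankPair(catalog.gene, level, e1.hap_id, e2.hap_id)
            )
    return pairs


def rank_histograms(
    pairs: Iterable[AssemblyRankPair],
) -> tuple[dict[str, Counter], dict[str, Counter]]:
    """Marginal rank histograms (per level) for each assembly axis."""
    h1: dict[str, Counter] = defaultdict(Counter)
    h2: dict[str, Counter] = defaultdict(Counter)
    for p in pairs:
        h1[p.level][p.rank_on_assembly_1] += 1
        h2[p.level][p.rank_on_assembly_2] += 1
    return dict(h1), dict(h2)
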