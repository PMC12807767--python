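"""Synthetic input generation: toy gene models, haplotype panels with
controlled frequency spectra and level-targeted variants, homopolymer
indel error injection with matched QV tables, and diploid cohorts with
planted expression effects.

Everything is driven by a master seed; each purpose draws from its own
stream split off the master seed, so partial pipelines are
reproducible on their own.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_model import (
    DEFAULT_FLANK,
    GenomicInterval,
    RegionPartition,
    TranscriptModel,
    partition_regions,
)
from .hapqtl import Diplotype, ExpressionStudy
from .nomenclature import HaplotypeCatalog, apply_variants
from .variant_engine import ContigAlignment, QVCalibration, RawVariant, revcomp

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class PanelSpec:
    """Shape of a synthetic haplotype panel."""

    n_haploids: int
    frequency_spectrum: Sequence[float]
    variants_per_level: Mapping[str, int] = field(default_factory=dict)
    homopolymer_error_rate: Mapping[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.frequency_spectrum))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequency spectrum sums to {total}, not 1")
        if any(not 0 < p <= 1 for p in self.frequency_spectrum):
            raise ValueError("spectrum proportions must be in (0, 1]")


@dataclass
class EffectSpec:
    """Planted additive haplotype effect on expression."""

    level: str
    target_hap_id: int
    effect_size: float  # in units of the noise SD, per allele
    noise_sd: float = 1.0
    n_samples: int = 100
    n_studies: int = 3
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if self.n_studies < 1:
            raise ValueError("need at least one study")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _random_cds(rng: np.random.Generator, n: int) -> str:
    """ATG + random internal codons (no stops) + TAA, total length n."""
    if n % 3 != 0 or n < 6:
        raise ValueError(f"CDS length {n} must be a multiple of 3 and >= 6")
    codons = []
    for _ in range(n // 3 - 2):
        while True:
            codon = _random_seq(rng, 3)
            if codon not in _STOPS and codon != "ATG":
                break
        codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


def make_gene_model(
    n_exons: int = 2,
    cds_span: int = 60,
    utr_spans: tuple[int, int] = (30, 30),
    strand: str = "+",
    seed: int = 0,
    intron_span: int = 50,
    flank: int = DEFAULT_FLANK,
    coding: bool = True,
    gene_symbol: str = "GENE1",
    transcript_id: str = "TX1",
    contig: str = "chrS",
    homopolymers: Sequence[tuple[str, int, str]] = (),
) -> tuple[TranscriptModel, str]:
    """Build a deterministic toy gene model plus its reference contig.

    ``homopolymers`` plants (base, run_length, region) tracts, region
    one of cds/intron/utr5/utr3/upstream; CDS tracts are codon-aligned
    runs that keep the frame intact.  Returns the model and the full
    contig sequence (the gene starts at position ``flank``).
    """
    rng = np.random.default_rng(seed)
    utr5_len, utr3_len = utr_spans
    if not coding:
        cds_span = 0
    exonic = utr5_len + cds_span + utr3_len
    if exonic < n_exons or n_exons < 1:
        raise ValueError("inconsistent spans: exonic sequence too short")
    if coding and (cds_span % 3 != 0 or cds_span < 6):
        raise ValueError("cds_span must be a multiple of 3 and >= 6")

    # transcript-order exonic sequence
    tx_seq = list(
        _random_seq(rng, utr5_len)
        + (_random_cds(rng, cds_span) if coding else "")
        + _random_seq(rng, utr3_len)
    )
    for base, run, region in homopolymers:
        if region == "cds":
            if not coding:
                raise ValueError("cds homopolymer in non-coding model")
            run = 3 * max(1, run // 3)
            start = utr5_len + 3 * (1 + int(rng.integers(0, cds_span // 3 - 2 - run // 3)))
            tx_seq[start : start + run] = base * run
        elif region in ("utr5", "utr3"):
            span = (0, utr5_len) if region == "utr5" else (exonic - utr3_len, exonic)
            if span[1] - span[0] < run:
                raise ValueError(f"{region} too short for run {run}")
            start = span[0] + int(rng.integers(0, span[1] - span[0] - run + 1))
            tx_seq[start : start + run] = base * run
    tx_str = "".join(tx_seq)

    # split exonic sequence across exons (transcript order)
    cuts = np.linspace(0, exonic, n_exons + 1).astype(int)
    exon_seqs = [tx_str[cuts[i] : cuts[i + 1]] for i in range(n_exons)]
    intron_seqs = [list(_random_seq(rng, intron_span)) for _ in range(n_exons - 1)]
    for base, run, region in homopolymers:
        if region == "intron":
            if n_exons < 2:
                raise ValueError("intron homopolymer in intronless model")
            if intron_span < run + 4:
                raise ValueError("intron too short for run")
            start = 2 + int(rng.integers(0, intron_span - run - 3))
            intron_seqs[0][start : start + run] = base * run
    intron_strs = ["".join(s) for s in intron_seqs]

    # lay out on the genome; on the minus strand the transcript reads
    # right-to-left, so genomic order is the reverse complement
    parts_tx = list(itertools.chain(*zip(exon_seqs, intron_strs + [""])))
    gene_seq_tx = "".join(parts_tx)
    gene_seq = gene_seq_tx if strand == "+" else revcomp(gene_seq_tx)

    upstream_flank = list(_random_seq(rng, flank))
    downstream_flank = list(_random_seq(rng, flank))
    for base, run, region in homopolymers:
        if region == "upstream":
            start = 2 + int(rng.integers(0, flank - run - 3))
            upstream_flank[start : start + run] = base * run
    contig_seq = "".join(upstream_flank) + gene_seq + "".join(downstream_flank)

    # exon/CDS genomic intervals
    gene_start = flank
    exon_ivs, cds_ivs = [], []
    if strand == "+":
        pos = gene_start
        tx_off = 0
        for i, eseq in enumerate(exon_seqs):
            exon_ivs.append(GenomicInterval(contig, pos, pos + len(eseq), strand))
            if coding:
                lo = max(tx_off, utr5_len)
                hi = min(tx_off + len(eseq), utr5_len + cds_span)
                if hi > lo:
                    cds_ivs.append(
                        GenomicInterval(
                            contig, pos + lo - tx_off, pos + hi - tx_off, strand
                        )
                    )
            pos += len(eseq)
            tx_off += len(eseq)
            if i < n_exons - 1:
                pos += len(intron_strs[i])
    else:
        gene_len = len(gene_seq)
        # per exon: offset in the full transcript (with introns) and in
        # the exonic transcript (without); both measured from the 5' end
        pos_tx, pos_ex = 0, 0
        exon_offsets = []
        for i, eseq in enumerate(exon_seqs):
            exon_offsets.append((len(eseq), pos_tx, pos_ex))
            pos_tx += len(eseq)
            pos_ex += len(eseq)
            if i < n_exons - 1:
                pos_tx += len(intron_strs[i])
        for length, tx_off, _ in exon_offsets:
            g_end = gene_start + gene_len - tx_off
            exon_ivs.append(GenomicInterval(contig, g_end - length, g_end, strand))
        if coding:
            lo_ex, hi_ex = utr5_len, utr5_len + cds_span
            for length, tx_off, ex_off in exon_offsets:
                lo = max(ex_off, lo_ex)
                hi = min(ex_off + length, hi_ex)
                if hi > lo:
                    g_end = gene_start + gene_len - (tx_off + (lo - ex_off))
                    g_start = gene_start + gene_len - (tx_off + (hi - ex_off))
                    cds_ivs.append(GenomicInterval(contig, g_start, g_end, strand))

    model = TranscriptModel(
        gene_symbol=gene_symbol,
        transcript_id=transcript_id,
        gene_id=f"{gene_symbol}.g",
        contig=contig,
        strand=strand,
        exons=exon_ivs,
        cds=cds_ivs,
        assembly="SYN1",
    )
    return model, contig_seq


# ---------------------------------------------------------------------------
# panels


@dataclass
class PanelHaplotype:
    """One haploid copy of the panel."""

    copy_id: str
    cluster: int  # 0 = reference haplotype
    variants: tuple[RawVariant, ...]
    window_seq: str


@dataclass
class PanelResult:
    haplotypes: list[PanelHaplotype]
    truth: pd.DataFrame  # cluster, pos, ref, alt, level
    window: GenomicInterval
    cluster_counts: list[int]


def _spectrum_counts(spectrum: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n haploids over the spectrum."""
    raw = [p * n for p in spectrum]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    if any(c == 0 for c in counts):
        raise ValueError("spectrum too fine for n_haploids: empty cluster")
    return counts


def _codon_info(model: TranscriptModel, partition: RegionPartition, reference: str):
    from .variant_engine import _genomic_to_cds_index, _splice_cds

    cds_seq = _splice_cds(model, reference)
    return cds_seq, _genomic_to_cds_index


def _plant_snv(
    rng: np.random.Generator,
    level: str,
    model: TranscriptModel,
    partition: RegionPartition,
    reference: str,
    used: set[int],
) -> Optional[RawVariant]:
    """Draw one SNV whose classification is the requested level."""
    from .variant_engine import classify

    region_map = {
        "T": partition.utr5 + partition.utr3,
        "G": partition.introns,
        "U": [partition.upstream],
        "D": [partition.downstream],
    }
    for _ in range(300):
        if level in ("A", "C"):
            ivs = partition.cds
        else:
            ivs = region_map[level]
            if not ivs:
                return None
        iv = ivs[int(rng.integers(0, len(ivs)))]
        pos = int(rng.integers(iv.start, iv.end))
        if pos in used or (pos - 1) in used or (pos + 1) in used:
            continue
        ref_b = reference[pos]
        alt_b = _BASES[int(rng.integers(0, 4))]
        if alt_b == ref_b:
            continue
        try:
            cv = classify(
                RawVariant(model.contig, pos, ref_b, alt_b),
                partition,
                model,
                reference,
            )
        except ValueError:
            continue
        if cv.level != level:
            continue
        if level == "A" and cv.flags != frozenset({"missense"}):
            continue  # keep planted A-variants translation-preserving
        used.add(pos)
        return RawVariant(model.contig, pos, ref_b, alt_b)
    return None


def make_panel(
    model: TranscriptModel,
    spec: PanelSpec,
    reference: str,
    flank: int = DEFAULT_FLANK,
) -> PanelResult:
    """Realize a haplotype panel from a frequency spectrum.

    Cluster 0 is the reference haplotype; clusters 1..K-1 each carry a
    distinct non-empty subset of the planted variants (round-robin
    assignment), so the clusters are pairwise distinct at the window
    level.  Raises when fewer variants are placeable than clusters
    require.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    partition = partition_regions(model, flank=flank)
    window = partition.window

    k = len(spec.frequency_spectrum)
    counts = _spectrum_counts(spec.frequency_spectrum, spec.n_haploids)

    used: set[int] = set()
    planted: list[tuple[RawVariant, str]] = []
    for level in sorted(spec.variants_per_level):
        for _ in range(spec.variants_per_level[level]):
            v = _plant_snv(rng, level, model, partition, reference, used)
            if v is None:
                raise ValueError(
                    f"could not place a level-{level} variant "
                    "(region absent or saturated)"
                )
            planted.append((v, level))

    if len(planted) < k - 1:
        raise ValueError(
            f"{k} clusters requested but only {len(planted)} variants planted"
        )

    cluster_variants: list[list[RawVariant]] = [[] for _ in range(k)]
    assigned: list[int] = []
    for i, (v, _level) in enumerate(planted):
        cluster = 1 + i % (k - 1) if k > 1 else -1
        assigned.append(cluster)
        if cluster > 0:
            cluster_variants[cluster].append(v)

    truth = pd.DataFrame(
        [
            {
                "cluster": cluster,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "level": level,
            }
            for cluster, (v, level) in zip(assigned, planted)
        ],
        columns=["cluster", "pos", "ref", "alt", "level"],
    )

    haplotypes = []
    copy_idx = 0
    for cluster, n_copies in enumerate(counts):
        variants = tuple(sorted(cluster_variants[cluster], key=lambda v: v.pos))
        seq, _ = apply_variants(reference, window, variants)
        for _ in range(n_copies):
            copy_id = f"hap{copy_idx:04d}"
            haplotypes.append(
                PanelHaplotype(
                    copy_id=copy_id,
                    cluster=cluster,
                    variants=tuple(
                        RawVariant(v.contig, v.pos, v.ref, v.alt, copy_id)
                        for v in variants
                    ),
                    window_seq=seq,
                )
            )
            copy_idx += 1
    return PanelResult(
        haplotypes=haplotypes,
        truth=truth,
        window=window,
        cluster_counts=counts,
    )


# ---------------------------------------------------------------------------
# homopolymer error injection


def _scan_runs(seq: str, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Maximal single-base runs as (start, length, base)."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


def _rate_for(run_len: int, rate_map: Mapping[int, float]) -> float:
    if not rate_map:
        return 0.0
    key = min(run_len, max(rate_map))
    return rate_map.get(key, 0.0)


def rate_map_to_calibration(
    rate_map: Mapping[int, float],
    contig_id: str = QVCalibration.FALLBACK,
    qv_cap: float = 60.0,
) -> QVCalibration:
    """QV table matching an injection rate map: QV = -10*log10(rate)
    per run length (capped for zero rates), for every base."""
    table = {}
    runs = set(rate_map) | {1}
    for base in _BASES:
        for run in runs:
            rate = rate_map.get(run, 0.0)
            qv = qv_cap if rate <= 0 else min(qv_cap, -10.0 * math.log10(rate))
            table[(contig_id, base, run)] = qv
    return QVCalibration(table)


def inject_homopolymer_errors(
    sequences: Mapping[str, str],
    rate_map: Mapping[int, float],
    seed: int = 0,
) -> tuple[dict[str, str], QVCalibration, pd.DataFrame]:
    """Corrupt sequences with single-base indels inside homopolymer runs.

    Each maximal run of length L suffers an indel with probability
    rate_map[min(L, max bin)] (insertion or deletion of one run base,
    equal odds).  Returns corrupted sequences, the matched QV table and
    an event table (seq_id, pos, kind, base, run_length).
    """
    if any(not 0 <= r < 1 for r in rate_map.values()):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    corrupted: dict[str, str] = {}
    events = []
    for seq_id in sorted(sequences):
        seq = sequences[seq_id]
        edits: list[tuple[int, str, str]] = []
        for start, length, base in _scan_runs(seq):
            rate = _rate_for(length, rate_map)
            if rate <= 0 or rng.random() >= rate:
                continue
            kind = "ins" if rng.random() < 0.5 else "del"
            edits.append((start, kind, base))
            events.append(
                {
                    "seq_id": seq_id,
                    "pos": start,
                    "kind": kind,
                    "base": base,
                    "run_length": length,
                }
            )
        out = seq
        for start, kind, base in sorted(edits, reverse=True):
            if kind == "ins":
                out = out[:start] + base + out[start:]
            else:
                out = out[:start] + out[start + 1 :]
        corrupted[seq_id] = out
    frame = pd.DataFrame(
        events, columns=["seq_id", "pos", "kind", "base", "run_length"]
    )
    return corrupted, rate_map_to_calibration(rate_map), frame


def inject_panel_errors(
    panel: PanelResult,
    reference: str,
    rate_map: Mapping[int, float],
    seed: int = 0,
    min_run: int = 2,
) -> tuple[list[PanelHaplotype], QVCalibration, pd.DataFrame]:
    """Per-copy, reference-anchored homopolymer indel injection.

    Scans homopolymer runs of the reference window, skips runs within
    2 bp of a planted variant, and independently corrupts each haploid
    copy.  The injected events are emitted as normalized anchored
    indel variants so downstream calling sees realistic artifacts.
    """
    if any(not 0 <= r < 1 for r in rate_map.values()):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    window = panel.window
    blocked = set()
    for pos in panel.truth["pos"]:
        blocked.update(range(int(pos) - 2, int(pos) + 3))
    runs = []
    for start, length, base in _scan_runs(reference[window.start : window.end], min_run):
        gstart = window.start + start
        if gstart == window.start:  # need an anchor base inside the window
            continue
        if any(p in blocked for p in range(gstart - 1, gstart + length + 1)):
            continue
        runs.append((gstart, length, base))

    new_haps = []
    events = []
    for hap in panel.haplotypes:
        extra: list[RawVariant] = []
        for gstart, length, base in runs:
            rate = _rate_for(length, rate_map)
            if rate <= 0 or rng.random() >= rate:
                continue
            anchor = gstart - 1
            if rng.random() < 0.5:
                v = RawVariant(
                    window.contig,
                    anchor,
                    reference[anchor],
                    reference[anchor] + base,
                    hap.copy_id,
                )
                kind = "ins"
            else:
                v = RawVariant(
                    window.contig,
                    anchor,
                    reference[anchor] + base,
                    reference[anchor],
                    hap.copy_id,
                )
                kind = "del"
            extra.append(v)
            events.append(
                {
                    "seq_id": hap.copy_id,
                    "pos": anchor,
                    "kind": kind,
                    "base": base,
                    "run_length": length,
                }
            )
        variants = tuple(sorted(hap.variants + tuple(extra), key=lambda v: v.pos))
        seq, _ = apply_variants(reference, window, variants)
        new_haps.append(
            PanelHaplotype(hap.copy_id, hap.cluster, variants, seq)
        )
    frame = pd.DataFrame(
        events, columns=["seq_id", "pos", "kind", "base", "run_length"]
    )
    return new_haps, rate_map_to_calibration(rate_map), frame


# ---------------------------------------------------------------------------
# alignments


def haplotype_alignment(
    hap: PanelHaplotype, reference: str, window: GenomicInterval
) -> ContigAlignment:
    """Exact gapped alignment of one haploid copy to the reference,
    reconstructed from its variant list."""
    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    cur = window.start
    for v in sorted(hap.variants, key=lambda v: v.pos):
        push("M", v.pos - cur)
        if len(v.ref) == len(v.alt):
            push("M", len(v.ref))
        else:
            push("M", 1)  # anchor base
            if len(v.alt) > len(v.ref):
                push("I", len(v.alt) - len(v.ref))
            else:
                push("D", len(v.ref) - len(v.alt))
        cur = v.pos + len(v.ref)
    push("M", window.end - cur)
    return ContigAlignment(
        name=hap.copy_id,
        contig=window.contig,
        ref_start=window.start,
        cigar=cigar,
        query=hap.window_seq,
    )


# ---------------------------------------------------------------------------
# cohorts and expression


def make_cohort_and_expression(
    catalog: HaplotypeCatalog,
    effect: EffectSpec,
    seed: int = 0,
) -> list[ExpressionStudy]:
    """Diploid cohorts sampled from catalog frequencies with an additive
    planted effect at one haplotype.

    Expression = baseline + effect_size * noise_sd * dosage + N(0,
    noise_sd), dosage = copies of the target haplotype id.  Studies use
    independent child seeds of the master seed.
    """
    entries = catalog.levels.get(effect.level, [])
    if len(entries) < 2:
        raise ValueError(f"catalog has < 2 haplotypes at level {effect.level}")
    ids = [e.hap_id for e in entries]
    if effect.target_hap_id not in ids:
        raise ValueError(
            f"target haplotype {effect.target_hap_id} absent at level "
            f"{effect.level}"
        )
    weights = np.array([e.count for e in entries], dtype=float)
    weights /= weights.sum()

    studies = []
    children = np.random.SeedSequence(seed).spawn(effect.n_studies)
    for s, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        expression: dict[str, float] = {}
        diplotypes: dict[str, Diplotype] = {}
        for i in range(effect.n_samples):
            sample = f"S{s}_{i:04d}"
            pair = tuple(rng.choice(ids, size=2, replace=True, p=weights))
            dosage = pair.count(effect.target_hap_id)
            value = (
                effect.baseline
                + effect.effect_size * effect.noise_sd * dosage
                + rng.normal(0.0, effect.noise_sd)
            )
            expression[sample] = float(value)
            diplotypes[sample] = Diplotype(effect.level, (int(pair[0]), int(pair[1])))
        studies.append(
            ExpressionStudy(
                study_id=f"study{s}",
                gene=catalog.gene,
                level=effect.level,
                expression=expression,
                diplotypes=diplotypes,
            )
        )
    return studies
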