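"""End-to-end gene build: trim alignments, call and classify variants,
apply the VQV filter, derive per-haplotype level sequences and rank the
catalog."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .gene_model import DEFAULT_FLANK, TranscriptModel, partition_regions
from .nomenclature import (
    ACTGCode,
    HaplotypeCatalog,
    LevelSequences,
    assign_code,
    build_catalog,
    derive_level_sequences,
)
from .variant_engine import (
    DEFAULT_THRESHOLDS,
    ClassifiedVariant,
    ContigAlignment,
    QVCalibration,
    RawVariant,
    aggregate_panel,
    call_variants_from_alignment,
    classify,
    filter_variants,
    score_variant,
    trim_to_gene_window,
)


@dataclass
class BuildResult:
    catalog: HaplotypeCatalog
    codes: dict[str, ACTGCode]  # per haploid copy
    variants: list[ClassifiedVariant]  # distinct variants with VQV/retained
    excluded: list[str]  # copies without end-to-end coverage
    body_haplotypes: list[dict]  # distinct gene-body haplotypes


def build_gene(
    model: TranscriptModel,
    reference: str,
    alignments: Sequence[ContigAlignment],
    calibration: Optional[QVCalibration] = None,
    *,
    flank: int = DEFAULT_FLANK,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    populations: Optional[Mapping[str, str]] = None,
    assemblies: Optional[Mapping[str, str]] = None,
    version: str = "v1",
    vqv_indels_only: bool = False,
) -> BuildResult:
    """Build one gene's haplotype catalog from contig alignments.

    Alignments that do not span the gene window end-to-end are excluded
    (mirroring the caller-side completeness criterion).  With no
    calibration table the VQV filter is skipped entirely.  With
    ``vqv_indels_only`` SNVs bypass the filter.
    """
    partition = partition_regions(model, flank=flank)
    window = partition.window

    per_copy: dict[str, list[RawVariant]] = {}
    excluded: list[str] = []
    for aln in alignments:
        try:
            trimmed = trim_to_gene_window(aln, model, flank=flank)
            per_copy[aln.name] = call_variants_from_alignment(
                trimmed, reference, window
            )
        except ValueError:
            excluded.append(aln.name)

    support, covering = aggregate_panel(per_copy)

    classified: dict[tuple, ClassifiedVariant] = {}
    for key, supporters in sorted(support.items()):
        contig, pos, ref, alt = key
        raw = RawVariant(contig, pos, ref, alt)
        cv = classify(raw, partition, model, reference)
        if calibration is not None and not (vqv_indels_only and not raw.is_indel):
            q = score_variant(raw, len(supporters), covering, calibration, reference)
            cv = ClassifiedVariant(
                contig, pos, ref, alt, "", cv.level, cv.flags, vqv=q
            )
        classified[key] = cv
    scored = filter_variants(list(classified.values()), thresholds)
    retained_keys = {
        v.key for v in scored if v.retained
    }
    classified = {v.key: v for v in scored}

    panel: list[LevelSequences] = []
    for copy_id in sorted(per_copy):
        kept = [
            RawVariant(*k, source_haplotype=copy_id)
            for k in sorted(v.key for v in per_copy[copy_id])
            if k in retained_keys
        ]
        ls = derive_level_sequences(kept, model, partition, reference)
        ls.source = copy_id
        panel.append(ls)

    catalog = build_catalog(
        panel,
        populations=populations,
        assemblies=assemblies,
        version=version,
        gene=model.gene_symbol,
    )
    codes = {
        ls.source: assign_code(ls, catalog, prefix=model.gene_symbol)
        for ls in panel
    }

    # distinct gene-body haplotypes: group copies by full window sequence
    by_window: dict[str, list[int]] = defaultdict(list)
    for i, ls in enumerate(panel):
        by_window[ls.window_seq].append(i)
    kept_by_copy = {
        ls.source: [
            RawVariant(*k)
            for k in sorted(v.key for v in per_copy[ls.source])
            if k in retained_keys
        ]
        for ls in panel
    }
    body = []
    pops = dict(populations or {})
    for seq in sorted(by_window, key=lambda s: (-len(by_window[s]), s)):
        idxs = by_window[seq]
        rep = panel[idxs[0]]
        code = codes[rep.source]
        members = [panel[i].source for i in idxs]
        body.append(
            {
                "ids": {"A": code.a, "C": code.c, "T": code.t, "G": code.g},
                "variants": kept_by_copy[rep.source],
                "count": len(idxs),
                "members": members,
                "pop_counts": dict(
                    Counter(pops[m] for m in members if m in pops)
                ),
            }
        )
    return BuildResult(
        catalog=catalog,
        codes=codes,
        variants=scored,
        excluded=excluded,
        body_haplotypes=body,
    )
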