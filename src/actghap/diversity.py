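"""Catalog-level diversity statistics.

Works on per-gene, per-level cluster count vectors (c_1..c_K): the
Good-Turing cover ratio 1 - f1/N, the Chao1 richness/completeness, a
fixed-depth subsampled haplotype count, length-normalized log2
z-scores, coverage summaries and simple OLS summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _check_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 1).any():
        raise ValueError("cluster counts must be >= 1")
    return arr


def good_turing_cover(counts: Sequence[int]) -> float:
    """Good-Turing coverage: probability that a newly sampled haplotype
    matches an already catalogued cluster, estimated as 1 - f1/N."""
    arr = _check_counts(counts)
    n = int(arr.sum())
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / n


def chao1_completeness(counts: Sequence[int]) -> tuple[float, float]:
    """Chao1 richness estimate and completeness = S_obs / richness.

    Classical estimator S_obs + f1^2/(2 f2) when doubletons exist,
    bias-corrected S_obs + f1(f1-1)/(2(f2+1)) otherwise.
    """
    arr = _check_counts(counts)
    s_obs = int(arr.size)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        richness = s_obs + f1 * f1 / (2.0 * f2)
    else:
        richness = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return richness, s_obs / richness


def subsample_distinct_counts(
    counts: Sequence[int],
    n_haploids: int,
    reps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Distinct-cluster counts over ``reps`` uniform without-replacement
    draws of ``n_haploids`` haploid observations."""
    arr = _check_counts(counts)
    n = int(arr.sum())
    if n < n_haploids:
        raise ValueError(f"panel has {n} haploids < subsample size {n_haploids}")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(arr.size), arr)
    out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        draw = rng.choice(labels, size=n_haploids, replace=False)
        out[r] = np.unique(draw).size
    return out


def subsample_median_count(
    counts: Sequence[int],
    n_haploids: int = 200,
    reps: int = 100,
    seed: Optional[int] = None,
) -> float:
    """Median distinct-haplotype count at fixed subsampling depth
    (deterministic under a fixed seed)."""
    draws = subsample_distinct_counts(counts, n_haploids, reps, seed=seed)
    return float(np.median(draws))


@dataclass(frozen=True)
class DiversitySummary:
    gene: str
    level: str
    median_subsampled_count: float
    level_length: int
    z: float


def length_normalized_z(
    summaries: Sequence[tuple[str, float, int]], level: str
) -> list[DiversitySummary]:
    """Standardize log2(count / length) across genes within one level.

    ``summaries`` rows are (gene, median haplotype count, level length
    in bp).  Standardizes with the population standard deviation (a
    symmetric ratio triple r/2, r, 2r maps to z = -1.22, 0, +1.22); a
    degenerate spread is an error.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 genes to standardize")
    genes, counts, lengths = zip(*summaries)
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any() or (counts <= 0).any():
        raise ValueError("counts and lengths must be positive")
    x = np.log2(counts / lengths)
    sd = float(np.std(x, ddof=0))
    if sd == 0.0:
        raise ValueError("zero variance: all genes share the same ratio")
    z = (x - x.mean()) / sd
    return [
        DiversitySummary(g, level, float(c), int(l), float(zz))
        for g, c, l, zz in zip(genes, counts, lengths, z)
    ]


def coverage_summary(
    per_gene_sample_counts: Mapping[str, int],
    thresholds: Sequence[int],
    classes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Fraction of genes with sample count >= threshold, stratified by
    chromosome class (one row per class x threshold)."""
    classes = classes or {}
    rows = []
    by_class: dict[str, list[int]] = {}
    for gene, n in per_gene_sample_counts.items():
        by_class.setdefault(classes.get(gene, "all"), []).append(n)
    for cls in sorted(by_class):
        vals = np.asarray(by_class[cls])
        for thr in thresholds:
            rows.append(
                {
                    "class": cls,
                    "threshold": int(thr),
                    "n_genes": int(vals.size),
                    "fraction": float((vals >= thr).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["class", "threshold", "n_genes", "fraction"])


def length_count_regression(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Ordinary least squares slope and R^2 for (x, y) points."""
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    x, y = map(np.asarray, zip(*points))
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: no spread")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def catalog_count_vector(catalog, level: str) -> list[int]:
    """Cluster counts of one catalog level, id order."""
    return [e.count for e in catalog.levels.get(level, [])]


def level_lengths(model, partition) -> dict[str, int]:
    """Reference-haplotype level lengths: A = CDS nt (3x protein), C =
    CDS nt, T = UTR nt, G = intron nt."""
    cds = sum(iv.length for iv in partition.cds)
    utr = sum(iv.length for iv in partition.utr5) + sum(
        iv.length for iv in partition.utr3
    )
    intron = sum(iv.length for iv in partition.introns)
    return {"A": cds, "C": cds, "T": utr, "G": intron}
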