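"""Pairwise haplotype-expression association (haplotype QTL).

Samples are grouped by unordered diplotype (the pair of haplotype ids
carried at one gene and level); every pair of groups with enough
samples is contrasted with a two-sided rank-sum test (Welch's t as the
configurable alternative), and associations are kept only when the
effect direction is concordant across independent studies.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_GROUP_SIZE = 3

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotype ids at one level."""

    level: str
    pair: tuple[int, int]

    def __post_init__(self) -> None:
        a, b = self.pair
        if a < 1 or b < 1:
            raise ValueError("haplotype ids must be positive")
        if a > b:
            object.__setattr__(self, "pair", (b, a))

    def __str__(self) -> str:
        lv = self.level.lower()
        return f"{lv}{self.pair[0]}-{lv}{self.pair[1]}"


@dataclass
class ExpressionStudy:
    """Normalized expression of one gene plus the sample diplotype map
    for one study."""

    study_id: str
    gene: str
    level: str
    expression: Mapping[str, float]
    diplotypes: Mapping[str, Diplotype]

    def tested_samples(self) -> list[str]:
        return sorted(set(self.expression) & set(self.diplotypes))


@dataclass(frozen=True)
class PairwiseAssociation:
    gene: str
    level: str
    study: str
    group_a: tuple[int, int]
    group_b: tuple[int, int]
    n_a: int
    n_b: int
    fold_change: float
    neg_log10_p: float
    direction: str  # "a<b" | "a>b" | "tie"

    @property
    def key(self) -> tuple:
        return (self.gene, self.level, self.group_a, self.group_b)


@dataclass(frozen=True)
class ConcordanceResult:
    key: tuple
    directions: Mapping[str, str]
    concordance_ratio: float
    concordant_all: bool


def group_samples(study: ExpressionStudy) -> dict[tuple[int, int], list[str]]:
    """Partition tested samples by unordered diplotype."""
    groups: dict[tuple[int, int], list[str]] = defaultdict(list)
    for sample in study.tested_samples():
        groups[study.diplotypes[sample].pair].append(sample)
    return dict(groups)


def pairwise_test(
    group_a_expr: Sequence[float],
    group_b_expr: Sequence[float],
    test: str = "ranksum",
    fold: str = "mean",
) -> tuple[float, float, str]:
    """Contrast two expression groups.

    Returns (fold_change, -log10 p, direction).  fold_change is
    mean(b)/mean(a) (or the median ratio); direction comes from the
    sign of the mean difference.
    """
    a = np.asarray(group_a_expr, dtype=float)
    b = np.asarray(group_b_expr, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty expression group")
    if test == "ranksum":
        if np.all(a[0] == a) and np.all(b[0] == b) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if math.isnan(p):
            p = 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    if fold == "mean":
        num, den = b.mean(), a.mean()
    elif fold == "median":
        num, den = float(np.median(b)), float(np.median(a))
    else:
        raise ValueError(f"unknown fold mode {fold!r}")
    fc = num / den if den != 0 else math.inf
    diff = b.mean() - a.mean()
    direction = "tie" if diff == 0 else ("a<b" if diff > 0 else "a>b")
    return fc, -math.log10(max(p, _P_FLOOR)), direction


def run_study(
    study: ExpressionStudy,
    min_group_size: int = MIN_GROUP_SIZE,
    test: str = "ranksum",
    fold: str = "mean",
) -> list[PairwiseAssociation]:
    """All pairwise diplotype-group contrasts of one study.

    Groups below ``min_group_size`` are skipped (not zero-filled).
    """
    groups = group_samples(study)
    eligible = sorted(k for k, v in groups.items() if len(v) >= min_group_size)
    out = []
    for ga, gb in itertools.combinations(eligible, 2):
        ea = [study.expression[s] for s in groups[ga]]
        eb = [study.expression[s] for s in groups[gb]]
        fc, nlp, direction = pairwise_test(ea, eb, test=test, fold=fold)
        out.append(
            PairwiseAssociation(
                gene=study.gene,
                level=study.level,
                study=study.study_id,
                group_a=ga,
                group_b=gb,
                n_a=len(ea),
                n_b=len(eb),
                fold_change=fc,
                neg_log10_p=nlp,
                direction=direction,
            )
        )
    return out


def concordance(
    results: Sequence[PairwiseAssociation],
) -> list[ConcordanceResult]:
    """Cross-study effect-direction concordance per association key.

    Keys present in fewer than two studies are excluded.  The ratio is
    the majority share of directions; ``concordant_all`` requires every
    non-tie direction to agree (and at least one non-tie).
    """
    by_key: dict[tuple, dict[str, str]] = defaultdict(dict)
    for r in results:
        by_key[r.key][r.study] = r.direction
    out = []
    for key in sorted(by_key):
        dirs = by_key[key]
        if len(dirs) < 2:
            continue
        votes = list(dirs.values())
        top = max(votes.count(d) for d in set(votes))
        ratio = top / len(votes)
        non_tie = {d for d in votes if d != "tie"}
        concordant = len(non_tie) == 1 and "tie" not in votes
        out.append(
            ConcordanceResult(
                key=key,
                directions=dict(dirs),
                concordance_ratio=ratio,
                concordant_all=concordant,
            )
        )
    return out


def significance_table(
    associations: Sequence[PairwiseAssociation],
    thresholds: Sequence[float],
    require_concordant: bool = True,
) -> pd.DataFrame:
    """Counts of associations per level at increasing -log10(p) cutoffs.

    An association key counts at a cutoff when every study reporting it
    reaches the cutoff; with ``require_concordant`` only keys whose
    effect direction agrees across all studies are counted.
    """
    conc = {c.key: c for c in concordance(associations)}
    by_key: dict[tuple, list[PairwiseAssociation]] = defaultdict(list)
    for r in associations:
        by_key[r.key].append(r)
    rows = []
    levels = sorted({r.level for r in associations})
    for level in levels:
        for thr in thresholds:
            n = 0
            for key, rs in by_key.items():
                if key[1] != level:
                    continue
                c = conc.get(key)
                if c is None:
                    continue
                if require_concordant and not c.concordant_all:
                    continue
                if min(r.neg_log10_p for r in rs) >= thr:
                    n += 1
            rows.append({"level": level, "threshold": float(thr), "count": n})
    return pd.DataFrame(rows, columns=["level", "threshold", "count"])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def associations_to_frame(
    associations: Sequence[PairwiseAssociation],
    concordances: Optional[Sequence[ConcordanceResult]] = None,
) -> pd.DataFrame:
    conc = {c.key: c for c in concordances or []}
    rows = []
    for r in associations:
        c = conc.get(r.key)
        rows.append(
            {
                "gene": r.gene,
                "level": r.level,
                "study": r.study,
                "group_a": Diplotype(r.level, r.group_a).__str__(),
                "group_b": Diplotype(r.level, r.group_b).__str__(),
                "n_a": r.n_a,
                "n_b": r.n_b,
                "fold_change": r.fold_change,
                "neg_log10_p": r.neg_log10_p,
                "direction": r.direction,
                "concordance_ratio": c.concordance_ratio if c else np.nan,
                "concordant_all": c.concordant_all if c else False,
            }
        )
    return pd.DataFrame(rows)
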