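"""Repertoire statistics: segment usage, V-J combinations, CDR3 length,
somatic mutation rate, and group comparisons.

Usage tables weight records with tied multi-allele calls fractionally
(1 / number of distinct labels at the chosen level) so a record never
contributes more than one count.  Group comparisons follow the classical
selection rule: Shapiro-Wilk normality per group at alpha = 0.05, Student's
t when both groups pass, the Wilcoxon rank-sum test otherwise, always
two-tailed; one-way ANOVA is available for three or more groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .germline import parse_allele_name
from .records import ChainRecord

logger = logging.getLogger(__name__)

USAGE_LEVELS = ("family", "gene", "allele")
ALPHA = 0.05


def _label(call: str, level: str) -> str:
    if level == "allele":
        return call
    name = parse_allele_name(call)
    return name.family if level == "family" else name.gene


def _weighted_labels(calls: Sequence[str], level: str) -> dict[str, float]:
    labels = sorted({_label(c, level) for c in calls})
    if not labels:
        return {}
    w = 1.0 / len(labels)
    return {lab: w for lab in labels}


@dataclass
class UsageTable:
    """Segment usage counts and frequencies at one level."""

    segment_type: str
    level: str
    entries: dict[str, tuple[float, float]]  # label -> (count, frequency)
    group: str = ""

    def counts(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.entries.items()}

    def frequencies(self) -> dict[str, float]:
        return {k: v[1] for k, v in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"label": k, "count": c, "frequency": f}
                for k, (c, f) in sorted(self.entries.items())
            ]
        )


def gene_usage(
    records: Iterable[ChainRecord],
    segment_type: str,
    level: str = "family",
    group: str = "",
    zero_labels: Iterable[str] = (),
) -> UsageTable:
    """Usage preference table for V, D or J calls.

    ``zero_labels`` optionally lists germline labels to report even at zero
    frequency, exposing absent families.  Raises on an empty record set.
    """
    if level not in USAGE_LEVELS:
        raise ValueError(f"unknown level: {level!r}")
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_type]
    counts: dict[str, float] = {lab: 0.0 for lab in zero_labels}
    total = 0.0
    n_records = 0
    for rec in records:
        n_records += 1
        for lab, w in _weighted_labels(getattr(rec, attr), level).items():
            counts[lab] = counts.get(lab, 0.0) + w
            total += w
    if n_records == 0:
        raise ValueError("gene_usage: empty record set")
    entries = {
        lab: (c, c / total if total else 0.0) for lab, c in counts.items()
    }
    return UsageTable(segment_type=segment_type, level=level, entries=entries, group=group)


@dataclass
class VJMatrix:
    """V-by-J combination count matrix with usage-consistent marginals."""

    matrix: pd.DataFrame  # index: V labels, columns: J labels

    @property
    def total(self) -> float:
        return float(self.matrix.to_numpy().sum())

    def row_marginals(self) -> dict[str, float]:
        return self.matrix.sum(axis=1).to_dict()

    def col_marginals(self) -> dict[str, float]:
        return self.matrix.sum(axis=0).to_dict()

    def top_combinations(self, k: int = 5) -> list[tuple[str, str, float]]:
        stacked = self.matrix.stack()
        stacked = stacked[stacked > 0].sort_values(ascending=False)
        return [(v, j, float(c)) for (v, j), c in stacked.head(k).items()]

    def nonzero_cells(self) -> list[tuple[str, str]]:
        stacked = self.matrix.stack()
        return sorted(stacked[stacked > 0].index.tolist())


def vj_matrix(records: Iterable[ChainRecord], level: str = "allele") -> VJMatrix:
    """Joint V-J combination counts; tied calls weighted fractionally."""
    cells: dict[tuple[str, str], float] = {}
    for rec in records:
        if not rec.v_call or not rec.j_call:
            continue
        v_labels = sorted({_label(c, level) for c in rec.v_call})
        j_labels = sorted({_label(c, level) for c in rec.j_call})
        w = 1.0 / (len(v_labels) * len(j_labels))
        for v in v_labels:
            for j in j_labels:
                cells[(v, j)] = cells.get((v, j), 0.0) + w
    v_labels = sorted({v for v, _ in cells})
    j_labels = sorted({j for _, j in cells})
    mat = pd.DataFrame(0.0, index=v_labels, columns=j_labels)
    for (v, j), c in cells.items():
        mat.loc[v, j] = c
    return VJMatrix(matrix=mat)


@dataclass
class LengthDistribution:
    histogram: dict[int, int]
    modes: list[int]
    shapiro_w: float | None
    shapiro_p: float | None
    n: int

    @property
    def normal(self) -> bool | None:
        if self.shapiro_p is None:
            return None
        return self.shapiro_p > ALPHA


def cdr3_length_distribution(records: Iterable[ChainRecord]) -> LengthDistribution:
    """CDR3 amino-acid length histogram with mode(s) and Shapiro-Wilk test.

    Lengths are counted on the anchor-free CDR3.  With n < 3 or zero
    variance the normality test is undefined (None) but the histogram is
    still returned; ties in the mode are all reported.
    """
    lengths = [len(r.cdr3_aa) for r in records if r.cdr3_aa]
    histogram: dict[int, int] = {}
    for length in lengths:
        histogram[length] = histogram.get(length, 0) + 1
    modes: list[int] = []
    if histogram:
        peak = max(histogram.values())
        modes = sorted(k for k, v in histogram.items() if v == peak)
    w = p = None
    if len(lengths) >= 3 and len(set(lengths)) > 1:
        w, p = sps.shapiro(lengths)
        w, p = float(w), float(p)
    return LengthDistribution(
        histogram=dict(sorted(histogram.items())), modes=modes,
        shapiro_w=w, shapiro_p=p, n=len(lengths),
    )


@dataclass
class MutationSummary:
    rates: list[float]
    five_number: tuple[float, float, float, float, float] | None
    n_excluded: int

    @property
    def median(self) -> float | None:
        return self.five_number[2] if self.five_number else None


def mutation_rate_summary(records: Iterable[ChainRecord]) -> MutationSummary:
    """Per-record V mutation rates and the box-plot five-number summary.

    Records with zero aligned germline length are excluded with a log line.
    """
    rates = []
    excluded = 0
    for rec in records:
        if rec.v_germline_aligned_length == 0:
            excluded += 1
            logger.info("mutation_rate_summary: excluding %s (zero aligned length)",
                        rec.sequence_id)
            continue
        rates.append(rec.v_mutation_count / rec.v_germline_aligned_length)
    five = None
    if rates:
        arr = np.asarray(rates)
        five = tuple(float(x) for x in (
            arr.min(), np.percentile(arr, 25), np.median(arr),
            np.percentile(arr, 75), arr.max(),
        ))
    return MutationSummary(rates=rates, five_number=five, n_excluded=excluded)


@dataclass
class ComparisonResult:
    """Two-group (or k-group) comparison with normality-based test selection."""

    group_sizes: list[int]
    means: list[float]
    medians: list[float]
    normality_p: list[float]
    test: str  # "t" | "wilcoxon" | "anova"
    statistic: float
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _normality_p(values: np.ndarray) -> float:
    # A constant sample has no Shapiro-Wilk statistic; treat it as
    # maximally non-normal so the rank test is selected.
    if len(set(values.tolist())) == 1:
        return 0.0
    return float(sps.shapiro(values)[1])


def compare_groups(*groups: Sequence[float]) -> ComparisonResult:
    """Compare 2 (t / Wilcoxon rank-sum) or >= 3 (ANOVA) groups of values.

    Each group needs n >= 3.  Both groups normal by Shapiro-Wilk (p > 0.05)
    selects Student's t; otherwise the Wilcoxon rank-sum test; all tests are
    two-tailed.  If every value in every group is identical, statistic 0 and
    p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for arr in arrays:
        if len(arr) < 3:
            raise ValueError("each group needs n >= 3")
    norm_p = [_normality_p(a) for a in arrays]
    sizes = [len(a) for a in arrays]
    means = [float(a.mean()) for a in arrays]
    medians = [float(np.median(a)) for a in arrays]

    pooled = set(np.concatenate(arrays).tolist())
    if len(pooled) == 1:
        test = "anova" if len(arrays) >= 3 else (
            "t" if all(p > ALPHA for p in norm_p) else "wilcoxon")
        return ComparisonResult(sizes, means, medians, norm_p, test, 0.0, 1.0)

    if len(arrays) >= 3:
        stat, p = sps.f_oneway(*arrays)
        test = "anova"
    elif all(p > ALPHA for p in norm_p):
        stat, p = sps.ttest_ind(arrays[0], arrays[1])
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        test = "wilcoxon"
    p = float(p)
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return ComparisonResult(sizes, means, medians, norm_p, test, float(stat), p)


@dataclass
class LightChainCounts:
    kappa: int
    lambda_: int
    p_value: float

    @property
    def lambda_fraction(self) -> float:
        return self.lambda_ / (self.kappa + self.lambda_)


def light_chain_class_counts(records: Iterable[ChainRecord]) -> LightChainCounts:
    """Kappa vs lambda counts with a two-sided exact binomial test vs 0.5."""
    kappa = sum(1 for r in records if r.locus == "IGK")
    lam = sum(1 for r in records if r.locus == "IGL")
    n = kappa + lam
    if n == 0:
        raise ValueError("no light-chain records")
    p = float(sps.binomtest(lam, n, 0.5, alternative="two-sided").pvalue)
    return LightChainCounts(kappa=kappa, lambda_=lam, p_value=p)
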