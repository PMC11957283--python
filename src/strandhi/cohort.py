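"""Population-level analyses of Health Index values.

Per-group descriptive summaries (with Fisher-Pearson g1 skewness), the
five-category HI binning used for frequency profiles, Kruskal-Wallis
omnibus comparison of HI across subjective health categories, Dunn's
rank-based pairwise post hoc test, and per-parameter contribution profiles
by HI category.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import HIResult, NecropsyRecord, Parameter, Taxon

__all__ = [
    "CohortSummary",
    "CategoryBin",
    "PairwiseResult",
    "GroupComparison",
    "ContributionProfile",
    "HI_BINS",
    "summarize",
    "summary_frame",
    "skewness_g1",
    "bin_hi",
    "bin_counts",
    "kruskal_wallis",
    "dunn_pairwise",
    "compare_groups",
    "parameter_contribution",
]


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics for one group's HI values.

    ``sd_hi`` uses the sample (n-1) denominator; a singleton group reports
    ``sd_hi = 0`` with ``sd_defined = False``.  ``g1`` is the biased
    Fisher-Pearson standardized third moment m3 / m2^(3/2); it is NaN when
    n < 3 or the variance is zero.
    """

    group_label: str
    n: int
    mean_hi: float
    sd_hi: float
    min_hi: float
    max_hi: float
    g1: float
    sd_defined: bool = True


@dataclass(frozen=True)
class CategoryBin:
    label: str
    lower: float  # inclusive
    upper: float  # exclusive, except the top bin which is closed


#: The five HI categories.  Printed labels like "0.20 to 0.39" are read as
#: half-open intervals [0.20, 0.40) on the continuous HI scale; the top bin
#: is closed at 1.0.
HI_BINS: Sequence[CategoryBin] = (
    CategoryBin("<0.20", 0.0, 0.20),
    CategoryBin("0.20–0.39", 0.20, 0.40),
    CategoryBin("0.40–0.59", 0.40, 0.60),
    CategoryBin("0.60–0.79", 0.60, 0.80),
    CategoryBin("0.80–1.0", 0.80, 1.0),
)


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus result plus Dunn pairwise entries."""

    groups: Sequence[str]
    H: float
    p_value: float
    pairwise: Sequence[PairwiseResult]


@dataclass(frozen=True)
class ContributionProfile:
    hi_category: str
    parameter: str
    mean_value: float
    sd_value: float
    standardized: bool


def summarize(hi_values: Sequence[float], group_label: str = "") -> CohortSummary:
    """n, mean, sample sd, min, max and g1 skewness of one group's HI values."""
    x = np.asarray(list(hi_values), dtype=float)
    if x.size == 0:
        raise ValueError(f"empty group {group_label!r}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("HI values must lie in [0, 1]")
    n = int(x.size)
    sd_defined = n > 1
    sd = float(np.std(x, ddof=1)) if sd_defined else 0.0
    if n >= 3 and np.ptp(x) > 0:
        g1 = skewness_g1(x)
    else:
        g1 = float("nan")
    return CohortSummary(
        group_label=group_label,
        n=n,
        mean_hi=float(np.mean(x)),
        sd_hi=sd,
        min_hi=float(np.min(x)),
        max_hi=float(np.max(x)),
        g1=g1,
        sd_defined=sd_defined,
    )


def summary_frame(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One summary row per group, in the fixed CSV column layout."""
    rows = [summarize(values, label) for label, values in groups.items()]
    return pd.DataFrame(
        {
            "group": [s.group_label for s in rows],
            "n": [s.n for s in rows],
            "mean_hi": [s.mean_hi for s in rows],
            "sd_hi": [s.sd_hi for s in rows],
            "min_hi": [s.min_hi for s in rows],
            "max_hi": [s.max_hi for s in rows],
            "g1": [s.g1 for s in rows],
        }
    )


def skewness_g1(values: Sequence[float]) -> float:
    """Fisher-Pearson standardized moment coefficient g1 = m3 / m2^(3/2).

    Central moments use the population (n) denominator, matching the g1
    symbol; negative values indicate a tail toward low values.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise ValueError("g1 requires at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("g1 undefined for zero-variance data")
    return float(stats.skew(x, bias=True))


def bin_hi(hi: float) -> str:
    """Label of the five-category HI bin containing ``hi``."""
    if not 0.0 <= hi <= 1.0:
        raise ValueError(f"HI {hi!r} outside [0, 1]")
    for b in HI_BINS[:-1]:
        if hi < b.upper:
            return b.label
    return HI_BINS[-1].label


def bin_counts(hi_values: Sequence[float]) -> dict[str, int]:
    """Frequency of HI values per category; counts sum to len(hi_values)."""
    counts = {b.label: 0 for b in HI_BINS}
    for hi in hi_values:
        counts[bin_hi(hi)] += 1
    return counts


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   labels: Optional[Sequence[str]] = None) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value.

    When every pooled value is identical the test is vacuous: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return GroupComparison(groups=labels, H=0.0, p_value=1.0, pairwise=())
    H, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return GroupComparison(groups=labels, H=float(H), p_value=float(p), pairwise=())


def dunn_pairwise(groups: Sequence[Sequence[float]],
                  labels: Optional[Sequence[str]] = None,
                  adjustment: str = "none") -> list[PairwiseResult]:
    """Dunn's rank-based post hoc test for all C(k,2) group pairs.

    z for pair (i, j) is the difference in mean pooled ranks divided by the
    tie-corrected pooled standard error

        sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),   T = sum(t^3 - t) / (12(N-1)),

    with two-sided normal p-values, optionally Bonferroni- or Holm-adjusted.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]

    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [float(ranks[offsets[i]:offsets[i + 1]].mean()) for i in range(len(arrays))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(arrays)), 2))
    zs, praws = [], []
    for i, j in pairs:
        se2 = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:  # all pooled values tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
        zs.append(z)
        praws.append(min(1.0, 2.0 * stats.norm.sf(abs(z))))

    if adjustment == "none":
        padj = list(praws)
    else:
        padj = list(multipletests(praws, method=adjustment)[1])

    return [
        PairwiseResult(labels[i], labels[j], zs[k], praws[k], padj[k])
        for k, (i, j) in enumerate(pairs)
    ]


def compare_groups(groups: Sequence[Sequence[float]],
                   labels: Optional[Sequence[str]] = None,
                   adjustment: str = "none") -> GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise entries in one report."""
    omnibus = kruskal_wallis(groups, labels)
    pairwise = dunn_pairwise(groups, labels, adjustment)
    return GroupComparison(
        groups=omnibus.groups, H=omnibus.H, p_value=omnibus.p_value, pairwise=tuple(pairwise)
    )


#: Maximum body-score value per taxon (score 3 x body weight), used to put
#: the only taxon-dependent parameter on a common [0, 1] scale.
_BODY_MAX = {Taxon.SEABIRD: 3, Taxon.MARINE_MAMMAL: 3, Taxon.SEA_TURTLE: 6}


def parameter_contribution(records: Sequence[NecropsyRecord],
                           results: Sequence[HIResult]) -> list[ContributionProfile]:
    """Mean and sd of each parameter's weighted value, per HI category.

    Only determinable results are used.  Body-score values are divided by
    the taxon-specific maximum (3 or 6) before aggregation, since body score
    is the only parameter whose weight differs between taxa.
    """
    taxon_by_id = {r.record_id: Taxon(r.taxon) for r in records}
    rows = []
    for res in results:
        if not res.determinable:
            continue
        category = bin_hi(res.hi)
        for ps in res.parameter_values:
            if ps.parameter is Parameter.BODY:
                value = ps.value / _BODY_MAX[taxon_by_id[res.record_id]]
                standardized = True
            else:
                value = float(ps.value)
                standardized = False
            rows.append((category, ps.parameter.value, value, standardized))
    if not rows:
        raise ValueError("no determinable results to profile")

    df = pd.DataFrame(rows, columns=["hi_category", "parameter", "value", "standardized"])
    profiles = []
    for (category, parameter), sub in df.groupby(["hi_category", "parameter"], sort=False):
        values = sub["value"].to_numpy()
        profiles.append(
            ContributionProfile(
                hi_category=category,
                parameter=parameter,
                mean_value=float(values.mean()),
                sd_value=float(values.std(ddof=1)) if values.size > 1 else 0.0,
                standardized=bool(sub["standardized"].iloc[0]),
            )
        )
    order = {b.label: i for i, b in enumerate(HI_BINS)}
    param_order = {p.value: i for i, p in enumerate(Parameter)}
    profiles.sort(key=lambda pr: (order[pr.hi_category], param_order[pr.parameter]))
    return profiles
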