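"""Correlation and set-partition analyses.

Covers the relationships the expression pipeline feeds into: tRNA abundance
versus annotated gene copy number, codon-usage (RSCU) family percentages
versus anticodon expression percentages paired through Watson-Crick decoding,
and shared/unique membership partitions of expressed sequence sets across
tissues or treatments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from trnakit.annotation import CopyNumberTable
from trnakit.codonusage import anticodon_to_codon


@dataclass
class CorrelationResult:
    """Pearson r with its two-sided t-test p-value (n - 2 df)."""

    r: float
    p_value: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=x.size)


def copy_number_expression(
    expression: pd.Series,
    table: CopyNumberTable | Mapping[str, int],
    drop: Iterable[str] | None = None,
) -> CorrelationResult:
    """Correlate mean expression (CPM) with annotated copy number over keys
    shared by both inputs.

    ``drop`` removes keys before computing — the sensitivity analysis of
    excluding a few very-high-copy anticodons.  Keys in ``drop`` may be full
    'AA-Anticodon' keys or bare anticodons.
    """
    counts = table.counts if isinstance(table, CopyNumberTable) else dict(table)
    cn = pd.Series(counts, dtype=float)
    shared = expression.index.intersection(cn.index)
    if drop:
        dropset = set(drop)
        shared = [
            k for k in shared
            if k not in dropset and k.rsplit("-", 1)[-1] not in dropset
        ]
    if len(shared) < 3:
        raise ValueError("fewer than 3 matched anticodon/sequence keys")
    return pearson(expression[shared].to_numpy(), cn[shared].to_numpy())


def family_percentages(
    values: pd.Series,
    family_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> pd.Series:
    """Rescale non-negative values to percentages summing to 100 within each
    amino-acid family; zero-sum families become NaN.

    Keys default to 'AA-Anticodon' form (family = prefix); pass ``family_of``
    for codon-keyed input.
    """
    if family_of is None:
        fam = values.index.map(lambda k: k.rsplit("-", 1)[0])
    elif callable(family_of):
        fam = values.index.map(family_of)
    else:
        fam = values.index.map(lambda k: family_of[k])
    if (values.fillna(0) < 0).any():
        raise ValueError("family_percentages expects non-negative values")
    totals = values.groupby(fam).transform("sum")
    out = values * 100.0 / totals
    out[totals == 0] = np.nan
    return out


def rscu_expression_correlation(
    usage_pct: pd.Series,
    expr_pct: pd.Series,
) -> CorrelationResult:
    """Correlate codon-usage family percentages with anticodon-expression
    family percentages, pairing each anticodon with its Watson-Crick codon.

    ``usage_pct`` is keyed by DNA codon, ``expr_pct`` by 'AA-Anticodon'.
    Anticodons whose codon is absent from the usage table are excluded (they
    are unannotated, not zero).
    """
    pairs = []
    for key, e in expr_pct.items():
        anticodon = key.rsplit("-", 1)[-1]
        codon = anticodon_to_codon(anticodon)
        if codon in usage_pct.index:
            u = usage_pct[codon]
            if not (pd.isna(u) or pd.isna(e)):
                pairs.append((u, e))
    if len(pairs) < 3:
        raise ValueError("fewer than 3 codon/anticodon pairs")
    arr = np.array(pairs, dtype=float)
    return pearson(arr[:, 0], arr[:, 1])


@dataclass
class SetPartition:
    """Counts of every nonempty membership pattern over k named sets."""

    labels: list
    regions: dict            # frozenset of labels -> count
    percentages: dict        # same keys, percent of union size

    def count(self, *labels) -> int:
        return self.regions.get(frozenset(labels), 0)

    def percent(self, *labels) -> float:
        return self.percentages.get(frozenset(labels), 0.0)

    @property
    def shared_all_percent(self) -> float:
        return self.percent(*self.labels)


def shared_unique(sets: Mapping[str, set]) -> SetPartition:
    """Exact membership-pattern partition of 2 or 3 named sets.

    Region percentages use the union size as the base, so they sum to 100.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("shared_unique takes 2 or 3 condition sets")
    union = set().union(*sets.values())
    if not union:
        raise ValueError("empty union")

    regions: dict = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(set(sets[l]) for l in combo))
            outside = set().union(*(set(sets[l]) for l in labels if l not in combo)) \
                if len(combo) < len(labels) else set()
            regions[frozenset(combo)] = len(inside - outside)
    total = len(union)
    percentages = {k: 100.0 * v / total for k, v in regions.items()}
    return SetPartition(labels=labels, regions=regions, percentages=percentages)


def partition_to_frame(p: SetPartition) -> pd.DataFrame:
    rows = [
        ("&".join(sorted(k)), v, p.percentages[k])
        for k, v in sorted(p.regions.items(), key=lambda kv: "&".join(sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["region", "count", "percent"])
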