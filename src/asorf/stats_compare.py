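"""Comparison statistics for scan outputs.

One-tailed Fisher exact tests compare ORF counts against available loci
between reading frames; one-tailed Mann-Whitney U tests compare length or
GC distributions; families of p values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted q values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass(frozen=True)
class ContingencyResult:
    """One 2x2 ORFs-versus-loci comparison between two groups."""

    label: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    q_value: float
    alternative: str


def frame_enrichment_test(
    counts: Dict,
    loci: Dict,
    pairs: Sequence[Tuple] = None,
    alternative: str = "greater",
) -> List[ContingencyResult]:
    """Pairwise one-tailed Fisher exact tests on ORF counts vs loci.

    Each pair (a, b) is tested on the table
    [[count_a, loci_a - count_a], [count_b, loci_b - count_b]] with the
    given one-tailed alternative (default: a enriched over b); q values
    are BH-adjusted across the family of requested pairs.  Loci counts
    may be non-integral (per-frame loci are thirds) and are rounded.
    """
    if pairs is None:
        keys = list(counts)
        pairs = [(keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    tables, labels = [], []
    for a, b in pairs:
        la, lb = int(round(loci[a])), int(round(loci[b]))
        ca, cb = counts[a], counts[b]
        if la <= 0 or lb <= 0:
            raise ValueError(f"zero loci in pair ({a}, {b})")
        if ca > la or cb > lb:
            raise ValueError(f"counts exceed loci in pair ({a}, {b})")
        tables.append(((ca, la - ca), (cb, lb - cb)))
        labels.append(f"{a}_vs_{b}")
    results = [stats.fisher_exact(t, alternative=alternative) for t in tables]
    qs = bh_adjust([r.pvalue for r in results])
    return [
        ContingencyResult(label=l, table=t, odds_ratio=float(r.statistic),
                          p_value=float(r.pvalue), q_value=float(q),
                          alternative=alternative)
        for l, t, r, q in zip(labels, tables, results, qs)
    ]


def length_comparison_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "greater",
) -> Dict[str, float]:
    """One-tailed Mann-Whitney U comparison of two distributions.

    Returns the U statistic, one-tailed p value and both medians;
    ``alternative`` states the direction claimed for sample a.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "alternative": alternative,
    }
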