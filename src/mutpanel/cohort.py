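"""Cohort association of SV counts by size class with drinking status.

Per-sample deletion/duplication counts in the three trimodal size classes are
compared between drinkers and non-drinkers with the Wilcoxon rank-sum
(Mann-Whitney U) test, as raw per-cell p-values without multiplicity
adjustment; the report states the number of tests performed so readers can
adjust if desired.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .svclass import SMALL, MID, LARGE, SVRecord, SizeClassScheme, classify_size

DRINKER, NON_DRINKER, UNKNOWN = "drinker", "non-drinker", "unknown"
SIZE_CLASSES = (SMALL, MID, LARGE)
COUNTED_TYPES = ("DEL", "DUP")


def count_by_class(
    records_by_sample: Mapping[str, Sequence[SVRecord]],
    scheme: SizeClassScheme | None = None,
    declared_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample DEL/DUP counts in each size class.

    Samples declared but absent from the records appear with zero counts
    (absence of events is data, not missingness). Columns are a (type, class)
    MultiIndex.
    """
    scheme = scheme or SizeClassScheme()
    samples = list(records_by_sample)
    if declared_samples is not None:
        extra = [s for s in declared_samples if s not in records_by_sample]
        samples += extra
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    cols = pd.MultiIndex.from_product([COUNTED_TYPES, SIZE_CLASSES], names=["type", "size_class"])
    table = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=cols)
    for sample, records in records_by_sample.items():
        for r in records:
            if r.svtype not in COUNTED_TYPES or r.length is None:
                continue
            cls = classify_size(r.length, scheme)
            if cls in SIZE_CLASSES:
                table.loc[sample, (r.svtype, cls)] += 1
    return table


def _u_statistic(ranks_x: np.ndarray, n: int) -> float:
    return float(ranks_x.sum() - n * (n + 1) / 2)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test; returns (U of x, two-sided p).

    Exact mode enumerates the permutation distribution of U over all group
    assignments, with ties mid-ranked (feasible for min(n, m) <= 10 or
    n + m <= 20). Normal mode uses the tie-corrected normal approximation
    with continuity correction. "auto" picks exact when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u = _u_statistic(ranks[:n], n)
    if np.ptp(pooled) == 0:
        return u, 1.0

    has_ties = len(np.unique(pooled)) < n + m
    if mode == "auto":
        mode = "exact" if (min(n, m) <= 10 or n + m <= 20) else "normal"
    if mode == "exact":
        if not (min(n, m) <= 10 or n + m <= 20):
            raise ValueError("exact mode infeasible for these group sizes")
        if not has_ties:
            # tie-free: scipy's exact U distribution (efficient recursion)
            res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue)
        total = comb(n + m, n)
        if total > 2_000_000:
            raise ValueError("exact enumeration with ties infeasible at these group sizes")
        base = n * (n + 1) / 2
        us = np.fromiter(
            (ranks[list(idx)].sum() - base for idx in combinations(range(n + m), n)),
            dtype=float,
            count=total,
        )
        p_le = np.count_nonzero(us <= u + 1e-9) / total
        p_ge = np.count_nonzero(us >= u - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p
    if mode == "normal":
        res = scipy.stats.mannwhitneyu(
            x, y, use_continuity=True, alternative="two-sided", method="asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def cohort_report(
    table: pd.DataFrame,
    exposure: Mapping[str, str] | pd.Series,
    mode: str = "auto",
) -> pd.DataFrame:
    """Group medians and Wilcoxon rank-sum tests per (type, size class) cell.

    Samples labelled "unknown" are excluded. Cells where either group has
    fewer than 2 samples are flagged untestable rather than dropped. No
    multiple-testing correction is applied; the ``n_tests`` column carries the
    number of tests performed for readers who wish to adjust.
    """
    labels = pd.Series(dict(exposure)) if isinstance(exposure, Mapping) else exposure
    labels = labels.reindex(table.index)
    bad = set(labels.dropna().unique()) - {DRINKER, NON_DRINKER, UNKNOWN}
    if bad:
        raise ValueError(f"unrecognized exposure labels: {bad}")
    drinkers = table.index[labels == DRINKER]
    nondrinkers = table.index[labels == NON_DRINKER]
    testable = len(drinkers) >= 2 and len(nondrinkers) >= 2
    rows = []
    n_tests = sum(
        1 for _ in table.columns
    ) if testable else 0
    for col in table.columns:
        svtype, cls = col
        a = table.loc[drinkers, col].to_numpy(dtype=float)
        b = table.loc[nondrinkers, col].to_numpy(dtype=float)
        row = {
            "type": svtype,
            "size_class": cls,
            "n_drinker": len(a),
            "n_nondrinker": len(b),
            "median_drinker": float(np.median(a)) if len(a) else np.nan,
            "median_nondrinker": float(np.median(b)) if len(b) else np.nan,
            "testable": testable,
            "n_tests": n_tests,
        }
        if testable:
            u, p = rank_sum_test(a, b, mode=mode)
            row["U"] = u
            row["p_value"] = p
        else:
            row["U"] = np.nan
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def length_histograms(
    records_by_sample: Mapping[str, Sequence[SVRecord]],
    exposure: Mapping[str, str],
    bins: int = 40,
) -> pd.DataFrame:
    """log10-length histogram counts per SV type and exposure group."""
    rows = []
    for sample, records in records_by_sample.items():
        group = exposure.get(sample, UNKNOWN)
        for r in records:
            if r.svtype in COUNTED_TYPES and r.length:
                rows.append({"group": group, "type": r.svtype, "log10_length": np.log10(r.length)})
    if not rows:
        return pd.DataFrame(columns=["group", "type", "bin_left", "count"])
    df = pd.DataFrame(rows)
    edges = np.linspace(2.0, 8.0, bins + 1)
    out = []
    for (group, svtype), sub in df.groupby(["group", "type"]):
        counts, _ = np.histogram(sub["log10_length"], bins=edges)
        for left, c in zip(edges[:-1], counts):
            out.append({"group": group, "type": svtype, "bin_left": float(left), "count": int(c)})
    return pd.DataFrame(out)
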