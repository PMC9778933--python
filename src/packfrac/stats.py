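"""Replicate aggregation and nonparametric tests.

The replication structure mirrors microfluidic biofilm experiments: technical
replicates are separate z-stacks from randomized locations within one flow
chamber and are averaged into a single biological-replicate value per
chamber; chambers are the n of all downstream tests.  Comparisons use
two-sided Mann-Whitney U (unpaired) and Wilcoxon signed-rank (paired) tests
with Bonferroni correction over the explicitly stated family of comparisons.

The U and signed-rank machinery is delegated to :mod:`scipy.stats`; this
module pins down the method-selection rules (exact by enumeration for small
tie-free samples, otherwise the tie-corrected normal approximation with
continuity correction) and reports which method was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "aggregate_technical",
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bonferroni",
    "pairwise_tests",
]

#: exact Mann-Whitney enumeration is used up to this combined sample size
MWU_EXACT_MAX_N = 16
#: exact Wilcoxon sign-flip enumeration is used up to this many nonzero pairs
WILCOXON_EXACT_MAX_N = 20


def aggregate_technical(
    records: pd.DataFrame,
    value_col: str = "value",
    chamber_col: str = "chamber_id",
    metric_col: str = "metric",
    condition_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Average technical replicates (fields of view) into per-chamber values.

    ``records`` is tidy: one row per (chamber, field of view) measurement.
    Exactly one metric may be aggregated per call — mixing metrics in one mean
    is a bookkeeping bug, so it raises.  The output has one row per chamber
    (per condition), and its row count is the n of downstream tests.
    """
    if metric_col in records.columns:
        metrics = records[metric_col].unique()
        if len(metrics) > 1:
            raise ValueError(
                f"records mix metrics {sorted(map(str, metrics))}; aggregate one metric at a time"
            )
    if records.empty:
        raise ValueError("no records to aggregate")
    keys = [chamber_col] + [
        c for c in (condition_cols or []) if c in records.columns
    ]
    if metric_col in records.columns:
        keys.append(metric_col)
    out = records.groupby(keys, as_index=False, sort=True)[value_col].mean()
    return out.rename(columns={value_col: "value"})


@dataclass(frozen=True)
class TestResult:
    """Statistic, two-sided p, and the method actually used (exact/approx)."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    n_zero_dropped: int = 0

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def mann_whitney_u(x, y, exact_if_small: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p value is exact (full enumeration of labelings) when the combined
    sample size is <= 16 and there are no ties across groups, provided
    ``exact_if_small``; otherwise the normal approximation with tie-corrected
    variance and continuity correction is used.  The U statistic reported is
    for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    use_exact = exact_if_small and (len(x) + len(y) <= MWU_EXACT_MAX_N) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n=(len(x), len(y)),
    )


def _signed_rank_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Midranks handle tied |d|; the sign-flip distribution of W+ is built by
    polynomial convolution over doubled (integer) ranks, which is identical to
    full enumeration.  Returns (W+, p).
    """
    ranks = sps.rankdata(np.abs(d))
    r2 = np.round(2 * ranks).astype(int)
    w_obs = float(ranks[d > 0].sum())
    w2 = int(round(2 * w_obs))
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    n_total = counts.sum()  # = 2^n exactly in float for n <= 20
    p_le = counts[: w2 + 1].sum() / n_total
    p_ge = counts[w2:].sum() / n_total
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_x, paired_y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic Wilcoxon convention) and their count
    reported.  The p value is exact (the full 2^n sign-flip distribution, with
    midranks for tied |differences|) for n <= 20 nonzero differences,
    otherwise the normal approximation with continuity correction.  The
    statistic is W+ (sum of positive-difference ranks) on the exact path.
    All-zero differences yield a NaN sentinel (no evidence either way), not an
    error.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples differ in length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    nz = d[d != 0]
    n_dropped = len(d) - len(nz)
    if len(nz) == 0:
        return TestResult(float("nan"), float("nan"), "degenerate", (0,), n_dropped)
    if len(nz) <= WILCOXON_EXACT_MAX_N:
        w, p = _signed_rank_exact(nz)
        return TestResult(w, p, "exact", (len(nz),), n_dropped)
    res = sps.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", correction=True, method="approx"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="approx",
        n=(len(nz),),
        n_zero_dropped=n_dropped,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m).

    ``m`` is the family size — the number of pairwise comparisons in one
    figure panel, stated explicitly rather than inferred.  Defaults to
    ``len(p_values)``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def pairwise_tests(
    values: pd.DataFrame,
    group_col: str,
    value_col: str = "value",
    pairs: list[tuple[str, str]] | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Run all (or the given) pairwise comparisons and Bonferroni-adjust them.

    Returns a tidy table: groups, per-group n, statistic, raw p, adjusted p,
    and the method used.  The Bonferroni family is exactly the set of pairs
    tested here.
    """
    groups = {g: sub[value_col].to_numpy() for g, sub in values.groupby(group_col)}
    names = sorted(groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        if paired:
            res = wilcoxon_signed_rank(groups[a], groups[b])
        else:
            res = mann_whitney_u(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(groups[a]),
                "n_b": len(groups[b]),
                "statistic": res.statistic,
                "p_raw": res.p_value,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_raw"].to_numpy(), m=len(out))
    return out
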