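"""Enrichment analysis of sorted-population counts against the pDNA pool.

Per-element read counts are normalized to relative abundance (% of the
sample total), fold changes are computed for each sorted population against
the plasmid library baseline, and significance is assessed with a
two-tailed unpaired (Welch) t-test across replicates. Elements are called
enriched (FC > 1.5, p < 0.05), depleted (FC < 0.67, p < 0.05) or neutral,
with strict inequalities throughout.

With two replicates per group the t-test is fragile: a zero-variance
degenerate pair yields an undefined p (flagged, call = "undetermined")
rather than a fabricated number. By default the t-test runs on
log10(abundance + pseudo), where replicate variance is approximately
mean-independent; fold changes are always computed on the raw percent
scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDO = 0.005  # percentage points
DEFAULT_FC_UP = 1.5
DEFAULT_FC_DOWN = 0.67
DEFAULT_ALPHA = 0.05

CALL_ENRICHED = "enriched"
CALL_DEPLETED = "depleted"
CALL_NEUTRAL = "neutral"
CALL_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class EnrichmentResult:
    element_id: str
    population_label: str
    day: int
    fold_change: float
    p_value: float  # NaN = undefined (degenerate variance)
    call: str = CALL_NEUTRAL


# ---------------------------------------------------------------------------
# normalization


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent abundance per column: 100 * count / column total.

    Columns with an all-zero total are left as NaN (flagged undefined)
    rather than raising, so a failed sample does not sink a whole screen.
    """
    totals = counts.sum(axis=0).astype(float)
    abund = 100.0 * counts.div(totals.where(totals > 0), axis=1)
    return abund


def fold_change(
    sorted_abund: Sequence[float],
    pdna_abund: Sequence[float],
    pseudo: float = DEFAULT_PSEUDO,
) -> float:
    """(mean sorted + pseudo) / (mean pDNA + pseudo), on percent abundance."""
    a = np.asarray(sorted_abund, dtype=float)
    b = np.asarray(pdna_abund, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("abundance vectors must be non-empty")
    return float((a.mean() + pseudo) / (b.mean() + pseudo))


def t_test_two_tailed(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Welch two-tailed unpaired t-test p-value.

    Degenerate cases with n = 2-scale replicate data: if both groups have
    zero variance and equal means the p-value is 1 (no evidence of any
    difference); zero variance with unequal means has no defined test
    statistic and returns NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else float("nan")
    with warnings.catch_warnings():
        # nearly identical replicates trip scipy's precision-loss warning;
        # the degenerate exact-tie cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def classify(
    fc: float,
    p: float,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Hit call from fold change and p-value (strict inequalities)."""
    if math.isnan(p):
        return CALL_UNDETERMINED
    if fc > fc_up and p < alpha:
        return CALL_ENRICHED
    if fc < fc_down and p < alpha:
        return CALL_DEPLETED
    return CALL_NEUTRAL


def call_hits(
    results: Sequence[EnrichmentResult],
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """(Re-)classify a result set under the given thresholds."""
    return [
        EnrichmentResult(
            r.element_id,
            r.population_label,
            r.day,
            r.fold_change,
            r.p_value,
            classify(r.fold_change, r.p_value, fc_up, fc_down, alpha),
        )
        for r in results
    ]


# ---------------------------------------------------------------------------
# screen-level analysis


def compute_enrichment(
    abundance: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pseudo: float = DEFAULT_PSEUDO,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    alpha: float = DEFAULT_ALPHA,
    test_on_log: bool = True,
) -> pd.DataFrame:
    """Full enrichment table for every sorted population vs the pDNA pool.

    ``abundance`` is elements x samples in percent; ``sample_sheet`` has
    columns sample/population/day/replicate/role with role in
    {"sorted", "pdna"}. The t-test compares replicate abundances per
    element, on log10(abundance + pseudo) when ``test_on_log`` (default).

    Returns a tidy frame: element_id, population, day, fold_change,
    p_value, call.
    """
    pdna_cols = sample_sheet.loc[sample_sheet["role"] == "pdna", "sample"]
    if pdna_cols.empty:
        raise ValueError("sample sheet contains no pDNA samples")
    pdna = abundance[list(pdna_cols)].to_numpy(dtype=float)

    rows = []
    sorted_sheet = sample_sheet[sample_sheet["role"] == "sorted"]
    for (pop, day), grp in sorted_sheet.groupby(["population", "day"], sort=False):
        cols = list(grp["sample"])
        obs = abundance[cols].to_numpy(dtype=float)
        fc = (obs.mean(axis=1) + pseudo) / (pdna.mean(axis=1) + pseudo)
        if test_on_log:
            ta = np.log10(obs + pseudo)
            tb = np.log10(pdna + pseudo)
        else:
            ta, tb = obs, pdna
        for i, eid in enumerate(abundance.index):
            p = t_test_two_tailed(ta[i], tb[i])
            rows.append(
                {
                    "element_id": eid,
                    "population": pop,
                    "day": day,
                    "fold_change": float(fc[i]),
                    "p_value": p,
                    "call": classify(float(fc[i]), p, fc_up, fc_down, alpha),
                }
            )
    return pd.DataFrame(rows)


def hit_composition(
    hits: Sequence[str], categories: Mapping[str, str]
) -> pd.DataFrame:
    """Category breakdown of a hit list: counts and percent of all hits."""
    unknown = [h for h in hits if h not in categories]
    if unknown:
        raise KeyError(f"hits not in library manifest: {unknown[:5]}")
    if not hits:
        return pd.DataFrame(columns=["count", "percent"])
    counts = pd.Series([categories[h] for h in hits]).value_counts()
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / counts.sum()}
    ).rename_axis("category")


def replicate_correlation(
    abund_a: Sequence[float],
    abund_b: Sequence[float],
    log_transform: bool = True,
    pseudo: float = DEFAULT_PSEUDO,
) -> float:
    """Pearson correlation between two replicate abundance vectors.

    Computed on log10(x + pseudo) by default. Returns NaN (undefined) if
    either vector has zero variance.
    """
    a = np.asarray(abund_a, dtype=float)
    b = np.asarray(abund_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if log_transform:
        a = np.log10(a + pseudo)
        b = np.log10(b + pseudo)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def mean_correlation(correlations: Sequence[float]) -> float:
    """Plain mean of replicate correlations (as screens commonly report)."""
    return float(np.mean(np.asarray(correlations, dtype=float)))


def coverage_and_cumulative(abund: Sequence[float]) -> tuple[float, pd.DataFrame]:
    """Library coverage and cumulative abundance curve.

    Coverage = percent of elements with nonzero abundance. The curve sorts
    abundances ascending and cumulates their fractions to 1.0 (the
    "relatively equal distribution" QC plot for a plasmid pool).
    """
    a = np.asarray(abund, dtype=float)
    coverage = 100.0 * float((a > 0).sum()) / a.size if a.size else 0.0
    order = np.sort(a)
    total = order.sum()
    cum = np.cumsum(order) / total if total > 0 else np.zeros_like(order)
    curve = pd.DataFrame(
        {
            "rank_fraction": np.arange(1, a.size + 1) / a.size,
            "cumulative_fraction": cum,
        }
    )
    return coverage, curve


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2 FC / -log10 p view of an enrichment table (one population)."""
    out = results.copy()
    out["log2_fc"] = np.log2(out["fold_change"])
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out[["element_id", "population", "day", "log2_fc", "neg_log10_p", "call"]]


def heatmap_matrix(
    abundance: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Elements x populations abundance matrix, averaged across replicates."""
    cols = {}
    for (pop, day), grp in sample_sheet.groupby(["population", "day"], sort=False):
        label = pop if pop == "pDNA" else f"{pop}_d{day}"
        cols[label] = abundance[list(grp["sample"])].mean(axis=1)
    return pd.DataFrame(cols)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; the screen's headline calls use raw p)."""
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = stats.false_discovery_control(p[mask], method="bh")
    return q
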