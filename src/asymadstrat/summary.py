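"""Cohort comparison statistics and descriptive summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import SquareTable
from statsmodels.stats.multitest import multipletests

from .cohort import CohortError, CohortTable
from .metrics import percent

log = logging.getLogger(__name__)

DEFAULT_CONTINUOUS = ["age", "education", "moca", "abeta42", "ttau", "ptau"]
DEFAULT_CATEGORICAL = ["sex", "race"]


@dataclass
class CohortSummary:
    """Per-variable group summaries and paired-test results."""

    variables: pd.DataFrame      # variable, summary_a, summary_b, test, p
    proportions: pd.DataFrame    # variable, level, count, total, percent


def _summarize(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def paired_continuous_test(a: np.ndarray, b: np.ndarray) -> tuple[str, float]:
    """Paired t-test if the differences pass Shapiro at alpha=0.05, else
    Wilcoxon signed-rank. Identical samples return p=1 flagged as trivial."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0):
        return "identical", 1.0
    normal = stats.shapiro(d).pvalue >= 0.05 if len(d) >= 3 else False
    if normal:
        return "paired_t", float(stats.ttest_rel(a, b).pvalue)
    return "wilcoxon", float(stats.wilcoxon(a, b,
                                            zero_method="wilcox").pvalue)


def mcnemar_bowker(a: Sequence, b: Sequence) -> tuple[float, float]:
    """Bowker symmetry test on the paired category table (McNemar for 2x2)."""
    levels = sorted(set(a) | set(b))
    k = len(levels)
    idx = {v: i for i, v in enumerate(levels)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    if k < 2 or np.allclose(table, table.T):
        return 0.0, 1.0
    res = SquareTable(table, shift_zeros=False).symmetry(method="bowker")
    return float(res.statistic), float(res.pvalue)


def kruskal_fdr(values: Sequence[float], groups: Sequence[str]
                ) -> dict:
    """Kruskal-Wallis across groups with BH-adjusted pairwise Mann-Whitney
    follow-ups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise CohortError("need >= 2 groups")
    samples = [values[groups == g] for g in uniq]
    h, p = stats.kruskal(*samples)
    pairs, raw = [], []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pairs.append((uniq[i], uniq[j]))
            raw.append(stats.mannwhitneyu(samples[i], samples[j],
                                          alternative="two-sided").pvalue)
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    return {"H": float(h), "p": float(p),
            "pairwise": {pair: float(q) for pair, q in zip(pairs, adj)}}


def cohort_summary(table: CohortTable,
                   pairs: Sequence[tuple[str, str]],
                   continuous: Sequence[str] | None = None,
                   categorical: Sequence[str] | None = None,
                   ) -> CohortSummary:
    """Paired comparison of two matched groups.

    `pairs` holds (subject_id_a, subject_id_b) tuples — e.g. matched
    Control/AsymAD pairs. Continuous variables route through a Shapiro
    normality screen to a paired t-test or Wilcoxon signed-rank; categorical
    variables use the McNemar-Bowker symmetry test. Proportions are reported
    with half-up one-decimal percents.
    """
    if not pairs:
        raise CohortError("paired tests require a non-empty pairing")
    continuous = list(continuous or
                      [c for c in DEFAULT_CONTINUOUS if c in table.data.columns])
    categorical = list(categorical or
                       [c for c in DEFAULT_CATEGORICAL if c in table.data.columns])
    df = table.data.set_index(table.data["subject_id"].astype(str))
    ids_a = [p[0] for p in pairs]
    ids_b = [p[1] for p in pairs]
    missing = [i for i in ids_a + ids_b if i not in df.index]
    if missing:
        raise CohortError(f"pairing references unknown subjects: {missing[:5]}")

    rows = []
    for var in continuous:
        a = df.loc[ids_a, var].to_numpy(dtype=float)
        b = df.loc[ids_b, var].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        test, p = paired_continuous_test(a[ok], b[ok])
        normal = test == "paired_t"
        rows.append((var, _summarize(a[ok], normal), _summarize(b[ok], normal),
                     test, p))
    for var in categorical:
        a = df.loc[ids_a, var].tolist()
        b = df.loc[ids_b, var].tolist()
        _, p = mcnemar_bowker(a, b)
        rows.append((var, "", "", "mcnemar_bowker", p))
    variables = pd.DataFrame(
        rows, columns=["variable", "group_a", "group_b", "test", "p_value"])

    prop_rows = []
    for var in categorical:
        col = table.data[var].dropna()
        total = len(col)
        for level, count in col.value_counts().items():
            prop_rows.append((var, level, int(count), total,
                              percent(int(count), total)))
    proportions = pd.DataFrame(
        prop_rows, columns=["variable", "level", "count", "total", "percent"])
    return CohortSummary(variables, proportions)
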