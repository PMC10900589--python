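"""Group statistics used across the figures, plus dotplot expression summaries.

Nonparametric two-group and k-group comparisons (Mann-Whitney U with a
small-sample exact path, Kruskal-Wallis), 2x2 chi-square with Yates
continuity correction, pairwise proportion tests with Holm step-down
adjustment, Student/Welch t-tests, and the per-cluster percent-expressing /
mean-expression summary behind single-cell dotplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: sample-size cutoff below which the exact Mann-Whitney null is used
EXACT_MWU_CUTOFF = 12


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null distribution when n + m <= 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= EXACT_MWU_CUTOFF) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult("U", float(res.statistic), float(res.pvalue),
                      f"mann-whitney-{method}", (len(x), len(y)),
                      flags={"ties": has_ties})


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi2 on k-1 df.

    All-identical values give H = 0, p = 1, flagged degenerate.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    n = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("H", 0.0, 1.0, "kruskal-wallis", n,
                          flags={"degenerate": True})
    res = sps.kruskal(*groups)
    return TestResult("H", float(res.statistic), float(res.pvalue),
                      "kruskal-wallis", n)


def chi2_yates(table) -> TestResult:
    """Chi-square test of a 2x2 table with Yates continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer) and \
            not np.allclose(table, np.rint(table)):
        raise ValueError("table must hold nonnegative integer counts")
    table = np.rint(table).astype(np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    res = sps.chi2_contingency(table, correction=True)
    return TestResult("chi2", float(res.statistic), float(res.pvalue),
                      "chi2-yates", (int(table[0].sum()), int(table[1].sum())))


def pairwise_prop_test(successes, totals, labels=None,
                       correction: str = "holm") -> pd.DataFrame:
    """All pairwise Yates chi2 proportion tests with Holm-adjusted p-values.

    Returns a tidy frame with one row per unordered pair: group labels,
    proportions, raw and adjusted p.  Holm step-down: sort raw p ascending,
    p~_(i) = max_{j<=i} min(1, (m - j + 1) p_(j)).
    """
    successes = np.asarray(successes, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    if len(successes) != len(totals):
        raise ValueError("successes and totals must align")
    if len(successes) < 2:
        raise ValueError("need at least two groups")
    if ((successes < 0) | (successes > totals)).any():
        raise ValueError("need 0 <= successes <= totals")
    if labels is None:
        labels = [f"group{i}" for i in range(len(successes))]

    rows = []
    for i, j in combinations(range(len(successes)), 2):
        t = np.array([[successes[i], totals[i] - successes[i]],
                      [successes[j], totals[j] - successes[j]]])
        try:
            p = chi2_yates(t).p_value
        except ValueError:  # degenerate margin: identical all-or-nothing groups
            p = 1.0
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "prop_a": successes[i] / totals[i],
                     "prop_b": successes[j] / totals[j],
                     "p_raw": p})
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p_raw"], method=correction)
    out["p_adj"] = p_adj
    return out


def t_test(x, y, variant: str = "student") -> TestResult:
    """Two-sided two-sample t-test, Student (pooled) or Welch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult("t", 0.0, 1.0, f"t-{variant}",
                              (len(x), len(y)), flags={"degenerate": True})
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return TestResult("t", float(res.statistic), float(res.pvalue),
                      f"t-{variant}", (len(x), len(y)))


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression with per-cell cluster / stage labels."""

    values: np.ndarray
    genes: list[str]
    clusters: np.ndarray
    stages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.clusters = np.asarray(self.clusters)
        if self.values.ndim != 2:
            raise ValueError("values must be cells x genes")
        if self.values.shape[1] != len(self.genes):
            raise ValueError("gene list does not match value columns")
        if self.values.shape[0] != len(self.clusters):
            raise ValueError("cluster labels do not match cell rows")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.stages is not None:
            self.stages = np.asarray(self.stages)
            if len(self.stages) != self.values.shape[0]:
                raise ValueError("stage labels do not match cell rows")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.genes)
        df.insert(0, "cluster", self.clusters)
        if self.stages is not None:
            df.insert(1, "stage", self.stages)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        stages = df["stage"].to_numpy() if "stage" in df else None
        genes = [c for c in df.columns if c not in ("cluster", "stage")]
        return cls(values=df[genes].to_numpy(dtype=float), genes=genes,
                   clusters=df["cluster"].to_numpy(), stages=stages)


def dotplot_summary(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    group_by: str = "cluster",
    mean_over: str = "expressing",
) -> pd.DataFrame:
    """Percent-expressing and mean expression per (group, gene).

    percent = 100 * #(value > 0) / n_group.  The mean is taken over
    expressing cells by default (``mean_over="expressing"``) with an
    all-cells option; for a group with no expressing cells the mean is
    reported as 0 with ``mean_undefined`` set.
    """
    genes = list(expr.genes) if genes is None else list(genes)
    unknown = set(genes) - set(expr.genes)
    if unknown:
        raise KeyError(f"genes not in matrix: {sorted(unknown)}")
    if group_by == "cluster":
        keys = expr.clusters
    elif group_by == "stage":
        if expr.stages is None:
            raise ValueError("matrix carries no stage labels")
        keys = expr.stages
    elif group_by == "cluster+stage":
        if expr.stages is None:
            raise ValueError("matrix carries no stage labels")
        keys = np.array([f"{c}|{s}" for c, s in zip(expr.clusters, expr.stages)])
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    if mean_over not in ("expressing", "all"):
        raise ValueError(f"unknown mean_over {mean_over!r}")

    rows = []
    for group in pd.unique(keys):
        sel = keys == group
        n = int(sel.sum())
        for gene in genes:
            col = expr.values[sel, expr.genes.index(gene)]
            expressing = col > 0
            k = int(expressing.sum())
            if mean_over == "expressing":
                mean = float(col[expressing].mean()) if k else 0.0
            else:
                mean = float(col.mean())
            rows.append({"group": group, "gene": gene, "n_cells": n,
                         "percent_expressing": 100.0 * k / n,
                         "mean_expression": mean,
                         "mean_undefined": k == 0 and mean_over == "expressing"})
    return pd.DataFrame(rows)
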