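"""Normality-gated group comparison.

The procedure mirrors common practice in cell-biology image quantitation:
every group is first screened with the D'Agostino-Pearson omnibus
normality test; if all groups look normal the comparison is parametric
(unpaired two-tailed t-test for 2 groups, one-way ANOVA with Tukey HSD
pairwise follow-up for more), otherwise non-parametric (Mann-Whitney U for
2 groups, Kruskal-Wallis with Dunn pairwise follow-up, Holm-adjusted, for
more).  Groups too small for the omnibus test (n < 8) route to the
non-parametric branch with a note.

Significance marks follow the star/hash convention: '*' tiers for
parametric results and '#' tiers for non-parametric ones, at
0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import err

MIN_N_NORMALITY = 8  # the omnibus test is undefined below this
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class GroupData:
    """Named groups of numeric observations for one metric."""

    groups: dict[str, np.ndarray]
    metric_name: str = ""
    units: str = ""

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float).ravel() for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise err("insufficient_n", "need at least two groups")
        for name, v in self.groups.items():
            if len(v) < 3:
                raise err("insufficient_n", f"group {name!r} has n < 3")
            if np.ptp(v) == 0:
                raise err("degenerate_group", f"group {name!r} is constant-valued")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group", value_col: str = "value", **kw):
        return cls({g: sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}, **kw)


@dataclass
class ComparisonResult:
    """Outcome of the gated comparison."""

    test_used: str  # t_test | anova_tukey | mann_whitney | kruskal_wallis
    parametric: bool
    p_overall: float
    p_pairwise: dict[tuple[str, str], float]
    significance_marks: dict[tuple[str, str], str]
    group_summaries: pd.DataFrame  # mean, sem, n per group
    normality_p: dict[str, float | None]
    notes: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = [f"test: {self.test_used}  (overall p = {self.p_overall:.4g})"]
        for (a, b), p in self.p_pairwise.items():
            mark = self.significance_marks[(a, b)] or "ns"
            lines.append(f"  {a} vs {b}: p = {p:.4g}  {mark}")
        lines.append(self.group_summaries.to_string())
        lines.extend(f"note: {n}" for n in self.notes)
        return "\n".join(lines)


def significance_mark(p: float, parametric: bool) -> str:
    """Star (parametric) or hash (non-parametric) tier for a p-value."""
    symbol = "*" if parametric else "#"
    n = sum(p < tier for tier in SIGNIFICANCE_TIERS)
    return symbol * n


def dunn_pairwise(groups: dict[str, np.ndarray], adjust: str = "holm") -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test following Kruskal-Wallis, with a
    tie correction and Holm adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    idx = 0
    mean_ranks, sizes = {}, {}
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[idx: idx + k].mean()
        sizes[g] = k
        idx += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adj = multipletests(raw, method=adjust)[1] if len(raw) > 1 else raw
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def compare_groups(data: GroupData, alpha_normality: float = 0.05) -> ComparisonResult:
    """Run the normality-gated comparison on ``data``.

    The parametric branch is taken iff every group passes the omnibus
    normality test (p > alpha_normality) and every group has n >= 8.
    """
    names = list(data.groups)
    vals = [data.groups[g] for g in names]
    notes: list[str] = []

    normality_p: dict[str, float | None] = {}
    parametric = True
    for g, v in data.groups.items():
        if len(v) < MIN_N_NORMALITY:
            normality_p[g] = None
            parametric = False
            notes.append(f"group {g!r}: n < {MIN_N_NORMALITY}, omnibus normality test "
                         "undefined; routed non-parametric")
        else:
            p = float(sps.normaltest(v).pvalue)
            normality_p[g] = p
            if p <= alpha_normality:
                parametric = False

    if parametric:
        if len(names) == 2:
            test_used = "t_test"
            res = sps.ttest_ind(vals[0], vals[1])
            p_overall = float(res.pvalue)
            p_pairs = {(names[0], names[1]): p_overall}
        else:
            test_used = "anova_tukey"
            p_overall = float(sps.f_oneway(*vals).pvalue)
            flat = np.concatenate(vals)
            labels = np.concatenate([[g] * len(v) for g, v in zip(names, vals)])
            tk = pairwise_tukeyhsd(flat, labels)
            rows = tk._results_table.data[1:]  # (group1, group2, meandiff, ...)
            p_pairs = {(str(r[0]), str(r[1])): float(p) for r, p in zip(rows, tk.pvalues)}
    else:
        if len(names) == 2:
            test_used = "mann_whitney"
            p_overall = float(sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided").pvalue)
            p_pairs = {(names[0], names[1]): p_overall}
        else:
            test_used = "kruskal_wallis"
            p_overall = float(sps.kruskal(*vals).pvalue)
            p_pairs = dunn_pairwise(data.groups)

    marks = {pair: significance_mark(p, parametric) for pair, p in p_pairs.items()}
    summaries = pd.DataFrame(
        {
            "group": names,
            "n": [len(v) for v in vals],
            "mean": [float(np.mean(v)) for v in vals],
            "sem": [float(sps.sem(v)) for v in vals],
        }
    ).set_index("group")
    return ComparisonResult(
        test_used=test_used,
        parametric=parametric,
        p_overall=p_overall,
        p_pairwise=p_pairs,
        significance_marks=marks,
        group_summaries=summaries,
        normality_p=normality_p,
        notes=notes,
    )
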