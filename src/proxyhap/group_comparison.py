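"""Shared group-comparison statistics.

One-way ANOVA, Fisher's (protected) LSD pairwise t tests on the pooled
error variance, Benjamini–Hochberg FDR adjustment, and compact letter
display (CLD) assignment.  Used by both the geography stage (latitude by
allele-combination group) and the phenology stage (R1/R8 by genotype
group).

Two groups share a letter exactly when their FDR-adjusted pairwise
p-value is >= alpha, which is how agronomy figures annotate boxplots:
"categories sharing a letter are not significantly different".
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupedValues:
    """Observations labelled by group, plus the significance level."""

    observations: list[tuple[str, float]]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, groups: dict[str, list[float]], alpha: float = 0.05):
        obs = [(g, float(v)) for g, vals in groups.items() for v in vals]
        return cls(obs, alpha=alpha)

    def by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for g, v in self.observations:
            out.setdefault(g, []).append(v)
        return {g: np.asarray(v, dtype=float) for g, v in out.items()}


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    mse: float
    p: float
    degenerate: bool = False  # within-group SS == 0 with differing means


@dataclass
class LetterAssignment:
    """Per-group summary with CLD letters plus the full pairwise table."""

    groups: pd.DataFrame  # group, n, mean, sd, letters
    pairwise: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj, significant
    alpha: float = 0.05
    degenerate: bool = False

    def letters(self) -> dict[str, str]:
        return dict(zip(self.groups["group"], self.groups["letters"]))


def anova_oneway(data: GroupedValues) -> AnovaResult:
    """One-way fixed-effects ANOVA with the MSE exposed for LSD."""
    groups = data.by_group()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    all_vals = np.concatenate(list(groups.values()))
    n, k = all_vals.size, len(groups)
    df_within = n - k
    if df_within <= 0:
        raise ValueError("zero within-group degrees of freedom")
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = k - 1
    msb = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        # all replicates identical within every group
        f = np.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
        return AnovaResult(f, df_between, df_within, 0.0, p, degenerate=msb > 0)
    f = msb / mse
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, float(mse), p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test.

    Returns (t, Welch–Satterthwaite df, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _cld_insert_absorb(group_order: list[str], sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one letter column containing every group; each
    significant pair splits any column holding both; columns that become
    subsets of another are absorbed.  The result is a faithful encoding:
    two groups share a letter iff their pair is not significant.
    """
    columns: list[set[str]] = [set(group_order)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        absorbed = []
        for i, col in enumerate(new_columns):
            if any(
                col < other or (col == other and i > j)
                for j, other in enumerate(new_columns)
                if j != i
            ):
                continue
            absorbed.append(col)
        columns = absorbed
    # letter columns ordered by the best-ranked group they contain so the
    # top group (by the caller's ordering) reads "a"
    rank = {g: i for i, g in enumerate(group_order)}
    columns.sort(key=lambda col: min(rank[g] for g in col) if col else len(rank))
    labels = string.ascii_lowercase
    out = {g: "" for g in group_order}
    for i, col in enumerate(columns):
        letter = labels[i] if i < len(labels) else f"l{i}"
        for g in col:
            out[g] += letter
    return out


def fisher_lsd_fdr(data: GroupedValues) -> LetterAssignment:
    """Fisher's LSD pairwise tests with BH-FDR correction and CLD letters.

    All pairwise t statistics share the ANOVA pooled MSE and the within
    degrees of freedom; raw p-values are BH-adjusted; letters come from
    the insert-and-absorb CLD over the non-significant adjacency.
    Letters run a, b, c, ... in descending group-mean order.

    Degenerate zero-variance data (MSE = 0): a pair is significant iff
    its means differ, and the result carries ``degenerate=True``.
    """
    aov = anova_oneway(data)
    groups = data.by_group()
    names = sorted(groups, key=lambda g: -groups[g].mean())
    means = {g: groups[g].mean() for g in names}
    ns = {g: groups[g].size for g in names}

    pairs = list(itertools.combinations(names, 2))
    t_stats, p_raw = [], []
    for a, b in pairs:
        if aov.mse == 0.0:
            diff = means[a] - means[b]
            t = np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(aov.mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = (means[a] - means[b]) / se
            p = 2.0 * float(stats.t.sf(abs(t), aov.df_within))
        t_stats.append(float(t))
        p_raw.append(float(p))
    p_adj = bh_adjust(p_raw) if pairs else np.array([])
    significant = p_adj < data.alpha

    sig_pairs = {
        frozenset((a, b))
        for (a, b), sig in zip(pairs, significant)
        if sig
    }
    letters = _cld_insert_absorb(names, sig_pairs)

    group_tbl = pd.DataFrame(
        {
            "group": names,
            "n": [ns[g] for g in names],
            "mean": [means[g] for g in names],
            "sd": [groups[g].std(ddof=1) if ns[g] > 1 else 0.0 for g in names],
            "letters": [letters[g] for g in names],
        }
    )
    pair_tbl = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "t": t_stats,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        }
    )
    return LetterAssignment(
        groups=group_tbl,
        pairwise=pair_tbl,
        alpha=data.alpha,
        degenerate=aov.mse == 0.0,
    )
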