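"""Group-comparison statistics used across the figure panels.

Two procedures: a one-sample t-test (e.g. His-skew vs the even-assembly null
of 0.5) and classical one-way ANOVA followed by Tukey's HSD, summarized as a
compact letter display (CLD): two groups share a letter iff their means are
not significantly different at the chosen cutoff. Letters are built with the
insert-and-absorb algorithm and assigned in order of descending group mean.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["OneSampleTResult", "one_sample_t", "anova_tukey_cld", "compact_letter_display"]


@dataclass(frozen=True)
class OneSampleTResult:
    statistic: float
    p_value: float
    significant: bool
    mu0: float
    n: int


def one_sample_t(values, mu0: float = 0.5, alpha: float = 0.05) -> OneSampleTResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("one-sample t-test undefined for zero-variance data")
    res = sps.ttest_1samp(x, mu0)
    return OneSampleTResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha), mu0=mu0, n=len(x),
    )


def compact_letter_display(
    groups: list[str], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be ordered (letters are assigned in that order, by
    convention descending mean); ``significant_pairs`` holds the pairs whose
    means differ. Guarantees: a significantly different pair never shares a
    letter, and every non-significant pair shares at least one letter.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
            # absorb: drop any column contained in another
            columns = [
                c for i, c in enumerate(columns)
                if c and not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
            ]
    # order letters by first (highest-ranked) member, then assign a, b, c...
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    if len(columns) > len(string.ascii_lowercase):
        raise ValueError("more letter classes than available letters")
    out = {g: "" for g in groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in groups:
            if g in col:
                out[g] += letter
    return out


def anova_tukey_cld(groups: dict[str, np.ndarray] | pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA, Tukey HSD, and compact-letter ranking of group means.

    ``groups`` is either a mapping label -> values or a tidy frame with
    ``group`` and ``value`` columns. Returns a dict with the ANOVA F and p,
    the Tukey pairwise table, and a letter per group (descending mean).
    """
    if isinstance(groups, pd.DataFrame):
        groups = {str(g): d["value"].to_numpy(dtype=float) for g, d in groups.groupby("group")}
    groups = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    f_stat, p_value = sps.f_oneway(*groups.values())

    labels = np.concatenate([[name] * len(v) for name, v in groups.items()])
    values = np.concatenate(list(groups.values()))
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    significant = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in pairs.iterrows() if bool(r["reject"])
    }
    order = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    letters = compact_letter_display(order, significant)
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "tukey": pairs,
        "significant_pairs": significant,
        "letters": letters,
        "group_means": {g: float(np.mean(v)) for g, v in groups.items()},
        "alpha": alpha,
    }
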