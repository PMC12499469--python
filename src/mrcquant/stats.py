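"""Group-comparison statistics used by the reporting pipeline.

Two groups are compared with a t-test (Welch by default — the
unequal-variance form is the safer choice when variances are unknown;
classical Student available by flag).  Three or more groups use one-way
ANOVA followed by Tukey's HSD post-hoc test with a compact-letter display:
groups sharing a letter are not significantly different at the chosen α.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupTest", "group_compare", "significance_stars"]


@dataclass
class GroupTest:
    test: str  # welch_t | student_t | anova_tukey
    groups: list[str]
    statistic: float
    p_value: float
    stars: str
    letters: dict[str, str] | None = None  # compact letter display (ANOVA)
    pairwise: list[dict] | None = None  # Tukey pairwise results


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _compact_letters(names: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display: groups share a letter iff
    they are not significantly different."""
    # each letter is a set of mutually non-different groups
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all(frozenset((name, other)) in nonsig_pairs for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb redundant sets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letter_sets):
        for name in names:
            if name in s:
                out[name] += letter
    return out


def group_compare(
    values_by_group: dict[str, np.ndarray],
    method: str = "auto",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupTest:
    """Compare 2 groups by t-test or >2 by ANOVA + Tukey HSD.

    ``method``: "auto" picks by group count; "t" or "anova" force a choice.
    ``equal_var=False`` gives the Welch t-test.  Each group needs n ≥ 2.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"group {name!r} has n < 2")

    if method == "auto":
        method = "t" if len(groups) == 2 else "anova"

    if method == "t":
        if len(groups) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return GroupTest(
            test="student_t" if equal_var else "welch_t",
            groups=names,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            stars=significance_stars(float(res.pvalue)),
        )

    f_stat, p = sps.f_oneway(*groups)
    data = np.concatenate(groups)
    labels = np.concatenate([[name] * g.size for name, g in zip(names, groups)])
    tukey = pairwise_tukeyhsd(data, labels, alpha=alpha)
    pairwise = []
    nonsig = {frozenset((n, n)) for n in names}
    for row in tukey.summary().data[1:]:
        g1, g2, meandiff, p_adj, lower, upper, reject = row
        pairwise.append({
            "group1": str(g1), "group2": str(g2),
            "mean_diff": float(meandiff), "p_adj": float(p_adj),
            "reject": bool(reject),
        })
        if not reject:
            nonsig.add(frozenset((str(g1), str(g2))))
    return GroupTest(
        test="anova_tukey",
        groups=names,
        statistic=float(f_stat),
        p_value=float(p),
        stars=significance_stars(float(p)),
        letters=_compact_letters(names, nonsig),
        pairwise=pairwise,
    )
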