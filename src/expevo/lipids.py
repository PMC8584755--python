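"""Longitudinal lipid-panel statistics: percent differences, fold changes,
Student's t and one-way ANOVA with Tukey's HSD.

Conventions (stated because they decide signs and magnitudes):

* percent difference = (mean_ref - mean_alt) / mean_ref * 100, with the
  reference group defaulting to WT, so "42.51%" reads "the alternative
  group is 42.51% lower than the reference";
* fold change = mean at the post timepoint / mean at the reference
  timepoint within one group (e.g. atherogenic-diet start at 6 months);
* the t-test is the pooled-variance two-sided Student's t with
  df = n_a + n_b - 2 (not Welch).

Both percent difference and fold change are invariant to rescaling the
measurement unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError


def _cell(panel: pd.DataFrame, analyte: str, age: int, diet: str,
          genotype: str) -> np.ndarray:
    sub = panel[
        (panel["analyte"] == analyte)
        & (panel["age_months"] == age)
        & (panel["diet"] == diet)
        & (panel["genotype"] == genotype)
    ]
    if sub.empty:
        raise ValidationError(
            f"no rows for genotype={genotype!r}, analyte={analyte!r}, "
            f"age={age}, diet={diet!r}"
        )
    return sub["value"].to_numpy(dtype=float)


@dataclass
class GroupComparison:
    analyte: str
    age_months: int
    diet: str
    ref_group: str
    alt_group: str
    mean_ref: float
    mean_alt: float
    percent_difference: float
    t_statistic: float
    p_value: float
    df: int
    n_ref: int
    n_alt: int
    zero_variance: bool = False


@dataclass
class FoldChange:
    analyte: str
    group: str
    diet: str
    ref_age_months: int
    post_age_months: int
    mean_ref: float
    mean_post: float
    fold: float


def student_t(a, b) -> tuple[float, float, int, bool]:
    """Pooled-variance two-sided Student's t.

    Returns (t, p, df, zero_variance_flag).  With zero pooled variance and
    unequal means the difference is infinitely significant relative to the
    model; this is reported as (inf-signed t, p=0) with the flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Student's t needs n >= 2 per group")
    df = int(a.size + b.size - 2)
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, df, False
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0, df, True
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue), df, False


def group_percent_difference(panel: pd.DataFrame, analyte: str, age: int,
                             diet: str = "standard", ref_group: str = "WT",
                             alt_group: str = "ASGR1-/-") -> GroupComparison:
    """Percent difference of group means, with an accompanying t-test.

    The t statistic and p-value are NaN when either group has n = 1
    (the means and percent difference are still defined).
    """
    ref = _cell(panel, analyte, age, diet, ref_group)
    alt = _cell(panel, analyte, age, diet, alt_group)
    mean_ref, mean_alt = float(ref.mean()), float(alt.mean())
    if mean_ref == 0:
        raise ValidationError("reference mean is zero; percent difference undefined")
    pct = (mean_ref - mean_alt) / mean_ref * 100.0
    if ref.size >= 2 and alt.size >= 2:
        t, p, df, zero_var = student_t(ref, alt)
    else:
        t, p, df, zero_var = float("nan"), float("nan"), 0, False
    return GroupComparison(analyte=analyte, age_months=age, diet=diet,
                           ref_group=ref_group, alt_group=alt_group,
                           mean_ref=mean_ref, mean_alt=mean_alt,
                           percent_difference=pct, t_statistic=t, p_value=p,
                           df=df, n_ref=int(ref.size), n_alt=int(alt.size),
                           zero_variance=zero_var)


def fold_change(panel: pd.DataFrame, analyte: str, group: str, ref_age: int,
                post_age: int, diet: str = "HFHC") -> FoldChange:
    """Ratio of group means between two timepoints within one group."""
    ref = _cell(panel, analyte, ref_age, diet, group)
    post = _cell(panel, analyte, post_age, diet, group)
    mean_ref, mean_post = float(ref.mean()), float(post.mean())
    if mean_ref <= 0:
        raise ValidationError("reference-timepoint mean must be positive")
    return FoldChange(analyte=analyte, group=group, diet=diet,
                      ref_age_months=ref_age, post_age_months=post_age,
                      mean_ref=mean_ref, mean_post=mean_post,
                      fold=mean_post / mean_ref)


@dataclass
class AnovaTukey:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj


def anova_tukey(groups: dict[str, np.ndarray]) -> AnovaTukey:
    """One-way ANOVA followed by Tukey's HSD over named groups.

    Requires at least three groups with n >= 2 each (use
    :func:`student_t` for two groups).  Tukey adjusted p-values come from
    the studentized-range distribution (statsmodels).
    """
    if len(groups) < 3:
        raise ValidationError("ANOVA/Tukey needs >= 3 groups; use student_t for 2")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValidationError("every group needs n >= 2")

    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
    elif ss_within == 0:
        f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))

    labels = np.concatenate([[k] * a.size for k, a in arrays.items()])
    if ss_within == 0:
        # studentized range degenerate; p_adj is 1 for equal means, else 0
        pairs = []
        names = list(arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = arrays[names[j]].mean() - arrays[names[i]].mean()
                pairs.append((names[i], names[j], diff, 1.0 if diff == 0 else 0.0))
        tukey = pd.DataFrame(pairs, columns=["group_a", "group_b", "mean_diff", "p_adj"])
    else:
        res = pairwise_tukeyhsd(all_values, labels)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tukey = pd.DataFrame(
            {
                "group_a": frame["group1"],
                "group_b": frame["group2"],
                "mean_diff": res.meandiffs,
                "p_adj": res.pvalues,
            }
        )
    return AnovaTukey(f_statistic=float(f), p_value=float(p), df_between=df_b,
                      df_within=df_w, tukey=tukey)


def anova_tukey_panel(panel: pd.DataFrame, analyte: str, age: int,
                      diet: str = "standard",
                      genotypes: tuple[str, ...] = ("WT", "ASGR1+/-", "ASGR1-/-")
                      ) -> AnovaTukey:
    """ANOVA + Tukey across genotype groups of one panel cell."""
    groups = {g: _cell(panel, analyte, age, diet, g) for g in genotypes}
    return anova_tukey(groups)
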