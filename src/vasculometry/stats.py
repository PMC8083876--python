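"""One- and two-way ANOVA with Fisher's LSD post hoc comparisons.

Fixed-effects ANOVA on tidy tables, sized for the small designs typical of
anatomical studies (cultivar x section position, n = 3-4 replicates per
cell, often unbalanced).  One-way designs use the classical decomposition;
two-way designs use partial (Type-III) sums of squares with sum-to-zero
contrasts, switchable to Type II.  Model fitting is delegated to
statsmodels OLS; this module owns the design handling, the LSD pairwise
machinery and the compact letter display.

Fisher's LSD is the unadjusted pairwise t-test on the pooled error mean
square, gated (by default) on a significant omnibus effect -- the
"protected LSD" convention.  Letters are assigned by a deterministic
insert-and-absorb pass so snapshot tests are stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class AnovaResult:
    """Effect table plus the design metadata needed for post hoc tests."""

    effects: pd.DataFrame  # index: effect name; columns: sum_sq, df, F, p
    mse: float
    df_error: float
    response: str
    factors: list[str]
    data: pd.DataFrame = field(repr=False, default=None)

    def p_value(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])


@dataclass
class LsdResult:
    """Pairwise comparisons and the compact letter display."""

    pairwise: pd.DataFrame  # group_1, group_2, diff, t, p, significant
    letters: dict[str, str]
    alpha: float
    grouping: str
    means: pd.DataFrame  # group, mean, n


def _q(name: str) -> str:
    return f"Q('{name}')"


def anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interaction: bool = False,
    ss_type: Literal[2, 3] = 3,
) -> AnovaResult:
    """Fixed-effects ANOVA on a tidy table.

    Parameters
    ----------
    table : DataFrame with the response and factor columns.
    response : response column name.
    factors : one or two factor column names.
    interaction : include the two-way interaction (two factors only).
    ss_type : sums-of-squares family for unbalanced two-way designs;
        Type III (sum-to-zero contrasts) by default, Type II available.
        One-way designs are unaffected by the choice.
    """
    factors = list(factors)
    if len(factors) not in (1, 2):
        raise ValueError("supply one or two factors")
    if interaction and len(factors) != 2:
        raise ValueError("interaction requires two factors")
    df = table.dropna(subset=[response, *factors]).copy()
    for f in factors:
        df[f] = df[f].astype(str)
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")

    terms = [f"C({_q(f)}, Sum)" for f in factors]
    if interaction:
        terms.append(" : ".join(terms))
    formula = f"{_q(response)} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 2:
        raise ValueError("need at least 2 error degrees of freedom")

    try:
        aov = anova_lm(model, typ=ss_type)
    except Exception as exc:  # singular design
        raise ValueError(f"singular design: {exc}") from exc
    aov = aov.rename(columns={"PR(>F)": "p", "F": "F"})
    if "Intercept" in aov.index:
        aov = aov.drop(index="Intercept")

    # map statsmodels term names back to user factor names
    rename = {}
    for row in aov.index:
        label = row
        for f in factors:
            label = label.replace(f"C({_q(f)}, Sum)", f)
        rename[row] = label.replace(":", " x ") if ":" in label else label
    aov = aov.rename(index=rename)
    resid_row = aov.loc["Residual"]
    effects = aov.drop(index="Residual")[["sum_sq", "df", "F", "p"]]
    return AnovaResult(
        effects=effects,
        mse=float(resid_row["sum_sq"] / resid_row["df"]),
        df_error=float(resid_row["df"]),
        response=response,
        factors=factors,
        data=df,
    )


def _compact_letters(
    groups: Sequence[str], different: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each letter names a clique of mutually non-different groups; two groups
    share a letter iff they are not significantly different.  Groups are
    processed in sorted order and redundant letter sets absorbed, so the
    output is deterministic.
    """
    groups = sorted(groups)
    sets: list[set[str]] = [set(groups)]
    for g1, g2 in sorted(different):
        new_sets: list[set[str]] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=lambda s: (-len(s), sorted(s))):
            if not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s):
            letters[g] += letter
    return letters


def fisher_lsd(
    result: AnovaResult,
    grouping: str,
    alpha: float = 0.05,
    require_significant: bool = True,
) -> LsdResult:
    """Fisher's (protected) LSD pairwise comparisons on one factor.

    Pairwise t = (mean_i - mean_j) / sqrt(MSE (1/n_i + 1/n_j)) on the ANOVA
    error df, with no multiplicity adjustment.  By default refuses to run
    when the omnibus effect for ``grouping`` is not significant at alpha.
    """
    if grouping not in result.factors:
        raise ValueError(f"{grouping!r} is not a factor of this ANOVA")
    omnibus_p = result.p_value(grouping)
    if require_significant and omnibus_p > alpha:
        raise ValueError(
            f"omnibus effect for {grouping!r} not significant "
            f"(p={omnibus_p:.4g} > alpha={alpha}); refusing unprotected LSD "
            "(pass require_significant=False to override)"
        )
    df = result.data
    stats = (
        df.groupby(grouping)[result.response]
        .agg(["mean", "count"])
        .rename(columns={"count": "n"})
    )
    rows = []
    different: set[tuple[str, str]] = set()
    for g1, g2 in itertools.combinations(sorted(stats.index), 2):
        m1, n1 = stats.loc[g1, "mean"], stats.loc[g1, "n"]
        m2, n2 = stats.loc[g2, "mean"], stats.loc[g2, "n"]
        se = np.sqrt(result.mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
        p = 2.0 * sps.t.sf(abs(t), result.df_error)
        sig = p < alpha
        if sig:
            different.add((g1, g2))
        rows.append(
            {"group_1": g1, "group_2": g2, "diff": m1 - m2, "t": t, "p": p,
             "significant": sig}
        )
    letters = _compact_letters(list(stats.index), different)
    return LsdResult(
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        grouping=grouping,
        means=stats.reset_index(),
    )


def tukey_hsd(
    result: AnovaResult, grouping: str, alpha: float = 0.05
) -> LsdResult:
    """Tukey HSD with the same interface as :func:`fisher_lsd`.

    Uses the studentized-range distribution on the ANOVA pooled MSE
    (Tukey-Kramer for unequal n).
    """
    if grouping not in result.factors:
        raise ValueError(f"{grouping!r} is not a factor of this ANOVA")
    df = result.data
    stats = (
        df.groupby(grouping)[result.response]
        .agg(["mean", "count"])
        .rename(columns={"count": "n"})
    )
    k = len(stats)
    rows = []
    different: set[tuple[str, str]] = set()
    for g1, g2 in itertools.combinations(sorted(stats.index), 2):
        m1, n1 = stats.loc[g1, "mean"], stats.loc[g1, "n"]
        m2, n2 = stats.loc[g2, "mean"], stats.loc[g2, "n"]
        se = np.sqrt(result.mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        q = abs(m1 - m2) / se
        p = float(sps.studentized_range.sf(q, k, result.df_error))
        sig = p < alpha
        if sig:
            different.add((g1, g2))
        rows.append(
            {"group_1": g1, "group_2": g2, "diff": m1 - m2, "t": q, "p": p,
             "significant": sig}
        )
    letters = _compact_letters(list(stats.index), different)
    return LsdResult(
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        grouping=grouping,
        means=stats.reset_index(),
    )
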