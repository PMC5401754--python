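"""Repeated-measures inference for the cohort feature table.

The design is fully within-subject (every animal contributes every
eye x session x intensity cell), so the classical univariate
repeated-measures decomposition applies: each within-subject effect is
tested against its own subject-by-effect interaction stratum. Follow-up
paired t-tests are judged against a Bonferroni-corrected threshold
(alpha divided by the number of comparisons). Summaries report mean +/- SD
(n-1 denominator).

No sphericity correction is applied by default; a Greenhouse-Geisser
epsilon would only matter for factors with three or more levels and the
headline contrasts here are two-level.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, InsufficientDataError

DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RMDesign:
    """A fully within-subject design: subject column, within factors, response."""

    subject: str = "animal"
    within: tuple[str, ...] = ("eye", "session")
    response: str = "value"

    def __post_init__(self) -> None:
        if not self.within:
            raise DesignError("at least one within-subject factor is required")


def _check_balanced(df: pd.DataFrame, design: RMDesign) -> None:
    cols = [design.subject, *design.within]
    counts = df.groupby(cols, observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise DesignError(f"design not balanced: cells with != 1 observation: {bad}")
    # completeness: every subject x cell combination present
    expected = np.prod([df[c].nunique() for c in cols])
    if len(counts) != expected:
        levels = {c: set(df[c].unique()) for c in cols}
        missing = [
            combo
            for combo in itertools.product(*levels.values())
            if combo not in set(counts.index)
        ][:5]
        raise DesignError(f"design incomplete: missing cells such as {missing}")


def rm_anova(df: pd.DataFrame, design: RMDesign) -> pd.DataFrame:
    """Univariate repeated-measures ANOVA on a balanced within-subject table.

    Returns one row per within-subject effect (main effects and all
    interactions) with SS, df, MS, F, p and the error stratum (the
    subject-by-effect interaction) it was tested against. Zero-variance
    error strata are flagged degenerate (F undefined) rather than dropped.
    """
    _check_balanced(df, design)
    subjects = df[design.subject].unique()
    if subjects.size < 2:
        raise DesignError("repeated-measures ANOVA needs >= 2 subjects")
    y = df[design.response].astype(float)
    if y.isna().any():
        raise DesignError("response contains missing values")

    all_factors = (design.subject, *design.within)
    levels = {c: df[c].nunique() for c in all_factors}
    N = len(df)
    grand_total = float(y.sum())

    # U-terms: for a subset B of factors, sum over B-cells of total^2 / cell size
    u_cache: dict[frozenset, float] = {frozenset(): grand_total**2 / N}

    def U(subset: frozenset) -> float:
        if subset not in u_cache:
            cols = [c for c in all_factors if c in subset]
            totals = df.groupby(cols, observed=True)[design.response].sum()
            per_cell = N / np.prod([levels[c] for c in cols])
            u_cache[subset] = float(np.sum(np.asarray(totals, dtype=float) ** 2) / per_cell)
        return u_cache[subset]

    def ss(effect: frozenset) -> float:
        total = 0.0
        members = sorted(effect)
        for r in range(len(members) + 1):
            for sub in itertools.combinations(members, r):
                total += (-1) ** (len(members) - r) * U(frozenset(sub))
        return max(total, 0.0)  # guard tiny negative rounding

    n_subj = levels[design.subject]
    rows = []
    for r in range(1, len(design.within) + 1):
        for combo in itertools.combinations(design.within, r):
            effect = frozenset(combo)
            df_eff = int(np.prod([levels[c] - 1 for c in combo]))
            ss_eff = ss(effect)
            err = effect | {design.subject}
            ss_err = ss(err)
            df_err = (n_subj - 1) * df_eff
            ms_eff = ss_eff / df_eff
            degenerate = ss_err <= DEGENERATE_TOL * max(ss_eff, 1.0)
            if degenerate:
                F = math.nan
                p = math.nan
            else:
                ms_err = ss_err / df_err
                F = ms_eff / ms_err
                p = float(sps.f.sf(F, df_eff, df_err))
            rows.append(
                {
                    "effect": " x ".join(combo),
                    "SS": ss_eff,
                    "df": df_eff,
                    "MS": ms_eff,
                    "F": F,
                    "p": p,
                    "error_SS": ss_err,
                    "error_df": df_err,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def bonferroni_alpha(alpha: float, k: int) -> float:
    """The Bonferroni-corrected per-comparison level alpha / k."""
    if k < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / k


def render_alpha(alpha: float, k: int) -> float:
    """Corrected threshold truncated to three decimals for reporting
    (0.05 over three comparisons renders as 0.016)."""
    return math.floor(bonferroni_alpha(alpha, k) * 1000.0) / 1000.0


def paired_followups(
    df: pd.DataFrame,
    contrasts: list[tuple[str, dict, dict]],
    subject: str = "animal",
    response: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided paired t-tests for a set of within-subject contrasts.

    Each contrast is (label, cell_a, cell_b) where the cells are
    column->level mappings selecting one condition per subject.
    Significance is judged against ``bonferroni_alpha(alpha, len(contrasts))``.
    Zero-variance differences are flagged degenerate, not significant.
    """
    if not contrasts:
        raise InsufficientDataError("no contrasts supplied")
    k = len(contrasts)
    alpha_adj = bonferroni_alpha(alpha, k)
    rows = []
    for label, cell_a, cell_b in contrasts:
        a = _cell_values(df, cell_a, subject, response)
        b = _cell_values(df, cell_b, subject, response)
        common = a.index.intersection(b.index)
        if common.size < 2:
            raise InsufficientDataError(f"contrast {label!r}: fewer than 2 pairs")
        diff = (a.loc[common] - b.loc[common]).to_numpy(dtype=float)
        degenerate = float(np.std(diff, ddof=1)) == 0.0
        if degenerate:
            # all-zero differences are a genuine null (t = 0); a constant
            # non-zero difference leaves t undefined
            t = 0.0 if float(np.mean(diff)) == 0.0 else math.nan
            p = 1.0 if t == 0.0 else math.nan
            sig = False
        else:
            res = sps.ttest_rel(a.loc[common], b.loc[common])
            t, p = float(res.statistic), float(res.pvalue)
            sig = p < alpha_adj
        rows.append(
            {
                "comparison": label,
                "n_pairs": int(common.size),
                "t": t,
                "df": int(common.size - 1),
                "p": p,
                "alpha_adj": alpha_adj,
                "significant": sig,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _cell_values(df: pd.DataFrame, cell: dict, subject: str,
                 response: str) -> pd.Series:
    sel = pd.Series(True, index=df.index)
    for col, level in cell.items():
        sel &= df[col] == level
    sub = df[sel]
    dupes = sub[subject].duplicated()
    if dupes.any():
        raise DesignError(f"cell {cell} has multiple rows per subject")
    return sub.set_index(subject)[response]


def summarize(df: pd.DataFrame, by: list[str],
              response: str = "value") -> pd.DataFrame:
    """Group means with sample SD (n-1 denominator; SD 0 and a flag at n=1)."""
    if df.empty:
        warnings.warn("empty table: nothing to summarize", stacklevel=2)
        return pd.DataFrame(columns=[*by, "mean", "sd", "n", "single"])
    g = df.groupby(by, observed=True)[response]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["single"] = out["n"] == 1
    out.loc[out["single"], "sd"] = 0.0
    return out
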