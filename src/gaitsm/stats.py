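"""Cohort statistics: Spearman correlation tables with BH adjustment and
subgroup difference testing (Shapiro-Wilk normality, Welch one-way ANOVA
omnibus, pairwise Welch's t-tests).

Spearman p-values use the t approximation for n > 10 and an exact/near-exact
permutation distribution for n <= 10.  The Benjamini-Hochberg step-up
adjustment is applied per reported family of comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "spearman",
    "bh_adjust",
    "correlation_table",
    "welch_anova",
    "group_difference_tests",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family per call)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    p_adj: float
    n: int
    significant: bool


@dataclass(frozen=True)
class GroupTestResult:
    groups: tuple[str, str]
    t: float
    df: float
    p: float
    significant: bool


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with tie-corrected ranks and a two-sided p-value.

    Exact permutation p for n <= ``exact_max_n`` (all n! pairings for n <= 8,
    otherwise 100,000 seeded Monte-Carlo permutations); t approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant column: Spearman rho undefined", RuntimeWarning)
        return np.nan, np.nan
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        p = float(_st.spearmanr(x, y).pvalue)
        return r, p
    # permutation distribution of rho over pairings of the observed ranks
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(np.dot(rxc, rxc) * np.dot(ryc, ryc)))
    obs = float(np.dot(rxc, ryc))
    if n <= 8:
        perms = np.array(list(permutations(range(n))))
    else:
        rng = np.random.default_rng(0)
        perms = np.array([rng.permutation(n) for _ in range(100_000)])
    stats = ryc[perms] @ rxc
    p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
    return r, p


def correlation_table(
    scores: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    q: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations for the listed measure pairs with BH adjustment.

    The listed pairs form one BH family; adjusted p-values use the step-up
    procedure at false-discovery rate ``q``.  Pairs whose rho is undefined
    (constant column) are reported with NaN and excluded from the family.
    """
    if pairs is None:
        pairs = list(combinations(scores.columns, 2))
    rows = []
    for a, b in pairs:
        sub = scores[[a, b]].dropna()
        if len(sub) < 4:
            raise ValueError(f"pair ({a}, {b}) has fewer than 4 complete observations")
        r, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
        rows.append({"measure_a": a, "measure_b": b, "r": r, "p": p, "n": len(sub)})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = bh_adjust(df.loc[ok, "p"])
    df["significant"] = df["p_adj"] < alpha
    return df


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's one-way ANOVA: (F, df1, df2, p) for k independent samples."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    w = ns / vars_
    grand = np.sum(w * means) / np.sum(w)
    F = np.sum(w * (means - grand) ** 2) / (k - 1)
    corr = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    F /= 1 + 2 * (k - 2) / (k**2 - 1) * corr
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * corr)
    p = float(_st.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), p


def group_difference_tests(
    scores: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    groups: tuple[str, ...] = ("TT", "TF", "VN", "LS"),
    alpha: float = 0.05,
) -> dict:
    """Normality, omnibus, and all pairwise Welch tests for one measure.

    Returns a dict with per-group Shapiro-Wilk p-values, the Welch one-way
    ANOVA omnibus (F, dfs, p) and a list of :class:`GroupTestResult` for all
    group pairs.  Groups with fewer than 2 members are excluded with a
    warning.
    """
    data: dict[str, np.ndarray] = {}
    for g in groups:
        vals = scores.loc[scores[group_col] == g, measure].dropna().to_numpy()
        if len(vals) < 2:
            warnings.warn(f"group '{g}' has fewer than 2 members; excluded", RuntimeWarning)
            continue
        data[g] = vals
    if len(data) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    shapiro_p = {
        g: (float(_st.shapiro(v).pvalue) if len(v) >= 3 else np.nan)
        for g, v in data.items()
    }
    F, df1, df2, omnibus_p = welch_anova(list(data.values()))
    pairwise = []
    for a, b in combinations(data, 2):
        res = _st.ttest_ind(data[a], data[b], equal_var=False)
        pairwise.append(
            GroupTestResult(
                groups=(a, b),
                t=float(res.statistic),
                df=float(res.df),
                p=float(res.pvalue),
                significant=bool(res.pvalue < alpha),
            )
        )
    return {
        "measure": measure,
        "shapiro_p": shapiro_p,
        "omnibus": {"F": F, "df1": df1, "df2": df2, "p": omnibus_p},
        "pairwise": pairwise,
    }
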