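"""Nonparametric statistics and the reliability meta-analysis.

Two-group comparisons use the Mann-Whitney U test; with three or more
groups a Kruskal-Wallis omnibus precedes all pairwise tests, with
Bonferroni adjustment.  Effect sizes use the rank-based eta-squared

    Z = (U - n1 n2 / 2) / sqrt(n1 n2 (n1 + n2 + 1) / 12),
    eta2 = Z^2 / (n1 + n2),

with critical eta2 values from the chi-square distribution (df = 1).
Note the Z used for eta2 deliberately carries no tie correction (it
follows the printed effect-size recipe), while the reported p-value uses
the standard exact/tie-corrected machinery; both are exposed so any
discrepancy stays visible.

The reliability layer compares repeated analyses of the same data by
different models/ensembles ("analysts"): the spread of eta2 per effect
within a strategy, the spread of centered eta2 per model, and each
model's deviations from the congruent majority vote.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectRecord",
    "ReliabilityReport",
    "grubbs_flag",
    "mann_whitney",
    "z_from_u",
    "eta_squared",
    "critical_eta2",
    "significance_bin",
    "multi_group_compare",
    "reliability_report",
]

_BIN_EDGES = (0.05, 0.01, 0.001)


@dataclass
class EffectRecord:
    """One pairwise group comparison."""

    comparison: str  # "group1 ~ group2"
    group1: str
    group2: str
    n1: int
    n2: int
    U: float  # Mann-Whitney U for group1
    Z: float
    p: float
    p_adjusted: float
    eta2: float
    bin: str  # significance bin on adjusted p: n.s. / * / ** / ***
    direction: int  # sign of (mean group1 - mean group2)


@dataclass
class ReliabilityReport:
    variation_per_effect: pd.DataFrame  # strategy, comparison, std_eta2
    variation_per_model: pd.DataFrame  # strategy, model, std_centered_eta2, deviations
    majority_votes: pd.DataFrame  # comparison, significant, direction, decided


def grubbs_flag(values: list[float] | np.ndarray, alpha: float = 0.05) -> list[int]:
    """Two-sided single-outlier Grubbs test, applied iteratively.

    Returns the indices (into the original list) whose values exceed the
    critical bound.  Values are flagged only — exclusion remains an expert
    decision downstream.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test needs n >= 3")
    flagged: list[int] = []
    active = list(range(len(x)))
    while len(active) >= 3:
        sub = x[active]
        s = sub.std(ddof=1)
        if s == 0:
            break
        n = len(sub)
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        G = dev[i] / s
        tcrit = sps.t.ppf(1 - alpha / (2 * n), n - 2)
        Gcrit = (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))
        if G > Gcrit:
            flagged.append(active.pop(i))
        else:
            break
    return sorted(flagged)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (reported for group ``a``, from midranks) and two-sided p.

    Small tie-free samples use the exact null distribution; otherwise the
    tie-corrected normal approximation.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def z_from_u(U: float, n1: int, n2: int) -> float:
    """Z statistic from U under the (uncorrected) normal null."""
    if n1 < 1 or n2 < 1:
        raise ValueError("n1, n2 must be >= 1")
    return (U - n1 * n2 / 2.0) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)


def eta_squared(Z: float, n1: int, n2: int) -> float:
    """Rank-based effect size eta2 = Z^2 / (n1 + n2)."""
    return Z**2 / (n1 + n2)


def critical_eta2(
    alphas: list[float] | tuple[float, ...],
    n1: int,
    n2: int,
    m_comparisons: int = 1,
) -> list[float]:
    """Critical eta2 marking the significance-level borders.

    eta2_crit(alpha) = chi2 quantile(1 - alpha/m, df=1) / (n1 + n2); the
    Bonferroni divisor m is applied when requested.
    """
    out = []
    for a in alphas:
        if not 0.0 < a <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        out.append(float(sps.chi2.ppf(1 - a / m_comparisons, df=1)) / (n1 + n2))
    return out


def significance_bin(p_adjusted: float) -> str:
    if p_adjusted <= 0.001:
        return "***"
    if p_adjusted <= 0.01:
        return "**"
    if p_adjusted <= 0.05:
        return "*"
    return "n.s."


class EffectList(list):
    """List of EffectRecord with the omnibus test attached (when >= 3 groups)."""

    kruskal_h: float | None = None
    kruskal_p: float | None = None


def multi_group_compare(
    groups: dict[str, list[float]] | list[tuple[str, list[float]]],
    m_comparisons: int | None = None,
) -> EffectList:
    """All pairwise Mann-Whitney comparisons with Bonferroni adjustment.

    With three or more groups a Kruskal-Wallis omnibus is computed first
    (attached to the returned list).  ``p_adjusted = min(1, m * p)`` with m
    defaulting to the number of pairwise comparisons; eta2 comes from the
    uncorrected Z-from-U formula.
    """
    items = list(groups.items()) if isinstance(groups, dict) else list(groups)
    if any(len(v) == 0 for _, v in items):
        raise ValueError("every group must be non-empty")
    pairs = list(itertools.combinations(range(len(items)), 2))
    m = m_comparisons if m_comparisons is not None else max(1, len(pairs))
    records = EffectList()
    if len(items) >= 3:
        h, p_kw = sps.kruskal(*[v for _, v in items])
        records.kruskal_h, records.kruskal_p = float(h), float(p_kw)
    for i, j in pairs:
        la, va = items[i]
        lb, vb = items[j]
        U, p = mann_whitney(va, vb)
        n1, n2 = len(va), len(vb)
        Z = z_from_u(U, n1, n2)
        p_adj = min(1.0, m * p)
        records.append(
            EffectRecord(
                comparison=f"{la} ~ {lb}",
                group1=la,
                group2=lb,
                n1=n1,
                n2=n2,
                U=U,
                Z=Z,
                p=p,
                p_adjusted=p_adj,
                eta2=eta_squared(Z, n1, n2),
                bin=significance_bin(p_adj),
                direction=int(np.sign(np.mean(va) - np.mean(vb))),
            )
        )
    return records


def _outcome(row: pd.Series, alpha: float) -> tuple[bool, int]:
    sig = bool(row["p_adjusted"] <= alpha)
    return (sig, int(row["direction"]) if sig else 0)


def reliability_report(effect_table: pd.DataFrame, alpha: float = 0.05) -> ReliabilityReport:
    """Reliability measures over repeated analyses of the same comparisons.

    ``effect_table`` needs columns strategy, model, comparison, eta2,
    p_adjusted, direction — one row per (strategy, model, comparison).

    * variation per effect: sample std of eta2 across a strategy's models,
      per comparison;
    * majority vote per comparison: the outcome (significant at adjusted
      p <= alpha, with direction) reported by the majority of models across
      all strategies; ties are undecided and excluded from deviation counts;
    * variation per model: std of centered eta2 (eta2 minus the strategy's
      across-model mean for that comparison) across comparisons, plus the
      model's count of deviations from the majority votes.
    """
    req = {"strategy", "model", "comparison", "eta2", "p_adjusted", "direction"}
    if not req.issubset(effect_table.columns):
        raise ValueError(f"effect_table must have columns {sorted(req)}")
    df = effect_table.copy()
    counts = df.groupby(["strategy", "comparison"])["model"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 models per strategy and comparison")

    vpe = (
        df.groupby(["strategy", "comparison"])["eta2"]
        .std(ddof=1)
        .rename("std_eta2")
        .reset_index()
    )

    df["outcome"] = df.apply(_outcome, axis=1, args=(alpha,))
    votes = []
    for comp, sub in df.groupby("comparison"):
        tally = sub["outcome"].value_counts()
        top = tally.iloc[0]
        winners = tally[tally == top]
        if len(winners) > 1:
            warnings.warn(f"majority vote tied for comparison {comp!r}; undecided",
                          stacklevel=2)
            votes.append({"comparison": comp, "significant": None, "direction": 0,
                          "decided": False})
        else:
            sig, direction = winners.index[0]
            votes.append({"comparison": comp, "significant": sig, "direction": direction,
                          "decided": True})
    votes_df = pd.DataFrame(votes)
    vote_map = {
        r["comparison"]: (r["significant"], r["direction"])
        for r in votes if r["decided"]
    }

    df["centered_eta2"] = df["eta2"] - df.groupby(["strategy", "comparison"])[
        "eta2"
    ].transform("mean")
    vpm_rows = []
    for (strategy, model), sub in df.groupby(["strategy", "model"]):
        deviations = sum(
            1
            for _, row in sub.iterrows()
            if row["comparison"] in vote_map and row["outcome"] != vote_map[row["comparison"]]
        )
        vpm_rows.append(
            {
                "strategy": strategy,
                "model": model,
                "std_centered_eta2": float(sub["centered_eta2"].std(ddof=1)),
                "deviations": deviations,
            }
        )
    return ReliabilityReport(
        variation_per_effect=vpe,
        variation_per_model=pd.DataFrame(vpm_rows),
        majority_votes=votes_df,
    )
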