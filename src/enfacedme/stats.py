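"""Cohort statistics: pooled summaries, group tests and logistic regression.

These mirror a standard retrospective-cohort analysis: χ² tests of
independence for categorical variables, one-way ANOVA / Kruskal–Wallis for
continuous ones, Student's t for the pooled two-group comparison, and a
logistic model for EZ disruption.  No multiplicity correction is applied
(each test is reported at its nominal level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GroupSummary",
    "pooled_proportion",
    "pooled_mean_sd",
    "chi_square_independence",
    "two_sample_t",
    "anova_oneway",
    "kruskal_wallis",
    "logistic_regression",
    "SeparationError",
    "table2_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / sd of one group (sd meaningless for n < 2)."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self):
        if self.n < 0 or self.sd < 0:
            raise ValueError("n and sd must be non-negative")


class SeparationError(RuntimeError):
    """Perfect separation: logistic estimates do not exist."""


def pooled_proportion(counts: list[tuple[int, int]]) -> float:
    """Pool per-group (events, n) counts: Σevents / Σn."""
    events = sum(e for e, _ in counts)
    total = sum(n for _, n in counts)
    if any(e > n for e, n in counts) or any(e < 0 for e, _ in counts):
        raise ValueError("need 0 <= events <= n in every group")
    if total == 0:
        raise ValueError("no observations to pool")
    return events / total


def pooled_mean_sd(groups: list[GroupSummary]) -> GroupSummary:
    """Combine group summaries into one, via the within + between variance
    decomposition (exactly what concatenating the raw data would give)."""
    if any(g.n <= 0 for g in groups):
        raise ValueError("every group needs n > 0")
    n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n
    if n < 2:
        return GroupSummary(n=n, mean=mean, sd=0.0)
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - mean) ** 2 for g in groups)
    return GroupSummary(n=n, mean=mean, sd=float(np.sqrt(ss / (n - 1))))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson χ² test of independence (no continuity correction).

    Returns (statistic, df, p).  Raises on negative counts or a zero
    marginal.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: χ² expectation undefined")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t(a: GroupSummary, b: GroupSummary, mode: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t test from summary statistics.

    ``mode``: "pooled" (Student) or "welch".  Returns (t, df, p).
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both groups")
    if mode not in ("pooled", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        return 0.0, float(a.n + b.n - 2), 1.0
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=(mode == "pooled"))
    df = a.n + b.n - 2 if mode == "pooled" else float(res.df) if hasattr(res, "df") else np.nan
    if mode == "welch":
        # Welch–Satterthwaite df
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA on raw per-group samples; returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H test with tie correction; returns (H, p)."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len({float(v) for g in arrays for v in g}) == 1:
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def logistic_regression(outcome, predictors) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with Wald 95% CIs and odds ratios.

    ``predictors`` is a DataFrame (or dict of arrays) of numeric columns;
    an intercept is added.  Raises :class:`SeparationError` on perfect
    separation instead of returning unstable estimates.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    design = sm.add_constant(X.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError("perfect separation: no finite estimates") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise SeparationError("non-finite standard errors: quasi-separation")
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "or_ci_low": np.exp(ci[0]),
            "or_ci_high": np.exp(ci[1]),
            "p": fit.pvalues,
        }
    )
    return out


# ---------------------------------------------------------------------------
# cohort report


def _group_block(sub: pd.DataFrame) -> dict:
    block = {"n": int(len(sub))}
    if len(sub) == 0:
        return block
    for col in ("age_years", "hba1c_pct", "bcva_logmar", "cst_um"):
        if col in sub and sub[col].notna().any():
            block[col] = (float(sub[col].mean()), float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0)
    for col in ("ez_disrupted", "erm_present", "pvd_incomplete"):
        if col in sub:
            block[col] = (int(sub[col].sum()), float(sub[col].mean()))
    if "mdrf_um" in sub and sub["mdrf_um"].notna().any():
        m = sub["mdrf_um"].dropna()
        block["mdrf_um"] = (float(m.mean()), float(m.std(ddof=1)) if len(m) > 1 else 0.0)
    return block


def table2_report(cohort) -> dict:
    """Per-type cohort comparison report plus the pooled Segment-2 block.

    ``cohort`` is a :class:`~enfacedme.cohort.CohortTable`.  Applies the
    test mapping: χ² for categorical variables, one-way ANOVA for age /
    HbA1c / CST / MDRF, Kruskal–Wallis for BCVA, Student's t and χ² for the
    pooled Segment-2 comparison.  Degenerate groups (n < 2) suppress the
    affected tests.
    """
    from .taxonomy import OBSERVED_TYPES

    df = cohort.frame
    report: dict = {"types": {}, "tests": {}, "segment2_pooled": {}}
    for label in OBSERVED_TYPES:
        sub = df[df["type_label"] == label]
        block = _group_block(sub)
        block["pct"] = 100.0 * len(sub) / len(df) if len(df) else 0.0
        report["types"][label] = block

    groups = [df[df["type_label"] == t] for t in OBSERVED_TYPES]
    testable = [g for g in groups if len(g) >= 2]
    if len(testable) >= 2:
        for col, test in (("age_years", "anova"), ("hba1c_pct", "anova"),
                          ("cst_um", "anova"), ("bcva_logmar", "kw")):
            vals = [g[col].dropna().to_numpy() for g in testable if col in g]
            vals = [v for v in vals if len(v) >= 2]
            if len(vals) >= 2:
                stat, p = (anova_oneway if test == "anova" else kruskal_wallis)(vals)
                report["tests"][col] = {"test": test, "statistic": stat, "p": p}
        for col in ("ez_disrupted", "erm_present", "pvd_incomplete"):
            if col in df:
                tab = np.array([[int(g[col].sum()), int((~g[col].astype(bool)).sum())]
                                for g in testable])
                if (tab.sum(axis=0) > 0).all():
                    stat, dof, p = chi_square_independence(tab)
                    report["tests"][col] = {"test": "chi2", "statistic": stat, "df": dof, "p": p}

    wet = df[df["segment2_fluid"]]
    dry = df[~df["segment2_fluid"]]
    if len(wet) >= 2 and len(dry) >= 2:
        block = {}
        for col in ("bcva_logmar", "cst_um"):
            a = GroupSummary(len(dry), float(dry[col].mean()), float(dry[col].std(ddof=1)))
            b = GroupSummary(len(wet), float(wet[col].mean()), float(wet[col].std(ddof=1)))
            t, dof, p = two_sample_t(a, b, mode="pooled")
            block[col] = {"dry": (a.mean, a.sd, a.n), "wet": (b.mean, b.sd, b.n),
                          "t": t, "p": p}
        for col in ("ez_disrupted", "erm_present"):
            tab = [[int(dry[col].sum()), int(len(dry) - dry[col].sum())],
                   [int(wet[col].sum()), int(len(wet) - wet[col].sum())]]
            stat, dof, p = chi_square_independence(tab)
            block[col] = {"dry_rate": float(dry[col].mean()), "wet_rate": float(wet[col].mean()),
                          "chi2": stat, "p": p}
        report["segment2_pooled"] = block
    report["n_total"] = int(len(df))
    return report
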