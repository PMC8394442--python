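"""Clinical comparison between the CTD and idiopathic groups.

Binary covariates (sex, smoking history, CTD symptoms, IPAF symptom
and serological domains, autoantibody positivity) are compared with
Fisher's exact test on the 2x2 table, with the Pearson chi-squared
test as a secondary column.  Continuous variables (serum biomarkers,
lung function, blood gas, BAL differentials) are compared with a
two-sample t-test computed from per-group summary statistics; the
default is the pooled-variance Student test, with Welch's unequal-
variance variant as an option.

The two-sided Fisher p-value follows the minimum-likelihood (point
probability) convention: the sum of hypergeometric probabilities, over
all tables with the observed margins, whose point probability does not
exceed that of the observed table.  Ties are resolved in exact integer
arithmetic, so the convention is applied at full rational precision.
The "doubling" convention (twice the smaller tail, capped at 1) is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "SummaryStats",
    "FisherResult",
    "ComparisonResult",
    "BINARY_VARIABLES",
    "CONTINUOUS_VARIABLES",
    "fisher_exact",
    "chi2_2x2",
    "ttest_from_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows are groups, columns positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and n for one group of one variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n={self.n}: at least 2 observations per group")
        if not self.sd >= 0:
            raise ValueError(f"sd={self.sd!r} must be non-negative")


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool  # a zero margin: every same-margin table is the observed one


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_summaries: dict


def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[range, list[int]]:
    """Integer numerators of P(X=x) over the support, common denominator C(N, c1)."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    return support, [comb(r1, x) * comb(r2, c1 - x) for x in support]


def fisher_exact(table: ContingencyTable2x2, method: str = "minlike") -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    ``method="minlike"`` (default) sums the probabilities of all tables
    no more likely than the observed one; ``method="doubling"`` doubles
    the smaller one-sided tail.  Computed in exact integer arithmetic.
    A zero row or column margin makes the table the only one with its
    margins; p = 1 is returned with ``degenerate=True``.
    """
    if method not in ("minlike", "doubling"):
        raise ValueError(f"unknown Fisher method {method!r}")
    r1, r2, c1, _ = table.margins
    if min(table.margins) == 0:
        odds = np.nan
        return FisherResult(p_value=1.0, odds_ratio=odds, degenerate=True)
    support, nums = _hypergeom_numerators(r1, r2, c1)
    denom = comb(table.total, c1)
    obs = nums[table.a - support.start]
    if method == "minlike":
        p_num = sum(n for n in nums if n <= obs)
    else:
        left = sum(nums[: table.a - support.start + 1])
        right = sum(nums[table.a - support.start:])
        p_num = min(denom, 2 * min(left, right))
    if table.b * table.c > 0:
        odds = (table.a * table.d) / (table.b * table.c)
    else:
        odds = np.inf if table.a * table.d > 0 else np.nan
    return FisherResult(p_value=p_num / denom, odds_ratio=odds, degenerate=False)


def chi2_2x2(table: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df), optional Yates continuity correction."""
    if min(table.margins) == 0:
        raise ValueError(
            "a zero margin leaves no variation to test; use fisher_exact, "
            "which handles degenerate tables"
        )
    stat, p, _, _ = stats.chi2_contingency(table.as_array(), correction=yates)
    return float(stat), float(p)


def ttest_from_summary(
    g1: SummaryStats,
    g2: SummaryStats,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from per-group summaries.

    ``pooled`` uses the common-variance Student test
    (sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2), df = n1+n2-2);
    ``welch`` uses unequal variances with Satterthwaite df.
    Returns (statistic, df, p_value).
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = float(g1.n + g2.n - 2)
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), df, float(res.pvalue)


#: Binary covariates of the clinical table (coded 1 = positive).
BINARY_VARIABLES: tuple[str, ...] = (
    "sex",            # 1 = female
    "smoking",        # 1 = ever-smoker
    "ctd_symptom",
    "ipaf_symptom",
    "autoantibody",
    "ipaf_serology",
)

#: Continuous covariates (units as sampled: U/mL, ng/mL, mmHg, %, counts).
CONTINUOUS_VARIABLES: tuple[str, ...] = (
    "kl6", "spd", "pao2", "paco2", "spo2_low", "fvc_pct", "dlco_pct",
    "bal_total", "bal_mac", "bal_ly", "bal_neut", "bal_eo", "cd4_8",
)


def compare_groups(
    clinical: pd.DataFrame,
    groups: pd.DataFrame,
    t_variant: str = "pooled",
    fisher_method: str = "minlike",
    binary_variables: Sequence[str] = BINARY_VARIABLES,
    continuous_variables: Sequence[str] = CONTINUOUS_VARIABLES,
) -> pd.DataFrame:
    """Variable-by-variable comparison of the CTD vs idiopathic groups.

    Binary variables get Fisher's exact p (chi-squared as a secondary
    column where margins allow); continuous variables get a t-test on
    per-group summaries computed after pairwise deletion of missing
    values.  Per-variable n is reported because missingness differs
    across variables (BAL and blood-gas panels are not run on every
    patient).

    Returns a long table: variable, kind, test, statistic, p_value,
    p_display (2 dp), per-group summaries and ns.
    """
    merged = clinical.merge(groups[["case_id", "group"]], on="case_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "case_id"].tolist()
        raise ValueError(f"cases without a group assignment: {missing}")
    g1 = merged[merged["group"] == "CTD"]
    g2 = merged[merged["group"] == "idiopathic"]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(
            f"both groups must be non-empty (CTD n={len(g1)}, idiopathic n={len(g2)})"
        )

    rows = []
    for var in binary_variables:
        x1 = g1[var].dropna().astype(int)
        x2 = g2[var].dropna().astype(int)
        table = ContingencyTable2x2(
            a=int((x1 == 1).sum()), b=int((x1 == 0).sum()),
            c=int((x2 == 1).sum()), d=int((x2 == 0).sum()),
        )
        fr = fisher_exact(table, method=fisher_method)
        try:
            chi_stat, chi_p = chi2_2x2(table)
        except ValueError:
            chi_stat, chi_p = np.nan, np.nan
        rows.append(
            {
                "variable": var, "kind": "binary", "test": "fisher",
                "statistic": fr.odds_ratio, "p_value": fr.p_value,
                "p_display": f"{fr.p_value:.2f}",
                "ctd_pos": table.a, "ctd_n": table.a + table.b,
                "idio_pos": table.c, "idio_n": table.c + table.d,
                "ctd_mean": np.nan, "ctd_sd": np.nan,
                "idio_mean": np.nan, "idio_sd": np.nan,
                "chi2_statistic": chi_stat, "chi2_p_value": chi_p,
            }
        )
    for var in continuous_variables:
        x1 = pd.to_numeric(g1[var], errors="coerce").dropna()
        x2 = pd.to_numeric(g2[var], errors="coerce").dropna()
        s1 = SummaryStats(mean=float(x1.mean()), sd=float(x1.std(ddof=1)), n=len(x1))
        s2 = SummaryStats(mean=float(x2.mean()), sd=float(x2.std(ddof=1)), n=len(x2))
        t_stat, _, p = ttest_from_summary(s1, s2, variant=t_variant)
        rows.append(
            {
                "variable": var, "kind": "continuous", "test": f"t_{t_variant}",
                "statistic": t_stat, "p_value": p, "p_display": f"{p:.2f}",
                "ctd_pos": np.nan, "ctd_n": s1.n,
                "idio_pos": np.nan, "idio_n": s2.n,
                "ctd_mean": s1.mean, "ctd_sd": s1.sd,
                "idio_mean": s2.mean, "idio_sd": s2.sd,
                "chi2_statistic": np.nan, "chi2_p_value": np.nan,
            }
        )
    return pd.DataFrame(rows)
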