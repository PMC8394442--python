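"""Tests for the 2x2 exact/asymptotic tests and summary t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ctdip import (
    ContingencyTable2x2,
    SummaryStats,
    SyntheticCohortConfig,
    chi2_2x2,
    classify_cohort,
    compare_groups,
    fisher_exact,
    generate_cohort,
    ttest_from_summary,
)

counts = st.integers(min_value=0, max_value=25)


def test_fisher_balanced_table_is_one():
    assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_degenerate():
    res = fisher_exact(ContingencyTable2x2(0, 0, 5, 7))
    assert res.p_value == 1.0
    assert res.degenerate


def test_fisher_matches_scipy_convention():
    """scipy implements the same minimum-likelihood two-sided rule."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        t = rng.integers(0, 16, size=4)
        if t.sum() == 0:
            continue
        tab = ContingencyTable2x2(*(int(x) for x in t))
        if min(tab.margins) == 0:
            continue
        sp = stats.fisher_exact(tab.as_array())[1]
        assert fisher_exact(tab).p_value == pytest.approx(sp, abs=1e-12)


def test_fisher_doubling_convention():
    """Doubling = 2 * min(lower tail, upper tail), capped at 1."""
    tab = ContingencyTable2x2(16, 4, 34, 40)
    lo = stats.hypergeom(94, 20, 50).cdf(16)
    hi = stats.hypergeom(94, 20, 50).sf(15)
    expected = min(1.0, 2 * min(lo, hi))
    assert fisher_exact(tab, method="doubling").p_value == pytest.approx(
        expected, abs=1e-10
    )
    assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5),
                        method="doubling").p_value == pytest.approx(1.0)


@given(counts, counts, counts, counts)
def test_fisher_invariant_under_row_and_column_swap(a, b, c, d):
    if a + b + c + d == 0:
        return
    p0 = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
    p_rows = fisher_exact(ContingencyTable2x2(c, d, a, b)).p_value
    p_both = fisher_exact(ContingencyTable2x2(d, c, b, a)).p_value
    assert p_rows == pytest.approx(p0, abs=1e-12)
    assert p_both == pytest.approx(p0, abs=1e-12)


def test_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def test_chi2_balanced_table():
    stat, p = chi2_2x2(ContingencyTable2x2(5, 5, 5, 5))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_longhand_identity():
    """Pearson statistic equals N(ad-bc)^2 / product of margins."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
        tab = ContingencyTable2x2(a, b, c, d)
        stat, _ = chi2_2x2(tab)
        n = a + b + c + d
        identity = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(identity, rel=1e-10)


def test_chi2_autoantibody_table():
    stat, _ = chi2_2x2(ContingencyTable2x2(16, 4, 34, 40))
    assert stat == pytest.approx(7.33, abs=0.005)


def test_chi2_yates_never_exceeds_uncorrected():
    rng = np.random.default_rng(9)
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
        tab = ContingencyTable2x2(a, b, c, d)
        assert chi2_2x2(tab, yates=True)[0] <= chi2_2x2(tab)[0] + 1e-12


def test_chi2_zero_margin_recommends_fisher():
    with pytest.raises(ValueError, match="fisher"):
        chi2_2x2(ContingencyTable2x2(0, 0, 5, 7))


def test_ttest_identical_groups():
    s = SummaryStats(mean=10.0, sd=2.0, n=30)
    stat, df, p = ttest_from_summary(s, s)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert df == 58


def test_ttest_pooled_df_and_welch_df():
    g1 = SummaryStats(1438.0, 1019.0, 20)
    g2 = SummaryStats(1830.0, 2433.0, 74)
    _, df_p, p_pooled = ttest_from_summary(g1, g2, "pooled")
    _, df_w, p_welch = ttest_from_summary(g1, g2, "welch")
    assert df_p == 92
    assert df_w < df_p  # unequal variances shrink the Satterthwaite df
    assert p_pooled == pytest.approx(0.4845, abs=5e-4)
    assert p_welch != pytest.approx(p_pooled, abs=1e-3)


def test_ttest_symmetric_under_group_exchange():
    g1 = SummaryStats(5.0, 1.0, 12)
    g2 = SummaryStats(6.5, 2.0, 20)
    _, _, p12 = ttest_from_summary(g1, g2)
    _, _, p21 = ttest_from_summary(g2, g1)
    assert p12 == pytest.approx(p21, abs=1e-14)


def test_ttest_p_decreases_with_mean_gap():
    base = SummaryStats(0.0, 1.0, 25)
    ps = [ttest_from_summary(base, SummaryStats(d, 1.0, 25))[2]
          for d in (0.0, 0.2, 0.5, 1.0, 2.0)]
    assert ps == sorted(ps, reverse=True)


def test_ttest_validation():
    with pytest.raises(ValueError):
        SummaryStats(0.0, -1.0, 10)
    with pytest.raises(ValueError):
        SummaryStats(0.0, 1.0, 1)
    with pytest.raises(ValueError):
        ttest_from_summary(SummaryStats(0, 1, 5), SummaryStats(0, 1, 5), "bogus")


def _tiny_cohort(values_ctd, values_idio, var="kl6"):
    clin = pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(len(values_ctd) + len(values_idio))],
            var: values_ctd + values_idio,
        }
    )
    groups = pd.DataFrame(
        {
            "case_id": clin["case_id"],
            "group": ["CTD"] * len(values_ctd) + ["idiopathic"] * len(values_idio),
        }
    )
    return clin, groups


def test_compare_groups_identical_continuous_gives_p_one():
    clin, groups = _tiny_cohort([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    out = compare_groups(clin, groups, binary_variables=(),
                        continuous_variables=("kl6",))
    assert out["p_value"].iloc[0] == pytest.approx(1.0)
    assert out["p_display"].iloc[0] == "1.00"


def test_compare_groups_requires_group_for_every_case():
    clin, groups = _tiny_cohort([1.0, 2.0], [3.0, 4.0])
    with pytest.raises(ValueError, match="c3"):
        compare_groups(clin, groups.iloc[:-1], binary_variables=(),
                       continuous_variables=("kl6",))


def test_compare_groups_rejects_empty_group():
    clin, groups = _tiny_cohort([1.0, 2.0, 3.0, 4.0], [])
    with pytest.raises(ValueError, match="non-empty"):
        compare_groups(clin, groups, binary_variables=(),
                       continuous_variables=("kl6",))


def test_compare_groups_pairwise_deletion_reports_n():
    clin, groups = _tiny_cohort([1.0, 2.0, np.nan], [4.0, 5.0, 6.0])
    out = compare_groups(clin, groups, binary_variables=(),
                        continuous_variables=("kl6",))
    assert out["ctd_n"].iloc[0] == 2
    assert out["idio_n"].iloc[0] == 3


def test_compare_groups_recovers_known_directions():
    """On a default synthetic cohort the CTD group should show more
    women, fewer ever-smokers and more autoantibody positives — the
    directions built into the class-conditional covariate rates."""
    cfg = SyntheticCohortConfig.default(seed=13)  # 94 cases, 4 raters
    cohort = generate_cohort(cfg)
    groups = classify_cohort(cohort.scores)
    out = compare_groups(cohort.clinical, groups).set_index("variable")
    for var, positive_in_ctd in (("sex", True), ("smoking", False),
                                 ("autoantibody", True)):
        row = out.loc[var]
        rate_ctd = row["ctd_pos"] / row["ctd_n"]
        rate_idio = row["idio_pos"] / row["idio_n"]
        assert bool(rate_ctd > rate_idio) is positive_in_ctd
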