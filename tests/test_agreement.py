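"""Tests for the kappa agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctdip import (
    RatingsMatrix,
    SyntheticCohortConfig,
    UndefinedKappaError,
    agreement_report,
    cohen_kappa,
    fleiss_kappa,
    generate_cohort,
)


def long_table(assignments):
    """cases x raters nested list -> long-format DataFrame."""
    rows = []
    for i, case in enumerate(assignments):
        for j, v in enumerate(case):
            rows.append({"case_id": f"c{i:03d}", "rater_id": f"r{j}", "v": v})
    return pd.DataFrame(rows)


def matrix_of(assignments, categories=None):
    return RatingsMatrix.from_dataframe(long_table(assignments), "v",
                                        categories=categories)


def test_fleiss_perfect_agreement_is_one():
    m = matrix_of([["X"] * 4, ["Y"] * 4, ["X"] * 4])
    assert fleiss_kappa(m).kappa == pytest.approx(1.0, abs=1e-12)


def test_fleiss_hand_oracle_two_cases():
    """Case 1 splits 2/2, case 2 unanimous: Po = 2/3, Pe = 5/8, kappa = 1/9."""
    m = matrix_of([["X", "X", "Y", "Y"], ["X", "X", "X", "X"]])
    assert fleiss_kappa(m).kappa == pytest.approx(1 / 9, abs=1e-12)


def test_fleiss_null_rating_near_zero():
    rng = np.random.default_rng(99)
    m = matrix_of(rng.integers(0, 4, size=(200, 4)).tolist(), categories=(0, 1, 2, 3))
    assert abs(fleiss_kappa(m).kappa) < 0.1


def test_fleiss_undefined_when_single_category():
    with pytest.raises(UndefinedKappaError):
        fleiss_kappa(matrix_of([["X"] * 4, ["X"] * 4, ["X"] * 4],
                               categories=("X", "Y")))


def test_fleiss_undefined_on_single_case():
    with pytest.raises(UndefinedKappaError):
        fleiss_kappa(matrix_of([["X", "Y", "X", "Y"]]))


def test_cohen_hand_oracle_confusion_table():
    """Confusion [[10,2],[3,5]]: po = 0.75, pe = 0.53, kappa = 0.22/0.47."""
    pairs = [("X", "X")] * 10 + [("X", "Y")] * 2 + [("Y", "X")] * 3 + [("Y", "Y")] * 5
    m = matrix_of([list(p) for p in pairs])
    assert cohen_kappa(m).kappa == pytest.approx((0.75 - 0.53) / 0.47, abs=1e-12)


def test_cohen_identical_raters():
    m = matrix_of([["X", "X"], ["Y", "Y"], ["Z", "Z"], ["X", "X"]])
    assert cohen_kappa(m).kappa == pytest.approx(1.0, abs=1e-12)


def test_cohen_independent_raters_near_zero():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 4, size=400)
    b = rng.permutation(a)
    m = matrix_of(np.column_stack([a, b]).tolist(), categories=(0, 1, 2, 3))
    assert abs(cohen_kappa(m).kappa) < 0.1


def test_cohen_requires_two_raters():
    with pytest.raises(ValueError):
        cohen_kappa(matrix_of([["X", "X", "Y"], ["Y", "Y", "X"]]))


def test_cohen_linear_weighted_matches_longhand():
    """Linear weights w_ij = |i-j|/(k-1): kappa = 1 - sum(w f)/sum(w e)."""
    rng = np.random.default_rng(31)
    a = rng.integers(0, 4, size=150)
    b = np.clip(a + rng.integers(-1, 2, size=150), 0, 3)
    m = matrix_of(np.column_stack([a, b]).tolist(), categories=(0, 1, 2, 3))
    got = cohen_kappa(m, weighting="linear").kappa

    k = 4
    f = np.zeros((k, k))
    for x, y in zip(a, b):
        f[x, y] += 1
    w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    e = np.outer(f.sum(axis=1), f.sum(axis=0)) / f.sum()
    expected = 1 - (w * f).sum() / (w * e).sum()
    assert got == pytest.approx(expected, abs=1e-10)


def test_fleiss_close_to_cohen_for_two_raters():
    """Two-rater Fleiss uses pooled marginals (Scott-style chance term),
    Cohen per-rater marginals; the definitional gap shrinks with n and
    both hit 1 under perfect agreement."""
    rng = np.random.default_rng(11)
    a = rng.integers(0, 3, size=300)
    agree_mask = rng.random(300) < 0.8
    b = np.where(agree_mask, a, rng.integers(0, 3, size=300))
    m = matrix_of(np.column_stack([a, b]).tolist(), categories=(0, 1, 2))
    fk = fleiss_kappa(m).kappa
    ck = cohen_kappa(m).kappa
    assert fk == pytest.approx(ck, abs=0.02)
    perfect = matrix_of([["A", "A"], ["B", "B"], ["C", "C"]])
    assert fleiss_kappa(perfect).kappa == pytest.approx(1.0, abs=1e-12)
    assert cohen_kappa(perfect).kappa == pytest.approx(1.0, abs=1e-12)


@given(st.permutations(["W", "X", "Y", "Z"]))
def test_kappa_invariant_under_category_relabeling(perm):
    rng = np.random.default_rng(7)
    base = rng.integers(0, 4, size=(40, 4))
    cats = ["W", "X", "Y", "Z"]
    orig = matrix_of([[cats[v] for v in row] for row in base], categories=cats)
    relab = matrix_of([[perm[v] for v in row] for row in base], categories=cats)
    assert fleiss_kappa(relab).kappa == pytest.approx(fleiss_kappa(orig).kappa,
                                                      abs=1e-12)


def test_ratings_matrix_validation():
    with pytest.raises(ValueError, match="category"):
        matrix_of([["X", "Q"]], categories=("X", "Y"))
    # incomplete cases are dropped, not imputed
    df = long_table([["X", "X"], ["Y", "Y"]])
    df = df.drop(index=3)  # remove one rating of case c001
    m = RatingsMatrix.from_dataframe(df, "v")
    assert m.n_cases == 1


def test_agreement_report_noise_free_cohort_is_unanimous():
    cfg = SyntheticCohortConfig.default(n_cases=100, rater_noise_eps=0.0, seed=11)
    rep = agreement_report(generate_cohort(cfg).scores)
    assert (rep["status"] == "ok").all()
    assert rep["kappa"].tolist() == pytest.approx([1.0] * len(rep))
    assert rep["subject"].iloc[0] == "diagnosis"


def test_agreement_report_diagnosis_beats_mean_item_kappa():
    """Item-level noise that preserves the diagnosis: the binary index
    label agrees better than the average raw item, the qualitative
    pattern motivating a score-based diagnosis."""
    cfg = SyntheticCohortConfig.default(n_cases=300, rater_noise_eps=0.25, seed=202)
    rep = agreement_report(generate_cohort(cfg).scores)
    diag = float(rep.loc[rep["subject"] == "diagnosis", "kappa"].iloc[0])
    items = rep.loc[rep["subject"] != "diagnosis", "kappa"]
    assert diag > items.mean()
    # items are listed in descending kappa
    assert items.tolist() == sorted(items.tolist(), reverse=True)


def test_agreement_report_surfaces_undefined_kappa():
    df = long_table([["CTD-IP", "CTD-IP"]])
    df = df.rename(columns={"v": "label"})
    for item in ("ff", "smh", "cip", "dpvc", "fat", "plasm", "lygc", "af"):
        df[item] = 0
    rep = agreement_report(df)
    assert (rep["status"] == "undefined").all()
    assert rep["kappa"].isna().all()
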