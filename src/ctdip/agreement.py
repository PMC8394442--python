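"""Inter-rater agreement (kappa statistics).

Agreement is quantified both per histological item (categories 0-3)
and for the binary index diagnosis derived from the items.  With more
than two raters the headline statistic is Fleiss' multi-rater kappa,

    kappa = (Po - Pe) / (1 - Pe),

where Po is the mean per-case pairwise agreement and Pe the sum of
squared marginal category proportions.  Item grades are treated as
nominal categories for the headline kappa (Fleiss' assumption); a
pairwise Cohen kappa, optionally linear-weighted for the ordinal 0-3
scale, is available as a secondary two-rater view.

kappa is undefined when the expected agreement Pe equals 1 — every
rating in the whole table falls in a single category — and such inputs
raise :class:`UndefinedKappaError` rather than returning a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater as smir

from .scoring import (
    DEFAULT_COEFFICIENTS,
    ITEM_NAMES,
    IndexCoefficients,
    score_table,
)

__all__ = [
    "RatingsMatrix",
    "AgreementResult",
    "UndefinedKappaError",
    "fleiss_kappa",
    "cohen_kappa",
    "agreement_report",
]


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (a single category everywhere): kappa undefined."""


@dataclass(frozen=True)
class RatingsMatrix:
    """Complete cases x raters table of categorical assignments.

    Every cell must hold one of the declared categories; incomplete
    matrices are rejected (kappa needs complete data).  Categories are
    an ordered list so that weighted statistics know the ordinal
    distances.
    """

    case_ids: tuple
    rater_ids: tuple
    categories: tuple
    assignments: np.ndarray  # object array, shape (n_cases, n_raters)

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignments, dtype=object)
        if arr.ndim != 2:
            raise ValueError("assignments must be a 2-D cases x raters table")
        if arr.shape != (len(self.case_ids), len(self.rater_ids)):
            raise ValueError(
                f"assignments shape {arr.shape} does not match "
                f"{len(self.case_ids)} cases x {len(self.rater_ids)} raters"
            )
        cats = set(self.categories)
        if len(cats) != len(self.categories):
            raise ValueError("duplicate category labels")
        for cell in arr.ravel():
            if cell not in cats:
                raise ValueError(f"assignment {cell!r} is not a declared category")
        object.__setattr__(self, "assignments", arr)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    def category_counts(self) -> np.ndarray:
        """Cases x categories count table (each row sums to n_raters)."""
        index = {c: j for j, c in enumerate(self.categories)}
        counts = np.zeros((self.n_cases, len(self.categories)), dtype=int)
        for i in range(self.n_cases):
            for cell in self.assignments[i]:
                counts[i, index[cell]] += 1
        return counts

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str,
        categories: Sequence | None = None,
        case_col: str = "case_id",
        rater_col: str = "rater_id",
    ) -> "RatingsMatrix":
        """Pivot a long-format table into a complete ratings matrix.

        Cases with any missing rater are dropped (complete-case
        analysis); the retained set is whatever is complete.
        """
        wide = df.pivot(index=case_col, columns=rater_col, values=value_col)
        complete = wide.dropna(axis=0, how="any")
        if categories is None:
            categories = sorted(pd.unique(complete.to_numpy().ravel()))
        return cls(
            case_ids=tuple(complete.index),
            rater_ids=tuple(complete.columns),
            categories=tuple(categories),
            assignments=complete.to_numpy(dtype=object),
        )


@dataclass(frozen=True)
class AgreementResult:
    """One kappa with the context needed to read it."""

    subject: str
    kappa: float
    n_cases: int
    n_raters: int
    n_categories: int
    method: str


def _check_defined(counts: np.ndarray) -> None:
    marginals = counts.sum(axis=0) / counts.sum()
    if float(marginals @ marginals) >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "all ratings fall in a single category; expected agreement is 1 "
            "and kappa is undefined"
        )


def fleiss_kappa(matrix: RatingsMatrix, subject: str = "ratings") -> AgreementResult:
    """Fleiss' multi-rater kappa for a complete ratings matrix."""
    if matrix.n_raters < 2:
        raise ValueError("Fleiss' kappa requires at least 2 raters")
    if matrix.n_cases < 2:
        # with a single case the marginals coincide with that case's own
        # votes, so chance correction degenerates
        raise UndefinedKappaError(
            "kappa needs at least 2 cases; a single case cannot be "
            "chance-corrected against its own marginals"
        )
    counts = matrix.category_counts()
    _check_defined(counts)
    kappa = float(smir.fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(
        subject=subject,
        kappa=kappa,
        n_cases=matrix.n_cases,
        n_raters=matrix.n_raters,
        n_categories=len(matrix.categories),
        method="fleiss",
    )


def cohen_kappa(
    matrix: RatingsMatrix,
    weighting: str = "none",
    subject: str = "ratings",
) -> AgreementResult:
    """Cohen's kappa between exactly two raters.

    ``weighting="linear"`` applies linear disagreement weights, the
    usual choice for ordinal grades.
    """
    if matrix.n_raters != 2:
        raise ValueError("Cohen's kappa is defined for exactly 2 raters")
    if weighting not in ("none", "linear"):
        raise ValueError(f"unknown weighting {weighting!r}")
    index = {c: j for j, c in enumerate(matrix.categories)}
    k = len(matrix.categories)
    confusion = np.zeros((k, k), dtype=int)
    for a, b in matrix.assignments:
        confusion[index[a], index[b]] += 1
    _check_defined(np.array([confusion.sum(axis=0) + confusion.sum(axis=1)]))
    wt = None if weighting == "none" else "linear"
    res = smir.cohens_kappa(confusion, wt=wt, return_results=True)
    method = "cohen" if weighting == "none" else "cohen_linear_weighted"
    return AgreementResult(
        subject=subject,
        kappa=float(res.kappa),
        n_cases=matrix.n_cases,
        n_raters=2,
        n_categories=k,
        method=method,
    )


def agreement_report(
    scores: pd.DataFrame,
    coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
    threshold: float = 0.5,
    method: str = "fleiss",
    weighting: str = "none",
) -> pd.DataFrame:
    """Per-item and diagnosis-level agreement for a multi-rater cohort.

    Computes one kappa per histological item (categories {0,1,2,3}) and
    one for the binary index diagnosis derived at the given threshold.
    The diagnosis row comes first; items follow in descending kappa.
    Subjects with undefined kappa are kept with ``status='undefined'``
    and a NaN kappa.
    """
    if "label" not in scores.columns:
        scores = score_table(scores, coeffs, threshold)

    def _one(subject: str, value_col: str, categories) -> dict:
        matrix = RatingsMatrix.from_dataframe(scores, value_col, categories=categories)
        row = {
            "subject": subject,
            "n_cases": matrix.n_cases,
            "n_raters": matrix.n_raters,
            "n_categories": len(matrix.categories),
        }
        try:
            if method == "fleiss":
                res = fleiss_kappa(matrix, subject=subject)
            elif method == "cohen":
                res = cohen_kappa(matrix, weighting=weighting, subject=subject)
            else:
                raise ValueError(f"unknown kappa method {method!r}")
            row.update(kappa=res.kappa, method=res.method, status="ok")
        except UndefinedKappaError:
            row.update(kappa=np.nan, method=method, status="undefined")
        return row

    rows = [_one("diagnosis", "label", ("CTD-IP", "idiopathic"))]
    item_rows = [_one(name, name, (0, 1, 2, 3)) for name in ITEM_NAMES]
    item_rows.sort(key=lambda r: (-(r["kappa"]) if np.isfinite(r["kappa"]) else np.inf))
    rows.extend(item_rows)
    return pd.DataFrame(rows)
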