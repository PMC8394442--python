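"""Scoring with the CTD-IP histological index.

The CTD-IP index is a logistic score that separates connective tissue
disease (CTD)-associated interstitial pneumonia from idiopathic
interstitial pneumonia on surgical lung biopsy.  A pathologist grades
eight histological items, each 0 (none), 1 (mild), 2 (moderate) or
3 (marked):

========  =====================================================
symbol    item
========  =====================================================
FF        fibroblastic focus
SMH       smooth muscle hyperplasia
CIP       cellular interstitial pneumonia
DPVC      dense perivascular collagen
Fat       fat metaplasia
Plasm     prominent plasmacytic infiltration
LyGC      lymphoid follicle with germinal center
AF        airspace fibrin
========  =====================================================

The published index combines the grades into a log-odds

    Z = +1.65 - 1.09 FF - 0.81 SMH - 0.85 CIP - 0.86 DPVC - 0.57 Fat
        + 0.86 Plasm + 0.64 LyGC + 2.47 AF

and maps it through the logistic function, P = exp(Z) / (1 + exp(Z)),
read as the probability that the biopsy shows CTD-associated rather
than idiopathic disease.  A rating with P strictly above 0.5 is
labelled ``CTD-IP``; P exactly at the threshold is labelled
``idiopathic`` (the published rule is a strict "P > 0.5").

Note a property of the published constants: the intercept is positive,
so a biopsy scored 0 on every item has P = logistic(1.65) ~= 0.839 and
is labelled CTD-IP.  Whether a featureless biopsy should be
classifiable at all is a clinical question the index does not address;
this module computes what the formula dictates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ITEM_NAMES",
    "ItemScores",
    "IndexCoefficients",
    "DEFAULT_COEFFICIENTS",
    "Label",
    "IndexResult",
    "ScoreValidationError",
    "compute_z",
    "logistic",
    "classify",
    "score_case",
    "score_table",
]

#: The eight histological items, in the order the index formula lists them.
ITEM_NAMES: tuple[str, ...] = (
    "ff", "smh", "cip", "dpvc", "fat", "plasm", "lygc", "af",
)

_VALID_SCORES = frozenset({0, 1, 2, 3})


class ScoreValidationError(ValueError):
    """An item score is missing, non-integer, or outside {0, 1, 2, 3}."""


class Label(str, enum.Enum):
    """Binary diagnosis emitted by the index."""

    CTD_IP = "CTD-IP"
    IDIOPATHIC = "idiopathic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ItemScores:
    """One rater's eight ordinal grades (0-3) for one biopsy."""

    ff: int
    smh: int
    cip: int
    dpvc: int
    fat: int
    plasm: int
    lygc: int
    af: int

    def __post_init__(self) -> None:
        for name in ITEM_NAMES:
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
                raise ScoreValidationError(
                    f"item {name!r}: score must be an integer, got {value!r}"
                )
            if int(value) not in _VALID_SCORES:
                raise ScoreValidationError(
                    f"item {name!r}: score {value} outside the 0-3 grading scale"
                )

    def as_array(self) -> np.ndarray:
        """Scores as a float vector in :data:`ITEM_NAMES` order."""
        return np.array([getattr(self, name) for name in ITEM_NAMES], dtype=float)

    @classmethod
    def from_mapping(cls, mapping) -> "ItemScores":
        missing = [name for name in ITEM_NAMES if name not in mapping]
        if missing:
            raise ScoreValidationError(f"missing item(s): {', '.join(missing)}")
        return cls(**{name: mapping[name] for name in ITEM_NAMES})


@dataclass(frozen=True)
class IndexCoefficients:
    """Intercept and per-item weights of the index.

    Defaults are the published constants.  Items weighing toward
    idiopathic disease (FF, SMH, CIP, DPVC, Fat) carry negative
    weights; items weighing toward CTD (Plasm, LyGC, AF) positive ones.
    The weights are configurable to allow refitting experiments, but
    every analysis in this package uses the defaults.
    """

    intercept: float = 1.65
    ff: float = -1.09
    smh: float = -0.81
    cip: float = -0.85
    dpvc: float = -0.86
    fat: float = -0.57
    plasm: float = 0.86
    lygc: float = 0.64
    af: float = 2.47

    def weights(self) -> np.ndarray:
        """Item weights as a vector in :data:`ITEM_NAMES` order."""
        return np.array([getattr(self, name) for name in ITEM_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping) -> "IndexCoefficients":
        unknown = set(mapping) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown coefficient(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


DEFAULT_COEFFICIENTS = IndexCoefficients()


@dataclass(frozen=True)
class IndexResult:
    """Index output for one rater x case: log-odds, probability, label."""

    z: float
    p: float
    label: Label


def compute_z(
    scores: ItemScores,
    coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Log-odds Z: intercept plus the weighted sum of the eight grades."""
    return float(coeffs.intercept + scores.as_array() @ coeffs.weights())


def logistic(z: float) -> float:
    """Logistic transform exp(z)/(1+exp(z)), overflow-safe.

    Strictly increasing; output in the open interval (0, 1).
    """
    if not math.isfinite(z):
        raise ScoreValidationError(f"log-odds must be finite, got {z!r}")
    return float(expit(z))


def classify(p: float, threshold: float = 0.5) -> Label:
    """Label a probability: CTD-IP iff p > threshold (strict).

    A probability exactly at the threshold is idiopathic, matching the
    strict "P > 0.5" rule of the published index.
    """
    if not 0.0 <= p <= 1.0:
        raise ScoreValidationError(f"probability {p!r} outside [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ScoreValidationError(f"threshold {threshold!r} outside [0, 1]")
    return Label.CTD_IP if p > threshold else Label.IDIOPATHIC


def score_case(
    scores: ItemScores,
    coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
    threshold: float = 0.5,
) -> IndexResult:
    """Full index evaluation of one rating: Z, P and the binary label."""
    z = compute_z(scores, coeffs)
    p = logistic(z)
    return IndexResult(z=z, p=p, label=classify(p, threshold))


def score_table(
    scores: pd.DataFrame,
    coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every row of a long-format rating table.

    Parameters
    ----------
    scores
        One row per (case, rater) with the eight item columns; any
        other columns (``case_id``, ``rater_id``) pass through.

    Returns
    -------
    Copy of the input with ``z``, ``p`` and ``label`` columns appended.
    Full floating precision is kept here; rounding for display happens
    only when writing output files.
    """
    missing = [name for name in ITEM_NAMES if name not in scores.columns]
    if missing:
        raise ScoreValidationError(f"missing item column(s): {', '.join(missing)}")
    values = scores[list(ITEM_NAMES)].to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values.astype(float)).any():
        raise ScoreValidationError("item scores must be numeric with no missing cells")
    values = values.astype(float)
    if not ((values == np.round(values)) & (values >= 0) & (values <= 3)).all():
        bad = np.argwhere(~((values == np.round(values)) & (values >= 0) & (values <= 3)))
        row, col = bad[0]
        raise ScoreValidationError(
            f"item {ITEM_NAMES[col]!r}: score {values[row, col]} outside the 0-3 "
            f"grading scale (table row {row})"
        )
    out = scores.copy()
    z = coeffs.intercept + values @ coeffs.weights()
    p = expit(z)
    out["z"] = z
    out["p"] = p
    out["label"] = np.where(p > threshold, Label.CTD_IP.value, Label.IDIOPATHIC.value)
    return out
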