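"""Consensus classification across raters.

The validation design assigns a case to the CTD group only when every
rater's index label is CTD-IP (unanimity); any dissent places the case
in the idiopathic group.  The rule generalises to any number of raters
(the original study used four pathologists).

Also implemented here is the morphological arm of the IPAF
(interstitial pneumonia with autoimmune features) research criteria as
operationalised on the index's grading scale: lymphoid follicles with
germinal centers (LyGC) graded >= 2 AND plasmacytic infiltration
(Plasm) graded >= 2.  A case meets the criterion at consensus level
when every rater's grades satisfy it, by analogy with the unanimity
rule of the CTD group.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import (
    DEFAULT_COEFFICIENTS,
    IndexCoefficients,
    ItemScores,
    Label,
    score_table,
)

__all__ = [
    "CaseConsensus",
    "consensus_group",
    "dissent_profile",
    "ipaf_morphology",
    "ipaf_consensus",
    "classify_cohort",
]


@dataclass(frozen=True)
class CaseConsensus:
    """Vote summary for one case.

    ``group`` is "CTD" only when every rater voted CTD-IP; ``unanimous``
    is true when all votes agree in either direction.
    """

    case_id: str
    rater_labels: tuple[Label, ...]
    group: str
    n_ctd_votes: int
    unanimous: bool

    @property
    def n_raters(self) -> int:
        return len(self.rater_labels)

    @property
    def n_dissenting(self) -> int:
        """Size of the minority vote (0 when unanimous)."""
        return min(self.n_ctd_votes, self.n_raters - self.n_ctd_votes)


def _as_label(value) -> Label:
    if isinstance(value, Label):
        return value
    return Label(value)


def consensus_group(
    rater_labels: Sequence[Label | str],
    case_id: str = "case",
) -> CaseConsensus:
    """Aggregate per-rater labels with the unanimity rule.

    Deterministic and invariant under permutation of the raters.
    """
    labels = tuple(_as_label(v) for v in rater_labels)
    if not labels:
        raise ValueError("consensus requires at least one rater label")
    n_ctd = sum(1 for v in labels if v is Label.CTD_IP)
    group = "CTD" if n_ctd == len(labels) else "idiopathic"
    unanimous = n_ctd in (0, len(labels))
    return CaseConsensus(
        case_id=case_id,
        rater_labels=labels,
        group=group,
        n_ctd_votes=n_ctd,
        unanimous=unanimous,
    )


def dissent_profile(cases: Iterable[CaseConsensus]) -> dict[int, int]:
    """Histogram of minority-vote sizes across a cohort.

    Key k counts the cases where exactly k raters disagreed with the
    majority (k = 0 is unanimity; ties count the full half).  Requires
    every case to carry the same number of raters, otherwise minority
    sizes are not comparable.
    """
    cases = list(cases)
    if not cases:
        return {}
    n_raters = {c.n_raters for c in cases}
    if len(n_raters) != 1:
        raise ValueError(f"ragged rater counts across cases: {sorted(n_raters)}")
    return dict(Counter(c.n_dissenting for c in cases))


def ipaf_morphology(scores: ItemScores) -> bool:
    """Morphological IPAF criterion for one rating: LyGC >= 2 and Plasm >= 2."""
    return scores.lygc >= 2 and scores.plasm >= 2


def ipaf_consensus(per_rater_scores: Sequence[ItemScores | Mapping]) -> bool:
    """True when every rater's grades meet the morphological IPAF criterion."""
    ratings = [
        s if isinstance(s, ItemScores) else ItemScores.from_mapping(s)
        for s in per_rater_scores
    ]
    if not ratings:
        raise ValueError("IPAF consensus requires at least one rater")
    return all(ipaf_morphology(s) for s in ratings)


def classify_cohort(
    scores: pd.DataFrame,
    coeffs: IndexCoefficients = DEFAULT_COEFFICIENTS,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-case consensus table from a long-format rating table.

    Accepts either a raw score table (case_id, rater_id, eight items) or
    one already scored (with a ``label`` column); scoring is invoked
    internally when absent.  Returns one row per case: case_id,
    n_raters, n_ctd_votes, group, unanimous, ipaf_morphology_consensus.
    """
    if "label" not in scores.columns:
        scores = score_table(scores, coeffs, threshold)
    rows = []
    for case_id, sub in scores.groupby("case_id", sort=True):
        cc = consensus_group(list(sub["label"]), case_id=str(case_id))
        ipaf = bool(((sub["lygc"] >= 2) & (sub["plasm"] >= 2)).all())
        rows.append(
            {
                "case_id": cc.case_id,
                "n_raters": cc.n_raters,
                "n_ctd_votes": cc.n_ctd_votes,
                "group": cc.group,
                "unanimous": cc.unanimous,
                "ipaf_morphology_consensus": ipaf,
            }
        )
    return pd.DataFrame(rows)
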