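"""Small bundled datasets used in documentation and tests."""

from __future__ import annotations

import pandas as pd

__all__ = ["worked_example_scores"]

# Published worked example: one IPF biopsy with CTD-like histology,
# independently graded by four pathologists (A-D).  Plasm and LyGC were
# scored 2-3 by everyone; all four index probabilities exceed 0.5, so
# the unanimity rule puts the case in the CTD group.
_WORKED_EXAMPLE = [
    # rater, ff, smh, cip, dpvc, fat, plasm, lygc, af
    ("A", 0, 0, 2, 0, 0, 3, 1, 0),
    ("B", 1, 1, 1, 0, 0, 2, 2, 0),
    ("C", 1, 1, 1, 1, 1, 2, 1, 1),
    ("D", 1, 2, 2, 0, 0, 3, 3, 0),
]


def worked_example_scores(case_id: str = "case-1") -> pd.DataFrame:
    """Score table (long format) for the published worked-example case."""
    return pd.DataFrame(
        [
            {
                "case_id": case_id, "rater_id": r,
                "ff": ff, "smh": smh, "cip": cip, "dpvc": dpvc,
                "fat": fat, "plasm": plasm, "lygc": lygc, "af": af,
            }
            for r, ff, smh, cip, dpvc, fat, plasm, lygc, af in _WORKED_EXAMPLE
        ]
    )
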