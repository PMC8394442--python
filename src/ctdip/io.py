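"""CSV interchange, pipeline configuration and the end-to-end report.

CSV (UTF-8, header row, comma separator, "." decimal) is the single
interchange format; YAML/JSON appear only in configuration files.
``case_id`` and ``rater_id`` are opaque strings with no ordering
semantics.

Schemas
-------
scores.csv    case_id, rater_id, ff, smh, cip, dpvc, fat, plasm, lygc, af
              (integers 0-3; scored output adds z, p, label, with p and z
              rounded to 4 decimals in files)
clinical.csv  case_id + binary covariates (0/1, blank = missing) +
              continuous covariates (numeric, blank = missing)
groups.csv    case_id, n_raters, n_ctd_votes, group, unanimous,
              ipaf_morphology_consensus
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agreement_mod
from . import consensus as consensus_mod
from . import group_comparison as gc_mod
from .scoring import (
    DEFAULT_COEFFICIENTS,
    ITEM_NAMES,
    IndexCoefficients,
    score_table,
)

__all__ = [
    "SCORE_COLUMNS",
    "SchemaError",
    "PipelineConfig",
    "read_scores",
    "read_clinical",
    "write_scored",
    "run_report",
]

logger = logging.getLogger("ctdip")

SCORE_COLUMNS: tuple[str, ...] = ("case_id", "rater_id") + ITEM_NAMES


class SchemaError(ValueError):
    """A CSV input violates its schema; message carries file line numbers."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"case_id": str, "rater_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no records (empty file)") from None
    if df.empty:
        raise SchemaError(f"{path}: no records (header only)")
    return df


def read_scores(path) -> pd.DataFrame:
    """Read and validate a long-format score table.

    Errors carry the offending column and 1-based file line number
    (header is line 1).  Duplicate (case_id, rater_id) pairs are
    rejected.
    """
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    for item in ITEM_NAMES:
        col = pd.to_numeric(df[item], errors="coerce")
        bad = col.isna() | (col != col.round()) | (col < 0) | (col > 3)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}, line {row + 2}: item {item!r} has invalid score "
                f"{df[item].iloc[row]!r} (integer 0-3 required)"
            )
        df[item] = col.astype(int)
    dup = df.duplicated(subset=["case_id", "rater_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = (df["case_id"].iloc[row], df["rater_id"].iloc[row])
        raise SchemaError(f"{path}, line {row + 2}: duplicate (case_id, rater_id) {key}")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical covariate table; blanks are missing values."""
    path = Path(path)
    df = _read_csv(path)
    if "case_id" not in df.columns:
        raise SchemaError(f"{path}: missing column(s): case_id")
    dup = df.duplicated(subset=["case_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"{path}, line {row + 2}: duplicate case_id {df['case_id'].iloc[row]!r}"
        )
    return df


def write_scored(df: pd.DataFrame, path, p_decimals: int = 4) -> None:
    """Write a scored table; z and p rounded for display, label verbatim."""
    out = df.copy()
    for col in ("z", "p"):
        if col in out.columns:
            out[col] = out[col].astype(float).round(p_decimals)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings shared by every pipeline stage.

    Defaults reproduce the published analysis: threshold 0.5, the
    published coefficients, minimum-likelihood Fisher, pooled t,
    Fleiss' kappa.
    """

    threshold: float = 0.5
    coefficients: IndexCoefficients = field(default_factory=IndexCoefficients)
    fisher_method: str = "minlike"
    t_variant: str = "pooled"
    kappa_method: str = "fleiss"
    p_decimals: int = 4
    pvalue_decimals: int = 2
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "coefficients": self.coefficients.to_dict(),
            "fisher_method": self.fisher_method,
            "t_variant": self.t_variant,
            "kappa_method": self.kappa_method,
            "p_decimals": self.p_decimals,
            "pvalue_decimals": self.pvalue_decimals,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_report(
    scores_path,
    clinical_path,
    out_dir,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full pipeline: score, classify, agreement, group comparison.

    Writes scored.csv, groups.csv, agreement.csv, table2.csv and
    run_log.json under ``out_dir`` and returns the paths plus the log
    dictionary.  Deterministic given inputs and config.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "inputs": {
            "scores": {"path": str(scores_path), "sha256": _file_digest(scores_path)},
            "clinical": {
                "path": str(clinical_path),
                "sha256": _file_digest(clinical_path),
            },
        },
        "stages": {},
    }

    scores = read_scores(scores_path)
    log["stages"]["read"] = {
        "n_rows": len(scores),
        "n_cases": scores["case_id"].nunique(),
        "n_raters": scores["rater_id"].nunique(),
    }

    scored = score_table(scores, config.coefficients, config.threshold)
    write_scored(scored, out_dir / "scored.csv", config.p_decimals)
    log["stages"]["score"] = {
        "n_ctdip_labels": int((scored["label"] == "CTD-IP").sum()),
    }

    groups = consensus_mod.classify_cohort(scored)
    groups.to_csv(out_dir / "groups.csv", index=False)
    log["stages"]["classify"] = {
        "n_cases": len(groups),
        "n_ctd_group": int((groups["group"] == "CTD").sum()),
        "n_ipaf_consensus": int(groups["ipaf_morphology_consensus"].sum()),
    }

    agree = agreement_mod.agreement_report(
        scored, config.coefficients, config.threshold, method=config.kappa_method
    )
    agree.to_csv(out_dir / "agreement.csv", index=False)
    log["stages"]["agree"] = {"n_subjects": len(agree)}

    clinical = read_clinical(clinical_path)
    missing = sorted(set(groups["case_id"]) - set(clinical["case_id"]))
    if missing:
        raise SchemaError(
            f"clinical table missing case(s) present in scores: {', '.join(missing)}"
        )
    clinical = clinical[clinical["case_id"].isin(groups["case_id"])]
    table2_path: Path | None = out_dir / "table2.csv"
    n_groups = groups["group"].nunique()
    if n_groups < 2:
        # a one-group cohort (e.g. a single case) has nothing to compare;
        # classification and agreement outputs above are still valid
        log["stages"]["compare"] = {
            "skipped": f"only {n_groups} consensus group(s) present"
        }
        table2_path = None
    else:
        table2 = gc_mod.compare_groups(
            clinical, groups,
            t_variant=config.t_variant, fisher_method=config.fisher_method,
        )
        table2.to_csv(table2_path, index=False)
        log["stages"]["compare"] = {"n_variables": len(table2)}

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    logger.info("report written to %s (config %s)", out_dir, config.digest())
    return {
        "scored": out_dir / "scored.csv",
        "groups": out_dir / "groups.csv",
        "agreement": out_dir / "agreement.csv",
        "table2": table2_path,
        "run_log": log_path,
        "log": log,
    }
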