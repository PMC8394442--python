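"""Synthetic multi-rater cohort generator.

No per-case data accompany the published validation cohort, so every
pipeline stage is exercised on cohorts drawn from a two-latent-class
model that carries the statistical structure the analysis assumes:

* each case belongs to a latent "ctd" or "idiopathic" class (Bernoulli
  prevalence);
* the case's *true* eight-item histology profile is drawn from
  class-conditional categorical distributions over the 0-3 scale;
* each rater observes the true score independently perturbed: with
  probability ``rater_noise_eps`` (per item) the observed grade moves
  one ordinal step toward 0 or 3 with equal odds, clamped at the
  boundary (so at 0 the only feasible step is up, at 3 down);
* binary clinical covariates are class-conditional Bernoulli draws and
  continuous covariates class-conditional Gaussians.

Randomness is structured so that each case owns a deterministic
sub-stream derived from (seed, case index), and each rater's
perturbations from (seed, case index, rater index): adding raters or
covariates never reshuffles the cases already drawn, and identical
configurations give byte-identical output tables.

The default configuration (``SyntheticCohortConfig.default()``) lives
in a versioned YAML file and mirrors the published cohort's frame: 94
cases, 4 raters, prevalence ~20/94, binary covariate rates and
continuous mean/sd pairs per class.  Class-conditional item
distributions are calibrated only so the index separates the classes
in the right direction; they are not fitted to any published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import ITEM_NAMES

__all__ = [
    "CLASSES",
    "SyntheticCohortConfig",
    "CohortData",
    "rater_perturb",
    "generate_cohort",
    "null_clinical_config",
]

CLASSES = ("ctd", "idiopathic")


def _check_probvec(name: str, vec) -> list[float]:
    v = [float(x) for x in vec]
    if len(v) != 4 or any(x < 0 for x in v) or abs(sum(v) - 1.0) > 1e-9:
        raise ValueError(f"{name}: probability vector over scores 0-3 must be "
                         f"length 4, non-negative, summing to 1 (got {vec!r})")
    return v


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full description of one synthetic cohort draw.

    ``item_dists`` maps item -> class -> probability vector over scores
    {0,1,2,3}; ``covariate_probs`` maps binary covariate -> class ->
    Bernoulli probability; ``continuous_params`` maps covariate ->
    class -> (mean, sd).
    """

    n_cases: int
    n_raters: int
    prevalence: float
    item_dists: Mapping[str, Mapping[str, list[float]]]
    rater_noise_eps: float
    covariate_probs: Mapping[str, Mapping[str, float]]
    continuous_params: Mapping[str, Mapping[str, tuple[float, float]]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_raters < 1:
            raise ValueError("n_cases and n_raters must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence!r} outside [0, 1]")
        if not 0.0 <= self.rater_noise_eps <= 1.0:
            raise ValueError(f"rater_noise_eps {self.rater_noise_eps!r} outside [0, 1]")
        dists = {}
        for item in ITEM_NAMES:
            if item not in self.item_dists:
                raise ValueError(f"item_dists missing item {item!r}")
            dists[item] = {
                cls: _check_probvec(f"item_dists[{item}][{cls}]",
                                    self.item_dists[item][cls])
                for cls in CLASSES
            }
        object.__setattr__(self, "item_dists", dists)
        for cov, per_class in self.covariate_probs.items():
            for cls in CLASSES:
                p = float(per_class[cls])
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"covariate_probs[{cov}][{cls}]={p} outside [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping, **overrides) -> "SyntheticCohortConfig":
        d = {**d, **overrides}
        return cls(
            n_cases=int(d["n_cases"]),
            n_raters=int(d["n_raters"]),
            prevalence=float(d["prevalence"]),
            item_dists=d["item_dists"],
            rater_noise_eps=float(d["rater_noise_eps"]),
            covariate_probs=d["covariate_probs"],
            continuous_params={
                k: {c: (float(v[0]), float(v[1])) for c, v in per.items()}
                for k, per in d["continuous_params"].items()
            },
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), **overrides)

    @classmethod
    def default(cls, **overrides) -> "SyntheticCohortConfig":
        """The versioned default configuration (see package data)."""
        text = resources.files("ctdip").joinpath("data/default_cohort.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text), **overrides)

    def with_(self, **overrides) -> "SyntheticCohortConfig":
        return replace(self, **overrides)


@dataclass(frozen=True)
class CohortData:
    """One generated cohort: latent truth, rating table, clinical table."""

    truth: pd.DataFrame     # case_id, latent_class, true item scores
    scores: pd.DataFrame    # case_id, rater_id, eight item columns
    clinical: pd.DataFrame  # case_id + clinical covariates


def rater_perturb(true_score: int, eps: float, rng: np.random.Generator) -> int:
    """Observe one grade through symmetric one-step ordinal noise.

    With probability 1-eps the true grade is returned; with probability
    eps it moves one step toward 0 or toward 3 with equal odds, clamped
    at the boundary so the step collapses to the only feasible
    direction (a true 0 can only go to 1, a true 3 only to 2).
    """
    if not 0 <= true_score <= 3:
        raise ValueError(f"true_score {true_score} outside the 0-3 scale")
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps {eps!r} outside [0, 1]")
    if rng.random() >= eps:
        return int(true_score)
    step = -1 if rng.random() < 0.5 else 1
    return int(min(3, max(0, true_score + step))) if 0 < true_score < 3 else (
        1 if true_score == 0 else 2
    )


def generate_cohort(config: SyntheticCohortConfig) -> CohortData:
    """Draw one cohort under the two-latent-class model.

    Reproducible: identical config (including seed) gives identical
    tables, cell for cell.
    """
    scores_lvls = np.arange(4)
    truth_rows, score_rows, clin_rows = [], [], []
    for i in range(config.n_cases):
        case_id = f"C{i + 1:04d}"
        case_rng = np.random.default_rng([config.seed, i])
        latent = "ctd" if case_rng.random() < config.prevalence else "idiopathic"
        true_scores = {
            item: int(case_rng.choice(scores_lvls, p=config.item_dists[item][latent]))
            for item in ITEM_NAMES
        }
        truth_rows.append({"case_id": case_id, "latent_class": latent, **true_scores})

        for j in range(config.n_raters):
            rater_rng = np.random.default_rng([config.seed, i, j])
            observed = {
                item: rater_perturb(true_scores[item], config.rater_noise_eps, rater_rng)
                for item in ITEM_NAMES
            }
            score_rows.append(
                {"case_id": case_id, "rater_id": f"R{j + 1}", **observed}
            )

        clin = {"case_id": case_id}
        for cov in sorted(config.covariate_probs):
            p = config.covariate_probs[cov][latent]
            clin[cov] = int(case_rng.random() < p)
        for cov in sorted(config.continuous_params):
            mean, sd = config.continuous_params[cov][latent]
            clin[cov] = float(np.round(case_rng.normal(mean, sd), 4))
        clin_rows.append(clin)

    return CohortData(
        truth=pd.DataFrame(truth_rows),
        scores=pd.DataFrame(score_rows),
        clinical=pd.DataFrame(clin_rows),
    )


def null_clinical_config(base: SyntheticCohortConfig | None = None,
                         **overrides) -> SyntheticCohortConfig:
    """A configuration with no class effect on any clinical covariate.

    Histology (and therefore group assignment) keeps its class
    structure, but every clinical covariate is drawn from the same
    distribution in both classes — the null hypothesis of the group
    comparison stage.  Pooled rates/moments from the default config's
    idiopathic class are used for both classes.
    """
    base = base or SyntheticCohortConfig.default()
    cov = {k: {c: per["idiopathic"] for c in CLASSES}
           for k, per in base.covariate_probs.items()}
    cont = {k: {c: per["idiopathic"] for c in CLASSES}
            for k, per in base.continuous_params.items()}
    return base.with_(covariate_probs=cov, continuous_params=cont, **overrides)
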