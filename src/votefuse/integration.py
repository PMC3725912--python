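"""Balanced-subsampling, attribute-separated majority-vote integration.

The ensemble keeps the two attribute blocks (genotype, cytokine) separate
until the last step:

1. draw a balanced subset of the training cohort — sampling_size/2 cases and
   sampling_size/2 controls, without replacement, independently per class;
2. train the chosen base classifier on that subset's *genotype* features;
3. repeat K times for the genotype pool;
4. repeat N times on *cytokine* features for the cytokine pool;
5. every predictor votes case (positive) or control (negative) on each test
   sample;
6. the simple majority of the K + N votes is the final call.

K = N + 1 (assigned to the genotype pool, the larger attribute block) makes
the total vote count odd, so a tie vote is impossible.  One master seed
drives a single documented RNG stream: the K genotype subsets are drawn
first, then the N cytokine subsets.  Every predictor must vote on every
sample — an unscorable sample is a hard error, never an abstention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .base_classifiers import BaseClassifierSpec, FittedPredictor, train
from .io_model import CASE, CONTROL, LabeledCohort, RunConfig, ValidationError

#: attempts at refitting on a fresh subset when a draw is degenerate
MAX_TRAIN_RETRIES = 10


@dataclass
class BalancedSubset:
    """Equal numbers of case and control ids drawn without replacement."""

    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self):
        if len(self.case_ids) != len(self.control_ids):
            raise ValidationError("balanced subset has unequal class counts")
        if len(set(self.case_ids)) != len(self.case_ids) or len(
            set(self.control_ids)
        ) != len(self.control_ids):
            raise ValidationError("balanced subset contains duplicate ids")

    @property
    def ids(self) -> list[str]:
        return self.case_ids + self.control_ids


@dataclass
class IntegrationModel:
    genotype_pool: list[FittedPredictor]
    cytokine_pool: list[FittedPredictor]
    config: RunConfig
    subset_log: list[BalancedSubset] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.genotype_pool)

    @property
    def n(self) -> int:
        return len(self.cytokine_pool)

    def __post_init__(self):
        if self.k != self.n + 1:
            raise ValidationError(
                f"genotype pool K={self.k} must equal cytokine pool N+1={self.n + 1}"
            )


@dataclass
class PredictionSummary:
    """Per-sample vote counts, positive ratios and final majority calls."""

    table: pd.DataFrame  # geno_votes, cyto_votes, r_g, r_c, final_call
    k: int
    n: int

    @property
    def final_calls(self) -> pd.Series:
        return self.table["final_call"]

    def genotype_only_calls(self) -> pd.Series:
        """Majority of the genotype pool alone; vote ties -> control."""
        pos = self.table["geno_votes"] * 2 > self.k
        return pd.Series(np.where(pos, CASE, CONTROL), index=self.table.index)

    def cytokine_only_calls(self) -> pd.Series:
        """Majority of the cytokine pool alone; vote ties -> control."""
        pos = self.table["cyto_votes"] * 2 > self.n
        return pd.Series(np.where(pos, CASE, CONTROL), index=self.table.index)

    def to_csv(self, path, truth: Optional[pd.Series] = None) -> None:
        out = self.table.copy()
        if truth is not None:
            out["true_label"] = truth.reindex(out.index)
        out.to_csv(path, index_label="sample_id")


def draw_balanced_subset(
    training: LabeledCohort, sampling_size: int, rng: np.random.Generator
) -> BalancedSubset:
    """Uniform without-replacement draw of size/2 per class."""
    if sampling_size % 2 or sampling_size <= 0:
        raise ValidationError("sampling_size must be an even positive integer")
    half = sampling_size // 2
    cases, controls = training.case_ids, training.control_ids
    if half > len(cases) or half > len(controls):
        raise ValidationError(
            f"sampling_size {sampling_size} exceeds class counts "
            f"({len(cases)} cases / {len(controls)} controls)"
        )
    pick_cases = list(rng.choice(cases, size=half, replace=False))
    pick_controls = list(rng.choice(controls, size=half, replace=False))
    return BalancedSubset(pick_cases, pick_controls)


def _fit_pool(
    training: LabeledCohort,
    X: pd.DataFrame,
    n_predictors: int,
    config: RunConfig,
    rng: np.random.Generator,
    subset_log: list[BalancedSubset],
) -> list[FittedPredictor]:
    pool = []
    spec = BaseClassifierSpec(config.classifier)
    for _ in range(n_predictors):
        last_err: Exception | None = None
        for _attempt in range(MAX_TRAIN_RETRIES):
            subset = draw_balanced_subset(training, config.sampling_size, rng)
            try:
                model = train(
                    spec, X.loc[subset.ids], training.labels.loc[subset.ids],
                    seed=config.seed,
                )
            except Exception as exc:  # degenerate subset: resample
                last_err = exc
                continue
            subset_log.append(subset)
            pool.append(model)
            break
        else:
            raise ValidationError(
                f"base training failed on {MAX_TRAIN_RETRIES} fresh subsets: {last_err}"
            )
    return pool


def fit_integration(
    training: LabeledCohort,
    genotype_X: pd.DataFrame,
    cytokine_X: pd.DataFrame,
    config: RunConfig,
    rng: Optional[np.random.Generator] = None,
) -> IntegrationModel:
    """Fit the K = N+1 genotype and N cytokine predictor pools.

    ``genotype_X`` / ``cytokine_X`` are the preprocessed training feature
    frames (rows = cohort samples).  ``rng`` defaults to a fresh generator
    seeded with ``config.seed``.
    """
    n = config.sampling_time
    k = n + 1
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for name, X in (("genotype", genotype_X), ("cytokine", cytokine_X)):
        if not set(training.sample_ids) <= set(X.index):
            raise ValidationError(f"{name} features do not cover the training cohort")
    log: list[BalancedSubset] = []
    geno_pool = _fit_pool(training, genotype_X, k, config, rng, log)
    cyto_pool = _fit_pool(training, cytokine_X, n, config, rng, log)
    return IntegrationModel(geno_pool, cyto_pool, config, log)


def predict_integration(
    model: IntegrationModel,
    genotype_X_test: pd.DataFrame,
    cytokine_X_test: pd.DataFrame,
) -> PredictionSummary:
    """Vote counts, positive ratios and the fused majority call per sample."""
    if list(genotype_X_test.index) != list(cytokine_X_test.index):
        raise ValidationError("test attribute frames are not sample-aligned")
    k, n = model.k, model.n
    geno_votes = np.zeros(len(genotype_X_test), dtype=int)
    for p in model.genotype_pool:
        geno_votes += p.predict(genotype_X_test) == CASE
    cyto_votes = np.zeros(len(cytokine_X_test), dtype=int)
    for p in model.cytokine_pool:
        cyto_votes += p.predict(cytokine_X_test) == CASE
    total = geno_votes + cyto_votes
    final = np.where(total * 2 > k + n, CASE, CONTROL)
    table = pd.DataFrame(
        {
            "geno_votes": geno_votes,
            "cyto_votes": cyto_votes,
            "r_g": geno_votes / k,
            "r_c": cyto_votes / n,
            "final_call": final,
        },
        index=genotype_X_test.index,
    )
    return PredictionSummary(table, k, n)
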