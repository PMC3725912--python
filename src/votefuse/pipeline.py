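"""End-to-end composition of the preprocessing and integration stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import cytokine_prep, genotype_prep
from .integration import IntegrationModel, PredictionSummary, fit_integration, predict_integration
from .io_model import LabeledCohort, RawGenotypeTable, RunConfig, ValidationError


@dataclass
class PreprocessResult:
    """Training-fitted preprocessing applied to both cohorts."""

    geno_train: pd.DataFrame
    geno_test: pd.DataFrame
    cyto_train: pd.DataFrame
    cyto_test: pd.DataFrame
    encodings: dict[str, genotype_prep.MarkerEncoding]
    prune_report: genotype_prep.LdPruneReport
    genotype_dropped: list[dict]
    qc_report: cytokine_prep.CytokineQcReport
    train_params: cytokine_prep.StandardizationParams
    test_params: cytokine_prep.StandardizationParams


def preprocess_cohorts(
    train: LabeledCohort,
    test: LabeledCohort,
    config: Optional[RunConfig] = None,
) -> PreprocessResult:
    """LD-prune, encode and normalize genotypes; QC and standardize cytokines.

    Marker pruning is panel-level (run on train + test calls pooled, before
    any modelling); risk alleles, normalization statistics and the kept
    cytokine list are fitted on the training set only, while the cytokine
    control anchor (m_i, s_i) is refit on each data set's own controls.
    """
    config = config or RunConfig()
    if train.genotype is None or train.cytokine is None:
        raise ValidationError("training cohort needs genotype and cytokine tables")
    if test.genotype is None or test.cytokine is None:
        raise ValidationError("test cohort needs genotype and cytokine tables")

    pooled = RawGenotypeTable(
        pd.concat([train.genotype.calls, test.genotype.calls]),
        dict(train.genotype.markers),
    )
    prune = genotype_prep.ld_prune(pooled, threshold=config.ld_r2)
    kept_train = RawGenotypeTable(
        train.genotype.calls[prune.kept],
        {m: train.genotype.markers[m] for m in prune.kept},
    )
    encodings, geno_dropped = genotype_prep.fit_encodings(kept_train, train.labels)
    kept = list(encodings)
    geno_train = genotype_prep.apply_normalization(
        RawGenotypeTable(train.genotype.calls[kept],
                         {m: train.genotype.markers[m] for m in kept}),
        encodings,
    ).values
    geno_test = genotype_prep.apply_normalization(
        RawGenotypeTable(test.genotype.calls[kept],
                         {m: test.genotype.markers[m] for m in kept}),
        encodings,
    ).values

    qc = cytokine_prep.run_qc(
        train.cytokine, train.labels,
        config.qc_missing_frac, config.qc_zero_frac, config.t_alpha,
    )
    if not qc.kept:
        raise ValidationError(
            "no cytokine analyte survived QC on the training set; "
            "relax the thresholds or inspect the assay"
        )
    train_params = cytokine_prep.fit_standardization(
        train.cytokine, train.labels, qc.kept
    )
    cyto_train = cytokine_prep.standardize(train.cytokine, train_params, qc).values
    test_params = cytokine_prep.fit_standardization(
        test.cytokine, test.labels, qc.kept
    )
    cyto_test = cytokine_prep.standardize(test.cytokine, test_params).values

    return PreprocessResult(
        geno_train, geno_test, cyto_train, cyto_test,
        encodings, prune, geno_dropped, qc, train_params, test_params,
    )


def run_integration(
    train: LabeledCohort,
    test: LabeledCohort,
    prep: PreprocessResult,
    config: RunConfig,
) -> tuple[IntegrationModel, PredictionSummary]:
    """Fit one integration model and predict the test cohort."""
    model = fit_integration(train, prep.geno_train, prep.cyto_train, config)
    summary = predict_integration(model, prep.geno_test, prep.cyto_test)
    return model, summary
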