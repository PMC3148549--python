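"""Null controls for the prediction pipeline: permutation and random-SNP.

The permutation control shuffles the training outcome labels (keeping every
predictor attached to its sample), re-runs SNP selection and model building
end-to-end on the permuted labels, and scores the untouched replication set;
under the null the replication AUC should sit at 0.5.  The random-SNP
control replaces the importance-selected SNPs with k SNPs drawn uniformly
from the panel; any residual AUC above 0.5 then comes from the clinical
covariates.  Both controls default to 10 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from exacerf.evaluation import AUCResult, auc
from exacerf.prediction_pipeline import (
    ModelSpec,
    build_prediction_model,
)
from exacerf.rf_screening import (
    RFConfig,
    ScreeningConfig,
    chunked_importance_scan,
    rerank_top,
    select_top,
)
from exacerf.synthetic_data import CohortBundle


@dataclass
class ControlConfig:
    n_iterations: int = 10
    control_type: str = "permutation"
    seed: int = 0
    reuse_selection: bool = False  # permutation control: skip re-screening

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.control_type not in ("permutation", "random_snp"):
            raise ValueError(f"unknown control type {self.control_type!r}")


@dataclass
class ControlResult:
    """Per-iteration AUCs plus their mean, and the SNP sets each model used."""

    auc_results: list[AUCResult]
    selected_snps: list[list[str]]

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.auc_results])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.auc_results) + 1),
                "auc": self.aucs,
                "p_value": [r.p_value for r in self.auc_results],
            }
        )


def permutation_control(
    train_bundle: CohortBundle,
    test_bundle: CohortBundle,
    k: int,
    rf_config: RFConfig,
    screening_config: ScreeningConfig,
    control_config: ControlConfig,
    include_clinical: bool = True,
    precomputed_records: pd.DataFrame | None = None,
) -> ControlResult:
    """Permute training labels, redo selection + model building, score stage 2.

    Each iteration permutes the stage-1 outcome uniformly at random, re-runs
    the two-step importance screening on the permuted labels (unless
    ``control_config.reuse_selection`` is set, in which case
    ``precomputed_records`` supplies a fixed ranking), builds the top-k (+
    clinical) model, and evaluates AUC on the unpermuted test set.
    """
    rng = np.random.default_rng(control_config.seed)
    if control_config.reuse_selection and precomputed_records is None:
        raise ValueError("reuse_selection requires precomputed_records")
    results: list[AUCResult] = []
    selections: list[list[str]] = []
    for it in range(control_config.n_iterations):
        perm = rng.permutation(len(train_bundle.phenotype))
        y_perm = train_bundle.phenotype[perm]
        iter_seed = int(rng.integers(2**31))
        iter_rf = rf_config.with_seed(iter_seed)
        if control_config.reuse_selection:
            records = precomputed_records
        else:
            records = chunked_importance_scan(
                train_bundle.genotypes, y_perm, iter_rf, screening_config
            )
            records = rerank_top(
                records, train_bundle.genotypes, y_perm, iter_rf, screening_config
            )
        snp_ids = select_top(records, k)
        spec = ModelSpec(
            snp_ids=snp_ids, include_clinical=include_clinical, rf_config=iter_rf
        )
        permuted_train = CohortBundle(
            genotypes=train_bundle.genotypes,
            covariates=train_bundle.covariates,
            phenotype=y_perm,
        )
        model = build_prediction_model(permuted_train, spec)
        results.append(auc(model.score(test_bundle), test_bundle.phenotype))
        selections.append(snp_ids)
    return ControlResult(auc_results=results, selected_snps=selections)


def random_snp_control(
    train_bundle: CohortBundle,
    test_bundle: CohortBundle,
    k: int,
    rf_config: RFConfig,
    control_config: ControlConfig,
    include_clinical: bool = True,
) -> ControlResult:
    """Model built on k uniformly random panel SNPs (plus clinical per flag)."""
    panel = train_bundle.genotypes.snp_ids
    if k > len(panel):
        raise ValueError(f"k={k} exceeds panel size {len(panel)}")
    rng = np.random.default_rng(control_config.seed)
    results: list[AUCResult] = []
    selections: list[list[str]] = []
    for it in range(control_config.n_iterations):
        snp_ids = [panel[j] for j in rng.choice(len(panel), size=k, replace=False)]
        iter_rf = rf_config.with_seed(int(rng.integers(2**31)))
        spec = ModelSpec(
            snp_ids=snp_ids, include_clinical=include_clinical, rf_config=iter_rf
        )
        model = build_prediction_model(train_bundle, spec)
        results.append(auc(model.score(test_bundle), test_bundle.phenotype))
        selections.append(snp_ids)
    return ControlResult(auc_results=results, selected_snps=selections)
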