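"""Top-k SNP + clinical-trait forests: training, internal CV, replication.

Models combine the stage-2 top-k SNPs with the four clinical covariates
(age, sex, FEV1 % predicted, treatment group) and are scored by the fraction
of trees voting "case".  Missing genotypes — in the replication stage and,
where present, in training — are imputed by drawing from each SNP's genotype
frequency distribution among the training controls.  ``run_snp_ladder``
sweeps the SNP-count ladder (clinical-only, then 10/40/160/320 by default),
reporting training, internal-cross-validation and independent-replication
AUC per rung.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from exacerf.evaluation import AUCResult, auc
from exacerf.genotype_io import (
    MISSING,
    COVARIATE_COLUMNS,
    GenotypeMatrix,
    encode_additive,
)
from exacerf.rf_screening import ForestModel, RFConfig, ScreeningConfig, fit_forest, select_top
from exacerf.synthetic_data import CohortBundle


@dataclass
class ModelSpec:
    """Which features go into one prediction model."""

    snp_ids: list[str] = field(default_factory=list)
    include_clinical: bool = True
    rf_config: RFConfig = field(default_factory=RFConfig)


@dataclass
class PredictionModel:
    """A fitted forest plus the feature recipe needed to score new samples."""

    forest: ForestModel
    spec: ModelSpec
    feature_names: list[str]

    def score(self, bundle: CohortBundle) -> np.ndarray:
        return self.forest.vote_fractions(assemble_features(bundle, self.spec))


def impute_missing_from_controls(
    target: GenotypeMatrix, controls: GenotypeMatrix, seed: int
) -> GenotypeMatrix:
    """Impute missing calls by sampling from control genotype frequencies.

    Each MISSING cell is replaced by a draw from {0, 1, 2} with probabilities
    equal to that SNP's observed genotype frequencies among the non-missing
    control calls.  Non-missing cells are untouched; the draw is
    deterministic given ``seed``.  A SNP with zero non-missing control calls
    falls back to the pooled genotype distribution over all control cells.
    """
    if target.snp_ids != controls.snp_ids:
        raise ValueError("target and control SNP panels are not aligned")
    rng = np.random.default_rng(seed)
    counts = target.counts.copy()
    ctrl = controls.counts
    pooled = np.array([(ctrl == g).sum() for g in (0, 1, 2)], dtype=float)
    if pooled.sum() == 0:
        raise ValueError("control matrix has no non-missing calls at all")
    pooled /= pooled.sum()
    for j in range(target.n_snps):
        miss = counts[:, j] == MISSING
        if not miss.any():
            continue
        col = ctrl[:, j]
        freq = np.array([(col == g).sum() for g in (0, 1, 2)], dtype=float)
        total = freq.sum()
        if total == 0:
            warnings.warn(
                f"SNP {target.snps[j].snp_id}: no non-missing control calls; "
                "imputing from pooled control frequencies"
            )
            prob = pooled
        else:
            prob = freq / total
        counts[miss, j] = rng.choice(3, size=int(miss.sum()), p=prob)
    return GenotypeMatrix(
        samples=list(target.samples), snps=list(target.snps), counts=counts
    )


def impute_bundle(
    bundle: CohortBundle, train_bundle: CohortBundle, seed: int
) -> CohortBundle:
    """Impute a bundle's missing genotypes from the training controls."""
    controls = train_bundle.genotypes.subset_samples(train_bundle.phenotype == 0)
    return CohortBundle(
        genotypes=impute_missing_from_controls(bundle.genotypes, controls, seed),
        covariates=bundle.covariates,
        phenotype=bundle.phenotype,
    )


def assemble_features(bundle: CohortBundle, spec: ModelSpec) -> np.ndarray:
    """Selected SNP columns (in spec order) plus clinical covariates if enabled."""
    blocks = []
    if spec.snp_ids:
        blocks.append(encode_additive(bundle.genotypes.subset_snps(spec.snp_ids)))
    if spec.include_clinical:
        blocks.append(bundle.covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float))
    if not blocks:
        raise ValueError("model spec selects no features")
    return np.hstack(blocks)


def build_prediction_model(train_bundle: CohortBundle, spec: ModelSpec) -> PredictionModel:
    """Fit the forest over (top-k SNPs || clinical covariates) on stage 1."""
    features = assemble_features(train_bundle, spec)
    forest = fit_forest(features, train_bundle.phenotype, spec.rf_config)
    names = list(spec.snp_ids) + (
        list(COVARIATE_COLUMNS) if spec.include_clinical else []
    )
    return PredictionModel(forest=forest, spec=spec, feature_names=names)


def predict_scores(model: PredictionModel, bundle: CohortBundle) -> np.ndarray:
    """Per-sample vote fractions in [0, 1], granularity 1/ntree."""
    return model.score(bundle)


def _subset_bundle(bundle: CohortBundle, idx: np.ndarray) -> CohortBundle:
    mask = np.zeros(len(bundle.phenotype), dtype=bool)
    mask[idx] = True
    return CohortBundle(
        genotypes=bundle.genotypes.subset_samples(mask),
        covariates=bundle.covariates.iloc[np.sort(idx)],
        phenotype=bundle.phenotype[np.sort(idx)],
    )


def internal_cross_validation(
    train_bundle: CohortBundle, spec: ModelSpec, seed: int
) -> AUCResult:
    """One stratified 90/10 split: fit on 90%, AUC on the held-out 10%."""
    n = len(train_bundle.phenotype)
    idx = np.arange(n)
    fit_idx, hold_idx = train_test_split(
        idx,
        test_size=0.1,
        stratify=train_bundle.phenotype,
        random_state=seed % (2**31),
    )
    model = build_prediction_model(_subset_bundle(train_bundle, fit_idx), spec)
    hold = _subset_bundle(train_bundle, hold_idx)
    return auc(model.score(hold), hold.phenotype)


def independent_replication(
    train_bundle: CohortBundle, test_bundle: CohortBundle, spec: ModelSpec
) -> AUCResult:
    """Fit on all of stage 1; AUC (with SE and p vs 0.5) on stage 2 scores."""
    if len(np.unique(test_bundle.phenotype)) < 2:
        raise ValueError("test outcome is single-class; AUC undefined")
    model = build_prediction_model(train_bundle, spec)
    return auc(model.score(test_bundle), test_bundle.phenotype)


def run_snp_ladder(
    train_bundle: CohortBundle,
    test_bundle: CohortBundle,
    stage2_records: pd.DataFrame,
    screening_config: ScreeningConfig,
    rf_config: RFConfig,
    include_clinical: bool = True,
    cv_seed: int | None = None,
) -> pd.DataFrame:
    """Sweep the SNP-count ladder: k = 0 (clinical-only) plus each top-k model.

    For each rung: training AUC (fit on stage 1, score stage 1), one
    stratified 90/10 internal-CV AUC, and the independent-replication AUC on
    stage 2.  Returns one row per rung.  ``include_clinical=False`` gives the
    SNPs-only ladder (k = 0 is then skipped).
    """
    pool = int(stage2_records["stage2_rank"].notna().sum())
    sizes = [0] if include_clinical else []
    for k in screening_config.selection_sizes:
        if k > pool:
            warnings.warn(f"k={k} exceeds stage-2 pool {pool}; clipping")
            k = pool
        if k not in sizes:
            sizes.append(k)
    if cv_seed is None:
        cv_seed = rf_config.seed
    rows = []
    for k in sizes:
        snp_ids = select_top(stage2_records, k) if k > 0 else []
        spec = ModelSpec(
            snp_ids=snp_ids, include_clinical=include_clinical, rf_config=rf_config
        )
        model = build_prediction_model(train_bundle, spec)
        train_auc = auc(model.score(train_bundle), train_bundle.phenotype)
        cv_auc = internal_cross_validation(train_bundle, spec, seed=cv_seed + k)
        repl_auc = auc(model.score(test_bundle), test_bundle.phenotype)
        rows.append(
            {
                "n_snps": k,
                "include_clinical": include_clinical,
                "train_auc": train_auc.auc,
                "cv_auc": cv_auc.auc,
                "replication_auc": repl_auc.auc,
                "replication_se": repl_auc.se,
                "replication_p": repl_auc.p_value,
            }
        )
    return pd.DataFrame(rows)
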