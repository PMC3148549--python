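"""Control-frequency imputation, model building, CV and replication."""

import numpy as np
import pytest

from exacerf.genotype_io import MISSING, GenotypeMatrix, SNPMeta
from exacerf.prediction_pipeline import (
    ModelSpec,
    build_prediction_model,
    impute_missing_from_controls,
    independent_replication,
    internal_cross_validation,
    predict_scores,
    run_snp_ladder,
)
from exacerf.rf_screening import chunked_importance_scan, rerank_top
from exacerf.synthetic_data import CohortBundle


def _matrix(counts, n_snps=None, prefix="s"):
    counts = np.asarray(counts, dtype=np.int8)
    n, p = counts.shape
    snps = [SNPMeta(f"rs{j}", "1", 100 + j, "A", "G") for j in range(p)]
    return GenotypeMatrix(
        samples=[f"{prefix}{i}" for i in range(n)], snps=snps, counts=counts
    )


class TestImputation:
    def test_degenerate_controls_impute_zero(self):
        controls = _matrix(np.zeros((20, 1)))
        target = _matrix(np.full((10, 1), MISSING), prefix="t")
        out = impute_missing_from_controls(target, controls, seed=1)
        assert (out.counts == 0).all()

    def test_no_missing_is_identity(self):
        controls = _matrix(np.random.default_rng(0).integers(0, 3, (20, 3)))
        target = _matrix(
            np.random.default_rng(1).integers(0, 3, (10, 3)), prefix="t"
        )
        out = impute_missing_from_controls(target, controls, seed=1)
        assert out == target

    def test_imputed_frequencies_match_controls(self):
        # controls with genotype frequencies (0.25, 0.5, 0.25) at one SNP
        ctrl_col = np.array([0] * 25 + [1] * 50 + [2] * 25)
        controls = _matrix(ctrl_col[:, None])
        target = _matrix(np.full((10_000, 1), MISSING), prefix="t")
        out = impute_missing_from_controls(target, controls, seed=3)
        freqs = np.array([(out.counts == g).mean() for g in (0, 1, 2)])
        ses = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert np.all(np.abs(freqs - [0.25, 0.5, 0.25]) < 3 * ses)

    def test_non_missing_cells_never_change(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, (30, 5)).astype(np.int8)
        mask = rng.random((30, 5)) < 0.3
        with_missing = counts.copy()
        with_missing[mask] = MISSING
        controls = _matrix(rng.integers(0, 3, (40, 5)))
        out = impute_missing_from_controls(
            _matrix(with_missing, prefix="t"), controls, seed=4
        )
        assert np.array_equal(out.counts[~mask], counts[~mask])
        assert (out.counts != MISSING).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        controls = _matrix(rng.integers(0, 3, (40, 4)))
        target = _matrix(np.full((50, 4), MISSING), prefix="t")
        a = impute_missing_from_controls(target, controls, seed=7)
        b = impute_missing_from_controls(target, controls, seed=7)
        assert a == b

    def test_all_missing_control_column_falls_back_pooled(self):
        ctrl = np.array([[0, 1], [1, 1], [2, 1]], dtype=np.int8)
        ctrl[:, 0] = MISSING
        controls = _matrix(ctrl)
        target = _matrix(np.full((5, 2), MISSING), prefix="t")
        with pytest.warns(UserWarning, match="pooled"):
            out = impute_missing_from_controls(target, controls, seed=8)
        assert (out.counts != MISSING).all()

    def test_panel_mismatch_rejected(self):
        a = _matrix(np.zeros((3, 2)))
        b = _matrix(np.zeros((3, 3)), prefix="t")
        with pytest.raises(ValueError, match="align"):
            impute_missing_from_controls(a, b, seed=0)


class TestModels:
    def test_feature_counts(self, signal_cohort, small_rf):
        _, split = signal_cohort
        clinical_only = build_prediction_model(
            split.stage1, ModelSpec(snp_ids=[], include_clinical=True, rf_config=small_rf)
        )
        assert clinical_only.forest.n_features == 4
        k5 = build_prediction_model(
            split.stage1,
            ModelSpec(
                snp_ids=split.stage1.genotypes.snp_ids[:5],
                include_clinical=True,
                rf_config=small_rf,
            ),
        )
        assert k5.forest.n_features == 9

    def test_unknown_snp_rejected(self, signal_cohort, small_rf):
        _, split = signal_cohort
        with pytest.raises(KeyError):
            build_prediction_model(
                split.stage1,
                ModelSpec(snp_ids=["rs_nope"], include_clinical=True, rf_config=small_rf),
            )

    def test_scores_granularity_and_determinism(self, signal_cohort, small_rf):
        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        m1 = build_prediction_model(split.stage1, spec)
        m2 = build_prediction_model(split.stage1, spec)
        s1 = predict_scores(m1, split.stage2)
        s2 = predict_scores(m2, split.stage2)
        assert np.array_equal(s1, s2)
        assert np.allclose(s1 * small_rf.ntree, np.round(s1 * small_rf.ntree))

    def test_cases_score_higher_on_signal(self, signal_cohort, small_rf):
        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        model = build_prediction_model(split.stage1, spec)
        scores = predict_scores(model, split.stage1)
        y = split.stage1.phenotype
        assert scores[y == 1].mean() > scores[y == 0].mean()


class TestCVAndReplication:
    def test_cv_holds_out_disjoint_samples(self, signal_cohort, small_rf):
        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        result = internal_cross_validation(split.stage1, spec, seed=1)
        n_hold = result.n_cases + result.n_controls
        assert n_hold == round(0.1 * len(split.stage1.phenotype))
        # stratified: the held-out fold keeps roughly the 30% case share
        assert 1 <= result.n_cases <= n_hold - 1

    def test_cv_detects_planted_signal(self, signal_cohort, small_rf):
        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        aucs = [
            internal_cross_validation(split.stage1, spec, seed=s).auc for s in range(6)
        ]
        assert np.mean(aucs) > 0.5

    def test_self_replication_equals_training_auc(self, signal_cohort, small_rf):
        from exacerf.evaluation import auc

        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        result = independent_replication(split.stage1, split.stage1, spec)
        model = build_prediction_model(split.stage1, spec)
        direct = auc(predict_scores(model, split.stage1), split.stage1.phenotype)
        assert result.auc == pytest.approx(direct.auc)

    def test_signal_replicates(self, signal_cohort, small_rf):
        _, split = signal_cohort
        spec = ModelSpec(
            snp_ids=split.causal_snps, include_clinical=True, rf_config=small_rf
        )
        result = independent_replication(split.stage1, split.stage2, spec)
        assert result.auc > 0.5

    def test_single_class_test_outcome_rejected(self, signal_cohort, small_rf):
        _, split = signal_cohort
        broken = CohortBundle(
            genotypes=split.stage2.genotypes,
            covariates=split.stage2.covariates,
            phenotype=np.zeros_like(split.stage2.phenotype),
        )
        spec = ModelSpec(snp_ids=[], include_clinical=True, rf_config=small_rf)
        with pytest.raises(ValueError, match="single-class"):
            independent_replication(split.stage1, broken, spec)


class TestLadder:
    def test_ladder_rows_and_clinical_only(
        self, signal_cohort, small_rf, small_screening
    ):
        _, split = signal_cohort
        rec = chunked_importance_scan(
            split.stage1.genotypes, split.stage1.phenotype, small_rf, small_screening
        )
        rec = rerank_top(
            rec, split.stage1.genotypes, split.stage1.phenotype, small_rf, small_screening
        )
        ladder = run_snp_ladder(
            split.stage1, split.stage2, rec, small_screening, small_rf
        )
        assert list(ladder["n_snps"]) == [0, 10, 40]
        assert ladder["train_auc"].between(0, 1).all()
        snps_only = run_snp_ladder(
            split.stage1,
            split.stage2,
            rec,
            small_screening,
            small_rf,
            include_clinical=False,
        )
        assert list(snps_only["n_snps"]) == [10, 40]
        assert not snps_only["include_clinical"].any()
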