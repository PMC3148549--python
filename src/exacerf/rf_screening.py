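"""Two-step genome-wide SNP screening by random-forest importance score.

Step 1 fits one forest per consecutive chunk of SNPs (default 4,000, in
chromosomal order) with the SNPs alone as predictors, and pools the per-SNP
importance scores into a single genome-wide ranking.  Step 2 refits one
forest on the top pool (default 4,000) jointly and re-ranks those SNPs; the
prediction models then take the stage-2 top k.  Importance is the total Gini
impurity decrease per feature by default, with out-of-bag permutation
importance as an alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from exacerf.genotype_io import GenotypeMatrix, encode_additive

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Forest hyper-parameters.

    ntree defaults to 1,500 — large enough that vote fractions are stable;
    mtry defaults to floor(sqrt(p)).  ``importance_measure`` is
    ``impurity_decrease`` (default) or ``oob_permutation``.
    """

    ntree: int = 1500
    mtry: int | None = None
    importance_measure: str = "impurity_decrease"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.importance_measure not in ("impurity_decrease", "oob_permutation"):
            raise ValueError(f"unknown importance measure {self.importance_measure!r}")

    def with_seed(self, seed: int) -> "RFConfig":
        return RFConfig(self.ntree, self.mtry, self.importance_measure, seed)


@dataclass
class ScreeningConfig:
    """Two-step screening layout: chunking, stage-2 pool, and the top-k ladder."""

    chunk_size: int = 4000
    stage2_pool: int = 4000
    selection_sizes: tuple[int, ...] = (10, 40, 160, 320)

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if any(k > self.stage2_pool for k in self.selection_sizes):
            raise ValueError("selection sizes must not exceed the stage-2 pool")


class ForestModel:
    """A fitted bagged-tree ensemble exposing vote fractions and importance."""

    def __init__(self, clf: RandomForestClassifier, features: np.ndarray, labels: np.ndarray):
        self._clf = clf
        self._train_features = features
        self._train_labels = labels
        self.n_features = features.shape[1]
        self.ntree = clf.n_estimators
        # index of the positive class among the classifier's classes
        self._case_class = 1

    def vote_fractions(self, features: np.ndarray) -> np.ndarray:
        """Fraction of trees voting 'case' per sample (granularity 1/ntree)."""
        features = _check_features(features, self.n_features)
        votes = np.zeros(features.shape[0])
        for tree in self._clf.estimators_:
            votes += tree.predict(features) == self._case_class
        return votes / self.ntree

    @property
    def sklearn_forest(self) -> RandomForestClassifier:
        return self._clf


def _check_features(features: np.ndarray, expected_p: int | None = None) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("feature block must be 2-D (samples x features)")
    if np.isnan(features).any():
        raise ValueError(
            "feature block contains missing values; impute genotypes first "
            "(impute_missing_from_controls)"
        )
    if expected_p is not None and features.shape[1] != expected_p:
        raise ValueError(
            f"feature count {features.shape[1]} != model's {expected_p}"
        )
    return features


def fit_forest(features: np.ndarray, labels: np.ndarray, rf_config: RFConfig) -> ForestModel:
    """Fit an ntree-tree classification forest (Gini splits, bagging, mtry).

    Deterministic given ``rf_config.seed``.  Features must be complete
    (no NaN) and labels must contain both classes.
    """
    features = _check_features(features)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    p = features.shape[1]
    mtry = rf_config.mtry if rf_config.mtry is not None else max(1, int(np.sqrt(p)))
    if not (1 <= mtry <= p):
        raise ValueError(f"mtry={mtry} outside [1, {p}]")
    clf = RandomForestClassifier(
        n_estimators=rf_config.ntree,
        criterion="gini",
        max_features=mtry,
        bootstrap=True,
        random_state=rf_config.seed % (2**31),
        n_jobs=1,
    )
    clf.fit(features, labels)
    return ForestModel(clf, features, labels)


def _oob_permutation_importance(model: ForestModel, rng: np.random.Generator) -> np.ndarray:
    """Mean out-of-bag accuracy drop per feature, averaged over trees.

    Bootstrap indices are reconstructed from each tree's random_state the
    same way the bagging draw is made at fit time.
    """
    X, y = model._train_features, model._train_labels
    n = X.shape[0]
    scores = np.zeros(model.n_features)
    counts = np.zeros(model.n_features)
    for tree in model._clf.estimators_:
        sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if not oob.any():
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        # permuting every feature is O(p * n_oob) per tree; restrict to
        # features the tree actually used
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(Xo.shape[0]), j]
            scores[j] += base - np.mean(tree.predict(Xp) == yo)
            counts[j] += 1
    counts[counts == 0] = 1
    return scores / counts


def compute_importance(model: ForestModel, rf_config: RFConfig | None = None) -> np.ndarray:
    """Per-feature importance score (length p, larger = more important)."""
    measure = rf_config.importance_measure if rf_config else "impurity_decrease"
    if measure == "impurity_decrease":
        # unnormalized mean Gini decrease per feature, averaged over trees:
        # raw-scale scores are comparable across chunk forests of unequal size
        return np.mean(
            [
                t.tree_.compute_feature_importances(normalize=False)
                for t in model._clf.estimators_
            ],
            axis=0,
        )
    rng = np.random.default_rng(rf_config.seed if rf_config else 0)
    return _oob_permutation_importance(model, rng)


def _chunk_seed(master_seed: int, chunk_index: int, stage: int = 1) -> int:
    """Stable per-chunk seed, order-independent given the master seed."""
    entropy = [abs(int(master_seed)), stage, chunk_index]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _rank_scores(scores: np.ndarray, order_index: np.ndarray) -> np.ndarray:
    """Ranks 1..n by descending score; ties broken by panel (chrom/pos) order."""
    order = np.lexsort((order_index, -scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def chunked_importance_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    rf_config: RFConfig,
    screening_config: ScreeningConfig,
) -> pd.DataFrame:
    """Stage 1: per-chunk forests over the whole panel, pooled into one ranking.

    The panel is split into consecutive chunks of ``chunk_size`` SNPs (last
    chunk smaller) in the stored chromosomal order; one forest is fitted per
    chunk on that chunk's SNPs only (no clinical covariates).  Chunk seeds
    derive deterministically from ``rf_config.seed`` and the chunk index.

    Returns the importance table (one row per SNP, chromosomal order) with
    stage-1 scores and global stage-1 ranks; stage-2 columns are NaN until
    :func:`rerank_top` fills them.
    """
    features = encode_additive(genotypes)
    if np.isnan(features).any():
        raise ValueError("genotypes contain missing calls; impute before screening")
    p = genotypes.n_snps
    scores = np.empty(p)
    n_chunks = int(np.ceil(p / screening_config.chunk_size))
    for c in range(n_chunks):
        lo = c * screening_config.chunk_size
        hi = min(lo + screening_config.chunk_size, p)
        cfg = rf_config.with_seed(_chunk_seed(rf_config.seed, c))
        model = fit_forest(features[:, lo:hi], phenotype, cfg)
        scores[lo:hi] = compute_importance(model, cfg)
        logger.info("chunk %d/%d (%d SNPs) scanned", c + 1, n_chunks, hi - lo)
    records = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chromosome": [s.chromosome for s in genotypes.snps],
            "position": [s.position for s in genotypes.snps],
            "stage1_score": scores,
            "stage1_rank": _rank_scores(scores, np.arange(p)),
            "stage2_score": np.nan,
            "stage2_rank": np.nan,
        }
    )
    return records


def rerank_top(
    stage1_records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    rf_config: RFConfig,
    screening_config: ScreeningConfig,
) -> pd.DataFrame:
    """Stage 2: refit one forest on the stage-1 top pool jointly and re-rank.

    Returns a copy of the records with ``stage2_score``/``stage2_rank``
    filled for exactly the pool SNPs.
    """
    records = stage1_records.copy()
    pool = screening_config.stage2_pool
    if pool > len(records):
        warnings.warn(
            f"stage2_pool={pool} exceeds panel size {len(records)}; using all SNPs"
        )
        pool = len(records)
    in_pool = records["stage1_rank"] <= pool
    pool_ids = records.loc[in_pool].sort_values("stage1_rank")["snp_id"].tolist()
    sub = genotypes.subset_snps(pool_ids)
    cfg = rf_config.with_seed(_chunk_seed(rf_config.seed, 0, stage=2))
    model = fit_forest(encode_additive(sub), phenotype, cfg)
    scores = compute_importance(model, cfg)
    # tie-break stage-2 ranks by higher stage-1 score, then panel order
    rec_idx = records.set_index("snp_id")
    stage1 = rec_idx.loc[pool_ids, "stage1_score"].to_numpy()
    panel_order = {sid: i for i, sid in enumerate(records["snp_id"])}
    order_key = np.array([panel_order[sid] for sid in pool_ids])
    order = np.lexsort((order_key, -stage1, -scores))
    ranks = np.empty(len(pool_ids), dtype=int)
    ranks[order] = np.arange(1, len(pool_ids) + 1)
    records = records.set_index("snp_id")
    records.loc[pool_ids, "stage2_score"] = scores
    records.loc[pool_ids, "stage2_rank"] = ranks.astype(float)
    return records.reset_index()[stage1_records.columns]


def select_top(stage2_records: pd.DataFrame, k: int) -> list[str]:
    """The first k SNP ids by stage-2 rank (deterministic)."""
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = stage2_records.dropna(subset=["stage2_rank"])
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds stage-2 pool of {len(ranked)}")
    return (
        ranked.sort_values("stage2_rank").head(k)["snp_id"].tolist()
    )


def export_importance_table(records: pd.DataFrame, path) -> None:
    """Write the importance table as TSV, sorted by (chromosome, position)."""
    if records.empty:
        raise ValueError("no importance records to export")
    out = records.copy()
    out["_chrom_key"] = pd.to_numeric(out["chromosome"], errors="coerce").fillna(99)
    out = out.sort_values(["_chrom_key", "position"]).drop(columns="_chrom_key")
    out.to_csv(path, sep="\t", index=False)


def read_importance_table(path) -> pd.DataFrame:
    """Re-read a TSV written by :func:`export_importance_table`."""
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})
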