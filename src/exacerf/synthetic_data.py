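"""Synthetic two-stage case-control GWAS cohort generator.

Emulates the statistical structure the pipeline assumes: a training stage of
417 children (30% with a severe exacerbation) and an independent replication
stage of 164 drawn from the same generative law, Hardy-Weinberg genotypes at
configurable minor-allele frequencies, a logistic disease model with planted
additive and pairwise-epistatic SNP effects plus weak clinical-covariate
effects, covariates matched to the cohort's published moments, and optional
uniform genotype missingness.  Everything is deterministic given
``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from exacerf.genotype_io import (
    MISSING,
    CovariateTable,
    GenotypeMatrix,
    SNPMeta,
    read_covariate_table,
    read_ped_map,
    write_ped_map,
    validate_covariates,
)

N_CHROMOSOMES = 22


class CalibrationError(RuntimeError):
    """Prevalence calibration could not reach the target."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults reproduce the cohort the analysis was designed around: 417
    training samples and 164 replication samples at 30% case prevalence,
    with covariate moments matching the published sample characteristics.
    ``additive_log_odds`` may be a scalar (shared by all causal SNPs) or a
    sequence of per-SNP effects; ``None`` spreads effects evenly over
    [1.0, 2.0].  ``epistatic_pairs`` are (snp_index_i, snp_index_j,
    interaction_log_odds) with 0-based indices into the panel.
    """

    n_train: int = 417
    n_test: int = 164
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_additive: int = 20
    additive_log_odds: float | tuple[float, ...] | None = None
    epistatic_pairs: tuple[tuple[int, int, float], ...] = ()
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.06,
            "sex": -0.20,
            "fev1_pct_pred": -0.004,
            "treatment": 0.18,
        }
    )
    target_prevalence: float = 0.30
    missing_rate: float = 0.0
    seed: int = 0
    # covariate moments (cohort-wide), all configurable
    age_mean: float = 8.7
    age_sd: float = 2.1
    age_min: float = 5.0
    fev1_mean: float = 93.3
    fev1_sd: float = 14.0
    fev1_min: float = 40.0
    male_fraction: float = 0.63

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 < self.target_prevalence < 1):
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.n_causal_additive > self.n_snps:
            raise ValueError("more causal SNPs than SNPs in the panel")
        for i, j, _ in self.epistatic_pairs:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ValueError("epistatic pair index outside the panel")

    def causal_effects(self) -> np.ndarray:
        """Per-causal-SNP additive log-odds, length n_causal_additive."""
        k = self.n_causal_additive
        if k == 0:
            return np.zeros(0)
        if self.additive_log_odds is None:
            return np.linspace(1.0, 2.0, k)
        arr = np.atleast_1d(np.asarray(self.additive_log_odds, dtype=float))
        if arr.size == 1:
            return np.repeat(arr, k)
        if arr.size != k:
            raise ValueError("additive_log_odds length != n_causal_additive")
        return arr


@dataclass
class CohortBundle:
    """One stage of the cohort: genotypes + covariates + binary outcome."""

    genotypes: GenotypeMatrix
    covariates: CovariateTable
    phenotype: np.ndarray


@dataclass
class CohortSplit:
    """Training (stage 1) and replication (stage 2) bundles on one SNP panel."""

    stage1: CohortBundle
    stage2: CohortBundle
    causal_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.stage1.genotypes.samples) & set(self.stage2.genotypes.samples):
            raise ValueError("stage 1 and stage 2 sample ids overlap")
        if self.stage1.genotypes.snp_ids != self.stage2.genotypes.snp_ids:
            raise ValueError("stage 1 and stage 2 SNP panels differ")


def _snp_panel(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[SNPMeta], np.ndarray]:
    """Draw per-SNP MAFs and lay SNPs out over 22 chromosomes in blocks."""
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    chrom_of = np.minimum(
        np.arange(config.n_snps) * N_CHROMOSOMES // max(config.n_snps, 1),
        N_CHROMOSOMES - 1,
    )
    snps = []
    pos = 0
    alleles = np.array(list("ACGT"))
    for j in range(config.n_snps):
        if j > 0 and chrom_of[j] != chrom_of[j - 1]:
            pos = 0
        pos += int(rng.integers(1_000, 50_000))
        a, b = rng.choice(4, size=2, replace=False)
        snps.append(
            SNPMeta(
                snp_id=f"rs{j + 1:06d}",
                chromosome=str(int(chrom_of[j]) + 1),
                position=pos,
                allele_a=str(alleles[a]),
                allele_b=str(alleles[b]),
            )
        )
    return snps, mafs


def simulate_genotypes(
    config: SimulationConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw an n x n_snps genotype matrix under Hardy-Weinberg equilibrium.

    Each SNP's MAF q is uniform over ``maf_range``; genotype counts are
    multinomial with probabilities ((1-q)^2, 2q(1-q), q^2).  SNPs are laid
    out over 22 chromosomes in contiguous blocks with increasing positions.
    """
    if config.n_snps == 0:
        raise ValueError("empty SNP panel (n_snps = 0)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = config.n_train
    snps, mafs = _snp_panel(config, rng)
    u = rng.random(size=(n, config.n_snps))
    p_hom_major = (1 - mafs) ** 2
    p_het = 2 * mafs * (1 - mafs)
    counts = (u >= p_hom_major).astype(np.int8) + (u >= p_hom_major + p_het).astype(np.int8)
    samples = [f"s{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts)


def simulate_covariates(
    config: SimulationConfig, n: int, rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> CovariateTable:
    """Draw clinical covariates with the cohort's published moments.

    Age ~ Normal(8.7, 2.1) truncated above 5 y; FEV1 %pred ~ Normal(93.3,
    14.0) truncated above 40; sex Bernoulli(male 0.63) coded 1/2; treatment
    uniform over {1, 2, 3}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sample_ids is None:
        sample_ids = [f"s{i + 1:05d}" for i in range(n)]

    def trunc_normal(mean, sd, lower, size):
        out = rng.normal(mean, sd, size=size)
        while True:
            bad = out <= lower
            if not bad.any():
                return out
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))

    table = pd.DataFrame(
        {
            "age": np.round(trunc_normal(config.age_mean, config.age_sd, config.age_min, n), 2),
            "sex": np.where(rng.random(n) < config.male_fraction, 1, 2),
            "fev1_pct_pred": np.round(
                trunc_normal(config.fev1_mean, config.fev1_sd, config.fev1_min, n), 1
            ),
            "treatment": rng.integers(1, 4, size=n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return validate_covariates(table)


def _linear_predictor(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    config: SimulationConfig,
    causal_idx: np.ndarray,
) -> np.ndarray:
    """Non-intercept part of the logistic disease model's log-odds."""
    G = genotypes.counts.astype(float)
    if (G < 0).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    eta = np.zeros(genotypes.n_samples)
    effects = config.causal_effects()
    for j, beta in zip(causal_idx, effects):
        eta += beta * G[:, j]
    for i, j, beta in config.epistatic_pairs:
        eta += beta * G[:, i] * G[:, j]
    for col, beta in config.covariate_effects.items():
        eta += beta * covariates[col].to_numpy(dtype=float)
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 0.005) -> float:
    """Bisection on the intercept so mean(logistic(b0 + eta)) hits the target."""

    def prevalence(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -60.0, 60.0
    if prevalence(lo) > target or prevalence(hi) < target:
        raise CalibrationError(
            f"target prevalence {target} unattainable for the given effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    if abs(prevalence(b0) - target) > tol:
        raise CalibrationError("intercept bisection did not converge")
    return b0


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    causal_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the binary outcome from the calibrated logistic disease model.

    P(case) = logistic(b0 + additive SNP terms + epistatic terms + covariate
    terms); b0 is bisected so the expected case fraction equals
    ``target_prevalence`` within 0.005.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if causal_idx is None:
        causal_idx = default_causal_indices(config)
    eta = _linear_predictor(genotypes, covariates, config, causal_idx)
    b0 = _calibrate_intercept(eta, config.target_prevalence)
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    return (rng.random(len(prob)) < prob).astype(np.int8)


def default_causal_indices(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Causal SNP columns: evenly spread over the panel (deterministic)."""
    k = config.n_causal_additive
    if k == 0:
        return np.zeros(0, dtype=int)
    return np.unique(np.linspace(0, config.n_snps - 1, k).round().astype(int))


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each genotype cell to MISSING independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return GenotypeMatrix(
            samples=list(genotypes.samples),
            snps=list(genotypes.snps),
            counts=genotypes.counts.copy(),
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.counts.shape) < rate
    counts = genotypes.counts.copy()
    counts[mask] = MISSING
    return GenotypeMatrix(
        samples=list(genotypes.samples), snps=list(genotypes.snps), counts=counts
    )


def simulate_cohort(config: SimulationConfig) -> CohortSplit:
    """Generate the full two-stage cohort on one shared SNP panel.

    Stage 1 (training) and stage 2 (replication) samples are drawn jointly
    from the same generative law and split; the prevalence intercept is
    calibrated on the combined cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_train + config.n_test
    genotypes = simulate_genotypes(config, n=n_total, rng=rng)
    sample_ids = [f"tr{i + 1:05d}" for i in range(config.n_train)] + [
        f"te{i + 1:05d}" for i in range(config.n_test)
    ]
    genotypes.samples = sample_ids
    covariates = simulate_covariates(config, n_total, rng=rng, sample_ids=sample_ids)
    causal_idx = default_causal_indices(config)
    phenotype = simulate_phenotype(genotypes, covariates, config, rng=rng, causal_idx=causal_idx)
    if config.missing_rate > 0:
        genotypes = inject_missingness(
            genotypes, config.missing_rate, seed=int(rng.integers(2**31))
        )
    train_mask = np.zeros(n_total, dtype=bool)
    train_mask[: config.n_train] = True
    stage1 = CohortBundle(
        genotypes=genotypes.subset_samples(train_mask),
        covariates=covariates.iloc[: config.n_train],
        phenotype=phenotype[: config.n_train],
    )
    stage2 = CohortBundle(
        genotypes=genotypes.subset_samples(~train_mask),
        covariates=covariates.iloc[config.n_train :],
        phenotype=phenotype[config.n_train :],
    )
    causal_ids = [genotypes.snps[j].snp_id for j in causal_idx]
    return CohortSplit(stage1=stage1, stage2=stage2, causal_snps=causal_ids)


def _write_bundle(bundle: CohortBundle, out_dir: Path, prefix: str) -> None:
    write_ped_map(
        bundle.genotypes,
        bundle.phenotype,
        out_dir / f"{prefix}.ped",
        out_dir / f"{prefix}.map",
    )
    bundle.covariates.to_csv(out_dir / f"{prefix}.cov.tsv", sep="\t")


def write_cohort(
    split: CohortSplit,
    out_dir,
    config: SimulationConfig | None = None,
    overwrite: bool = False,
) -> None:
    """Write stage1/stage2 .ped/.map + covariates + a JSON manifest."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is non-empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_bundle(split.stage1, out_dir, "stage1")
    _write_bundle(split.stage2, out_dir, "stage2")
    manifest = {"causal_snps": split.causal_snps}
    if config is not None:
        cfg = asdict(config)
        cfg["epistatic_pairs"] = [list(p) for p in config.epistatic_pairs]
        manifest["config"] = cfg
        manifest["seed"] = config.seed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_cohort(out_dir) -> CohortSplit:
    """Re-read a cohort written by :func:`write_cohort`."""
    out_dir = Path(out_dir)
    bundles = {}
    for prefix in ("stage1", "stage2"):
        geno, pheno = read_ped_map(out_dir / f"{prefix}.ped", out_dir / f"{prefix}.map")
        cov = read_covariate_table(out_dir / f"{prefix}.cov.tsv")
        bundles[prefix] = CohortBundle(
            genotypes=geno, covariates=cov.loc[geno.samples], phenotype=pheno
        )
    causal = []
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            causal = json.load(fh).get("causal_snps", [])
    return CohortSplit(stage1=bundles["stage1"], stage2=bundles["stage2"], causal_snps=causal)
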