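import numpy as np
import pytest

from exacerf import SimulationConfig, simulate_cohort
from exacerf.rf_screening import RFConfig, ScreeningConfig


@pytest.fixture(scope="session")
def signal_cohort():
    """Small cohort with 5 planted additive SNPs, strong effects."""
    cfg = SimulationConfig(
        n_train=150,
        n_test=80,
        n_snps=200,
        n_causal_additive=5,
        additive_log_odds=(1.2, 1.4, 1.6, 1.8, 2.0),
        maf_range=(0.15, 0.45),
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic and no covariate effects at all."""
    cfg = SimulationConfig(
        n_train=150,
        n_test=80,
        n_snps=120,
        n_causal_additive=0,
        covariate_effects={},
        maf_range=(0.1, 0.4),
        seed=23,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def small_rf():
    return RFConfig(ntree=60, seed=5)


@pytest.fixture
def small_screening():
    return ScreeningConfig(chunk_size=80, stage2_pool=100, selection_sizes=(10, 40))


@pytest.fixture
def tiny_ped_map(tmp_path):
    """Three samples, two SNPs; at rs1 the calls are A A / A G / G G (G minor)."""
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    ped.write_text(
        "f1 s1 0 0 0 1 A A C C\n"
        "f2 s2 0 0 0 2 A G C T\n"
        "f3 s3 0 0 0 1 G G 0 0\n"
    )
    map_.write_text("1 rs1 0 1000\n1 rs2 0 2000\n")
    return ped, map_
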