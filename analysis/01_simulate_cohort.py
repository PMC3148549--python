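"""Simulate and write the two-stage synthetic GWAS cohort.

Generates a training stage of 417 children (30% with a severe exacerbation)
and an independent replication stage of 164 on a shared 2,000-SNP panel with
20 planted additive risk SNPs, and writes PLINK-text genotype files,
covariate tables and a manifest under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from exacerf import SimulationConfig, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42


def main() -> None:
    config = SimulationConfig(
        n_snps=2000,
        n_causal_additive=20,
        additive_log_odds=tuple(np.linspace(1.0, 2.0, 20)),
        missing_rate=0.01,
        seed=SEED,
    )
    split = simulate_cohort(config)
    write_cohort(split, OUT, config=config, overwrite=True)
    for name, bundle in (("stage 1", split.stage1), ("stage 2", split.stage2)):
        y = bundle.phenotype
        print(
            f"{name}: n={len(y)}, cases={int(y.sum())} ({y.mean():.0%}), "
            f"SNPs={bundle.genotypes.n_snps}"
        )
    print(f"planted risk SNPs: {', '.join(split.causal_snps[:5])} ...")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
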