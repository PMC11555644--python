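"""GBJ region test, individual-level and summary-statistics routes.

The same planted region is tested twice: once from genotypes (LD pruning,
covariate-adjusted score statistics, Monte Carlo GBJ p-value) and once from
per-SNP summary statistics with a separate genotype panel standing in as the
LD reference — the situation of a validation study that shares only its
association table. The two p-values should agree on the same data-generating
process; a null region is included for contrast.
"""

import numpy as np

from regiongwas import (EffectSpec, GbjConfig, Region, build_haplotype_pool,
                        emit_summary_study, simulate_study,
                        test_region_individual, test_region_summary)

pool = build_haplotype_pool(n_hap=1500, n_snp=400, block_len=25, seed=37)
pos0 = pool.variants["pos"].to_numpy() - 1
region = Region("1", 400_000, 500_000, "planted")
null_region = Region("1", 1_000_000, 1_100_000, "null")
inside = np.flatnonzero((pos0 >= region.start) & (pos0 < region.end))
vids = pool.variants["vid"].to_numpy()[inside[[4, 12, 20]]]
effect = EffectSpec(region, tuple(vids), or_per_allele=1.3)

config = GbjConfig(n_mc=10_000, seed=37)
study = simulate_study(pool, 2000, 2000, effects=[effect], seed=37)
for reg in (region, null_region):
    res = test_region_individual(study, reg, config=config)
    print(f"individual-level {reg.label:8s}: GBJ = {res.stat:6.2f}, "
          f"p = {res.p:.4g} ({res.n_snps_tested} SNPs after pruning)")

summary = emit_summary_study(pool, 2000, 2000, effects=[effect], seed=38)
reference = simulate_study(pool, 0, 600, seed=39, study_label="ref")
res = test_region_summary(summary, region, reference, config=config)
print(f"summary + reference  planted : GBJ = {res.stat:6.2f}, p = {res.p:.4g}")
print("\nsmall p at the planted region on both routes; the null region "
      "stays non-significant")
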