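"""Simulate a small bisulfite time course and summarize it at 1-kb bins.

Generates per-CpG methylated/total read counts for a 4-timepoint
transdifferentiation course, applies the >=5x all-sample coverage filter,
and averages CpG fractions per 1-kb window (windows need >= 3 CpGs).
"""

from methdyn import SimConfig, bin_methylation, filter_coverage, simulate_methylome

cfg = SimConfig(seed=1, n_chroms=1, chrom_length_bp=500_000,
                cpg_spacing_mean_bp=150.0, n_genes=300)
calls, truth = simulate_methylome(cfg)
print(f"simulated CpGs: {calls.n_cpgs}  samples: {calls.samples}")

kept = filter_coverage(calls, min_cov=5)
print(f"CpGs covered >=5x in all samples: {kept.n_cpgs}")

profiles = bin_methylation(kept, bin_width=1000, min_cpgs=3)
print(f"analyzable 1-kb bins (>=3 CpGs): {len(profiles)}")
print(profiles.head(3).to_string(index=False))
# Each sample column holds the bin's mean CpG methylation fraction at that
# timepoint; trajectories of these fractions drive everything downstream.
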