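"""Couple promoter demethylation to gene induction and rank candidates.

Builds a full small synthetic genome (methylome + ATAC/H3K4me1 peaks +
TSSs + expression), classifies dynamic bins into promoter/enhancer GREs,
pairs each region's methylation step change with its gene's log2
fold-change, and ranks promoter-loss events IL1RN-style: deepest
demethylation combined with strongest induction first.
"""

from methdyn import (
    SimConfig,
    bin_methylation,
    build_integration_table,
    classify_gre,
    correlations_by_group,
    filter_coverage,
    rank_candidates,
    simulate_methylome,
    simulate_regulome_and_expression,
    timepoint_delta,
)

cfg = SimConfig(seed=2, n_chroms=1, chrom_length_bp=1_000_000,
                cpg_spacing_mean_bp=150.0, n_genes=600)
calls, truth = simulate_methylome(cfg)
atac, h3k4me1, genes, expr = simulate_regulome_and_expression(cfg, truth, calls)

profiles = bin_methylation(filter_coverage(calls, 5))
deltas = timepoint_delta(profiles, calls.sample_timepoints)
ann = classify_gre(profiles[["chrom", "start", "end"]], atac, h3k4me1, genes)
table = build_integration_table(ann, deltas, expr)
print("integration records by group:")
print(table["group"].value_counts().to_string())

print("\nper-group Pearson correlation (delta methylation vs log2FC):")
print(correlations_by_group(table).to_string(index=False))

ranked = rank_candidates(table)
print("\ntop 3 promoter-loss candidates:")
print(ranked.head(3)[["gene_id", "delta_meth", "log2fc", "rank"]]
      .to_string(index=False))
print(f"\nplanted hallmark gene: {truth.hallmark_gene} "
      f"(region {truth.hallmark_region_id})")
# The negative promoter-loss correlation mirrors the planted coupling; the
# hallmark locus (deep demethylation + >=1000-fold induction) ranks first.
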