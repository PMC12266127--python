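# methdyn

Integrative analysis of DNA-methylation dynamics during cell-fate
conversion, for epigenomics groups working with whole-genome bisulfite
sequencing (WGBS) time courses, chromatin-accessibility/histone-mark peak
sets, expression matrices, and methylation arrays.

The package covers the analytic chain used to dissect a
B-cell-to-macrophage transdifferentiation course (0/24/96/168 h) and an
epigenome-editing specificity screen:

1. **Bin-level methylome** — per-CpG methylation calls (Bismark coverage or
   bedGraph) are kept only when covered ≥ 5× in *every* sample; the genome
   is tiled into 1-kb windows and each window's methylation per sample is
   the unweighted mean of its CpG fractions m/(m+u), requiring ≥ 3 CpGs.
2. **Temporal dynamics** — windows whose methylation range across the
   course is ≥ 10 percentage points are *dynamic*; k-means on
   delta-from-baseline trajectories groups them into four archetypes
   (C-I monotone gain, C-II transient gain, C-III transient/late loss,
   C-IV monotone late loss). A two-group mode handles paired cell-type
   comparisons (≥ 3× coverage, ≥ 10 pp group difference).
3. **Regulatory elements** — a dynamic window is a *promoter* GRE when it
   overlaps an ATAC peak intersecting a TSS window (± 2 kb), an *enhancer*
   when its ATAC peak instead intersects an H3K4me1 peak; genes associate
   by TSS hit or nearest TSS.
4. **Methylation–expression integration** — each accessible region's step
   change ΔDNAm (final − reference) is paired with its gene's
   log2((final + c)/(ref + c)); per-group Pearson R with two-sided p from
   t = R·sqrt((n−2)/(1−R²)); promoter-loss events are ranked by combined
   rank of demethylation depth and induction strength, surfacing
   IL1RN-style loci (≥ 40 pp promoter methylation loss coupled to
   ≥ 1000-fold expression gain).
5. **Editing specificity** — differentially methylated positions from
   two-group beta-value matrices via per-probe Welch t tests with
   Benjamini–Hochberg adjustment and the joint gate Δβ ≥ 0.3 AND
   FDR < 0.05; the three-way overlap of bound-promoter genes, DMP genes
   and DEGs summarizes off-target impact.

A first-class synthetic-data module generates every input with planted
ground truth (archetype trajectories, GRE placement, an expression matrix
whose promoter-loss correlation is realized exactly, the hallmark locus,
spiked hypermethylated probes), so the full chain is testable without any
external download.

## Worked example

`examples/03_correlate_expression.py` simulates a 1-Mb genome, runs the
binning → dynamics → GRE → integration chain, and prints:

```
integration records by group:
group
promoter_loss       164
gain                 52
nonpromoter_loss     26

per-group Pearson correlation (delta methylation vs log2FC):
           group   n         r  p_value
            gain  52  0.019519 0.890757
nonpromoter_loss  26 -0.009224 0.964329
   promoter_loss 164 -0.318815 0.000032

top 3 promoter-loss candidates:
gene_id  delta_meth    log2fc  rank
 g00023   -0.704375 10.966505     1
 g00140   -0.510517  4.413567     2
 g00045   -0.483904  4.262585     3

planted hallmark gene: g00023 (region chr1:103000-104000)
```

Promoter regions losing methylation show the planted negative coupling to
expression (r here includes the extreme hallmark record; the planted
background value is −0.25), gain regions show none, and the hallmark locus
— 70 pp promoter methylation loss with a log2 fold-change of ~11 (>1000×)
— ranks first. The other examples cover binning, archetype clustering, the
DMP screen, and the file-based end-to-end run; the `methdyn` CLI exposes
the same stages as subcommands (`simulate`, `bin`, `dynamics`, `annotate`,
`correlate`, `dmp`, `overlap`, `run`).

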