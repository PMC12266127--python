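# Methods

## Bin-level methylome

Methylation per CpG and sample is the fraction of reads reporting C over
reads reporting C or T, recomputed from counts (the percent column of
coverage files is ignored). A CpG enters the analysis only if its total
read count is at or above `min_cov` in **every** sample (default 5; the
two-group primary-cell mode conventionally uses 3); a CpG absent from any
sample is treated as uncovered. Chromosomes are tiled from coordinate 0
into half-open `[start, start + bin_width)` windows (default 1 kb) and a
window's methylation per sample is the **unweighted arithmetic mean** of
its CpG fractions — each CpG counts equally rather than each read, which
keeps deeply covered CpGs from dominating a window. Windows need
`min_cpgs` retained CpGs (default 3). All values are fractions in [0, 1]
internally; interfaces that quote percentages convert at the boundary.
Duplicate (chrom, pos, sample) records are a hard error rather than a
silent last-wins, and strand merging is not performed (coverage files are
already cytosine-resolved).

## Dynamic selection and archetype clustering

A window is dynamic when the max−min range of its replicate-averaged
per-timepoint methylation is at least `min_delta` (default 0.10,
inclusive). Range rather than net change is used so that transient
episodes — windows that deviate mid-course and return — are retained; the
net last-minus-first change then classifies direction (loss / gain /
transient). Clustering runs k-means (k = 4, 25 restarts, fixed seed) on
trajectories anchored at zero in the reference state (each trajectory
minus its first value), so windows are grouped by the *shape and timing*
of their change, not by baseline methylation. Cluster labels come from a
one-to-one Hungarian matching between centroids and four canonical
delta templates:

| archetype | shape (delta from baseline at the 4 default timepoints) |
|-----------|----------------------------------------------------------|
| C-I   | (0, +0.2, +0.4, +0.4) — monotone gain |
| C-II  | (0, +0.3, +0.3, 0) — transient gain |
| C-III | (0, 0, −0.3, −0.1) — transient/late loss |
| C-IV  | (0, 0, −0.2, −0.4) — monotone loss from the third timepoint |

The templates are a declared labelling convention (they only name
clusters; they are resampled by linear interpolation for other timepoint
counts and are configurable). Identical-trajectory degenerate input
collapses to a single warned cluster. The two-group mode computes
`delta = mean(group b) − mean(group a)` per shared window and flags
|delta| ≥ `min_delta`; it is antisymmetric under group exchange.

Inclusive thresholds are compared with a 1e−12 tolerance so that values
like 0.60 − 0.50 (not exactly 0.10 in binary floating point) still count
as reaching a 10-pp cutoff.

## Regulatory-element classification

A window is a **promoter** GRE when it overlaps an ATAC peak whose
interval intersects a TSS window `[tss − w, tss + w)` (default w = 2 kb,
half-open), an **enhancer** when it overlaps an ATAC peak intersecting an
H3K4me1 peak but no TSS window, and **none** otherwise; ATAC overlap is
required for either class and promoter wins ties. The rule attaches the
TSS test to the ATAC peak, not to the window itself. Promoter regions
associate to the gene whose TSS window their peak hits (nearest TSS on
ties, then lexicographically smaller gene id); other regions take the
nearest TSS by window midpoint, with a strand-aware signed distance
(negative = upstream). Feature annotation uses the region midpoint with
priority promoter > exon > intron > intergenic. All coordinates are
0-based half-open; interval queries run on interval trees and are
regression-tested against O(n·m) brute-force scans.

## Integration and ranking

Accessible regions (GRE class ≠ none) with |ΔDNAm| ≥ `min_delta` between
reference and final states are grouped as promoter-loss, non-promoter
loss, or gain, and paired with their gene's
log2((mean_final + c)/(mean_ref + c)) with pseudocount c = 0.5 (the
">1000-fold" style statements presuppose a finite baseline; c is
configurable). Correlation per group is Pearson's product-moment r with a
two-sided p from the t transform on n − 2 df; zero-variance input raises
an explicit error instead of returning NaN. Candidate ranking is a
declared convention: score = rank of ΔDNAm ascending (deepest loss first)
plus rank of log2FC descending (average ranks for ties), lower score
first, ties broken by larger fold-change then gene id. One record per
region is kept, so genes with several regulatory regions appear once per
region.

## DMP calling and the overlap screen

Per probe, a Welch two-sample t-test compares edited versus control beta
values; p-values are Benjamini–Hochberg adjusted over **all** tested
probes, and a call requires both gates: FDR strictly below `fdr_max`
(default 0.05) and Δβ at or above `delta_min` (default 0.30, inclusive)
in the requested direction. Probes with zero variance in both groups and
equal means get p = 1 by convention. Welch's test is an unmoderated
choice: with very small groups (e.g. 4 vs 4) its p-values are noisy, and
against a mostly-null probe background the BH cutoff sits near the center
of the Welch p-value distribution, so the per-probe power of the joint
gate is modest (≈ 0.5 at Δβ = 0.4, logit noise sd 0.3, 13 true probes of
1000) — the acceptance suite reports this honestly. Empirical-Bayes
variance moderation, which rescues power at such sample sizes, is out of
scope. An optional exclusion list supports masking SNP-overlapping or
cross-reactive probes. Probes map to genes by nearest TSS within ± 2 kb
(else unassigned), and the specificity summary reports all seven disjoint
cells of the bound-genes × DMP-genes × DEG overlap; the cells always
partition the union (asserted).

## Synthetic data

The generator emulates the study design the analyses assume:

* **CpG landscape** — exponential inter-CpG spacing (mean 300 bp), two
  5-Mb chromosomes by default (~33k CpGs).
* **Trajectories** — each 1-kb bin draws an archetype
  (C-I 10%, C-II 15%, C-III 20%, C-IV 30%, flat 25% by default) and a
  baseline from archetype-specific ranges chosen so the template delta
  stays in [0, 1]; per-CpG latent methylation is baseline + template +
  N(0, 0.05), clipped. Template amplitudes (0.3–0.4) comfortably exceed
  the 10-pp dynamic gate.
* **Counts** — read totals are negative binomial (mean 30, dispersion 5;
  overdispersed like real WGBS depth), methylated reads binomial in the
  latent fraction. One replicate per timepoint by default, matching a
  single observed trajectory per condition; more are supported.
* **Regulome** — 40% of archetype bins become promoters (one TSS planted
  inside each, with an ATAC peak over it), 30% enhancers (ATAC ∩ H3K4me1
  peaks placed away from every TSS window so the classification is
  unambiguous), the rest stay peak-free; filler genes go to GRE-free
  territory.
* **Expression** — two conditions × two replicates. Promoter-loss genes'
  log2 fold-changes *realize the configured correlation exactly in
  sample* (Gram–Schmidt construction) against the **realized** bin deltas
  — the generator reuses the package's own binning so the planted
  correlation refers to precisely the quantity the pipeline later
  measures. Planting against latent values instead would attenuate the
  recovered r by count-noise measurement error, and a stochastic draw
  would add Fisher-z noise on top; the exact construction makes recovery
  checks reflect the estimation path alone and keeps them reproducible.
  Gain-region genes realize r = 0 the same way; everything else is
  uncorrelated noise. Replicates sit symmetrically around the planted
  condition mean (±2–10%), so means — hence fold-changes — are exact
  while replicates still vary.
* **Hallmark locus** — one C-IV promoter bin gets a deep-loss trajectory
  (baseline 0.92 falling to ≈ 0.25, i.e. 1.5× the configured ≥ 40 pp
  loss) and a floor of 10 reads on its CpGs so the planted locus
  deterministically survives the coverage filters; its gene is silent at
  reference and set to twice `hallmark_fold` × pseudocount at the final
  state (≥ 1000-fold by construction).
* **Beta matrix** — group-1 probe means uniform on [0.1, 0.9]; true DMPs
  redrawn from [0.15, 0.97 − Δβ] so the +Δβ shift stays inside (0, 1);
  logit-space Gaussian noise keeps values strictly in (0, 1).

What the generator does **not** emulate: read sequences and bisulfite
conversion errors, strand-resolved CpG pairs, copy-number or mappability
artifacts, spatially correlated methylation beyond the bin structure,
probe cross-reactivity, or biological replicate variation in the WGBS
arm. Passing tests therefore demonstrate that the statistical machinery
recovers planted effects under the stated noise models, not that it is
robust to every artifact of real libraries.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical seeds give byte-identical outputs end to end
  (manifests carry no timestamps).
* Fractions in [0, 1] everywhere internally; thresholds compared with a
  1e−12 inclusive tolerance.
* K-means ties and restarts are fixed by `random_state`; archetype label
  assignment uses Hungarian matching on centroid–template Pearson
  correlation, which is injective even when two centroids resemble the
  same template.
* Nearest-TSS ties break to the lexicographically smaller gene id;
  equidistant annotations are therefore deterministic.
* Empty peak sets classify everything as "none" (logged); empty filter
  results are allowed and logged, not errors.
* The end-to-end determinism check and the acceptance script run the full
  two-chromosome, 5-Mb-per-chromosome design (~33k CpGs, ~10k bins); the
  operating-characteristic loops use 100–200 seeds at 1000–2000 units
  each. These sizes recover all planted structure while keeping a full
  run in well under a minute per pipeline pass.

## Known limitations

* Welch-based DMP calling is underpowered at n ≈ 4 per group compared to
  moderated statistics (see above); the joint gate's false-call rate is
  conservative (measured 0 across 200 null simulations).
* Gene association by nearest TSS ignores 3D contacts and multi-gene
  regulatory domains.
* The dynamic-bin gate operates on replicate-averaged trajectories; it
  does not test per-bin differential methylation from read counts (no
  beta-binomial model), matching the descriptive character of the
  upstream analyses.
* Trailing partial windows at chromosome ends are reported with nominal
  full width since chromosome lengths are not part of the input formats.
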