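"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a 4-timepoint (0/24/96/168 h) transdifferentiation
time course: CpGs placed with exponential spacing, 1-kb bins following one
of four temporal archetypes (monotone gain, transient gain, transient/late
loss, monotone late loss) or staying flat, overdispersed sequencing depth
(negative binomial) with binomial methylated-read counts, ATAC/H3K4me1
peaks planted at promoter/enhancer bins, an expression matrix whose
log2 fold-changes realize a configured correlation with promoter
demethylation, a hallmark locus combining strong promoter methylation loss
with a >=1000-fold expression gain, and a two-group beta-value matrix with
planted hypermethylated probes.

Planted correlations are realized *exactly* in-sample (Gram-Schmidt
construction against the methylation deltas the pipeline itself will
measure), so that recovery checks reflect the estimation path rather than
an extra layer of planting noise; see the methods notes for rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import annotation, methylome
from .dynamics import ARCHETYPE_TEMPLATES, timepoint_delta
from .integration import ExpressionMatrix
from .methylome import MethCalls

#: baseline methylation ranges per archetype, chosen so the template delta
#: never pushes the latent value outside [0, 1]
_BASELINE_RANGES = {
    "C-I": (0.05, 0.35),
    "C-II": (0.05, 0.45),
    "C-III": (0.50, 0.90),
    "C-IV": (0.60, 0.92),
    "flat": (0.05, 0.95),
}

ARCHETYPES = ("C-I", "C-II", "C-III", "C-IV", "flat")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic methylome and its regulome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    cpg_spacing_mean_bp: float = 300.0
    timepoints_h: tuple[int, ...] = (0, 24, 96, 168)
    n_replicates_per_timepoint: int = 1
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "C-I": 0.10, "C-II": 0.15, "C-III": 0.20, "C-IV": 0.30, "flat": 0.25,
        }
    )
    trajectory_noise_sd: float = 0.05
    n_genes: int = 4000
    promoter_effect_r: float = -0.25
    hallmark_delta: float = -0.45
    hallmark_fold: float = 1000.0
    dmp_n_probes: int = 1000
    dmp_n_true: int = 13
    dmp_delta_beta: float = 0.4
    dmp_noise_sd: float = 0.3
    group_sizes: tuple[int, int] = (4, 4)
    # analysis-facing knobs mirrored by the pipeline
    bin_width: int = 1000
    min_cov: int = 5
    min_cpgs: int = 3
    min_delta: float = 0.10
    tss_window: int = 2000
    expr_pseudocount: float = 0.5
    # regulome composition (fractions of archetype bins)
    promoter_fraction: float = 0.40
    enhancer_fraction: float = 0.30
    lfc_mean_loss: float = 1.5
    lfc_sd: float = 1.5

    def __post_init__(self) -> None:
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype fractions sum to {total}, expected 1")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        tps = list(self.timepoints_h)
        if len(tps) < 2:
            raise ValueError("need >= 2 timepoints")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        for name in ("n_chroms", "chrom_length_bp", "cpg_spacing_mean_bp",
                     "n_replicates_per_timepoint", "coverage_mean",
                     "coverage_dispersion", "n_genes", "dmp_n_probes",
                     "dmp_noise_sd", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.promoter_effect_r <= 0.0:
            raise ValueError("promoter_effect_r must lie in [-1, 0]")
        if self.hallmark_delta > -0.40:
            raise ValueError("hallmark_delta must be <= -0.40")
        if self.hallmark_fold < 1000:
            raise ValueError("hallmark_fold must be >= 1000")
        if not 0 < self.dmp_delta_beta < 1:
            raise ValueError("dmp_delta_beta must be in (0, 1)")
        if self.dmp_n_true > self.dmp_n_probes:
            raise ValueError("dmp_n_true cannot exceed dmp_n_probes")
        if min(self.group_sizes) < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass
class TruthSet:
    """Planted ground truth recoverable by the pipeline."""

    bin_archetype: dict[str, str] = field(default_factory=dict)
    gre_class: dict[str, str] = field(default_factory=dict)
    gene_for_region: dict[str, str] = field(default_factory=dict)
    planted_promoter_r: float | None = None
    hallmark_region_id: str | None = None
    hallmark_gene: str | None = None
    true_dmp_probes: set[str] = field(default_factory=set)


def _region_id(chrom: str, start: int, width: int) -> str:
    return f"{chrom}:{start}-{start + width}"


def _template_matrix(timepoints: tuple[int, ...]) -> dict[str, np.ndarray]:
    """Archetype delta templates resampled onto the configured timepoint count."""
    k = len(timepoints)
    out: dict[str, np.ndarray] = {"flat": np.zeros(k)}
    xs = np.linspace(0, 1, k)
    for name, tmpl in ARCHETYPE_TEMPLATES.items():
        xt = np.linspace(0, 1, len(tmpl))
        out[name] = np.interp(xs, xt, tmpl)
    return out


def exact_corr_vector(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """A unit-variance vector whose sample Pearson correlation with x is r.

    Gram-Schmidt: y = r * u + sqrt(1 - r^2) * v with u the standardized
    direction of x and v an orthogonal standardized noise direction, so
    corr(x, y) = r exactly (up to float rounding).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3 or np.std(x) == 0:
        return rng.standard_normal(n)
    u = x - x.mean()
    u /= np.linalg.norm(u)
    v = rng.standard_normal(n)
    v -= v.mean()
    v -= (v @ u) * u
    nv = np.linalg.norm(v)
    if nv == 0:  # pragma: no cover - measure-zero draw
        v = np.roll(u, 1) - np.roll(u, 1).mean()
        v -= (v @ u) * u
        nv = np.linalg.norm(v)
    v /= nv
    y = r * u + math.sqrt(max(0.0, 1.0 - r * r)) * v
    return y / y.std()


def simulate_methylome(cfg: SimConfig) -> tuple[MethCalls, TruthSet]:
    """Simulate per-CpG methylation counts over latent bin archetype trajectories.

    CpG positions have exponential spacing; each 1-kb bin draws an archetype
    and a baseline; per-CpG latent methylation is baseline + archetype delta
    + Gaussian noise clipped to [0, 1]; read totals are negative binomial
    (``coverage_mean``, ``coverage_dispersion``) and methylated counts
    binomial.  One bin is designated the hallmark locus: a strong-loss
    promoter trajectory whose CpGs get a depth floor so the planted locus
    deterministically survives the coverage filters.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    tmpls = _template_matrix(cfg.timepoints_h)
    n_tp = len(cfg.timepoints_h)

    chroms, positions = [], []
    for c in range(cfg.n_chroms):
        name = f"chr{c + 1}"
        n_guess = int(cfg.chrom_length_bp / cfg.cpg_spacing_mean_bp * 1.3) + 10
        gaps = rng.exponential(cfg.cpg_spacing_mean_bp, size=n_guess)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        pos = pos[(pos > 0) & (pos < cfg.chrom_length_bp)]
        chroms.append(np.repeat(name, len(pos)))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n_cpg = len(pos)

    starts = (pos // cfg.bin_width) * cfg.bin_width
    keys = np.char.add(np.char.add(chrom.astype(str), "\t"), starts.astype(str))
    bins, bin_idx = np.unique(keys, return_inverse=True)
    n_bins = len(bins)

    arch_names = list(cfg.archetype_fractions)
    arch_p = np.array([cfg.archetype_fractions[a] for a in arch_names])
    bin_arch = rng.choice(arch_names, size=n_bins, p=arch_p)
    lo = np.array([_BASELINE_RANGES[a][0] for a in bin_arch])
    hi = np.array([_BASELINE_RANGES[a][1] for a in bin_arch])
    bin_base = rng.uniform(lo, hi)

    # hallmark locus: a C-IV promoter-to-be with a deep, reliable loss;
    # only planted when the design includes the monotone-loss archetype
    cpg_per_bin = np.bincount(bin_idx, minlength=n_bins)
    hallmark_bin: int | None = None
    civ = np.flatnonzero(bin_arch == "C-IV")
    if len(civ):
        with4 = civ[cpg_per_bin[civ] >= 4]
        hallmark_bin = int(with4[0]) if len(with4) else \
            int(civ[np.argmax(cpg_per_bin[civ])])
        bin_base[hallmark_bin] = 0.92

    deltas = np.empty((n_bins, n_tp))
    for i, a in enumerate(bin_arch):
        deltas[i] = tmpls[a]
    if hallmark_bin is not None:
        hall_amp = min(1.5 * abs(cfg.hallmark_delta), bin_base[hallmark_bin] - 0.03)
        hall_shape = np.interp(np.linspace(0, 1, n_tp), [0, 0.15, 0.6, 1.0],
                               [0.0, -0.07, -0.7, -1.0])
        deltas[hallmark_bin] = hall_amp * hall_shape

    latent = bin_base[bin_idx, None] + deltas[bin_idx]
    latent = latent + rng.normal(0.0, cfg.trajectory_noise_sd, size=latent.shape)
    np.clip(latent, 0.0, 1.0, out=latent)

    nb_n = cfg.coverage_dispersion
    nb_p = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    is_hall = (bin_idx == hallmark_bin) if hallmark_bin is not None \
        else np.zeros(n_cpg, dtype=bool)
    frames = []
    sample_timepoints: dict[str, float] = {}
    for ti, tp in enumerate(cfg.timepoints_h):
        for rep in range(cfg.n_replicates_per_timepoint):
            sid = f"t{tp:03d}h_r{rep + 1}"
            sample_timepoints[sid] = float(tp)
            total = rng.negative_binomial(nb_n, nb_p, size=n_cpg)
            total[is_hall] = np.maximum(total[is_hall], 10)
            meth = rng.binomial(total, latent[:, ti])
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "sample_id": sid,
                "n_meth": meth, "n_total": total,
            }))
    df = pd.concat(frames, ignore_index=True)
    df = df[df["n_total"] > 0].reset_index(drop=True)

    truth = TruthSet()
    for b, a in zip(bins, bin_arch):
        c, s = b.split("\t")
        truth.bin_archetype[_region_id(c, int(s), cfg.bin_width)] = a
    if hallmark_bin is not None:
        c, s = bins[hallmark_bin].split("\t")
        truth.hallmark_region_id = _region_id(c, int(s), cfg.bin_width)
    return MethCalls(df, sample_timepoints), truth


def simulate_regulome_and_expression(
    cfg: SimConfig, truth: TruthSet, calls: MethCalls
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ExpressionMatrix]:
    """Plant ATAC/H3K4me1 peaks, gene TSSs and an anticorrelated expression matrix.

    Returns (atac_peaks, h3k4me1_peaks, gene_table, expression).  Promoter
    bins receive a TSS plus an ATAC peak over it; enhancer bins an ATAC and
    an overlapping H3K4me1 peak, placed away from every TSS; remaining
    genes go to GRE-free territory.  Expression log2 fold-changes for
    promoter-loss genes realize ``promoter_effect_r`` exactly against the
    realized bin deltas; gain-region genes realize r = 0; the hallmark gene
    is silent at reference and exceeds ``hallmark_fold`` at the final state.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    w = cfg.tss_window

    profiles = methylome.bin_methylation(
        methylome.filter_coverage(calls, cfg.min_cov), cfg.bin_width, cfg.min_cpgs
    )
    deltas = timepoint_delta(profiles, calls.sample_timepoints, cfg.min_delta)
    rid = profiles["chrom"].str.cat(
        (profiles["start"].astype(str) + "-" + profiles["end"].astype(str)), sep=":"
    )
    profiles = profiles.assign(region_id=rid)
    arch = profiles["region_id"].map(truth.bin_archetype)
    arch_bins = profiles[arch.notna() & (arch != "flat")].reset_index(drop=True)
    if arch_bins.empty:
        raise ValueError("no analyzable archetype bins; increase coverage or size")

    n_arch = len(arch_bins)
    n_prom = int(round(cfg.promoter_fraction * n_arch))
    if n_prom > cfg.n_genes:
        raise ValueError(f"{n_prom} promoters exceed n_genes={cfg.n_genes}")
    order = rng.permutation(n_arch)
    hall_pos_arr = np.flatnonzero(
        arch_bins["region_id"].to_numpy() == truth.hallmark_region_id)
    prom_idx = list(order[:n_prom])
    if len(hall_pos_arr):
        hall_i = int(hall_pos_arr[0])
        if hall_i not in prom_idx:
            prom_idx[0] = hall_i
    prom_set = set(prom_idx)

    # enhancers must keep their ATAC peak clear of every TSS window
    margin = cfg.bin_width + w + 500
    prom_df = arch_bins.loc[sorted(prom_set)]
    prom_starts = {
        c: np.sort(prom_df.loc[prom_df["chrom"] == c, "start"].to_numpy())
        for c in arch_bins["chrom"].unique()
    }
    enh_candidates = []
    for i in range(n_arch):
        if i in prom_set:
            continue
        c = arch_bins.at[i, "chrom"]
        s = arch_bins.at[i, "start"]
        ps = prom_starts[c]
        j = np.searchsorted(ps, s)
        near = []
        if j > 0:
            near.append(abs(s - ps[j - 1]))
        if j < len(ps):
            near.append(abs(ps[j] - s))
        if not near or min(near) >= margin:
            enh_candidates.append(i)
    n_enh = min(int(round(cfg.enhancer_fraction * n_arch)), len(enh_candidates))
    enh_pick = rng.permutation(len(enh_candidates))[:n_enh]
    enh_set = {enh_candidates[i] for i in enh_pick}

    gre_class = np.array(["none"] * n_arch, dtype=object)
    gre_class[list(prom_set)] = "promoter"
    gre_class[list(enh_set)] = "enhancer"
    for r, cl in zip(arch_bins["region_id"], gre_class):
        truth.gre_class[r] = cl

    # genes: one TSS inside each promoter bin, fillers in GRE-free territory
    gene_rows = []
    prom_order = sorted(prom_set)
    for k, i in enumerate(prom_order):
        c = arch_bins.at[i, "chrom"]
        s = int(arch_bins.at[i, "start"])
        tss = s + int(rng.integers(200, cfg.bin_width - 200))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{k + 1:05d}"
        gene_rows.append((gid, c, tss, strand))
    gre_rows = sorted(prom_set | enh_set)
    gre_df = arch_bins.loc[gre_rows]
    forbid = {
        c: np.sort(gre_df.loc[gre_df["chrom"] == c, "start"].to_numpy())
        for c in arch_bins["chrom"].unique()
    }
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    n_filler = cfg.n_genes - len(gene_rows)
    made = 0
    attempts = 0
    while made < n_filler and attempts < 50 * n_filler:
        attempts += 1
        c = chrom_names[int(rng.integers(cfg.n_chroms))]
        tss = int(rng.integers(w + 1, cfg.chrom_length_bp - w - 1))
        ps = forbid.get(c, np.array([], dtype=np.int64))
        j = np.searchsorted(ps, tss)
        clear = True
        if j > 0 and tss - ps[j - 1] < cfg.bin_width + w + 100:
            clear = False
        if j < len(ps) and ps[j] - tss < w + 100 + cfg.bin_width:
            clear = False
        if not clear:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"g{len(gene_rows) + 1:05d}", c, tss, strand))
        made += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss_pos", "strand"])

    # peaks
    tss_of_prom = {i: gene_rows[k][2] for k, i in enumerate(prom_order)}
    atac_rows, k4_rows = [], []
    for i in gre_rows:
        c = arch_bins.at[i, "chrom"]
        s = int(arch_bins.at[i, "start"])
        if i in prom_set:
            tss = tss_of_prom[i]
            half = int(rng.integers(100, 200))
            atac_rows.append((c, max(0, int(tss) - half), int(tss) + half))
        else:
            off = int(rng.integers(250, 400))
            width = int(rng.integers(250, 450))
            atac_rows.append((c, s + off, s + off + width))
            k4_rows.append((c, s + off - 50, s + off + width + 50))
    atac = pd.DataFrame(atac_rows, columns=["chrom", "start", "end"])
    atac["name"] = [f"atac_{i}" for i in range(len(atac))]
    h3k4me1 = pd.DataFrame(k4_rows, columns=["chrom", "start", "end"])
    h3k4me1["name"] = [f"k4me1_{i}" for i in range(len(h3k4me1))]

    # region -> gene map, via the same classifier the pipeline uses
    ann = annotation.classify_gre(
        arch_bins[["chrom", "start", "end"]], atac, h3k4me1, genes, tss_window=w
    )
    ann = ann.assign(region_id=arch_bins["region_id"].to_numpy())
    for r, g in zip(ann["region_id"], ann["associated_gene"]):
        if g is not None and not (isinstance(g, float) and np.isnan(g)):
            truth.gene_for_region[r] = g

    # strata on the realized deltas the pipeline will recompute
    dmap = deltas.assign(region_id=deltas["chrom"].str.cat(
        deltas["start"].astype(str) + "-" + deltas["end"].astype(str), sep=":"
    )).set_index("region_id")["delta"]
    ann = ann.assign(delta=ann["region_id"].map(dmap))
    hall_gene = truth.gene_for_region.get(truth.hallmark_region_id)
    loss = ann[(ann["gre_class"] == "promoter") & (ann["delta"] <= -cfg.min_delta)
               & (ann["region_id"] != truth.hallmark_region_id)]
    loss = loss.drop_duplicates(subset="associated_gene")
    gain = ann[(ann["gre_class"] != "none") & (ann["delta"] >= cfg.min_delta)]
    gain = gain.drop_duplicates(subset="associated_gene")
    gain = gain[~gain["associated_gene"].isin(loss["associated_gene"])]
    if hall_gene is not None:
        loss = loss[loss["associated_gene"] != hall_gene]
        gain = gain[gain["associated_gene"] != hall_gene]

    lfc = pd.Series(rng.normal(0.0, cfg.lfc_sd, len(genes)),
                    index=genes["gene_id"])
    if len(loss) >= 3:
        y = exact_corr_vector(loss["delta"].to_numpy(), cfg.promoter_effect_r, rng)
        lfc.loc[loss["associated_gene"]] = cfg.lfc_mean_loss + cfg.lfc_sd * y
    if len(gain) >= 3:
        y0 = exact_corr_vector(gain["delta"].to_numpy(), 0.0, rng)
        lfc.loc[gain["associated_gene"]] = cfg.lfc_sd * y0
    truth.planted_promoter_r = cfg.promoter_effect_r
    truth.hallmark_gene = hall_gene

    pc = cfg.expr_pseudocount
    base = rng.lognormal(3.0, 0.8, len(genes)) + 20.0
    mean_ref = pd.Series(base, index=genes["gene_id"])
    mean_fin = (mean_ref + pc) * np.power(2.0, lfc) - pc
    mean_fin = mean_fin.clip(lower=0.0)
    if hall_gene is not None:
        mean_ref.loc[hall_gene] = 0.0
        mean_fin.loc[hall_gene] = 2.0 * cfg.hallmark_fold * pc
    jit_r = rng.uniform(0.02, 0.10, len(genes))
    jit_f = rng.uniform(0.02, 0.10, len(genes))
    values = pd.DataFrame(
        {
            "ref_1": mean_ref * (1 + jit_r),
            "ref_2": mean_ref * (1 - jit_r),
            "final_1": mean_fin * (1 + jit_f),
            "final_2": mean_fin * (1 - jit_f),
        },
        index=genes["gene_id"],
    )
    expr = ExpressionMatrix(values, {"ref_1": "ref", "ref_2": "ref",
                                     "final_1": "final", "final_2": "final"})
    return atac, h3k4me1, genes, expr


def simulate_beta_matrix(cfg: SimConfig) -> tuple["BetaMatrix", TruthSet]:
    """Two-group beta-value matrix with planted hypermethylated probes.

    Group-1 probe means are uniform on [0.1, 0.9]; true DMPs get group-1
    means restricted so the +``dmp_delta_beta`` shift stays inside (0, 1);
    logit-space Gaussian noise with sd ``dmp_noise_sd`` yields strictly
    (0, 1) values.  Deterministic under the seed.
    """
    from .editing import BetaMatrix

    rng = np.random.default_rng([cfg.seed, 2])
    n = cfg.dmp_n_probes
    upper = min(0.9, 0.97 - cfg.dmp_delta_beta)
    if upper <= 0.15:
        raise ValueError(
            f"dmp_delta_beta={cfg.dmp_delta_beta} leaves no room for group means in (0,1)"
        )
    m1 = rng.uniform(0.1, 0.9, n)
    true_idx = rng.choice(n, size=cfg.dmp_n_true, replace=False)
    m1[true_idx] = rng.uniform(0.15, upper, cfg.dmp_n_true)
    m2 = m1.copy()
    m2[true_idx] += cfg.dmp_delta_beta

    n_ctrl, n_edit = cfg.group_sizes
    cols, data, groups = [], [], {}
    for j in range(n_ctrl):
        sid = f"ctrl_{j + 1}"
        cols.append(sid)
        groups[sid] = "control"
        data.append(expit(logit(m1) + rng.normal(0, cfg.dmp_noise_sd, n)))
    for j in range(n_edit):
        sid = f"edited_{j + 1}"
        cols.append(sid)
        groups[sid] = "edited"
        data.append(expit(logit(m2) + rng.normal(0, cfg.dmp_noise_sd, n)))
    probe_ids = [f"cg{i + 1:06d}" for i in range(n)]
    values = pd.DataFrame(np.column_stack(data), index=probe_ids, columns=cols)
    coords = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": "chr1",
        "pos": np.sort(rng.integers(0, cfg.chrom_length_bp, size=n)),
    })
    truth = TruthSet(true_dmp_probes={probe_ids[i] for i in true_idx})
    return BetaMatrix(values, groups, coords), truth


def simulate_bin_trajectories(
    n_bins: int,
    archetype_fractions: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    timepoints_h: tuple[int, ...] = (0, 24, 96, 168),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bin-level trajectories drawn directly from the archetype templates.

    A lightweight generator for clustering studies: no read counts, just
    per-bin trajectories (baseline + template + N(0, noise_sd) per
    timepoint, clipped to [0, 1]).  Returns a trajectory table compatible
    with :func:`methdyn.dynamics.cluster_trajectories` and the true labels.
    """
    fractions = archetype_fractions or {a: 0.25 for a in ARCHETYPE_TEMPLATES}
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("archetype fractions must sum to 1")
    rng = np.random.default_rng([seed, 3])
    tmpls = _template_matrix(timepoints_h)
    names = list(fractions)
    labels = rng.choice(names, size=n_bins, p=[fractions[a] for a in names])
    lo = np.array([_BASELINE_RANGES[a][0] for a in labels])
    hi = np.array([_BASELINE_RANGES[a][1] for a in labels])
    base = rng.uniform(lo, hi)
    T = np.stack([tmpls[a] for a in labels])
    traj = base[:, None] + T + rng.normal(0, noise_sd, size=T.shape)
    np.clip(traj, 0.0, 1.0, out=traj)
    df = pd.DataFrame(traj, columns=[f"t{tp:g}" for tp in timepoints_h])
    df.insert(0, "chrom", "sim")
    df.insert(1, "start", np.arange(n_bins) * 1000)
    df.insert(2, "end", np.arange(n_bins) * 1000 + 1000)
    return df, labels


def simulate_integration_records(
    n_promoter_loss: int = 1500,
    n_gain: int = 500,
    r: float = -0.25,
    seed: int = 0,
    hallmark: bool = True,
    hallmark_delta: float = -0.45,
    hallmark_fold: float = 1000.0,
    pseudocount: float = 0.5,
    lfc_mean_loss: float = 1.5,
    lfc_sd: float = 1.5,
) -> tuple[pd.DataFrame, str | None]:
    """Region-level integration records with planted correlation structure.

    Promoter-loss records get deltas uniform on [-0.55, -0.10] and log2
    fold-changes realizing ``r`` exactly; gain records get deltas on
    [0.10, 0.45] with r = 0.  When ``hallmark`` is set, one extra
    promoter-loss record mimics the planted hallmark locus (delta
    1.5x ``hallmark_delta``, expression fold 2x ``hallmark_fold``).
    Returns (records, hallmark_gene_id).
    """
    rng = np.random.default_rng([seed, 4])
    d_loss = rng.uniform(-0.55, -0.10, n_promoter_loss)
    lfc_loss = lfc_mean_loss + lfc_sd * exact_corr_vector(d_loss, r, rng)
    d_gain = rng.uniform(0.10, 0.45, n_gain)
    lfc_gain = lfc_sd * exact_corr_vector(d_gain, 0.0, rng)
    rows = []
    for i in range(n_promoter_loss):
        rows.append(("chrS", 1000 * i, 1000 * i + 1000, "promoter",
                     f"g{i + 1:05d}", d_loss[i], lfc_loss[i], "promoter_loss"))
    for i in range(n_gain):
        rows.append(("chrS", 10_000_000 + 1000 * i, 10_000_000 + 1000 * i + 1000,
                     "enhancer", f"h{i + 1:05d}", d_gain[i], lfc_gain[i], "gain"))
    hall_gene = None
    if hallmark:
        hall_gene = "HALLMARK"
        d = 1.5 * hallmark_delta
        lfc = float(np.log2((2 * hallmark_fold * pseudocount + pseudocount)
                            / pseudocount))
        rows.append(("chrS", 99_000_000, 99_001_000, "promoter",
                     hall_gene, d, lfc, "promoter_loss"))
    records = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gre_class", "gene_id",
                 "delta_meth", "log2fc", "group"],
    )
    return records, hall_gene


# ---------------------------------------------------------------------------
# file bundle


def write_simulation(cfg: SimConfig, outdir) -> dict[str, object]:
    """Run all generators and write the pipeline's input files to ``outdir``.

    Writes per-sample Bismark coverage files, a sample sheet, ATAC/H3K4me1
    and dCas9-binding BEDs, a gene BED6, expression + condition TSVs, the
    beta matrix with its probe sidecar and group map, a DEG list, and
    truth tables.  Returns a manifest of paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    calls, truth = simulate_methylome(cfg)
    atac, h3k4me1, genes, expr = simulate_regulome_and_expression(cfg, truth, calls)
    betas, beta_truth = simulate_beta_matrix(cfg)
    truth.true_dmp_probes = beta_truth.true_dmp_probes

    paths: dict[str, object] = {}
    sample_rows = []
    for sid, tp in calls.sample_timepoints.items():
        sub = calls.df[calls.df["sample_id"] == sid]
        p = os.path.join(outdir, f"{sid}.cov")
        pd.DataFrame({
            "chrom": sub["chrom"],
            "start": sub["pos"] + 1,
            "end": sub["pos"] + 1,
            "pct": (100 * sub["n_meth"] / sub["n_total"]).round(4),
            "n_meth": sub["n_meth"],
            "n_unmeth": sub["n_total"] - sub["n_meth"],
        }).to_csv(p, sep="\t", header=False, index=False)
        sample_rows.append((sid, tp, os.path.basename(p)))
        paths.setdefault("coverage", []).append(p)
    pd.DataFrame(sample_rows, columns=["sample_id", "timepoint_h", "path"]).to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False)

    annotation.write_bed(atac, os.path.join(outdir, "atac.bed"),
                         cols=["chrom", "start", "end", "name"])
    annotation.write_bed(h3k4me1, os.path.join(outdir, "h3k4me1.bed"),
                         cols=["chrom", "start", "end", "name"])
    gene_bed = pd.DataFrame({
        "chrom": genes["chrom"], "start": genes["tss_pos"],
        "end": genes["tss_pos"] + 1, "name": genes["gene_id"],
        "score": 0, "strand": genes["strand"],
    })
    annotation.write_bed(gene_bed, os.path.join(outdir, "genes.bed"))

    expr.values.rename_axis("gene_id").to_csv(
        os.path.join(outdir, "expression.tsv"), sep="\t", float_format="%.6g")
    pd.DataFrame(sorted(expr.conditions.items()),
                 columns=["sample_id", "condition"]).to_csv(
        os.path.join(outdir, "conditions.tsv"), sep="\t", index=False)

    betas.values.rename_axis("probe_id").to_csv(
        os.path.join(outdir, "beta.tsv"), sep="\t", float_format="%.8g")
    betas.coords.to_csv(os.path.join(outdir, "probes.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(betas.groups.items()),
                 columns=["sample_id", "group"]).to_csv(
        os.path.join(outdir, "beta_groups.tsv"), sep="\t", index=False)

    # a small dCas9-binding peak set: the hallmark promoter plus off-targets
    rng = np.random.default_rng([cfg.seed, 5])
    bind_rows = []
    if truth.hallmark_region_id:
        c, span = truth.hallmark_region_id.split(":")
        s = int(span.split("-")[0])
        bind_rows.append((c, s + 200, s + 800, "bind_target"))
    off = genes.sample(n=min(30, len(genes)), random_state=int(rng.integers(2**31)))
    for k, (_, g) in enumerate(off.iterrows()):
        bind_rows.append((g["chrom"], max(0, g["tss_pos"] - 300),
                          g["tss_pos"] + 300, f"bind_off_{k}"))
    binding = pd.DataFrame(bind_rows, columns=["chrom", "start", "end", "name"])
    annotation.write_bed(binding, os.path.join(outdir, "dcas9_binding.bed"),
                         cols=["chrom", "start", "end", "name"])
    degs = [g for g in ([truth.hallmark_gene] if truth.hallmark_gene else [])]
    degs += off["gene_id"].head(3).tolist()
    with open(os.path.join(outdir, "degs.txt"), "w") as fh:
        fh.write("\n".join(degs) + "\n")

    pd.DataFrame(
        [(r, truth.bin_archetype.get(r, ""), truth.gre_class.get(r, ""),
          truth.gene_for_region.get(r, "")) for r in sorted(truth.bin_archetype)],
        columns=["region_id", "archetype", "gre_class", "gene_id"],
    ).to_csv(os.path.join(outdir, "truth_regions.tsv"), sep="\t", index=False)
    pd.Series(sorted(truth.true_dmp_probes)).to_csv(
        os.path.join(outdir, "truth_dmps.txt"), index=False, header=False)
    with open(os.path.join(outdir, "truth_summary.tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"hallmark_region_id\t{truth.hallmark_region_id}\n")
        fh.write(f"hallmark_gene\t{truth.hallmark_gene}\n")
        fh.write(f"planted_promoter_r\t{truth.planted_promoter_r}\n")
    paths["outdir"] = outdir
    return {"paths": paths, "truth": truth, "config": asdict(cfg)}
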