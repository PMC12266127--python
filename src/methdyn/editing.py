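"""Epigenome-editing specificity screen: DMP calling and tri-set overlap.

Differentially methylated positions (DMPs) between control and edited
samples are called from array-style beta values with a per-probe Welch
two-sample t-test, Benjamini-Hochberg adjustment over all tested probes,
and a joint gate: FDR strictly below ``fdr_max`` AND an effect of at least
``delta_min`` beta units in the requested direction (inclusive, matching
the "equal to or greater than 30%" convention).  The specificity summary is
the three-way overlap of genes with dCas9-bound promoters, genes carrying
called DMPs, and differentially expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .integration import bh_adjust

logger = logging.getLogger(__name__)

EPS = 1e-12  # inclusive-threshold tolerance


@dataclass
class BetaMatrix:
    """Beta values (probes x samples) with probe coordinates and group labels."""

    values: pd.DataFrame
    groups: dict[str, str]  # sample -> {control, edited}
    coords: pd.DataFrame | None = None  # probe_id, chrom, pos

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("beta values must lie in [0, 1]")
        unmapped = set(self.values.columns) - set(self.groups)
        if unmapped:
            raise ValueError(f"samples without group labels: {sorted(unmapped)}")

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]


def call_dmps(
    betas: BetaMatrix,
    delta_min: float = 0.30,
    fdr_max: float = 0.05,
    direction: str = "hyper",
    exclude_probes: set[str] | None = None,
) -> pd.DataFrame:
    """Call DMPs under the joint effect-size / FDR gate.

    delta_beta = mean(edited) - mean(control).  Direction 'hyper' requires
    delta_beta >= delta_min, 'hypo' requires delta_beta <= -delta_min,
    'both' requires |delta_beta| >= delta_min.  Probes with zero variance in
    both groups and equal means get p = 1 by convention.  ``exclude_probes``
    supports masking of SNP-overlapping/cross-reactive probes.
    """
    if not 0 < delta_min < 1:
        raise ValueError("delta_min must be in (0, 1)")
    if direction not in ("hyper", "hypo", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    vals = betas.values
    if exclude_probes:
        vals = vals.loc[~vals.index.isin(exclude_probes)]
    ctrl = vals[betas.group_samples("control")].to_numpy(dtype=float)
    edit = vals[betas.group_samples("edited")].to_numpy(dtype=float)
    if ctrl.shape[1] < 2 or edit.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a Welch test")

    delta = edit.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(edit, ctrl, axis=1, equal_var=False)
    # degenerate probes: no variance anywhere
    flat = (ctrl.std(axis=1) == 0) & (edit.std(axis=1) == 0)
    equal = flat & (np.abs(delta) < 1e-12)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    unequal = flat & ~equal
    t = np.where(unequal, np.where(delta > 0, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)

    fdr = bh_adjust(p)
    if direction == "hyper":
        effect_ok = delta >= delta_min - EPS
    elif direction == "hypo":
        effect_ok = delta <= -(delta_min - EPS)
    else:
        effect_ok = np.abs(delta) >= delta_min - EPS
    called = (fdr < fdr_max) & effect_ok
    out = pd.DataFrame(
        {
            "probe_id": vals.index,
            "delta_beta": delta,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "called": called,
        }
    ).reset_index(drop=True)
    logger.info("call_dmps: %d of %d probes called (%s, delta>=%.2f, FDR<%.2f)",
                int(called.sum()), len(out), direction, delta_min, fdr_max)
    return out


def genes_with_bound_promoters(
    binding: pd.DataFrame, genes: pd.DataFrame, tss_window: int = 2000
) -> set[str]:
    """Genes whose TSS window ([tss-w, tss+w)) intersects >= 1 binding peak."""
    if binding.empty or genes.empty:
        return set()
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in binding.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    hit = set()
    for gid, chrom, tss in zip(genes["gene_id"], genes["chrom"], genes["tss_pos"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(max(0, int(tss) - tss_window),
                                             int(tss) + tss_window):
            hit.add(gid)
    return hit


def map_probes_to_genes(
    coords: pd.DataFrame, genes: pd.DataFrame, tss_window: int = 2000
) -> dict[str, str]:
    """Map probes to the nearest gene with a TSS within +/- ``tss_window``.

    Probes with no TSS in range are left unassigned.  Ties go to the
    lexicographically smaller gene_id.
    """
    out: dict[str, str] = {}
    by_chrom = {c: g.sort_values(["tss_pos", "gene_id"])
                for c, g in genes.groupby("chrom", sort=False)}
    for pid, chrom, pos in zip(coords["probe_id"], coords["chrom"], coords["pos"]):
        g = by_chrom.get(chrom)
        if g is None:
            continue
        d = np.abs(g["tss_pos"].to_numpy() - int(pos))
        best = int(np.min(d))
        if best > tss_window:
            continue
        cand = np.flatnonzero(d == best)
        ids = g["gene_id"].to_numpy()
        out[pid] = min((ids[i] for i in cand))
    return out


@dataclass
class OverlapReport:
    """Three-set overlap: marginal sizes plus the 7 disjoint intersection cells."""

    labels: tuple[str, str, str]
    sizes: dict[str, int]
    cells: dict[str, int]
    union: int
    members: dict[str, set] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cell": k, "count": v} for k, v in self.cells.items()]
        return pd.DataFrame(rows)


def overlap_sets(
    a: set, b: set, c: set, labels: tuple[str, str, str] = ("bound", "dmp", "deg")
) -> OverlapReport:
    """All disjoint intersection cells of three sets (UpSet-style tabulation)."""
    la, lb, lc = labels
    sets = {la: set(a), lb: set(b), lc: set(c)}
    union = set(a) | set(b) | set(c)
    cells: dict[str, int] = {}
    members: dict[str, set] = {}
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo)) if combo else set()
            outside = set.union(*(sets[l] for l in labels if l not in combo), set())
            exclusive = inside - outside
            key = "&".join(combo) + ("_only" if r < 3 else "")
            cells[key] = len(exclusive)
            members[key] = exclusive
    report = OverlapReport(
        labels=labels,
        sizes={l: len(sets[l]) for l in labels},
        cells=cells,
        union=len(union),
        members=members,
    )
    assert sum(cells.values()) == len(union), "overlap cells must partition the union"
    return report
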