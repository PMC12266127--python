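"""Regulatory-element classification and gene association for genomic windows.

A dynamic window is called a *promoter* GRE when it overlaps an ATAC peak
whose interval intersects a TSS window (default +/-2 kb, half-open), an
*enhancer* GRE when it overlaps an ATAC peak that intersects an H3K4me1
peak but no TSS window, and *none* otherwise.  Promoter wins ties.  All
coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, source: str | None = None) -> pd.DataFrame:
    """Read a BED3/BED6 file into a peak table (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: intervals must satisfy start < end")
    if source is not None:
        df["source"] = source
    return df


def write_bed(df: pd.DataFrame, path, cols: list[str] | None = None) -> None:
    cols = cols or [c for c in BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Read a BED6 of gene TSSs: name=gene_id, strand in column 6.

    TSS = start for '+' genes, end-1 for '-' genes (BED convention).
    """
    bed = read_bed(path)
    if "strand" not in bed.columns:
        raise ValueError(f"{path}: gene table must be BED6 with a strand column")
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    genes = pd.DataFrame(
        {"gene_id": bed["name"], "chrom": bed["chrom"], "tss_pos": tss,
         "strand": bed["strand"]}
    )
    if genes["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in enumerate(zip(grp["start"], grp["end"]))
        )
    return trees


def _validate_peaks(peaks: pd.DataFrame, label: str) -> None:
    if peaks[["start", "end"]].isna().any().any():
        raise ValueError(f"{label}: NaN coordinates")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError(f"{label}: intervals must satisfy start < end")


def nearest_tss(
    regions: pd.DataFrame, genes: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-TSS gene for each region midpoint.

    Returns (gene_ids, signed distances).  Distance is strand-aware:
    negative means the region lies upstream of the gene.  Midpoint-distance
    ties go to the lexicographically smaller gene_id.  Regions on a
    chromosome with no gene get gene_id None and distance NaN.
    """
    if genes.empty:
        raise ValueError("gene table is empty")
    gene_ids = np.empty(len(regions), dtype=object)
    dists = np.full(len(regions), np.nan)
    gsort = genes.sort_values(["chrom", "tss_pos", "gene_id"])
    by_chrom = {c: g for c, g in gsort.groupby("chrom", sort=False)}
    mid = ((regions["start"].to_numpy() + regions["end"].to_numpy()) // 2).astype(np.int64)
    for chrom, idx in regions.groupby("chrom", sort=False).indices.items():
        g = by_chrom.get(chrom)
        if g is None:
            continue
        tss = g["tss_pos"].to_numpy()
        ids = g["gene_id"].to_numpy()
        strands = g["strand"].to_numpy()
        for i in idx:
            m = mid[i]
            d = np.abs(tss - m)
            best = np.min(d)
            cand = np.flatnonzero(d == best)
            j = min(cand, key=lambda t: ids[t]) if len(cand) > 1 else cand[0]
            gene_ids[i] = ids[j]
            raw = m - tss[j]
            dists[i] = raw if strands[j] == "+" else -raw
    return gene_ids, dists


def classify_gre(
    bins: pd.DataFrame,
    atac: pd.DataFrame,
    h3k4me1: pd.DataFrame,
    genes: pd.DataFrame,
    tss_window: int = 2000,
) -> pd.DataFrame:
    """Classify windows as promoter / enhancer / none GREs.

    Promoter: window overlaps an ATAC peak intersecting [tss-w, tss+w).
    Enhancer: window overlaps an ATAC peak intersecting an H3K4me1 peak and
    no TSS window.  None otherwise (ATAC overlap is required for either
    class).  Adds ``gre_class``, ``associated_gene`` and ``distance_to_tss``
    columns; promoter regions take the gene whose TSS window their peak
    hits (nearest on ties), other regions the nearest-TSS gene.
    """
    if tss_window <= 0:
        raise ValueError("tss_window must be positive")
    out = bins.copy().reset_index(drop=True)
    n = len(out)
    gre = np.array(["none"] * n, dtype=object)
    if atac.empty:
        logger.info("empty ATAC peak set: all regions classified 'none'")
        out["gre_class"] = gre
        gid, dist = nearest_tss(out, genes)
        out["associated_gene"] = gid
        out["distance_to_tss"] = dist
        return out
    _validate_peaks(atac, "ATAC")
    atac = atac.reset_index(drop=True)

    # flag each ATAC peak: does it hit a TSS window / an H3K4me1 peak?
    tss_trees: dict[str, IntervalTree] = {}
    for chrom, g in genes.groupby("chrom", sort=False):
        tss_trees[chrom] = IntervalTree.from_tuples(
            (max(0, int(t) - tss_window), int(t) + tss_window, gid)
            for t, gid in zip(g["tss_pos"], g["gene_id"])
        )
    k4_trees = {}
    if not h3k4me1.empty:
        _validate_peaks(h3k4me1, "H3K4me1")
        k4_trees = _trees(h3k4me1)

    peak_is_prom = np.zeros(len(atac), dtype=bool)
    peak_is_enh = np.zeros(len(atac), dtype=bool)
    peak_genes: list[set] = [set() for _ in range(len(atac))]
    for i, (chrom, s, e) in enumerate(zip(atac["chrom"], atac["start"], atac["end"])):
        tt = tss_trees.get(chrom)
        if tt is not None:
            hits = tt.overlap(int(s), int(e))
            if hits:
                peak_is_prom[i] = True
                peak_genes[i] = {h.data for h in hits}
        kt = k4_trees.get(chrom)
        if kt is not None and kt.overlap(int(s), int(e)):
            peak_is_enh[i] = True

    atac_trees = _trees(atac)
    # map positional index within each chrom group back to the atac row
    chrom_rows = {c: g.index.to_numpy() for c, g in atac.groupby("chrom", sort=False)}

    assoc = np.empty(n, dtype=object)
    gid_near, dist_near = nearest_tss(out, genes)
    gene_pos = dict(zip(genes["gene_id"], genes["tss_pos"]))
    gene_strand = dict(zip(genes["gene_id"], genes["strand"]))
    dist = np.full(n, np.nan)
    for i, (chrom, s, e) in enumerate(zip(out["chrom"], out["start"], out["end"])):
        tree = atac_trees.get(chrom)
        if tree is None:
            continue
        hits = tree.overlap(int(s), int(e))
        if not hits:
            continue
        rows = [chrom_rows[chrom][h.data] for h in hits]
        prom_genes: set = set()
        for r in rows:
            if peak_is_prom[r]:
                prom_genes |= peak_genes[r]
        if prom_genes:
            gre[i] = "promoter"
            mid = (int(s) + int(e)) // 2
            best = min(prom_genes, key=lambda g: (abs(gene_pos[g] - mid), g))
            assoc[i] = best
            raw = mid - gene_pos[best]
            dist[i] = raw if gene_strand[best] == "+" else -raw
        elif any(peak_is_enh[r] for r in rows):
            gre[i] = "enhancer"
    out["gre_class"] = gre
    fill = pd.isna(assoc)
    assoc[fill] = gid_near[fill]
    dist[fill] = dist_near[fill]
    out["associated_gene"] = assoc
    out["distance_to_tss"] = dist
    return out


def annotate_feature(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    gene_models: pd.DataFrame | None = None,
    tss_window: int = 2000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label regions by genomic feature and tabulate the distribution.

    Priority promoter > exon > intron > intergenic, decided at the region
    midpoint.  ``gene_models`` is an exon table (chrom, start, end, gene_id);
    gene bodies are taken as each gene's exon span.  Without gene models only
    promoter/intergenic can be assigned (warned).  Returns the labelled
    table and a percentage distribution summing to 100.
    """
    if regions.empty:
        raise ValueError("no regions to annotate")
    out = regions.copy().reset_index(drop=True)
    mid = ((out["start"].to_numpy() + out["end"].to_numpy()) // 2).astype(np.int64)

    prom_trees = {
        c: IntervalTree.from_tuples(
            (max(0, int(t) - tss_window), int(t) + tss_window, None)
            for t in g["tss_pos"]
        )
        for c, g in genes.groupby("chrom", sort=False)
    }
    exon_trees, span_trees = {}, {}
    if gene_models is not None and not gene_models.empty:
        exon_trees = _trees(gene_models)
        spans = gene_models.groupby(["chrom", "gene_id"]).agg(
            start=("start", "min"), end=("end", "max")
        ).reset_index()
        span_trees = _trees(spans)
    else:
        warnings.warn("no gene models given: exon/intron labels unavailable")

    labels = np.empty(len(out), dtype=object)
    for i, (chrom, m) in enumerate(zip(out["chrom"], mid)):
        pt = prom_trees.get(chrom)
        if pt is not None and pt.overlap(int(m), int(m) + 1):
            labels[i] = "promoter"
        elif chrom in exon_trees and exon_trees[chrom].overlap(int(m), int(m) + 1):
            labels[i] = "exon"
        elif chrom in span_trees and span_trees[chrom].overlap(int(m), int(m) + 1):
            labels[i] = "intron"
        else:
            labels[i] = "intergenic"
    out["feature"] = labels
    dist = out["feature"].value_counts(normalize=True) * 100.0
    return out, dist


def associate_gene(
    regions: pd.DataFrame, genes: pd.DataFrame, tss_window: int = 2000
) -> pd.DataFrame:
    """Map each region to a gene by nearest TSS (midpoint distance).

    Returns the regions with ``associated_gene`` and signed
    ``distance_to_tss`` columns added (negative = upstream of the gene).
    """
    out = regions.copy().reset_index(drop=True)
    gid, dist = nearest_tss(out, genes)
    out["associated_gene"] = gid
    out["distance_to_tss"] = dist
    return out
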