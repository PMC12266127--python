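"""Methylation-expression integration and candidate ranking.

Regions that are accessible (GRE class promoter or enhancer) and change
methylation by at least ``min_delta`` between the reference and final states
are paired with the expression log2 fold-change of their associated gene and
grouped as promoter-loss, non-promoter-loss, or gain.  Per-group Pearson
correlations quantify the coupling; the promoter-loss group is ranked to
surface loci that combine strong demethylation with strong induction (the
IL1RN-style candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EPS = 1e-12  # inclusive-threshold tolerance


@dataclass
class ExpressionMatrix:
    """Normalized expression (genes x samples) with a sample->condition map."""

    values: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        unmapped = set(self.values.columns) - set(self.conditions)
        if unmapped:
            raise ValueError(f"samples without condition labels: {sorted(unmapped)}")

    def condition_mean(self, cond: str) -> pd.Series:
        cols = [s for s, c in self.conditions.items() if c == cond]
        if not cols:
            raise KeyError(f"unknown condition {cond!r}")
        return self.values[cols].mean(axis=1)


@dataclass
class CorrelationResult:
    group: str
    n: int
    r: float
    p_value: float


def log2_fold_change(
    expr: ExpressionMatrix,
    gene: str,
    cond_ref: str,
    cond_final: str,
    pseudocount: float = 0.5,
) -> float:
    """log2((mean_final + c) / (mean_ref + c)) for one gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if gene not in expr.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    ref = expr.condition_mean(cond_ref)[gene]
    fin = expr.condition_mean(cond_final)[gene]
    return float(np.log2((fin + pseudocount) / (ref + pseudocount)))


def _all_log2fc(
    expr: ExpressionMatrix, cond_ref: str, cond_final: str, pseudocount: float
) -> pd.Series:
    ref = expr.condition_mean(cond_ref)
    fin = expr.condition_mean(cond_final)
    return np.log2((fin + pseudocount) / (ref + pseudocount))


def build_integration_table(
    annotations: pd.DataFrame,
    deltas: pd.DataFrame,
    expr: ExpressionMatrix,
    min_delta: float = 0.10,
    cond_ref: str = "ref",
    cond_final: str = "final",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Join GRE annotations with methylation deltas and expression changes.

    Keeps accessible regions (gre_class != none) whose |delta| >= min_delta
    and whose associated gene is present in the expression matrix.  Groups:
    ``promoter_loss`` (promoter, delta <= -min_delta), ``nonpromoter_loss``
    (other GRE, delta <= -min_delta), ``gain`` (delta >= +min_delta).
    """
    key = ["chrom", "start", "end"]
    merged = annotations.merge(deltas[key + ["delta"]], on=key, how="inner")
    merged = merged[merged["gre_class"] != "none"]
    merged = merged[merged["delta"].abs() >= min_delta - EPS]
    no_gene = merged["associated_gene"].isna()
    if no_gene.any():
        logger.info("%d regions without an associated gene excluded", int(no_gene.sum()))
        merged = merged[~no_gene]
    lfc = _all_log2fc(expr, cond_ref, cond_final, pseudocount)
    known = merged["associated_gene"].isin(lfc.index)
    if (~known).any():
        logger.info("%d regions with genes absent from expression excluded",
                    int((~known).sum()))
        merged = merged[known]
    merged = merged.copy()
    merged["log2fc"] = lfc.loc[merged["associated_gene"]].to_numpy()
    merged["group"] = np.select(
        [
            (merged["gre_class"] == "promoter") & (merged["delta"] <= -(min_delta - EPS)),
            (merged["gre_class"] != "promoter") & (merged["delta"] <= -(min_delta - EPS)),
        ],
        ["promoter_loss", "nonpromoter_loss"],
        default="gain",
    )
    cols = key + ["gre_class", "associated_gene", "delta", "log2fc", "group"]
    out = merged[cols].rename(
        columns={"associated_gene": "gene_id", "delta": "delta_meth"}
    )
    return out.reset_index(drop=True)


def pearson_with_p(x, y, group: str = "") -> CorrelationResult:
    """Pearson r with a two-sided p from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(group=group, n=len(x),
                             r=float(res.statistic), p_value=float(res.pvalue))


def correlations_by_group(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group Pearson correlation of delta_meth vs log2fc."""
    rows = []
    for group, grp in table.groupby("group", sort=True):
        if len(grp) < 3:
            logger.info("group %s has n=%d < 3; skipped", group, len(grp))
            continue
        res = pearson_with_p(grp["delta_meth"], grp["log2fc"], group=group)
        rows.append({"group": group, "n": res.n, "r": res.r, "p_value": res.p_value})
    return pd.DataFrame(rows, columns=["group", "n", "r", "p_value"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_candidates(records: pd.DataFrame) -> pd.DataFrame:
    """Rank promoter-loss records by combined demethylation/induction rank.

    Score = rank of delta_meth ascending (most negative first) plus rank of
    log2fc descending (largest first), average ranks for ties; lower score
    ranks first.  Score ties break by higher log2fc, then gene_id.
    """
    prom = records[records["group"] == "promoter_loss"].copy()
    if prom.empty:
        raise ValueError("no promoter_loss records to rank")
    prom["_rd"] = stats.rankdata(prom["delta_meth"], method="average")
    prom["_rl"] = stats.rankdata(-prom["log2fc"].to_numpy(), method="average")
    prom["score"] = prom["_rd"] + prom["_rl"]
    prom = prom.sort_values(
        ["score", "log2fc", "gene_id"], ascending=[True, False, True]
    ).drop(columns=["_rd", "_rl"])
    prom["rank"] = np.arange(1, len(prom) + 1)
    return prom.reset_index(drop=True)
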