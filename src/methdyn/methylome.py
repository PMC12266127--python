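"""Per-CpG methylation calls, the all-sample coverage filter, and 1-kb binning.

The bin-level summary used throughout the pipeline is deliberately simple:
the genome is tiled from coordinate 0 into fixed-width half-open windows,
and a window's methylation in a sample is the unweighted mean of its CpGs'
methylated/total read fractions.  CpGs enter the analysis only if they are
covered at or above ``min_cov`` reads in *every* sample, and windows only if
they retain at least ``min_cpgs`` such CpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "sample_id", "n_meth", "n_total"]


class FormatError(ValueError):
    """Raised when an input file does not match the declared dialect."""


class DataError(ValueError):
    """Raised when file contents violate methylation-call invariants."""


@dataclass
class MethCalls:
    """Per-CpG, per-sample methylated/total read counts.

    ``df`` holds one row per (chrom, pos, sample_id) with integer counts;
    ``sample_timepoints`` maps each sample to its timepoint (hours), in
    acquisition order.  Positions are 0-based.
    """

    df: pd.DataFrame
    sample_timepoints: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"methylation call table lacks columns: {missing}")
        bad = self.df["n_meth"] > self.df["n_total"]
        if bad.any():
            rows = self.df.index[bad][:5].tolist()
            raise DataError(f"n_meth > n_total at rows {rows}")
        if (self.df["n_meth"] < 0).any() or (self.df["n_total"] < 0).any():
            raise DataError("negative read counts")
        dup = self.df.duplicated(subset=["chrom", "pos", "sample_id"])
        if dup.any():
            rows = self.df.index[dup][:5].tolist()
            raise DataError(f"duplicate (chrom, pos, sample) records at rows {rows}")
        if self.sample_timepoints:
            samples = set(self.df["sample_id"].unique())
            unmapped = samples - set(self.sample_timepoints)
            if unmapped:
                raise DataError(f"samples without a timepoint: {sorted(unmapped)}")

    @property
    def samples(self) -> list[str]:
        if self.sample_timepoints:
            return list(self.sample_timepoints)
        return sorted(self.df["sample_id"].unique())

    @property
    def n_cpgs(self) -> int:
        return len(self.df[["chrom", "pos"]].drop_duplicates())


def read_meth_calls(path, dialect: str, sample_id: str = "sample") -> pd.DataFrame:
    """Read one sample's per-CpG calls from a Bismark coverage or bedGraph file.

    ``bismark_cov`` columns: chrom, start(1-based), end(1-based), percent,
    count_methylated, count_unmethylated.  ``bedgraph`` columns: chrom,
    start(0-based), end, fraction, count_methylated, count_unmethylated.
    The percent/fraction column is ignored; fractions are recomputed from
    counts downstream.
    """
    if dialect not in ("bismark_cov", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "frac", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
            comment="#",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    if raw.shape[1] < 6 or raw[["start", "n_meth", "n_unmeth"]].isna().any().any():
        raise FormatError(f"{path}: expected 6 whitespace-separated columns")
    for col in ("start", "end", "n_meth", "n_unmeth"):
        if not np.allclose(raw[col], raw[col].astype(np.int64)):
            raise FormatError(f"{path}: non-integer values in column {col!r}")
        raw[col] = raw[col].astype(np.int64)
    bad = raw.index[raw["n_unmeth"] < 0]
    if len(bad):
        raise DataError(f"{path}: negative unmethylated count at line {bad[0] + 1}")
    bad = raw.index[raw["n_meth"] < 0]
    if len(bad):
        raise DataError(f"{path}: negative methylated count at line {bad[0] + 1}")
    pos = raw["start"] - 1 if dialect == "bismark_cov" else raw["start"]
    out = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": pos,
            "sample_id": sample_id,
            "n_meth": raw["n_meth"],
            "n_total": raw["n_meth"] + raw["n_unmeth"],
        }
    )
    return out


def load_meth_calls(
    sample_paths: dict[str, object],
    dialect: str,
    sample_timepoints: dict[str, float] | None = None,
) -> MethCalls:
    """Read several per-sample call files into one :class:`MethCalls`."""
    frames = [read_meth_calls(p, dialect, sample_id=s) for s, p in sample_paths.items()]
    df = pd.concat(frames, ignore_index=True)
    return MethCalls(df, dict(sample_timepoints or {}))


def filter_coverage(calls: MethCalls, min_cov: int = 5) -> MethCalls:
    """Keep CpGs covered >= ``min_cov`` reads in *every* sample.

    A CpG absent from any sample counts as uncovered there and is dropped.
    The retained-CpG count is logged; an empty result is allowed.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    df = calls.df
    n_samples = len(calls.samples)
    grp = df.groupby(["chrom", "pos"], sort=False)["n_total"]
    ok = (grp.transform("min") >= min_cov) & (grp.transform("size") == n_samples)
    kept = df[ok].reset_index(drop=True)
    out = MethCalls(kept, calls.sample_timepoints)
    logger.info(
        "coverage filter (>=%dx in all %d samples): %d of %d CpGs retained",
        min_cov, n_samples, out.n_cpgs, calls.n_cpgs,
    )
    return out


def bin_methylation(
    calls: MethCalls, bin_width: int = 1000, min_cpgs: int = 3
) -> pd.DataFrame:
    """Tile the genome into ``bin_width`` windows and average CpG fractions.

    Returns a wide table with one row per (chrom, start) window holding
    ``n_cpgs`` and one mean-methylation column per sample.  Windows tile each
    chromosome from coordinate 0 in half-open [start, start+width) intervals;
    only windows containing >= ``min_cpgs`` coverage-filtered CpGs are kept
    (pass ``min_cpgs=1`` for all CpG-containing windows).
    """
    if bin_width < 100:
        raise ValueError("bin_width must be >= 100")
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    df = calls.df.copy()
    df["frac"] = df["n_meth"] / df["n_total"]
    df["start"] = (df["pos"] // bin_width) * bin_width
    means = (
        df.pivot_table(index=["chrom", "start"], columns="sample_id",
                       values="frac", aggfunc="mean")
        .reindex(columns=calls.samples)
    )
    n_cpgs = df.groupby(["chrom", "start"])["pos"].nunique().rename("n_cpgs")
    out = pd.concat([n_cpgs, means], axis=1).reset_index()
    out["end"] = out["start"] + bin_width
    out = out[["chrom", "start", "end", "n_cpgs"] + list(calls.samples)]
    out = out[out["n_cpgs"] >= min_cpgs].reset_index(drop=True)
    out.columns.name = None
    return out


def write_bin_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
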