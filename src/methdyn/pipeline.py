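"""End-to-end orchestration: bin -> dynamics -> annotate -> correlate (-> dmp/overlap).

A single config drives the run; every stage writes a TSV and contributes row
counts to a JSON manifest.  Outputs carry no timestamps, so re-running with
an identical config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from . import annotation, dynamics, editing, integration, methylome


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    ``mode`` 'timecourse' clusters trajectories and uses the last-vs-first
    timepoint step change; 'two_group' compares two labelled sample groups
    directly (primary-cell style).
    """

    outdir: str = "methdyn_out"
    sample_sheet: str = ""          # TSV: sample_id, timepoint_h (or group), path
    dialect: str = "bismark_cov"
    atac_bed: str = ""
    h3k4me1_bed: str = ""
    genes_bed: str = ""
    expression_tsv: str = ""
    conditions_tsv: str = ""
    beta_tsv: str = ""
    beta_probes_tsv: str = ""
    beta_groups_tsv: str = ""
    binding_bed: str = ""
    degs_txt: str = ""
    mode: str = "timecourse"
    min_cov: int = 5
    min_cpgs: int = 3
    bin_width: int = 1000
    min_delta: float = 0.10
    k: int = 4
    tss_window: int = 2000
    pseudocount: float = 0.5
    cond_ref: str = "ref"
    cond_final: str = "final"
    delta_min: float = 0.30
    fdr_max: float = 0.05
    dmp_direction: str = "hyper"
    seed: int = 0
    thresholds_doc: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("timecourse", "two_group"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.min_delta < 1 or not 0 < self.delta_min < 1:
            raise ValueError("delta thresholds must lie in (0, 1)")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "thresholds": {
            "min_cov": cfg.min_cov, "min_cpgs": cfg.min_cpgs,
            "bin_width": cfg.bin_width, "min_delta": cfg.min_delta,
            "k": cfg.k, "tss_window": cfg.tss_window,
            "pseudocount": cfg.pseudocount, "delta_min": cfg.delta_min,
            "fdr_max": cfg.fdr_max,
        },
        "counts": {},
    }
    counts = manifest["counts"]

    # --- bin ---------------------------------------------------------------
    try:
        sheet = pd.read_csv(cfg.sample_sheet, sep="\t")
        if sheet.empty:
            raise ValueError("sample sheet is empty")
        base = os.path.dirname(os.path.abspath(cfg.sample_sheet))
        paths = {r["sample_id"]: os.path.join(base, r["path"])
                 for _, r in sheet.iterrows()}
        if cfg.mode == "timecourse":
            tps = {r["sample_id"]: float(r["timepoint_h"])
                   for _, r in sheet.iterrows()}
        else:
            tps = {s: 0.0 for s in paths}
            groups = {r["sample_id"]: str(r["group"]) for _, r in sheet.iterrows()}
        calls = methylome.load_meth_calls(paths, cfg.dialect, tps)
        if calls.df.empty:
            raise ValueError("no methylation calls loaded")
        counts["cpgs_input"] = calls.n_cpgs
        calls = methylome.filter_coverage(calls, cfg.min_cov)
        counts["cpgs_retained"] = calls.n_cpgs
        profiles = methylome.bin_methylation(calls, cfg.bin_width, cfg.min_cpgs)
        counts["bins_analyzable"] = len(profiles)
        methylome.write_bin_profiles(profiles, os.path.join(cfg.outdir, "bins.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("bin", str(exc)) from exc

    # --- dynamics ----------------------------------------------------------
    try:
        if cfg.mode == "timecourse":
            trajs = dynamics.select_dynamic_bins(
                profiles, calls.sample_timepoints, cfg.min_delta)
            counts["dynamic_bins"] = len(trajs)
            assignments = dynamics.cluster_trajectories(
                trajs, k=cfg.k, seed=cfg.seed)
            trajs = trajs.merge(assignments, on=["chrom", "start", "end"])
            deltas = dynamics.timepoint_delta(
                profiles, calls.sample_timepoints, cfg.min_delta)
        else:
            a_samples = [s for s, g in groups.items() if g == "a"]
            b_samples = [s for s, g in groups.items() if g == "b"]
            key = ["chrom", "start", "end"]
            deltas = dynamics.two_group_delta(
                profiles[key + a_samples], profiles[key + b_samples],
                cfg.min_delta)
            trajs = deltas[deltas["flagged"]].copy()
            counts["dynamic_bins"] = len(trajs)
        _write(trajs, os.path.join(cfg.outdir, "dynamic_bins.tsv"))
        _write(deltas, os.path.join(cfg.outdir, "deltas.tsv"))
    except Exception as exc:
        raise PipelineError("dynamics", str(exc)) from exc

    # --- annotate ----------------------------------------------------------
    try:
        atac = annotation.read_bed(cfg.atac_bed, source="ATAC")
        h3k4me1 = (annotation.read_bed(cfg.h3k4me1_bed, source="H3K4me1")
                   if cfg.h3k4me1_bed else pd.DataFrame(columns=["chrom", "start", "end"]))
        genes = annotation.read_gene_table(cfg.genes_bed)
        ann = annotation.classify_gre(
            trajs[["chrom", "start", "end"]], atac, h3k4me1, genes,
            tss_window=cfg.tss_window)
        counts["gre_promoter"] = int((ann["gre_class"] == "promoter").sum())
        counts["gre_enhancer"] = int((ann["gre_class"] == "enhancer").sum())
        counts["gre_none"] = int((ann["gre_class"] == "none").sum())
        _write(ann, os.path.join(cfg.outdir, "gre_annotations.tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    # --- correlate ---------------------------------------------------------
    try:
        values = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
        cond = pd.read_csv(cfg.conditions_tsv, sep="\t")
        conditions = dict(zip(cond["sample_id"], cond["condition"]))
        expr = integration.ExpressionMatrix(values, conditions)
        table = integration.build_integration_table(
            ann, deltas, expr, min_delta=cfg.min_delta,
            cond_ref=cfg.cond_ref, cond_final=cfg.cond_final,
            pseudocount=cfg.pseudocount)
        counts["integration_records"] = len(table)
        for g in ("promoter_loss", "nonpromoter_loss", "gain"):
            counts[f"records_{g}"] = int((table["group"] == g).sum())
        corrs = integration.correlations_by_group(table)
        ranked = (integration.rank_candidates(table)
                  if (table["group"] == "promoter_loss").any()
                  else pd.DataFrame())
        counts["candidates"] = len(ranked)
        _write(table, os.path.join(cfg.outdir, "integration_table.tsv"))
        _write(corrs, os.path.join(cfg.outdir, "correlations.tsv"))
        _write(ranked, os.path.join(cfg.outdir, "candidates.tsv"))
    except Exception as exc:
        raise PipelineError("correlate", str(exc)) from exc

    # --- dmp / overlap (optional) ------------------------------------------
    if cfg.beta_tsv:
        try:
            values = pd.read_csv(cfg.beta_tsv, sep="\t", index_col=0)
            gmap = pd.read_csv(cfg.beta_groups_tsv, sep="\t")
            coords = (pd.read_csv(cfg.beta_probes_tsv, sep="\t",
                                  dtype={"chrom": str})
                      if cfg.beta_probes_tsv else None)
            betas = editing.BetaMatrix(
                values, dict(zip(gmap["sample_id"], gmap["group"])), coords)
            dmps = editing.call_dmps(betas, delta_min=cfg.delta_min,
                                     fdr_max=cfg.fdr_max,
                                     direction=cfg.dmp_direction)
            counts["probes_tested"] = len(dmps)
            counts["dmps_called"] = int(dmps["called"].sum())
            _write(dmps, os.path.join(cfg.outdir, "dmps.tsv"))
        except Exception as exc:
            raise PipelineError("dmp", str(exc)) from exc

        if cfg.binding_bed and cfg.degs_txt:
            try:
                binding = annotation.read_bed(cfg.binding_bed, source="dCas9")
                bound = editing.genes_with_bound_promoters(
                    binding, genes, tss_window=cfg.tss_window)
                probe_gene = editing.map_probes_to_genes(
                    betas.coords, genes, tss_window=cfg.tss_window) \
                    if betas.coords is not None else {}
                dmp_genes = {probe_gene[p] for p in
                             dmps.loc[dmps["called"], "probe_id"]
                             if p in probe_gene}
                with open(cfg.degs_txt) as fh:
                    degs = {l.strip() for l in fh if l.strip()}
                report = editing.overlap_sets(bound, dmp_genes, degs)
                counts["genes_bound"] = report.sizes["bound"]
                counts["genes_dmp"] = report.sizes["dmp"]
                counts["genes_deg"] = report.sizes["deg"]
                counts["overlap_union"] = report.union
                _write(report.to_frame(),
                       os.path.join(cfg.outdir, "overlap.tsv"))
            except Exception as exc:
                raise PipelineError("overlap", str(exc)) from exc

    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_config(cfg: PipelineConfig, path) -> None:
    data = asdict(cfg)
    data.pop("thresholds_doc", None)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
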