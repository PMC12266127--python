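"""The synthetic-data generators and their planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn import (
    SimConfig,
    pearson_with_p,
    simulate_beta_matrix,
    simulate_bin_trajectories,
    simulate_integration_records,
    simulate_methylome,
    simulate_regulome_and_expression,
)
from methdyn.dynamics import ARCHETYPE_TEMPLATES


class TestSimConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            SimConfig(archetype_fractions={"C-I": 0.5, "flat": 0.4})

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            SimConfig(timepoints_h=(0,))

    def test_nonincreasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SimConfig(timepoints_h=(0, 96, 24))

    def test_weak_hallmark_rejected(self):
        with pytest.raises(ValueError, match="hallmark_delta"):
            SimConfig(hallmark_delta=-0.2)

    def test_overfull_beta_shift_rejected(self):
        cfg = SimConfig(dmp_delta_beta=0.86)
        with pytest.raises(ValueError, match="dmp_delta_beta"):
            simulate_beta_matrix(cfg)


class TestSimulateMethylome:
    def test_counts_respect_invariants(self, tiny_methylome):
        calls, _ = tiny_methylome
        df = calls.df
        assert (df["n_meth"] <= df["n_total"]).all()
        assert (df["n_meth"] >= 0).all() and (df["n_total"] > 0).all()

    def test_flat_noiseless_genome_is_time_constant(self):
        cfg = SimConfig(
            seed=2, n_chroms=1, chrom_length_bp=100_000, cpg_spacing_mean_bp=100,
            archetype_fractions={"flat": 1.0}, trajectory_noise_sd=0.0,
            coverage_mean=100.0,
        )
        calls, truth = simulate_methylome(cfg)
        assert truth.hallmark_region_id is None  # no C-IV bins to host it
        df = calls.df.copy()
        df["frac"] = df["n_meth"] / df["n_total"]
        by_tp = df.groupby("sample_id")["frac"].mean()
        assert by_tp.max() - by_tp.min() < 0.01  # binomial error only

    def test_pure_civ_loss_matches_template_amplitude(self, ):
        cfg = SimConfig(
            seed=3, n_chroms=1, chrom_length_bp=200_000, cpg_spacing_mean_bp=100,
            archetype_fractions={"C-IV": 1.0}, trajectory_noise_sd=0.0,
            coverage_mean=50.0,
        )
        calls, truth = simulate_methylome(cfg)
        df = calls.df.copy()
        df["frac"] = df["n_meth"] / df["n_total"]
        df["bin"] = df["pos"] // 1000 * 1000
        first, last = "t000h_r1", "t168h_r1"
        wide = df.pivot_table(index="bin", columns="sample_id", values="frac")
        hall_start = int(truth.hallmark_region_id.split(":")[1].split("-")[0])
        wide = wide.drop(index=hall_start)  # hallmark uses its own trajectory
        drop = wide[first] - wide[last]
        amplitude = -ARCHETYPE_TEMPLATES["C-IV"][-1]  # 0.4
        # per-bin empirical loss matches the template within binomial error
        assert drop.mean() == pytest.approx(amplitude, abs=0.02)

    def test_identical_seeds_are_byte_identical(self):
        cfg = SimConfig(seed=7, n_chroms=1, chrom_length_bp=50_000)
        a, _ = simulate_methylome(cfg)
        b, _ = simulate_methylome(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_hallmark_region_is_civ(self, tiny_methylome):
        _, truth = tiny_methylome
        assert truth.bin_archetype[truth.hallmark_region_id] == "C-IV"


class TestSimulateRegulome:
    def test_promoters_map_to_unique_genes(self, tiny_bundle):
        truth = tiny_bundle["truth"]
        prom_regions = [r for r, c in truth.gre_class.items() if c == "promoter"]
        genes = [truth.gene_for_region[r] for r in prom_regions]
        assert len(genes) == len(set(genes))

    def test_hallmark_is_promoter_with_massive_induction(self, tiny_bundle):
        truth, expr, cfg = (tiny_bundle["truth"], tiny_bundle["expr"],
                            tiny_bundle["cfg"])
        assert truth.gre_class[truth.hallmark_region_id] == "promoter"
        gene = truth.hallmark_gene
        ref = expr.condition_mean("ref")[gene]
        fin = expr.condition_mean("final")[gene]
        assert ref == pytest.approx(0.0)
        assert fin >= cfg.hallmark_fold * (ref + cfg.expr_pseudocount)

    def test_h3k4me1_only_at_enhancers(self, tiny_bundle):
        truth, k4 = tiny_bundle["truth"], tiny_bundle["h3k4me1"]
        enh_starts = {
            int(r.split(":")[1].split("-")[0])
            for r, c in truth.gre_class.items() if c == "enhancer"
        }
        assert len(k4) == len(enh_starts)
        assert {s // 1000 * 1000 for s in k4["start"]} <= enh_starts

    def test_null_effect_gives_null_correlation(self):
        cfg = SimConfig(seed=11, n_chroms=1, chrom_length_bp=400_000,
                        cpg_spacing_mean_bp=120, n_genes=400,
                        promoter_effect_r=0.0)
        calls, truth = simulate_methylome(cfg)
        atac, k4, genes, expr = simulate_regulome_and_expression(cfg, truth, calls)
        from methdyn import methylome, dynamics, annotation, integration

        profiles = methylome.bin_methylation(methylome.filter_coverage(calls, 5))
        deltas = dynamics.timepoint_delta(profiles, calls.sample_timepoints)
        ann = annotation.classify_gre(profiles[["chrom", "start", "end"]],
                                      atac, k4, genes)
        table = integration.build_integration_table(ann, deltas, expr)
        prom = table[table["group"] == "promoter_loss"]
        prom = prom[prom["gene_id"] != truth.hallmark_gene]
        res = pearson_with_p(prom["delta_meth"], prom["log2fc"])
        # 3 Fisher-z standard errors around the planted null
        assert abs(res.r) <= 3 / np.sqrt(res.n - 3)

    def test_promoters_cannot_outnumber_genes(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length_bp=300_000,
                        cpg_spacing_mean_bp=100, n_genes=10)
        calls, truth = simulate_methylome(cfg)
        with pytest.raises(ValueError, match="exceed n_genes"):
            simulate_regulome_and_expression(cfg, truth, calls)


class TestSimulateBetaMatrix:
    def test_null_pvalues_roughly_uniform(self):
        from methdyn import call_dmps

        cfg = SimConfig(seed=4, dmp_n_true=0, dmp_n_probes=2000)
        betas, truth = simulate_beta_matrix(cfg)
        assert truth.true_dmp_probes == set()
        out = call_dmps(betas)
        stat, p = stats.kstest(out["p_value"], "uniform")
        assert p > 1e-3

    def test_planted_shift_recovered_with_small_noise(self):
        cfg = SimConfig(seed=5, dmp_n_true=13, dmp_delta_beta=0.4,
                        dmp_noise_sd=0.05, group_sizes=(4, 4))
        betas, truth = simulate_beta_matrix(cfg)
        ctrl = betas.values[betas.group_samples("control")].mean(axis=1)
        edit = betas.values[betas.group_samples("edited")].mean(axis=1)
        delta = (edit - ctrl).loc[sorted(truth.true_dmp_probes)]
        assert ((delta - 0.4).abs() < 0.05).all()

    def test_values_in_open_unit_interval_and_deterministic(self):
        cfg = SimConfig(seed=6)
        a, _ = simulate_beta_matrix(cfg)
        b, _ = simulate_beta_matrix(cfg)
        assert ((a.values > 0) & (a.values < 1)).all().all()
        pd.testing.assert_frame_equal(a.values, b.values)


class TestRecordLevelSimulators:
    def test_trajectories_have_planted_label_structure(self):
        traj, labels = simulate_bin_trajectories(500, noise_sd=0.0, seed=8)
        mat = traj[["t0", "t24", "t96", "t168"]].to_numpy()
        for name, tmpl in ARCHETYPE_TEMPLATES.items():
            rows = mat[labels == name]
            if len(rows) == 0:
                continue
            deltas = rows - rows[:, [0]]
            np.testing.assert_allclose(deltas, np.tile(tmpl, (len(rows), 1)),
                                       atol=1e-9)

    def test_integration_records_realize_requested_correlation(self):
        records, hall = simulate_integration_records(
            n_promoter_loss=1500, n_gain=500, r=-0.25, seed=10
        )
        prom = records[(records["group"] == "promoter_loss")
                       & (records["gene_id"] != hall)]
        res = pearson_with_p(prom["delta_meth"], prom["log2fc"])
        assert res.r == pytest.approx(-0.25, abs=1e-9)
        gain = records[records["group"] == "gain"]
        assert pearson_with_p(gain["delta_meth"], gain["log2fc"]).r == \
            pytest.approx(0.0, abs=1e-9)
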