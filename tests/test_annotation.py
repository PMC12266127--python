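"""GRE classification, feature annotation, and nearest-TSS gene association."""

import numpy as np
import pandas as pd
import pytest

from methdyn import annotation
from methdyn.annotation import (
    annotate_feature,
    associate_gene,
    classify_gre,
    nearest_tss,
    read_bed,
    read_gene_table,
)


def regions(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def peaks(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def gene_table(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss_pos", "strand"])


EMPTY = pd.DataFrame(columns=["chrom", "start", "end"])


class TestClassifyGre:
    def test_atac_peak_near_tss_makes_promoter(self):
        bins = regions(("chr1", 10_000, 11_000))
        atac = peaks(("chr1", 10_400, 10_600))
        genes = gene_table(("gA", "chr1", 10_100, "+"))  # peak at TSS-500..TSS+500
        out = classify_gre(bins, atac, EMPTY, genes, tss_window=2000)
        assert out.loc[0, "gre_class"] == "promoter"
        assert out.loc[0, "associated_gene"] == "gA"

    def test_atac_with_h3k4me1_far_from_tss_is_enhancer(self):
        bins = regions(("chr1", 10_000, 11_000))
        atac = peaks(("chr1", 10_400, 10_600))
        k4 = peaks(("chr1", 10_300, 10_700))
        genes = gene_table(("gA", "chr1", 60_000, "+"))
        out = classify_gre(bins, atac, k4, genes, tss_window=2000)
        assert out.loc[0, "gre_class"] == "enhancer"
        assert out.loc[0, "associated_gene"] == "gA"  # nearest TSS fallback

    def test_h3k4me1_without_atac_is_none(self):
        bins = regions(("chr1", 10_000, 11_000))
        k4 = peaks(("chr1", 10_300, 10_700))
        atac = peaks(("chr2", 0, 100))  # no overlap on chr1
        genes = gene_table(("gA", "chr1", 60_000, "+"))
        out = classify_gre(bins, atac, k4, genes)
        assert out.loc[0, "gre_class"] == "none"

    def test_promoter_wins_over_enhancer_evidence(self):
        bins = regions(("chr1", 10_000, 11_000))
        atac = peaks(("chr1", 10_400, 10_600))
        k4 = peaks(("chr1", 10_300, 10_700))
        genes = gene_table(("gA", "chr1", 10_500, "+"))
        out = classify_gre(bins, atac, k4, genes)
        assert out.loc[0, "gre_class"] == "promoter"

    def test_empty_atac_gives_all_none(self):
        bins = regions(("chr1", 0, 1000), ("chr1", 5000, 6000))
        genes = gene_table(("gA", "chr1", 500, "+"))
        out = classify_gre(bins, EMPTY, EMPTY, genes)
        assert (out["gre_class"] == "none").all()

    def test_partition_is_exclusive_and_exhaustive(self, rng):
        bins = regions(*[("chr1", int(s), int(s) + 1000)
                         for s in rng.integers(0, 200_000, 40) // 1000 * 1000])
        atac = peaks(*[("chr1", int(s), int(s) + 300)
                       for s in rng.integers(0, 200_000, 25)])
        k4 = peaks(*[("chr1", int(s), int(s) + 400)
                     for s in rng.integers(0, 200_000, 15)])
        genes = gene_table(*[(f"g{i}", "chr1", int(p), "+")
                             for i, p in enumerate(rng.integers(0, 200_000, 10))])
        out = classify_gre(bins, atac, k4, genes)
        assert set(out["gre_class"]) <= {"promoter", "enhancer", "none"}
        assert len(out) == len(bins)

    def test_matches_brute_force_rule(self, rng):
        for trial in range(40):
            r = np.random.default_rng(trial)
            bins = regions(*[("c", int(s), int(s + r.integers(200, 1500)))
                             for s in r.integers(0, 30_000, 8)])
            atac = peaks(*[("c", int(s), int(s + r.integers(100, 800)))
                           for s in r.integers(0, 30_000, 6)])
            k4 = peaks(*[("c", int(s), int(s + r.integers(100, 800)))
                         for s in r.integers(0, 30_000, 4)])
            genes = gene_table(*[(f"g{i}", "c", int(p), "+")
                                 for i, p in enumerate(r.integers(0, 30_000, 5))])
            out = classify_gre(bins, atac, k4, genes, tss_window=2000)

            def overlaps(s1, e1, s2, e2):
                return s1 < e2 and s2 < e1

            for i, b in bins.iterrows():
                prom = enh = False
                for _, a in atac.iterrows():
                    if not overlaps(b.start, b.end, a.start, a.end):
                        continue
                    if any(overlaps(a.start, a.end, t - 2000, t + 2000)
                           for t in genes["tss_pos"]):
                        prom = True
                    if any(overlaps(a.start, a.end, k.start, k.end)
                           for _, k in k4.iterrows()):
                        enh = True
                expect = "promoter" if prom else ("enhancer" if enh else "none")
                assert out.loc[i, "gre_class"] == expect

    def test_translation_invariance(self):
        shift = 37_000
        bins = regions(("chr1", 10_000, 11_000))
        atac = peaks(("chr1", 10_400, 10_600))
        k4 = peaks(("chr1", 10_300, 10_700))
        genes = gene_table(("gA", "chr1", 10_100, "+"))
        a = classify_gre(bins, atac, k4, genes)
        b = classify_gre(
            bins.assign(start=bins.start + shift, end=bins.end + shift),
            atac.assign(start=atac.start + shift, end=atac.end + shift),
            k4.assign(start=k4.start + shift, end=k4.end + shift),
            genes.assign(tss_pos=genes.tss_pos + shift),
        )
        assert a.loc[0, "gre_class"] == b.loc[0, "gre_class"]
        assert a.loc[0, "distance_to_tss"] == b.loc[0, "distance_to_tss"]


class TestAnnotateFeature:
    def test_promoter_priority_over_intron(self):
        regs = regions(("chr1", 900, 1100))  # midpoint 1000
        genes = gene_table(("gA", "chr1", 1500, "+"))
        exons = pd.DataFrame(
            [("chr1", 0, 500, "gA"), ("chr1", 4000, 5000, "gA")],
            columns=["chrom", "start", "end", "gene_id"],
        )
        out, dist = annotate_feature(regs, genes, exons)
        assert out.loc[0, "feature"] == "promoter"

    def test_exon_intron_intergenic(self):
        genes = gene_table(("gA", "chr1", 100_000, "+"))
        exons = pd.DataFrame(
            [("chr1", 100_000, 100_500, "gA"), ("chr1", 104_000, 105_000, "gA")],
            columns=["chrom", "start", "end", "gene_id"],
        )
        regs = regions(
            ("chr1", 104_100, 104_300),   # exon
            ("chr1", 103_000, 103_200),   # intron (inside span, not exon, not TSS+-2k)
            ("chr1", 500_000, 500_200),   # intergenic
        )
        out, dist = annotate_feature(regs, genes, exons)
        assert out["feature"].tolist() == ["exon", "intron", "intergenic"]
        assert dist.sum() == pytest.approx(100.0)

    def test_all_intergenic_distribution(self):
        regs = regions(("chr1", 0, 100), ("chr1", 200, 300))
        genes = gene_table(("gA", "chr2", 50_000, "+"))
        with pytest.warns(UserWarning):
            out, dist = annotate_feature(regs, genes, None)
        assert dist.to_dict() == {"intergenic": 100.0}

    def test_matches_midpoint_oracle(self, rng):
        genes = gene_table(*[(f"g{i}", "c", int(p), "+")
                             for i, p in enumerate(rng.integers(0, 50_000, 4))])
        exons = pd.DataFrame(
            [("c", int(s), int(s) + 600, f"g{i % 4}")
             for i, s in enumerate(rng.integers(0, 50_000, 8))],
            columns=["chrom", "start", "end", "gene_id"],
        )
        regs = regions(*[("c", int(s), int(s) + 200)
                         for s in rng.integers(0, 50_000, 20)])
        out, _ = annotate_feature(regs, genes, exons)
        spans = exons.groupby("gene_id").agg(s=("start", "min"), e=("end", "max"))
        for i, r in regs.iterrows():
            m = (r.start + r.end) // 2
            if any(-2000 <= m - t < 2000 for t in genes["tss_pos"]):
                expect = "promoter"
            elif any((m >= e.start) and (m < e.end) for _, e in exons.iterrows()):
                expect = "exon"
            elif any((m >= x.s) and (m < x.e) for _, x in spans.iterrows()):
                expect = "intron"
            else:
                expect = "intergenic"
            assert out.loc[i, "feature"] == expect


class TestAssociateGene:
    def test_upstream_distance_is_negative(self):
        regs = regions(("chr1", 950, 1050))  # midpoint 1000
        genes = gene_table(("gA", "chr1", 1100, "+"))
        out = associate_gene(regs, genes)
        assert out.loc[0, "associated_gene"] == "gA"
        assert out.loc[0, "distance_to_tss"] == -100

    def test_minus_strand_flips_sign(self):
        regs = regions(("chr1", 950, 1050))
        genes = gene_table(("gA", "chr1", 900, "-"))
        out = associate_gene(regs, genes)
        assert out.loc[0, "distance_to_tss"] == -100  # upstream of a minus gene

    def test_tie_breaks_lexicographically(self):
        regs = regions(("chr1", 950, 1050))
        genes = gene_table(("gB", "chr1", 900, "+"), ("gA", "chr1", 1100, "+"))
        out = associate_gene(regs, genes)
        assert out.loc[0, "associated_gene"] == "gA"

    def test_matches_exhaustive_search(self, rng):
        genes = gene_table(*[(f"g{i:02d}", "c", int(p), "+")
                             for i, p in enumerate(rng.integers(0, 100_000, 10))])
        regs = regions(*[("c", int(s), int(s) + 400)
                         for s in rng.integers(0, 100_000, 50)])
        gid, dist = nearest_tss(regs, genes)
        for i, r in regs.iterrows():
            m = (r.start + r.end) // 2
            best = min(
                genes.itertuples(),
                key=lambda g: (abs(g.tss_pos - m), g.gene_id),
            )
            assert gid[i] == best.gene_id
            assert dist[i] == m - best.tss_pos


class TestBedIO:
    def test_roundtrip_and_gene_tss_convention(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\tgPlus\t0\t+\nchr1\t300\t400\tgMinus\t0\t-\n")
        genes = read_gene_table(p)
        assert genes.set_index("gene_id")["tss_pos"].to_dict() == {
            "gPlus": 100, "gMinus": 399,
        }

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="start < end"):
            read_bed(p)
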