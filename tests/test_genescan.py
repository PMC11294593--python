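"""Gene scan layer: exon FST, flanks, percentiles, haplotype calls, chi2."""

import numpy as np
import pandas as pd
import pytest

from krillpop import genescan, popio
from krillpop.divergence import ContrastSpec
from krillpop.genescan import (
    call_haplotypes,
    chisq_enrichment_2x2,
    cumulative_fst_curves,
    exon_fst,
    flank_percentiles,
    gene_flank_enrichment,
    make_flanks,
    summarize_sweep_scores,
)


def _hm(calls, positions, samples):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[1]
    return popio.HaplotypeMatrix(
        np.full(n, "c", dtype=object),
        np.asarray(positions),
        np.full(n, "A", dtype=object),
        np.full(n, "T", dtype=object),
        calls,
        samples,
    )


class TestExonFst:
    def test_single_fixed_difference_equals_per_locus(self, worked_example):
        e = worked_example["expected"]
        got = exon_fst(
            worked_example["hm"], worked_example["genes"],
            worked_example["contrast"], worked_example["mask"],
        )
        assert got["exon_fst"].iloc[0] == pytest.approx(e["exon_reynolds_fst"], rel=1e-12)
        assert got["n_exonic_snps"].iloc[0] == 3

    def test_gene_without_exonic_snps_missing(self):
        hm = _hm([[1], [0], [1], [0]], [500], ["a", "b"])
        genes = popio.GeneSet([popio.Gene("g", "c", "+", 10, 60, exons=[(10, 60)])])
        ctr = ContrastSpec("x", ["a"], ["b"])
        got = exon_fst(hm, genes, ctr)
        assert np.isnan(got["exon_fst"].iloc[0])

    def test_planted_gene_matches_generator_contract(self, small_synth):
        got = exon_fst(
            small_synth["read_hm"], small_synth["read_genes"],
            small_synth["contrast"], small_synth["read_mask"],
        )
        for rec in small_synth["truth"]["planted_genes"]:
            row = got[got.gene_id == rec["gene_id"]].iloc[0]
            assert row["exon_fst"] == pytest.approx(rec["expected_exon_fst"], abs=0.05)

    def test_order_and_orientation_invariance(self, small_synth):
        hm = small_synth["read_hm"].take_sites(np.arange(2000))
        genes = popio.GeneSet(small_synth["read_genes"][:5])
        c = small_synth["contrast"]
        base = exon_fst(hm, genes, c)
        flipped = ContrastSpec("r", c.group2, c.group1)
        other = exon_fst(hm, genes, flipped)
        assert np.allclose(base["exon_fst"], other["exon_fst"], equal_nan=True)


class TestFlanks:
    LEN = {"c": 1_000_000}

    def test_isolated_gene_gets_two_flanks(self):
        genes = popio.GeneSet(
            [popio.Gene("g", "c", "+", 400_000, 402_000, exons=[(400_000, 402_000)])]
        )
        fl = make_flanks(genes, self.LEN)
        assert set(fl["side"]) == {"up", "down"}
        up = fl[fl.side == "up"].iloc[0]
        assert (up.start, up.end) == (400_000 - 100_000, 400_000 - 50_000)

    def test_contig_edge_discards_side(self):
        genes = popio.GeneSet(
            [popio.Gene("g", "c", "+", 60_000, 62_000, exons=[(60_000, 62_000)])]
        )
        fl = make_flanks(genes, self.LEN)
        assert fl["side"].tolist() == ["down"]

    def test_overlap_with_any_gene_body_discards(self):
        g1 = popio.Gene("a", "c", "+", 400_000, 402_000, exons=[(400_000, 402_000)])
        g2 = popio.Gene("b", "c", "+", 330_000, 331_000, exons=[(330_000, 331_000)])
        fl = make_flanks(popio.GeneSet([g1, g2]), self.LEN)
        # a's upstream flank [300k,350k) overlaps b -> dropped
        assert ("a", "up") not in set(zip(fl.gene_id, fl.side))

    def test_count_matches_brute_force_interval_arithmetic(self, rng):
        starts = np.sort(rng.choice(np.arange(10_000, 900_000, 1000), 40, replace=False))
        genes = popio.GeneSet(
            [popio.Gene(f"g{i}", "c", "+", int(s), int(s) + 800, exons=[(int(s), int(s) + 800)])
             for i, s in enumerate(starts)]
        )
        fl = make_flanks(genes, self.LEN, flank_size=20_000, gap=20_000)
        bodies = [(g.start, g.end) for g in genes]
        expect = 0
        for g in genes:
            for s, e in ((g.start - 40_000, g.start - 20_000), (g.end + 20_000, g.end + 40_000)):
                if s < 0 or e > 1_000_000:
                    continue
                if any(s < be and e > bs for bs, be in bodies):
                    continue
                expect += 1
        assert len(fl) == expect


class TestFlankPercentiles:
    def test_exhaustive_small_case(self):
        vals = np.arange(1, 1001) / 1000.0
        thr = flank_percentiles(vals, levels=[0.01, 0.001])
        assert thr[0.001] == pytest.approx(0.999)
        assert thr[0.01] == pytest.approx(0.990)

    def test_constant_values(self):
        thr = flank_percentiles(np.full(2000, 0.3), levels=[0.01, 0.001])
        assert thr[0.01] == thr[0.001] == 0.3

    def test_monotone_in_level(self, rng):
        vals = rng.random(5000)
        thr = flank_percentiles(vals, levels=[0.05, 0.01, 0.001])
        assert thr[0.05] <= thr[0.01] <= thr[0.001]


class TestEnrichment:
    def test_identical_distributions_ratio_near_one(self, rng):
        vals = rng.random(4000)
        thr = flank_percentiles(vals[:2000], levels=[0.01])
        enr = gene_flank_enrichment(vals[2000:], vals[:2000], thr)
        assert enr["ratio"].iloc[0] == pytest.approx(1.0, abs=0.6)

    def test_counts_conserve_totals(self, rng):
        g, f = rng.random(500), rng.random(800)
        thr = flank_percentiles(f, levels=[0.01])
        enr = gene_flank_enrichment(g, f, thr)
        assert enr["n_genes"].iloc[0] == 500
        assert enr["n_flanks"].iloc[0] == 800
        assert enr["genes_above"].iloc[0] <= 500

    def test_planted_sweeps_inflate_top_ratio(self, rng):
        flanks = rng.normal(0.05, 0.02, 2000).clip(0, 1)
        genes = np.concatenate([rng.normal(0.05, 0.02, 950), rng.normal(0.7, 0.05, 50)]).clip(0, 1)
        thr = flank_percentiles(flanks, levels=[0.01])
        enr = gene_flank_enrichment(genes, flanks, thr)
        assert enr["ratio"].iloc[0] > 2
        curves = cumulative_fst_curves(genes, flanks)
        assert (curves["prop_genes"] >= curves["prop_flanks"] - 0.02).all()


class TestCallHaplotypes:
    def _setup(self, calls_g1, calls_g2, positions):
        samples = [f"a{i}" for i in range(len(calls_g1[0]) // 2)] + [
            f"b{i}" for i in range(len(calls_g2[0]) // 2)
        ]
        # calls_g1/g2 are per-site lists over haplotypes: stack to haps x sites
        calls = np.concatenate(
            [np.asarray(calls_g1, dtype=np.int8).T, np.asarray(calls_g2, dtype=np.int8).T],
            axis=0,
        )
        hm = _hm(calls, positions, samples)
        panel = popio.SamplePanel(
            samples, ["p1"] * (len(calls_g1[0]) // 2) + ["p2"] * (len(calls_g2[0]) // 2)
        )
        n1 = len(calls_g1[0]) // 2
        ctr = ContrastSpec("x", samples[:n1], samples[n1:])
        genes = popio.GeneSet(
            [popio.Gene("g", "c", "+", 0, max(positions) + 10,
                        exons=[(0, max(positions) + 10)])]
        )
        return hm, panel, ctr, genes

    def test_fixed_difference_gene_is_private(self):
        """Class A fixed in group 1, class B fixed in group 2: not shared."""
        n_sites = 5
        g1 = [[0] * 8 for _ in range(n_sites)]  # 4 diploids, all class A
        g2 = [[1] * 8 for _ in range(n_sites)]
        hm, panel, ctr, genes = self._setup(g1, g2, list(range(10, 10 + n_sites)))
        records = exon_fst(hm, genes, ctr)
        calls = call_haplotypes(hm, records, genes, ctr, panel, min_diag=4)
        assert len(calls) == 1
        assert calls[0].sharing == "private-to-group2"
        assert len(calls[0].diagnostic_positions) == 5

    def test_shared_when_both_classes_in_both_groups(self):
        n_sites = 6
        # group1: 7 class-A chromosomes + 1 class-B; group2: 1 A + 7 B
        g1 = [[0] * 7 + [1] for _ in range(n_sites)]
        g2 = [[0] + [1] * 7 for _ in range(n_sites)]
        hm, panel, ctr, genes = self._setup(g1, g2, list(range(10, 10 + n_sites)))
        records = exon_fst(hm, genes, ctr)
        calls = call_haplotypes(hm, records, genes, ctr, panel, min_diag=4)
        assert len(calls) == 1
        c = calls[0]
        assert c.sharing == "shared"
        assert c.population_freqs.loc["p1", "freq_B"] == pytest.approx(1 / 8)
        assert c.population_freqs.loc["p2", "freq_B"] == pytest.approx(7 / 8)

    def test_class_frequencies_sum_to_one(self, small_synth):
        hm = small_synth["read_hm"]
        records = exon_fst(
            hm, small_synth["read_genes"], small_synth["contrast"], small_synth["read_mask"]
        )
        calls = call_haplotypes(
            hm, records, small_synth["read_genes"], small_synth["contrast"],
            small_synth["read_panel"], mask=small_synth["read_mask"],
        )
        assert len(calls) >= 1
        for c in calls:
            sums = c.population_freqs.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_planted_genes_called_with_expected_classes(self, small_synth):
        """Planted two-class genes are recovered with >= 4 diagnostic SNPs and
        class-B frequencies near the planted group frequencies."""
        hm = small_synth["read_hm"]
        records = exon_fst(
            hm, small_synth["read_genes"], small_synth["contrast"], small_synth["read_mask"]
        )
        calls = {
            c.gene_id: c
            for c in call_haplotypes(
                hm, records, small_synth["read_genes"], small_synth["contrast"],
                small_synth["read_panel"], mask=small_synth["read_mask"],
            )
        }
        panel = small_synth["read_panel"]
        cfg = small_synth["config"]
        for rec in small_synth["truth"]["planted_genes"]:
            assert rec["gene_id"] in calls
            c = calls[rec["gene_id"]]
            assert len(c.diagnostic_positions) >= 4
            freqs = c.population_freqs
            g2_freq = np.mean(
                [freqs.loc[p, "freq_B"] for p in cfg.group2_pops]
            )
            assert g2_freq == pytest.approx(rec["class_b_freq_group2"], abs=0.15)


class TestChisq:
    def test_null_table(self):
        chi2, p, enr = chisq_enrichment_2x2(10, 10, 10, 10)
        assert chi2 == 0 and p == 1 and enr == 1

    def test_matches_expected_count_formula(self):
        a, b, c, d = 20, 80, 10, 90
        chi2, p, enr = chisq_enrichment_2x2(a, b, c, d)
        # brute-force Pearson statistic from expected counts
        n = a + b + c + d
        exp = [
            [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
            [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
        ]
        obs = [[a, b], [c, d]]
        stat = sum(
            (obs[i][j] - exp[i][j]) ** 2 / exp[i][j] for i in range(2) for j in range(2)
        )
        assert chi2 == pytest.approx(stat, rel=1e-12)
        assert enr == pytest.approx(2.0)

    def test_row_col_swap_invariance(self):
        chi2a, pa, _ = chisq_enrichment_2x2(20, 80, 10, 90)
        chi2b, pb, _ = chisq_enrichment_2x2(90, 10, 80, 20)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)
        assert pa == pytest.approx(pb, rel=1e-12)

    def test_zero_margin_fatal(self):
        with pytest.raises(ValueError):
            chisq_enrichment_2x2(0, 0, 5, 5)


class TestSweepScores:
    def _region_mask(self, L, genic_until):
        codes = {"c": np.full(L, popio.INTERGENIC, dtype=np.uint8)}
        codes["c"][:genic_until] = popio.CDS
        return popio.RegionMask(codes)

    def _window_fst(self, L, w, values):
        rows = [("c", s, e, 1, 0.0, 1.0, v) for (s, e), v in
                zip([(s, min(s + w, L)) for s in range(0, L, w)], values)]
        return pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps", "num", "den", "fst"])

    def test_constant_scores_and_genic_filter(self):
        L, w = 4000, 1000
        scores = pd.DataFrame(
            {"contig": ["c"] * 8, "position": [100, 200, 1100, 1200, 2100, 2200, 3100, 3200],
             "score": [2.0] * 8}
        )
        rm = self._region_mask(L, 2500)  # windows 0,1 fully genic; 2 is 50%; 3 is 0%
        wfst = self._window_fst(L, w, [0.05, 0.15, 0.25, 0.35])
        win, cls = summarize_sweep_scores(scores, rm, wfst, {"c": L}, n_boot=50, seed=0)
        assert (win["mean_abs_score"] == 2.0).all()
        assert set(win["start"]) == {0, 1000, 2000}  # 40%-genic window excluded? 2000 window is 50%
        assert 3000 not in set(win["start"])

    def test_planted_high_scores_rise_with_fst_class(self, rng):
        L, w = 100_000, 1000
        wins = [(s, s + w) for s in range(0, L, w)]
        fst_vals = np.repeat([0.05, 0.45], 50)
        scores_rows = []
        for (s, e), f in zip(wins, fst_vals):
            val = rng.normal(3.0 if f > 0.4 else 0.5, 0.1)
            scores_rows.append(("c", s + 500, val))
        scores = pd.DataFrame(scores_rows, columns=["contig", "position", "score"])
        rm = self._region_mask(L, L)
        wfst = self._window_fst(L, w, fst_vals)
        _, cls = summarize_sweep_scores(scores, rm, wfst, {"c": L}, n_boot=100, seed=1)
        cls = cls.sort_values("fst_lo")
        assert cls["mean_abs_score"].iloc[-1] > cls["mean_abs_score"].iloc[0]
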