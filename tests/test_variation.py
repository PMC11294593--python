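"""Diversity estimators against brute-force and hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from krillpop import popio, variation
from krillpop.variation import (
    bootstrap_ci,
    distance_from_gene_profile,
    folded_afs,
    harmonic,
    net_divergence_da,
    pi_site,
    polymorphism_sharing,
    tajima_d_window,
    theta_w_window,
)

from conftest import random_haplotype_matrix


class TestPiSite:
    def test_forced_by_formula(self):
        assert pi_site(2, 4) == pytest.approx(2 * 0.25 * (4 / 3))

    def test_monomorphic_zero(self):
        assert pi_site(0, 10) == 0.0

    def test_n_below_two_fatal(self):
        with pytest.raises(ValueError):
            pi_site(0, 1)

    def test_window_mean_equals_pairwise_hamming(self, rng):
        """Summed per-site pi equals the mean pairwise Hamming distance."""
        hm = random_haplotype_matrix(rng, n_samples=5, n_sites=40)
        k, m = hm.allele_counts()
        pi_sum = pi_site(k, m).sum()
        n = hm.n_hap
        ham = [
            (hm.calls[i] != hm.calls[j]).sum()
            for i, j in itertools.combinations(range(n), 2)
        ]
        assert pi_sum == pytest.approx(np.mean(ham))


class TestThetaW:
    def test_two_chromosomes(self):
        assert theta_w_window(3, 2, 100) == pytest.approx(0.03)

    def test_no_segregating_sites(self):
        assert theta_w_window(0, 10, 100) == 0.0

    def test_zero_accessible_length_missing(self):
        assert np.isnan(theta_w_window(5, 10, 0))

    def test_large_n_matches_harmonic_sum_oracle(self):
        n, S, L = 148, 250, 10_000
        a = sum(1.0 / i for i in range(1, n))
        assert theta_w_window(S, n, L) == pytest.approx(S / (a * L), rel=1e-12)


def tajima_d_oracle(S, pi_sum, n):
    """Independent scalar transcription of the 1989 constants."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


class TestTajimaD:
    def test_zero_when_pi_equals_watterson(self):
        n = 12
        S = 7
        assert tajima_d_window(S, S / harmonic(n - 1), n) == pytest.approx(0.0, abs=1e-12)

    def test_negative_under_excess_rare_variants(self):
        # ten singletons in n=20: pi well below S/a1
        n, S = 20, 10
        pi_sum = float(pi_site(1, n) * S)
        assert tajima_d_window(S, pi_sum, n) < 0

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(tajima_d_window(0, 0.0, 10))

    def test_matches_textbook_oracle_on_random_matrix(self, rng):
        hm = random_haplotype_matrix(rng, n_samples=7, n_sites=25)
        k, m = hm.allele_counts()
        seg = (k > 0) & (k < m)
        S = int(seg.sum())
        pi_sum = float(pi_site(k[seg], m[seg]).sum())
        got = tajima_d_window(S, pi_sum, hm.n_hap)
        assert got == pytest.approx(tajima_d_oracle(S, pi_sum, hm.n_hap), rel=1e-12)


class TestWorkedExample:
    def test_window_stats_match_hand_computation(self, worked_example):
        st = variation.window_diversity(
            worked_example["hm"], worked_example["mask"],
            worked_example["contig_lengths"], window=100,
        )
        e = worked_example["expected"]
        row = st.iloc[0]
        assert row["L_acc"] == e["L_acc"]
        assert row["S"] == e["S"]
        assert row["pi"] == pytest.approx(e["pi_per_base"], rel=1e-9)
        assert row["theta_w"] == pytest.approx(e["theta_w_per_base"], rel=1e-9)
        assert row["tajima_d"] == pytest.approx(e["tajima_d"], rel=1e-9)

    def test_dxy_matches_hand_computation(self, worked_example):
        hm, panel = worked_example["hm"], worked_example["panel"]
        r1 = hm.hap_indices(panel.samples_in("pop1"))
        r2 = hm.hap_indices(panel.samples_in("pop2"))
        d = variation.dxy_total(
            hm, r1, r2, worked_example["mask"], worked_example["contig_lengths"]
        )
        assert d == pytest.approx(worked_example["expected"]["dxy_per_base"], rel=1e-12)


class TestDxy:
    def test_fixed_difference(self, rng):
        hm = random_haplotype_matrix(rng, n_samples=2, n_sites=1)
        hm.calls[:2] = 1
        hm.calls[2:] = 0
        mask = popio.AccessibilityMask({"c1": [[0, 100]]})
        df = variation.dxy_window(hm, np.array([0, 1]), np.array([2, 3]), mask, {"c1": 100})
        assert df["dxy"].iloc[0] == pytest.approx(0.01)

    def test_two_sequence_groups_equal_hamming(self, rng):
        hm = random_haplotype_matrix(rng, n_samples=2, n_sites=50, contig="c1")
        L = int(hm.positions.max())
        mask = popio.AccessibilityMask({"c1": [[0, L]]})
        d = variation.dxy_total(hm, np.array([0]), np.array([2]), mask, {"c1": L})
        assert d == pytest.approx((hm.calls[0] != hm.calls[2]).sum() / L)

    def test_identical_groups_match_within_diversity(self, rng):
        """For one group split in two halves, dxy approximates within-group
        pi (they share the same expectation)."""
        hm = random_haplotype_matrix(rng, n_samples=20, n_sites=400)
        L = int(hm.positions.max())
        mask = popio.AccessibilityMask({"c1": [[0, L]]})
        d = variation.dxy_total(hm, np.arange(0, 20), np.arange(20, 40), mask, {"c1": L})
        k, m = hm.allele_counts()
        pi = float(pi_site(k, m).sum() / L)
        assert d == pytest.approx(pi, rel=0.1)


class TestDa:
    def test_paper_style_values(self):
        assert net_divergence_da(0.0171, 0.0164, 0.0164) == pytest.approx(0.0007)

    def test_zero_when_dxy_equals_mean_pi(self):
        assert net_divergence_da(0.01, 0.012, 0.008) == 0.0

    def test_linearity(self, rng):
        d, p1, p2 = rng.random(3)
        assert net_divergence_da(2 * d, 2 * p1, 2 * p2) == pytest.approx(
            2 * net_divergence_da(d, p1, p2)
        )


class TestFoldedAfs:
    def _hm_with_counts(self, counts, n_samples):
        calls = np.zeros((2 * n_samples, len(counts)), dtype=np.int8)
        for j, k in enumerate(counts):
            calls[:k, j] = 1
        return popio.HaplotypeMatrix(
            np.full(len(counts), "c", dtype=object),
            np.arange(1, len(counts) + 1),
            np.full(len(counts), "A", dtype=object),
            np.full(len(counts), "T", dtype=object),
            calls,
            [f"s{i}" for i in range(n_samples)],
        )

    def test_singleton_bin(self):
        afs = folded_afs(self._hm_with_counts([1], 2))
        assert afs.tolist() == [1, 0]

    def test_folding_symmetry(self):
        afs = folded_afs(self._hm_with_counts([1, 3], 2))  # k=3 = n-1 folds to 1
        assert afs.tolist() == [2, 0]

    def test_total_equals_polymorphic_sites(self, rng):
        hm = random_haplotype_matrix(rng, n_samples=6, n_sites=80)
        k, m = hm.allele_counts()
        assert folded_afs(hm).sum() == ((k > 0) & (k < m)).sum()


class TestPolymorphismSharing:
    def test_shared_everywhere_and_singleton(self, rng):
        calls = np.zeros((8, 2), dtype=np.int8)
        calls[[0, 3, 5], 0] = 1  # polymorphic in both pops (rows 0-3 / 4-7)
        calls[0, 1] = 1  # singleton: pop1 only
        hm = popio.HaplotypeMatrix(
            np.array(["c", "c"], dtype=object), np.array([1, 2]),
            np.array(["A", "A"], dtype=object), np.array(["T", "T"], dtype=object),
            calls, ["a", "b", "c", "d"],
        )
        panel = popio.SamplePanel(["a", "b", "c", "d"], ["p1", "p1", "p2", "p2"])
        tab = polymorphism_sharing(hm, panel)
        row_shared = tab[(tab.minor_count == 3)]
        assert row_shared.n_pops_polymorphic.tolist() == [2]
        row_single = tab[(tab.minor_count == 1)]
        assert row_single.n_pops_polymorphic.tolist() == [1]

    def test_matches_brute_force(self, small_synth):
        hm = small_synth["read_hm"].take_sites(np.arange(500))
        panel = small_synth["read_panel"]
        tab = polymorphism_sharing(hm, panel)
        # brute force per SNP
        total = 0
        for j in range(hm.n_sites):
            col = hm.calls[:, j]
            k = int(col.sum())
            minor = min(k, hm.n_hap - k)
            if minor == 0:
                continue
            npoly = 0
            for pop in panel.population_names:
                rows = hm.hap_indices(panel.samples_in(pop))
                s = col[rows].sum()
                npoly += 0 < s < len(rows)
            got = tab[(tab.minor_count == minor) & (tab.n_pops_polymorphic == npoly)]
            assert len(got) == 1
            total += 1
        assert tab.n_snps.sum() == total


class TestBootstrap:
    def test_constant_vector(self):
        mean, lo, hi = bootstrap_ci([2.0, 2.0, 2.0], 100, seed=1)
        assert mean == lo == hi == 2.0

    def test_seed_determinism(self, rng):
        v = rng.normal(size=50)
        assert bootstrap_ci(v, 200, seed=9) == bootstrap_ci(v, 200, seed=9)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], 10, seed=0)

    def test_coverage_near_nominal(self, rng):
        """95% interval covers the true mean about 95% of the time."""
        hits = 0
        trials = 300
        for t in range(trials):
            sample = rng.normal(0.0, 1.0, size=100)
            _, lo, hi = bootstrap_ci(sample, 300, seed=t)
            hits += lo <= 0.0 <= hi
        assert 0.89 <= hits / trials <= 0.99


class TestDistanceFromGeneProfile:
    def _stats(self, contig_len, window, values):
        rows = []
        for i, (s, e) in enumerate(variation.tile_windows(contig_len, window)):
            rows.append(("c", s, e, window, 1, values[i], values[i], 0.0))
        return pd.DataFrame(
            rows, columns=["contig", "start", "end", "L_acc", "S", "pi", "theta_w", "tajima_d"]
        )

    def test_adjacent_window_in_first_bin(self):
        genes = popio.GeneSet(
            [popio.Gene("g", "c", "+", 5000, 6000, exons=[(5000, 6000)])]
        )
        st = self._stats(10_000, 1000, np.ones(10))
        prof = distance_from_gene_profile(st, genes, n_boot=10, seed=0)
        assert prof["dist_lo"].iloc[0] == 0
        # windows [4000,5000) and [6000,7000) are adjacent: bin 0 has 2
        assert prof["n_windows"].iloc[0] == 2

    def test_gene_overlapping_windows_excluded(self):
        genes = popio.GeneSet(
            [popio.Gene("g", "c", "+", 4500, 5500, exons=[(4500, 5500)])]
        )
        st = self._stats(10_000, 1000, np.ones(10))
        prof = distance_from_gene_profile(st, genes, n_boot=10, seed=0)
        assert prof["n_windows"].sum() == 8  # two windows overlap the body

    def test_planted_dip_recovered(self, rng):
        """Diversity dip at genes rises monotonically with distance."""
        L, w = 200_000, 1000
        genes = popio.GeneSet(
            [
                popio.Gene("g1", "c", "+", 40_000, 42_000, exons=[(40_000, 42_000)]),
                popio.Gene("g2", "c", "+", 140_000, 142_000, exons=[(140_000, 142_000)]),
            ]
        )
        centers = np.arange(0, L, w) + w / 2
        dist = np.minimum(
            np.abs(centers - 41_000) - 1000, np.abs(centers - 141_000) - 1000
        ).clip(0)
        vals = 0.01 + 0.01 * np.minimum(dist, 30_000) / 30_000
        vals = vals + rng.normal(0, 5e-4, len(vals))
        st = self._stats(L, w, vals)
        prof = distance_from_gene_profile(st, genes, n_boot=50, seed=3, max_dist=30_000)
        means = prof["pi_mean"].to_numpy()
        assert means[-1] > means[0]
        assert np.corrcoef(prof["dist_lo"], means)[0, 1] > 0.9


class TestRegionStratification:
    def test_class_totals_conserve_genome_totals(self, small_synth):
        hm = small_synth["read_hm"]
        mask = small_synth["read_mask"]
        lengths = small_synth["contig_lengths"]
        rm = popio.build_region_mask(small_synth["read_genes"], lengths)
        full = variation.window_diversity(hm, mask, lengths, window=60_000)
        parts = [
            variation.window_diversity(
                hm, mask, lengths, window=60_000, region_mask=rm, region_classes={c}
            )
            for c in (1, 2, 3, 4, 5, 6)
        ]
        assert sum(p["S"].sum() for p in parts) == full["S"].sum()
        assert sum(p["L_acc"].sum() for p in parts) == full["L_acc"].sum()

    def test_invariance_to_sample_order_and_allele_labels(self, rng):
        hm = random_haplotype_matrix(rng, n_samples=6, n_sites=60)
        L = int(hm.positions.max())
        mask = popio.AccessibilityMask({"c1": [[0, L]]})
        base = variation.window_diversity(hm, mask, {"c1": L}, window=L)
        perm = hm.take_samples(list(np.array(hm.samples)[::-1]))
        swapped = popio.HaplotypeMatrix(
            hm.contigs, hm.positions, hm.alt, hm.ref, 1 - hm.calls, hm.samples
        )
        for other in (perm, swapped):
            st = variation.window_diversity(other, mask, {"c1": L}, window=L)
            for col in ("S", "pi", "theta_w", "tajima_d"):
                assert st[col].iloc[0] == pytest.approx(base[col].iloc[0], nan_ok=True)
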