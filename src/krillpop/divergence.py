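"""FST estimation, population matrices, LD thinning and isolation by distance.

Two moment estimators of the coancestry theta are provided, matching their
standard roles: the Reynolds (1983) two-population estimator on haploid allele
counts for every aggregated scope (window, exon set, contig, genome; always as
a ratio of summed numerators and denominators, never a mean of ratios), and
the Weir-Cockerham (1984) estimator with observed heterozygote frequencies for
per-SNP values.  Negative estimates are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popio import AccessibilityMask, HaplotypeMatrix, SamplePanel, write_phylip
from .variation import tile_windows


@dataclass
class ContrastSpec:
    """A named two-group partition of samples."""

    name: str
    group1: list[str]
    group2: list[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("contrast groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ValueError("contrast groups must be disjoint")

    @classmethod
    def from_populations(
        cls, panel: SamplePanel, name: str, pops1: list[str], pops2: list[str]
    ) -> "ContrastSpec":
        g1 = [s for p in pops1 for s in panel.samples_in(p)]
        g2 = [s for p in pops2 for s in panel.samples_in(p)]
        return cls(name, g1, g2)


# ---------------------------------------------------------------------------
# Reynolds (1983) estimator on haploid allele counts
# ---------------------------------------------------------------------------


def reynolds_components(k1, m1, k2, m2):
    """Per-locus numerator a_l and denominator a_l + b_l.

    ``k_i`` are ALT allele counts and ``m_i`` haploid sample sizes.  Computed
    as the two-population coancestry moment estimator (between/within mean
    squares over allele indicators, variance-component form); loci that are
    monomorphic across both samples contribute (0, 0).
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    m1 = np.broadcast_to(np.asarray(m1, dtype=float), k1.shape).copy()
    m2 = np.broadcast_to(np.asarray(m2, dtype=float), k2.shape).copy()
    if np.any(m1 < 2) or np.any(m2 < 2):
        raise ValueError("need >= 2 chromosomes per population")
    M = m1 + m2
    p1 = k1 / m1
    p2 = k2 / m2
    pbar = (k1 + k2) / M
    msp = m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2  # df = 1
    msg = (m1 * p1 * (1 - p1) + m2 * p2 * (1 - p2)) / (M - 2)
    n_c = M - (m1**2 + m2**2) / M
    num = (msp - msg) / n_c
    den = num + msg
    mono = (k1 + k2 == 0) | (k1 + k2 == M)
    num = np.where(mono, 0.0, num)
    den = np.where(mono, 0.0, den)
    return num, den


def ratio_of_sums(num, den) -> float:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    d = den.sum()
    return float(num.sum() / d) if d != 0 else float("nan")


def reynolds_fst(k1, m1, k2, m2) -> float:
    """Multi-locus Reynolds FST as a ratio of sums over loci."""
    num, den = reynolds_components(k1, m1, k2, m2)
    return ratio_of_sums(num, den)


# ---------------------------------------------------------------------------
# Weir-Cockerham (1984) per-SNP estimator (r = 2 diploid samples)
# ---------------------------------------------------------------------------


def wc_fst_components(p1, p2, h1, h2, n1, n2):
    """Variance components (a, b, c) for two diploid samples.

    ``p_i`` are ALT frequencies, ``h_i`` observed heterozygote frequencies and
    ``n_i`` diploid sample sizes.  theta-hat = a / (a + b + c).
    """
    p1, p2, h1, h2 = (np.asarray(x, dtype=float) for x in (p1, p2, h1, h2))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need >= 2 diploids per population")
    r = 2.0
    nbar = (n1 + n2) / r
    n_c = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def wc_fst_snp(p1, p2, h1, h2, n1, n2):
    """Per-SNP Weir-Cockerham theta-hat; NaN where a + b + c = 0."""
    a, b, c = wc_fst_components(p1, p2, h1, h2, n1, n2)
    den = a + b + c
    return np.where(den != 0, np.divide(a, den, out=np.zeros_like(a), where=den != 0), np.nan)


def wc_fst_haploid(k1, m1, k2, m2):
    """Per-SNP theta-hat on haploid allele counts (no genotype information);
    the moment-estimator form used for simulated chromosome samples."""
    num, den = reynolds_components(k1, m1, k2, m2)
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    return np.where(den != 0, np.divide(num, den, out=np.zeros_like(num), where=den != 0), np.nan)


def _genotype_stats(hm: HaplotypeMatrix, samples: list[str]):
    """Per-site ALT frequency and observed heterozygote frequency over the
    diploid genotypes formed by consecutive haplotype pairs."""
    rows = hm.hap_indices(samples)
    a = hm.calls[rows[0::2]]
    b = hm.calls[rows[1::2]]
    p = (a + b).sum(axis=0) / (2.0 * len(samples))
    h = (a != b).sum(axis=0) / float(len(samples))
    return p, h, len(samples)


def per_snp_wc_fst(hm: HaplotypeMatrix, contrast: ContrastSpec) -> np.ndarray:
    p1, h1, n1 = _genotype_stats(hm, contrast.group1)
    p2, h2, n2 = _genotype_stats(hm, contrast.group2)
    return wc_fst_snp(p1, p2, h1, h2, n1, n2)


# ---------------------------------------------------------------------------
# Aggregated scopes
# ---------------------------------------------------------------------------


def contrast_counts(hm: HaplotypeMatrix, contrast: ContrastSpec):
    k1, m1 = hm.allele_counts(hm.hap_indices(contrast.group1))
    k2, m2 = hm.allele_counts(hm.hap_indices(contrast.group2))
    return k1, m1, k2, m2


def site_fst_components(
    hm: HaplotypeMatrix,
    contrast: ContrastSpec,
    mask: AccessibilityMask | None = None,
):
    """Per-site Reynolds (num, den) with inaccessible sites zeroed out."""
    k1, m1, k2, m2 = contrast_counts(hm, contrast)
    num, den = reynolds_components(k1, m1, k2, m2)
    if mask is not None:
        ok = np.zeros(hm.n_sites, dtype=bool)
        for ctg in dict.fromkeys(hm.contigs.tolist()):
            on = hm.contigs == ctg
            ok[on] = mask.is_accessible(ctg, hm.positions[on] - 1)
        num = np.where(ok, num, 0.0)
        den = np.where(ok, den, 0.0)
    return num, den


def genome_fst(hm, contrast, mask=None) -> float:
    num, den = site_fst_components(hm, contrast, mask)
    return ratio_of_sums(num, den)


def window_fst(
    hm: HaplotypeMatrix,
    contrast: ContrastSpec,
    contig_lengths: dict[str, int],
    window: int = 1000,
    mask: AccessibilityMask | None = None,
) -> pd.DataFrame:
    """Reynolds ratio-of-sums per tiling window; windows without an
    informative SNP get NaN."""
    num, den = site_fst_components(hm, contrast, mask)
    records = []
    for ctg in sorted(contig_lengths):
        site_idx = np.nonzero(hm.contigs == ctg)[0]
        pos0 = hm.positions[site_idx] - 1
        for start, end in tile_windows(contig_lengths[ctg], window):
            lo, hi = np.searchsorted(pos0, [start, end])
            sel = site_idx[lo:hi]
            nsum = float(num[sel].sum())
            dsum = float(den[sel].sum())
            n_inf = int((den[sel] != 0).sum())
            records.append(
                (ctg, start, end, n_inf, nsum, dsum, nsum / dsum if dsum else float("nan"))
            )
    return pd.DataFrame(
        records, columns=["contig", "start", "end", "n_snps", "num", "den", "fst"]
    )


def interval_fst(hm, contrast, intervals, mask=None) -> pd.DataFrame:
    """Reynolds ratio-of-sums over arbitrary (contig, start, end) intervals."""
    num, den = site_fst_components(hm, contrast, mask)
    records = []
    for ctg, start, end in intervals:
        sel = hm.sites_in(ctg, start, end)
        nsum = float(num[sel].sum())
        dsum = float(den[sel].sum())
        records.append(
            (ctg, start, end, int((den[sel] != 0).sum()), nsum, dsum,
             nsum / dsum if dsum else float("nan"))
        )
    return pd.DataFrame(
        records, columns=["contig", "start", "end", "n_snps", "num", "den", "fst"]
    )


# ---------------------------------------------------------------------------
# Pairwise matrices, downsampling, LD thinning, isolation by distance
# ---------------------------------------------------------------------------


def pairwise_matrices(
    hm: HaplotypeMatrix,
    panel: SamplePanel,
    mask: AccessibilityMask,
    contig_lengths: dict[str, int],
):
    """Genome-wide population-pair Reynolds FST and d_XY matrices.

    Returns ``(fst_df, dxy_df)`` as symmetric DataFrames over populations.
    """
    from .variation import dxy_total

    pops = panel.population_names
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    dxy = pd.DataFrame(0.0, index=pops, columns=pops)
    rows = {p: hm.hap_indices(panel.samples_in(p)) for p in pops}
    counts = {p: hm.allele_counts(rows[p]) for p in pops}
    for i, p in enumerate(pops):
        for q in pops[i + 1 :]:
            k1, m1 = counts[p]
            k2, m2 = counts[q]
            f = reynolds_fst(k1, m1, k2, m2)
            d = dxy_total(hm, rows[p], rows[q], mask, contig_lengths)
            fst.loc[p, q] = fst.loc[q, p] = f
            dxy.loc[p, q] = dxy.loc[q, p] = d
    return fst, dxy


def export_distance_matrix(matrix: pd.DataFrame, path) -> None:
    """PHYLIP export; negative entries are clamped to 0 for tree builders."""
    write_phylip(matrix.clip(lower=0.0), path)


def downsample_equal_n(
    hm: HaplotypeMatrix, panel: SamplePanel, n_per_pop: int, seed: int
):
    """Seeded uniform subsample of ``n_per_pop`` samples from each population."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for pop in panel.population_names:
        members = panel.samples_in(pop)
        if len(members) < n_per_pop:
            raise ValueError(
                f"population {pop} has {len(members)} samples < {n_per_pop}"
            )
        pick = rng.choice(len(members), size=n_per_pop, replace=False)
        chosen.extend(members[i] for i in sorted(pick))
    return hm.take_samples(chosen), panel.subset(chosen)


def ld_thin(
    hm: HaplotypeMatrix,
    r2_max: float = 0.1,
    window_snps: int = 500,
    subsample_frac: float | None = None,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Greedy left-to-right LD pruning within windows of ``window_snps`` SNPs.

    A SNP is dropped when its squared Pearson correlation (on haplotype 0/1
    vectors) with an already retained SNP in the same window exceeds
    ``r2_max``; the leftmost SNP of a correlated pair survives.  An optional
    uniform subsample by fraction is applied first.
    """
    idx = np.arange(hm.n_sites)
    if subsample_frac is not None:
        rng = np.random.default_rng(seed)
        take = rng.random(hm.n_sites) < subsample_frac
        idx = idx[take]
    calls = hm.calls[:, idx].astype(float)
    keep_mask = np.zeros(len(idx), dtype=bool)
    contigs = hm.contigs[idx]
    for ctg in dict.fromkeys(contigs.tolist()):
        where = np.nonzero(contigs == ctg)[0]
        for w0 in range(0, len(where), window_snps):
            block = where[w0 : w0 + window_snps]
            x = calls[:, block]
            sd = x.std(axis=0)
            kept: list[int] = []
            for j in range(len(block)):
                if sd[j] == 0:
                    keep_mask[block[j]] = True  # monomorphic: uncorrelated
                    kept.append(j)
                    continue
                ok = True
                for kj in kept:
                    if sd[kj] == 0:
                        continue
                    r = np.corrcoef(x[:, j], x[:, kj])[0, 1]
                    if r * r > r2_max:
                        ok = False
                        break
                if ok:
                    keep_mask[block[j]] = True
                    kept.append(j)
    return hm.take_sites(idx[keep_mask])


def linearize_fst(fst):
    """FST / (1 - FST); fatal at FST = 1."""
    fst = np.asarray(fst, dtype=float)
    if np.any(fst >= 1.0):
        raise ValueError("FST = 1 cannot be linearized")
    return fst / (1.0 - fst)


def ibd_regression(fst_matrix: pd.DataFrame, distance_matrix: pd.DataFrame):
    """OLS of linearized FST on pairwise distance over the upper triangle.

    Returns (slope, intercept, r_squared, p_value).
    """
    pops = list(fst_matrix.index)
    dm = distance_matrix.loc[pops, pops]
    iu = np.triu_indices(len(pops), k=1)
    y = linearize_fst(fst_matrix.to_numpy()[iu])
    x = dm.to_numpy()[iu]
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue
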