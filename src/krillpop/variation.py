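"""Accessibility-corrected diversity statistics.

All per-base estimators divide by the number of *accessible* bases in the
window, not the window span; windows with no accessible base are emitted with
missing statistics rather than dropped.  Tajima's D is undefined (NaN) when a
window holds no segregating site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popio import AccessibilityMask, GeneSet, HaplotypeMatrix, RegionMask


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


# ---------------------------------------------------------------------------
# Per-site / per-window estimators
# ---------------------------------------------------------------------------


def pi_site(k, n):
    """Unbiased per-site pairwise diversity 2*(k/n)*(1-k/n)*n/(n-1)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("need n >= 2 chromosomes")
    return 2.0 * k * (n - k) / (n * (n - 1.0))


def theta_w_window(S: float, n: int, L_acc: float) -> float:
    """Watterson estimator per base: S / (a_{n-1} * L_acc)."""
    if L_acc <= 0:
        return float("nan")
    return S / (harmonic(n - 1) * L_acc)


def tajima_d_window(S: float, pi_sum: float, n: int) -> float:
    """Tajima's (1989) D from the segregating-site count and the summed
    per-site pairwise diversity of a window."""
    if S < 1:
        return float("nan")
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n, dtype=float) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - S / a1) / np.sqrt(var))


def tile_windows(length: int, size: int) -> list[tuple[int, int]]:
    return [(s, min(s + size, length)) for s in range(0, length, size)]


def window_diversity(
    hm: HaplotypeMatrix,
    mask: AccessibilityMask,
    contig_lengths: dict[str, int],
    window: int = 1000,
    rows: np.ndarray | None = None,
    region_mask: RegionMask | None = None,
    region_classes: set[int] | None = None,
) -> pd.DataFrame:
    """Per-window S, pi, Watterson's theta and Tajima's D.

    ``rows`` restricts the calculation to a haplotype subset (for example one
    population).  With a region mask and a class set, both the SNPs and the
    accessible-base denominator are restricted to bases of those classes, so
    region-stratified (S, L_acc) totals add up to the genome totals.
    """
    k_all, m_all = hm.allele_counts(rows)
    seg_all = (k_all > 0) & (k_all < m_all)
    pi_all = np.zeros(hm.n_sites)
    ok_n = m_all >= 2
    pi_all[ok_n] = pi_site(k_all[ok_n], m_all[ok_n])

    records = []
    for ctg in sorted(contig_lengths):
        length = contig_lengths[ctg]
        site_idx = np.nonzero(hm.contigs == ctg)[0]
        pos0 = hm.positions[site_idx] - 1
        acc_b = mask.to_boolean(ctg, length)
        if region_mask is not None and region_classes is not None:
            acc_b &= np.isin(region_mask.codes[ctg], list(region_classes))
        site_ok = acc_b[pos0]
        for start, end in tile_windows(length, window):
            L_acc = int(acc_b[start:end].sum())
            lo, hi = np.searchsorted(pos0, [start, end])
            sel = site_idx[lo:hi][site_ok[lo:hi]]
            S = int(seg_all[sel].sum())
            pi_sum = float(pi_all[sel].sum())
            if L_acc > 0:
                n = int(m_all[sel].max()) if len(sel) else int(m_all.max(initial=2))
                pi = pi_sum / L_acc
                theta = theta_w_window(S, n, L_acc)
                taj = tajima_d_window(S, pi_sum, n) if S >= 1 else float("nan")
            else:
                pi = theta = taj = float("nan")
            records.append((ctg, start, end, L_acc, S, pi, theta, taj))
    return pd.DataFrame(
        records,
        columns=["contig", "start", "end", "L_acc", "S", "pi", "theta_w", "tajima_d"],
    )


def genome_diversity(window_stats: pd.DataFrame) -> dict[str, float]:
    """Genome-wide per-base summaries from window sums (ratio of sums)."""
    L = window_stats["L_acc"].sum()
    pi_sum = (window_stats["pi"] * window_stats["L_acc"]).sum()
    return {
        "L_acc": float(L),
        "S": float(window_stats["S"].sum()),
        "pi": float(pi_sum / L) if L else float("nan"),
    }


# ---------------------------------------------------------------------------
# Allele frequency spectrum and divergence
# ---------------------------------------------------------------------------


def folded_afs(hm: HaplotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Folded minor-allele-count spectrum, bins 1 .. floor(n/2).

    Monomorphic sites (k in {0, n}) are not counted.
    """
    k, m = hm.allele_counts(rows)
    n = int(m.max(initial=0))
    if n < 2:
        raise ValueError("need >= 2 chromosomes")
    seg = (k > 0) & (k < m) & (m == n)
    minor = np.minimum(k[seg], n - k[seg])
    out = np.zeros(n // 2 + 1, dtype=np.int64)
    np.add.at(out, minor, 1)
    return out[1:]


def dxy_counts(k1, m1, k2, m2):
    """Per-site absolute divergence p1*(1-p2) + p2*(1-p1)."""
    p1 = np.divide(k1, m1, out=np.zeros(np.shape(k1)), where=np.asarray(m1) > 0)
    p2 = np.divide(k2, m2, out=np.zeros(np.shape(k2)), where=np.asarray(m2) > 0)
    return p1 * (1 - p2) + p2 * (1 - p1)


def dxy_window(
    hm: HaplotypeMatrix,
    rows1: np.ndarray,
    rows2: np.ndarray,
    mask: AccessibilityMask,
    contig_lengths: dict[str, int],
    window: int | None = None,
) -> pd.DataFrame:
    """Windowed (or per-contig when ``window`` is None) d_XY per base."""
    k1, m1 = hm.allele_counts(rows1)
    k2, m2 = hm.allele_counts(rows2)
    per_site = dxy_counts(k1, m1, k2, m2)
    records = []
    for ctg in sorted(contig_lengths):
        length = contig_lengths[ctg]
        site_idx = np.nonzero(hm.contigs == ctg)[0]
        pos0 = hm.positions[site_idx] - 1
        acc_b = mask.to_boolean(ctg, length)
        site_ok = acc_b[pos0]
        spans = tile_windows(length, window) if window else [(0, length)]
        for start, end in spans:
            L_acc = int(acc_b[start:end].sum())
            lo, hi = np.searchsorted(pos0, [start, end])
            tot = float(per_site[site_idx[lo:hi]][site_ok[lo:hi]].sum())
            records.append(
                (ctg, start, end, L_acc, tot / L_acc if L_acc else float("nan"))
            )
    return pd.DataFrame(records, columns=["contig", "start", "end", "L_acc", "dxy"])


def dxy_total(
    hm: HaplotypeMatrix,
    rows1: np.ndarray,
    rows2: np.ndarray,
    mask: AccessibilityMask,
    contig_lengths: dict[str, int],
) -> float:
    df = dxy_window(hm, rows1, rows2, mask, contig_lengths, window=None)
    L = df["L_acc"].sum()
    return float((df["dxy"] * df["L_acc"]).sum() / L) if L else float("nan")


def net_divergence_da(dxy_syn: float, pi_syn_1: float, pi_syn_2: float) -> float:
    """Net divergence: d_XY minus mean within-group diversity (may be < 0)."""
    return dxy_syn - (pi_syn_1 + pi_syn_2) / 2.0


# ---------------------------------------------------------------------------
# Polymorphism sharing across populations
# ---------------------------------------------------------------------------


def polymorphism_sharing(hm: HaplotypeMatrix, panel) -> pd.DataFrame:
    """SNP counts in a (global minor-allele count) x (number of populations in
    which the SNP is polymorphic) table."""
    pops = panel.population_names
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    k, m = hm.allele_counts()
    minor = np.minimum(k, m - k)
    n_poly = np.zeros(hm.n_sites, dtype=np.int64)
    for pop in pops:
        rows = hm.hap_indices(panel.samples_in(pop))
        kp, mp = hm.allele_counts(rows)
        n_poly += ((kp > 0) & (kp < mp)).astype(np.int64)
    df = pd.DataFrame({"minor_count": minor, "n_pops_polymorphic": n_poly})
    df = df[minor > 0]
    return (
        df.groupby(["minor_count", "n_pops_polymorphic"])
        .size()
        .rename("n_snps")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Bootstrap and distance-from-gene profiles
# ---------------------------------------------------------------------------


def bootstrap_ci(values, n_reps: int, seed: int, level: float = 0.95):
    """Percentile bootstrap (mean, lo, hi); seeded and reproducible."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("bootstrap over empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_reps, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def distance_from_gene_profile(
    window_stats: pd.DataFrame,
    genes: GeneSet,
    bin_bp: int = 1000,
    max_dist: int = 100_000,
    n_boot: int = 200,
    seed: int = 0,
    columns: tuple[str, ...] = ("pi", "theta_w"),
) -> pd.DataFrame:
    """Mean diversity in distance bins from the nearest gene-body edge.

    Windows overlapping any gene body are excluded; the remaining windows are
    assigned to ``bin_bp`` bins of distance to the nearest gene on the same
    contig (ties between an upstream and a downstream gene resolve to the
    upstream/5' gene, which does not change the distance).  95% CIs come from
    a percentile bootstrap over windows within each bin.
    """
    by_ctg = genes.by_contig()
    dist = np.full(len(window_stats), -1, dtype=np.int64)
    for i, row in enumerate(window_stats.itertuples(index=False)):
        glist = by_ctg.get(row.contig, [])
        if not glist:
            continue
        starts = np.array([g.start for g in glist])
        ends = np.array([g.end for g in glist])
        if ((row.start < ends) & (row.end > starts)).any():
            continue  # overlaps a gene body
        up = ends[ends <= row.start]
        down = starts[starts >= row.end]
        cand = []
        if len(up):
            cand.append(row.start - up.max())
        if len(down):
            cand.append(down.min() - row.end)
        if cand:
            dist[i] = min(cand)
    keep = (dist >= 0) & (dist < max_dist)
    sub = window_stats[keep].copy()
    sub["dist_bin"] = dist[keep] // bin_bp
    records = []
    for b, grp in sub.groupby("dist_bin"):
        rec = {"dist_lo": int(b) * bin_bp, "dist_hi": (int(b) + 1) * bin_bp, "n_windows": len(grp)}
        for col in columns:
            vals = grp[col].dropna().to_numpy()
            if len(vals):
                mean, lo, hi = bootstrap_ci(vals, n_boot, seed + int(b))
            else:
                mean = lo = hi = float("nan")
            rec[f"{col}_mean"], rec[f"{col}_lo"], rec[f"{col}_hi"] = mean, lo, hi
        records.append(rec)
    return pd.DataFrame(records).sort_values("dist_lo").reset_index(drop=True)
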