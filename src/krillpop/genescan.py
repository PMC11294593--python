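"""Selection-scan layer: per-gene exon FST, flanking-region null
distributions, gene-haplotype calling, enrichment tests and sweep-score
summaries.

The scan contrasts exon-wide divergence (Reynolds ratio-of-sums over the SNPs
in a gene's exons, cds + UTRs) against similarly sized intergenic flanking
regions placed 50-100 kb away from genes, which are expected to evolve
closer to neutrality.  Genes whose exon FST exceeds upper-tail percentiles of
the flank distribution are sweep candidates; phased chromosomes at strongly
divergent genes are classified into two gene-level haplotype classes from
diagnostic SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import ContrastSpec, interval_fst, per_snp_wc_fst, site_fst_components
from .popio import AccessibilityMask, GeneSet, HaplotypeMatrix, RegionMask, SamplePanel
from .variation import bootstrap_ci, tile_windows


# ---------------------------------------------------------------------------
# Exon-wide per-gene FST and flanking regions
# ---------------------------------------------------------------------------


def exon_fst(
    hm: HaplotypeMatrix,
    genes: GeneSet,
    contrast: ContrastSpec,
    mask: AccessibilityMask | None = None,
) -> pd.DataFrame:
    """Reynolds ratio-of-sums over the exonic SNPs of each gene.

    SNPs in inaccessible exonic bases are excluded when a mask is given.
    Genes without an informative exonic SNP get NaN.
    """
    num, den = site_fst_components(hm, contrast, mask)
    records = []
    for g in genes:
        sel = np.concatenate(
            [hm.sites_in(g.contig, s, e) for s, e in g.exons]
        ) if g.exons else np.empty(0, dtype=np.intp)
        nsum = float(num[sel].sum())
        dsum = float(den[sel].sum())
        records.append(
            (
                g.gene_id,
                g.contig,
                int((den[sel] != 0).sum()),
                nsum,
                dsum,
                nsum / dsum if dsum else float("nan"),
            )
        )
    return pd.DataFrame(
        records, columns=["gene_id", "contig", "n_exonic_snps", "num", "den", "exon_fst"]
    )


def make_flanks(
    genes: GeneSet,
    contig_lengths: dict[str, int],
    flank_size: int = 50_000,
    gap: int = 50_000,
) -> pd.DataFrame:
    """Candidate neutral flanks: one ``flank_size`` interval per gene side,
    ``gap`` away from the gene body.

    Candidates truncated by a contig edge or overlapping any gene body are
    discarded, so the flank count is at most twice the gene count.
    """
    bodies = {
        ctg: np.array([(g.start, g.end) for g in glist])
        for ctg, glist in genes.by_contig().items()
    }

    def clear(ctg: str, s: int, e: int) -> bool:
        if s < 0 or e > contig_lengths[ctg]:
            return False
        b = bodies[ctg]
        return not ((s < b[:, 1]) & (e > b[:, 0])).any()

    records = []
    for g in genes:
        up = (g.start - gap - flank_size, g.start - gap)
        down = (g.end + gap, g.end + gap + flank_size)
        for side, (s, e) in (("up", up), ("down", down)):
            if clear(g.contig, s, e):
                records.append((g.gene_id, side, g.contig, s, e))
    return pd.DataFrame(records, columns=["gene_id", "side", "contig", "start", "end"])


def flank_fst(
    hm: HaplotypeMatrix,
    flanks: pd.DataFrame,
    contrast: ContrastSpec,
    mask: AccessibilityMask | None = None,
) -> pd.DataFrame:
    fst = interval_fst(
        hm, contrast, flanks[["contig", "start", "end"]].itertuples(index=False), mask
    )
    out = flanks.reset_index(drop=True).copy()
    out[["n_snps", "num", "den", "fst"]] = fst[["n_snps", "num", "den", "fst"]]
    return out


def flank_percentiles(flank_fsts, levels=(0.01, 0.001)) -> dict[float, float]:
    """Upper-tail empirical thresholds by the nearest-rank method."""
    v = np.sort(np.asarray(flank_fsts, dtype=float))
    v = v[~np.isnan(v)]
    out = {}
    for level in levels:
        if len(v) < 1.0 / level:
            raise ValueError(f"need >= {1/level:.0f} values for level {level}")
        rank = int(np.ceil((1.0 - level) * len(v)))  # 1-based nearest rank
        out[level] = float(v[rank - 1])
    return out


def gene_flank_enrichment(
    gene_fsts, flank_fsts, thresholds: dict[float, float]
) -> pd.DataFrame:
    """Proportion of genes vs flanks exceeding each flank-derived threshold.

    The enrichment ratio is P(gene > thr) / P(flank > thr); counts are
    returned so the contingency table is reconstructible.
    """
    g = np.asarray(gene_fsts, dtype=float)
    f = np.asarray(flank_fsts, dtype=float)
    g = g[~np.isnan(g)]
    f = f[~np.isnan(f)]
    records = []
    for level, thr in sorted(thresholds.items(), reverse=True):
        ga = int((g > thr).sum())
        fa = int((f > thr).sum())
        pg = ga / len(g)
        pf = fa / len(f)
        records.append(
            (level, thr, ga, len(g), fa, len(f), pg, pf, pg / pf if pf else float("inf"))
        )
    return pd.DataFrame(
        records,
        columns=[
            "level", "threshold", "genes_above", "n_genes",
            "flanks_above", "n_flanks", "prop_genes", "prop_flanks", "ratio",
        ],
    )


def cumulative_fst_curves(gene_fsts, flank_fsts, step: float = 0.1) -> pd.DataFrame:
    """Proportion of genes and flanks at or above each FST level."""
    levels = np.round(np.arange(0.0, 1.0 + step, step), 10)
    g = np.asarray(gene_fsts, dtype=float)
    f = np.asarray(flank_fsts, dtype=float)
    g = g[~np.isnan(g)]
    f = f[~np.isnan(f)]
    return pd.DataFrame(
        {
            "fst_level": levels,
            "prop_genes": [(g >= lv).mean() for lv in levels],
            "prop_flanks": [(f >= lv).mean() for lv in levels],
        }
    )


# ---------------------------------------------------------------------------
# Gene-level haplotype calling
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeCall:
    """Two-class haplotype structure of one divergent gene.

    Class A is enriched in contrast group 1, class B in group 2; chromosomes
    are assigned by majority vote over diagnostic SNPs oriented so that
    allele 1 is the group-2-enriched allele; exact ties stay unassigned.
    """

    gene_id: str
    diagnostic_positions: np.ndarray
    chromosome_class: np.ndarray  # per haplotype: 1=A, 2=B, 0=unassigned
    population_freqs: pd.DataFrame  # per population: freq_A, freq_B, unassigned
    sharing: str  # shared | private-to-group1 | private-to-group2


def call_haplotypes(
    hm: HaplotypeMatrix,
    gene_records: pd.DataFrame,
    genes: GeneSet,
    contrast: ContrastSpec,
    panel: SamplePanel,
    min_diag: int = 4,
    diag_fst: float = 0.5,
    divergent_fst: float = 0.4,
    mask: AccessibilityMask | None = None,
) -> list[HaplotypeCall]:
    """Call gene-level haplotypes at divergent genes.

    A gene qualifies when its exon-wide FST exceeds ``divergent_fst`` and it
    carries at least ``min_diag`` exonic SNPs with per-SNP Weir-Cockerham FST
    above ``diag_fst``.  Sharing is "shared" iff both classes are observed
    (>= 1 chromosome) in both contrast groups.
    """
    snp_fst = per_snp_wc_fst(hm, contrast)
    rows1 = hm.hap_indices(contrast.group1)
    rows2 = hm.hap_indices(contrast.group2)
    acc_ok = np.ones(hm.n_sites, dtype=bool)
    if mask is not None:
        for ctg in dict.fromkeys(hm.contigs.tolist()):
            on = hm.contigs == ctg
            acc_ok[on] = mask.is_accessible(ctg, hm.positions[on] - 1)

    calls = []
    fst_by_gene = dict(zip(gene_records["gene_id"], gene_records["exon_fst"]))
    for g in genes:
        gf = fst_by_gene.get(g.gene_id, float("nan"))
        if not (gf == gf and gf > divergent_fst):
            continue
        sel = (
            np.concatenate([hm.sites_in(g.contig, s, e) for s, e in g.exons])
            if g.exons
            else np.empty(0, dtype=np.intp)
        )
        sel = sel[acc_ok[sel]]
        diag = sel[np.nan_to_num(snp_fst[sel], nan=-1.0) > diag_fst]
        if len(diag) < min_diag:
            continue
        block = hm.calls[:, diag].astype(float)
        # orient allele 1 toward group 2
        f1 = block[rows1].mean(axis=0)
        f2 = block[rows2].mean(axis=0)
        flip = f2 < f1
        block[:, flip] = 1.0 - block[:, flip]
        votes = block.mean(axis=1)
        cls = np.zeros(hm.n_hap, dtype=np.int8)
        cls[votes > 0.5] = 2  # B, group-2-like
        cls[votes < 0.5] = 1  # A
        freqs = {}
        for pop in panel.population_names:
            rows = hm.hap_indices(panel.samples_in(pop))
            c = cls[rows]
            freqs[pop] = {
                "freq_A": float((c == 1).mean()),
                "freq_B": float((c == 2).mean()),
                "unassigned": float((c == 0).mean()),
            }
        in1 = cls[rows1]
        in2 = cls[rows2]
        a_both = (in1 == 1).any() and (in2 == 1).any()
        b_both = (in1 == 2).any() and (in2 == 2).any()
        if a_both and b_both:
            sharing = "shared"
        elif not (in1 == 2).any():
            sharing = "private-to-group2"  # class B confined to group 2
        else:
            sharing = "private-to-group1"
        calls.append(
            HaplotypeCall(
                gene_id=g.gene_id,
                diagnostic_positions=hm.positions[diag],
                chromosome_class=cls,
                population_freqs=pd.DataFrame(freqs).T,
                sharing=sharing,
            )
        )
    return calls


def haplotype_summary(calls: list[HaplotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "n_diagnostic": len(c.diagnostic_positions),
                "sharing": c.sharing,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_diagnostic", "sharing"])


# ---------------------------------------------------------------------------
# Enrichment test and sweep-score summaries
# ---------------------------------------------------------------------------


def chisq_enrichment_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]].

    Returns (chi2, two-tailed p, enrichment ratio (a/(a+b)) / (c/(c+d))).
    All margins must be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    enrichment = (a / (a + b)) / (c / (c + d))
    return float(chi2), float(p), float(enrichment)


def summarize_sweep_scores(
    scores: pd.DataFrame,
    region_mask: RegionMask,
    window_fst: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 1000,
    genic_min: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Mean |score| per window and per 0.1-wide window-FST class.

    Windows with genic fraction below ``genic_min`` are excluded.  Returns
    ``(window_table, class_table)``; the class table carries percentile
    bootstrap 95% CIs over windows.
    """
    fst_lookup = {
        (r.contig, r.start): r.fst for r in window_fst.itertuples(index=False)
    }
    records = []
    for ctg in sorted(contig_lengths):
        sub = scores[scores["contig"] == ctg]
        pos0 = sub["position"].to_numpy() - 1
        vals = sub["score"].to_numpy(dtype=float)
        order = np.argsort(pos0)
        pos0, vals = pos0[order], vals[order]
        for start, end in tile_windows(contig_lengths[ctg], window):
            genic = region_mask.genic_fraction(ctg, start, end)
            lo, hi = np.searchsorted(pos0, [start, end])
            if hi == lo:
                continue
            mean_abs = float(np.abs(vals[lo:hi]).mean())
            records.append(
                (ctg, start, end, genic, hi - lo, mean_abs, fst_lookup.get((ctg, start)))
            )
    win = pd.DataFrame(
        records,
        columns=["contig", "start", "end", "genic_frac", "n_snps", "mean_abs_score", "fst"],
    )
    win = win[win["genic_frac"] >= genic_min].reset_index(drop=True)
    win = win.dropna(subset=["fst"])
    cls_records = []
    classes = np.minimum((np.clip(win["fst"], 0, 1) / 0.1).astype(int), 9)
    for c in sorted(classes.unique()):
        vals = win.loc[classes == c, "mean_abs_score"].to_numpy()
        mean, lo, hi = bootstrap_ci(vals, n_boot, seed + int(c))
        cls_records.append((c * 0.1, (c + 1) * 0.1, len(vals), mean, lo, hi))
    cls = pd.DataFrame(
        cls_records,
        columns=["fst_lo", "fst_hi", "n_windows", "mean_abs_score", "ci_lo", "ci_hi"],
    )
    return win, cls
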