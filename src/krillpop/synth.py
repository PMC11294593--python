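"""Seeded synthetic inputs for the whole pipeline.

The generator emulates a small multi-contig genome with gene annotations,
phased SNPs for eight population samples drawn from a two-deme split
coalescent, planted inaccessible regions recoverable from depth tracks, and
planted divergent genes carrying two deeply diverged gene-level haplotype
classes.  Every stochastic choice flows from one seed; a truth file records
every planted signal so recovery can be asserted end to end.

Planted divergent genes model ancient standing haplotype variation: all
exonic SNPs of a planted gene segregate between the two classes (with a small
within-class mismatch rate), so the gene is an exon-wide FST outlier with
many diagnostic SNPs, not a handful of isolated ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim, divergence
from .popio import (
    AccessibilityMask,
    Gene,
    GeneSet,
    HaplotypeMatrix,
    SamplePanel,
    write_fasta,
    write_gff3,
    write_mask_bed,
    write_panel,
    write_vcf,
)
from .accessibility import DepthProfile, write_depth_tsv

_DEFAULT_POPS = {
    "no": 10, "is": 10, "sv": 10, "ba": 10, "sc": 10, "us": 10, "cn": 7, "me": 7,
}
_POP_KM = {
    "no": 0, "sc": 500, "is": 1200, "sv": 1800, "ba": 2200,
    "cn": 3800, "us": 4400, "me": 5800,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Population sizes, theta, split time, depth peak and planted-gene
    architecture mirror the study system; the genome span is desk-scale.
    """

    n_contigs: int = 10
    contig_length: int = 150_000
    n_genes: int = 500
    utr5_len: int = 60
    cds_exon_len: int = 150
    intron_len: int = 300
    utr3_len: int = 60
    populations: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_POPS))
    group1_pops: tuple[str, ...] = ("no", "is", "sv", "ba", "sc", "us", "cn")
    group2_pops: tuple[str, ...] = ("me",)
    theta_w: float = 0.0162
    t_join: float = 0.01443
    locus_bp: int = 1146
    n_planted: int = 20
    class_b_freq: tuple[float, float] = (0.10, 0.90)  # group 1, group 2
    min_diag: int = 8
    class_noise: float = 0.02
    depth_peak: int = 188
    depth_dispersion: float = 50.0
    n_inaccessible_per_contig: int = 3
    inaccessible_len: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for p, n in self.populations.items():
            if n < 2:
                raise ValueError(f"population {p} needs >= 2 samples")
        if self.n_planted > self.n_genes:
            raise ValueError("planted genes must be a subset of genes")

    @property
    def gene_len(self) -> int:
        return (
            self.utr5_len + 2 * self.cds_exon_len + self.intron_len + self.utr3_len
        )

    @property
    def n_samples(self) -> int:
        return sum(self.populations.values())

    def panel(self) -> SamplePanel:
        ordered = list(self.group1_pops) + list(self.group2_pops)
        extra = [p for p in self.populations if p not in ordered]
        samples, pops = [], []
        for p in ordered + extra:
            for i in range(self.populations[p]):
                samples.append(f"{p}{i + 1}")
                pops.append(p)
        names = ordered + extra
        km = [_POP_KM.get(p, 500.0 * i) for i, p in enumerate(names)]
        dist = pd.DataFrame(
            np.abs(np.subtract.outer(km, km)).astype(float), index=names, columns=names
        )
        return SamplePanel(samples, pops, dist)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _contig_names(cfg: SyntheticConfig) -> list[str]:
    return [f"ctg{i + 1:02d}" for i in range(cfg.n_contigs)]


def _make_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> GeneSet:
    genes = GeneSet()
    glen = cfg.gene_len
    gid = 0
    base, rem = divmod(cfg.n_genes, cfg.n_contigs)
    for ci, ctg in enumerate(_contig_names(cfg)):
        n_here = base + (1 if ci < rem else 0)
        spacing = cfg.contig_length // (n_here + 1)
        if spacing < glen + 400:
            raise ValueError("genes overflow contig: reduce n_genes or lengthen contigs")
        for k in range(n_here):
            jitter = int(rng.integers(-200, 201))
            s = (k + 1) * spacing - glen // 2 + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            u5, ce, it, u3 = cfg.utr5_len, cfg.cds_exon_len, cfg.intron_len, cfg.utr3_len
            b1 = (s, s + u5 + ce)  # exon block 1
            b2 = (s + u5 + ce + it, s + glen)  # exon block 2
            if strand == "+":
                utr5 = [(s, s + u5)]
                cds = [(s + u5, b1[1]), (b2[0], b2[0] + ce)]
                utr3 = [(b2[0] + ce, b2[1])]
            else:
                utr3 = [(s, s + u3)]
                cds = [(s + u3, b1[1]), (b2[0], b2[0] + ce)]
                utr5 = [(b2[0] + ce, b2[1])]
            gid += 1
            genes.append(
                Gene(
                    gene_id=f"g{gid:04d}",
                    contig=ctg,
                    strand=strand,
                    start=s,
                    end=s + glen,
                    exons=[b1, b2],
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return genes


def _plant_inaccessible(cfg, genes: GeneSet, rng) -> dict[str, list[tuple[int, int]]]:
    """Intergenic intervals to be rendered inaccessible via the depth model."""
    out: dict[str, list[tuple[int, int]]] = {}
    by_ctg = genes.by_contig()
    for ctg in _contig_names(cfg):
        glist = by_ctg.get(ctg, [])
        gaps = []
        prev = 0
        for g in glist:
            if g.start - prev >= cfg.inaccessible_len + 400:
                gaps.append((prev, g.start))
            prev = g.end
        if cfg.contig_length - prev >= cfg.inaccessible_len + 400:
            gaps.append((prev, cfg.contig_length))
        pick = rng.choice(
            len(gaps), size=min(cfg.n_inaccessible_per_contig, len(gaps)), replace=False
        )
        ivs = []
        for gi in sorted(pick):
            lo, hi = gaps[gi]
            mid = (lo + hi) // 2
            s = mid - cfg.inaccessible_len // 2
            ivs.append((s, s + cfg.inaccessible_len))
        out[ctg] = ivs
    return out


def _make_depth(cfg, inaccessible, rng) -> DepthProfile:
    """Negative-binomial totals clamped inside the accessible band; planted
    intervals forced below both the depth and sample-count thresholds so the
    mask is recoverable exactly."""
    total, n_mapped = {}, {}
    k = cfg.depth_dispersion
    mu = cfg.depth_peak
    p = k / (k + mu)
    for ctg in _contig_names(cfg):
        L = cfg.contig_length
        t = rng.negative_binomial(k, p, size=L).astype(np.int64)
        t = np.clip(t, mu - 60, mu + 60)
        m = np.maximum(cfg.n_samples - rng.binomial(cfg.n_samples, 0.02, size=L), 38)
        for s, e in inaccessible[ctg]:
            t[s:e] = np.clip(rng.poisson(20, size=e - s), 0, 60)
            m[s:e] = np.minimum(rng.binomial(cfg.n_samples, 0.2, size=e - s), 36)
        total[ctg] = t
        n_mapped[ctg] = m.astype(np.int64)
    return DepthProfile(total, n_mapped, cfg.n_samples)


# ---------------------------------------------------------------------------
# Variation
# ---------------------------------------------------------------------------


def _neutral_variants(cfg, ctg_index: int, acc: np.ndarray, rng_seed: int):
    """Neutral split-coalescent SNPs for one contig.

    Contigs are tiled into ``locus_bp`` loci; each locus draws an independent
    genealogy, a Poisson number of mutations with mean theta_locus * L_tree
    (so Watterson's estimator over accessible bases recovers theta_w), and
    uniform positions among the locus's accessible bases.
    """
    panel_cfg = cfg.panel()
    n1 = 2 * sum(cfg.populations[p] for p in cfg.group1_pops)
    n2 = 2 * sum(cfg.populations[p] for p in cfg.group2_pops)
    L = cfg.contig_length
    positions: list[np.ndarray] = []
    call_blocks: list[np.ndarray] = []
    pos_rng = np.random.default_rng([rng_seed, 101, ctg_index])
    n_loci = -(-L // cfg.locus_bp)
    for li in range(n_loci):
        s, e = li * cfg.locus_bp, min((li + 1) * cfg.locus_bp, L)
        avail = np.nonzero(acc[s:e])[0] + s
        if len(avail) == 0:
            continue
        rng = coalsim._locus_rng(rng_seed + 7919 * ctg_index, li)
        tree = coalsim.simulate_genealogy(n1, n2, cfg.t_join, rng)
        theta = cfg.theta_w * len(avail)
        S = min(pos_rng.poisson(theta * tree.total_length), len(avail))
        if S == 0:
            continue
        pos = np.sort(pos_rng.choice(avail, size=S, replace=False))
        below = coalsim.leaf_sets(tree)
        cum = np.cumsum(tree.blen)
        branches = np.searchsorted(cum, pos_rng.random(S) * tree.total_length, side="right")
        block = below[branches]  # (S, n_hap)
        positions.append(pos)
        call_blocks.append(block)
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty((0, n1 + n2), dtype=bool)
    return np.concatenate(positions), np.concatenate(call_blocks, axis=0)


def _plant_gene(cfg, gene: Gene, acc, pos, calls, rng):
    """Overlay the two-class haplotype architecture on one gene.

    Existing exonic SNPs are re-coded to the class indicator (with the
    configured within-class mismatch rate); extra diagnostic positions are
    added if fewer than ``min_diag`` exist.  Returns updated (pos, calls),
    the diagnostic positions and per-chromosome class vector.
    """
    n1 = 2 * sum(cfg.populations[p] for p in cfg.group1_pops)
    n2 = 2 * sum(cfg.populations[p] for p in cfg.group2_pops)
    f1, f2 = cfg.class_b_freq
    z = np.concatenate([rng.random(n1) < f1, rng.random(n2) < f2])  # class B flag
    exonic = np.zeros(cfg.contig_length, dtype=bool)
    for s, e in gene.exons:
        exonic[s:e] = True
    on_gene = exonic[pos]
    diag_pos = pos[on_gene]
    if len(diag_pos) < cfg.min_diag:
        avail = np.nonzero(exonic & acc)[0]
        avail = np.setdiff1d(avail, pos)
        extra = np.sort(
            rng.choice(avail, size=cfg.min_diag - len(diag_pos), replace=False)
        )
        pos = np.concatenate([pos, extra])
        calls = np.concatenate(
            [calls, np.zeros((len(extra), calls.shape[1]), dtype=bool)], axis=0
        )
        order = np.argsort(pos, kind="stable")
        pos, calls = pos[order], calls[order]
        on_gene = exonic[pos]
        diag_pos = pos[on_gene]
    block = np.broadcast_to(z, (int(on_gene.sum()), len(z))).copy()
    noise = rng.random(block.shape) < cfg.class_noise
    block[noise] = ~block[noise]
    calls[on_gene] = block
    return pos, calls, diag_pos, z


def generate(cfg: SyntheticConfig, outdir) -> dict:
    """Write the full synthetic dataset and its truth file into ``outdir``.

    Outputs: genome.fa, genes.gff3, accessible.bed, depth.tsv, variants.vcf,
    panel.tsv, distances.tsv, truth.json.  Returns a dict of paths plus the
    parsed truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = cfg.panel()
    rng_geom = np.random.default_rng([cfg.seed, 1])
    rng_depth = np.random.default_rng([cfg.seed, 2])
    rng_plant = np.random.default_rng([cfg.seed, 3])
    rng_seq = np.random.default_rng([cfg.seed, 4])

    genes = _make_genes(cfg, rng_geom)
    inaccessible = _plant_inaccessible(cfg, genes, rng_geom)
    depth = _make_depth(cfg, inaccessible, rng_depth)
    ctgs = _contig_names(cfg)
    contig_lengths = {c: cfg.contig_length for c in ctgs}
    genome = {
        c: "".join(np.array(list("ACGT"))[rng_seq.integers(0, 4, cfg.contig_length)])
        for c in ctgs
    }
    mask = AccessibilityMask(
        {
            c: _complement(inaccessible[c], cfg.contig_length)
            for c in ctgs
        }
    )

    planted_idx = np.sort(
        rng_plant.choice(cfg.n_genes, size=cfg.n_planted, replace=False)
    )
    planted_ids = {f"g{int(i) + 1:04d}" for i in planted_idx}
    by_ctg = genes.by_contig()

    all_contig, all_pos, all_ref, all_alt, all_calls = [], [], [], [], []
    truth_genes = []
    for ci, ctg in enumerate(ctgs):
        acc = mask.to_boolean(ctg, cfg.contig_length)
        pos, calls = _neutral_variants(cfg, ci, acc, cfg.seed)
        for g in by_ctg.get(ctg, []):
            if g.gene_id not in planted_ids:
                continue
            pos, calls, diag_pos, z = _plant_gene(cfg, g, acc, pos, calls, rng_plant)
            truth_genes.append((g, diag_pos, z))
        seq = genome[ctg]
        ref = np.array([seq[p] for p in pos], dtype=object)
        others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        alt = np.array(
            [others[r][rng_seq.integers(0, 3)] for r in ref], dtype=object
        )
        all_contig.append(np.full(len(pos), ctg, dtype=object))
        all_pos.append(pos + 1)  # to 1-based
        all_ref.append(ref)
        all_alt.append(alt)
        all_calls.append(calls)

    calls = np.concatenate(all_calls, axis=0).T.astype(np.int8)
    hm = HaplotypeMatrix(
        np.concatenate(all_contig),
        np.concatenate(all_pos),
        np.concatenate(all_ref),
        np.concatenate(all_alt),
        calls,
        panel.samples,
        phased=True,
    )

    # truth record, including the realized exon-wide FST per planted gene
    g1_rows = hm.hap_indices([s for p in cfg.group1_pops for s in panel.samples_in(p)])
    g2_rows = hm.hap_indices([s for p in cfg.group2_pops for s in panel.samples_in(p)])
    planted_records = []
    for g, diag_pos, z in truth_genes:
        sel = np.concatenate([hm.sites_in(g.contig, s, e) for s, e in g.exons])
        k1, m1 = hm.allele_counts(g1_rows)
        k2, m2 = hm.allele_counts(g2_rows)
        fst = divergence.reynolds_fst(k1[sel], m1[sel], k2[sel], m2[sel])
        n1 = len(g1_rows)
        planted_records.append(
            {
                "gene_id": g.gene_id,
                "contig": g.contig,
                "diagnostic_positions": (diag_pos + 1).tolist(),
                "class_b_freq_group1": float(z[:n1].mean()),
                "class_b_freq_group2": float(z[n1:].mean()),
                "expected_exon_fst": float(fst),
            }
        )

    paths = {
        "genome": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "mask": outdir / "accessible.bed",
        "depth": outdir / "depth.tsv",
        "vcf": outdir / "variants.vcf",
        "panel": outdir / "panel.tsv",
        "distances": outdir / "distances.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(genes, paths["gff"])
    write_mask_bed(mask, paths["mask"])
    write_depth_tsv(depth, paths["depth"])
    write_vcf(hm, paths["vcf"], contig_lengths)
    write_panel(panel, paths["panel"], paths["distances"])
    truth = {
        "seed": cfg.seed,
        "theta_w": cfg.theta_w,
        "t_join": cfg.t_join,
        "n_samples": cfg.n_samples,
        "group1_pops": list(cfg.group1_pops),
        "group2_pops": list(cfg.group2_pops),
        "contig_lengths": contig_lengths,
        "depth_peak": cfg.depth_peak,
        "n_snps": int(hm.n_sites),
        "inaccessible": {c: [list(map(int, iv)) for iv in inaccessible[c]] for c in ctgs},
        "planted_genes": planted_records,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth, "hm": hm,
            "genes": genes, "mask": mask, "panel": panel, "depth": depth,
            "contig_lengths": contig_lengths}


def _complement(intervals, length: int) -> np.ndarray:
    b = np.ones(length, dtype=bool)
    for s, e in intervals:
        b[s:e] = False
    edges = np.flatnonzero(np.diff(np.concatenate(([0], b.view(np.int8), [0]))))
    return edges.reshape(-1, 2)


# ---------------------------------------------------------------------------
# Hand-checked worked example
# ---------------------------------------------------------------------------


def worked_example_paths() -> dict[str, Path]:
    """Paths of the tiny checked-in dataset (8 chromosomes, 5 SNPs, 1 gene)
    whose statistics are computed by hand in the adjacent expected.json."""
    root = Path(__file__).parent / "data" / "worked_example"
    return {
        "vcf": root / "example.vcf",
        "gff": root / "genes.gff3",
        "mask": root / "mask.bed",
        "panel": root / "panel.tsv",
        "expected": root / "expected.json",
    }


def worked_example_expected() -> dict:
    return json.loads(worked_example_paths()["expected"].read_text())
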