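"""Readers, writers and core containers for phased-SNP population data.

Internal coordinates are 0-based half-open everywhere.  VCF positions are
converted at the I/O boundary: a site at VCF POS ``p`` occupies the internal
interval ``[p-1, p)``.  BED and GFF3 follow their own standards (0-based
half-open and 1-based closed, respectively) and are converted on read/write.
"""

from __future__ import annotations

import logging
import textwrap
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


# ---------------------------------------------------------------------------
# Sample panel
# ---------------------------------------------------------------------------


@dataclass
class SamplePanel:
    """Sample -> population assignment, with optional pairwise distances (km)."""

    samples: list[str]
    populations: list[str]
    distances: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.populations):
            raise ValueError("samples and populations must be parallel lists")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if self.distances is not None:
            d = self.distances
            if not (d.index == d.columns).all():
                raise ValueError("distance matrix index/columns mismatch")
            a = d.to_numpy(dtype=float)
            if not np.allclose(a, a.T):
                raise ValueError("distance matrix must be symmetric")
            if not np.allclose(np.diag(a), 0.0):
                raise ValueError("distance matrix diagonal must be zero")
            if (a < 0).any():
                raise ValueError("distances must be non-negative")

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def population_of(self, sample: str) -> str:
        return self.populations[self.samples.index(sample)]

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in zip(self.samples, self.populations) if p == population]

    def subset(self, samples: list[str]) -> "SamplePanel":
        pops = [self.population_of(s) for s in samples]
        return SamplePanel(list(samples), pops, self.distances)


def read_panel(path, distances_path=None) -> SamplePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population_id"} <= set(df.columns):
        raise ValueError("panel TSV requires columns sample_id, population_id")
    dist = None
    if distances_path is not None:
        dist = pd.read_csv(distances_path, sep="\t", index_col=0)
        dist.index = dist.index.astype(str)
    return SamplePanel(df["sample_id"].tolist(), df["population_id"].tolist(), dist)


def write_panel(panel: SamplePanel, path, distances_path=None) -> None:
    pd.DataFrame(
        {"sample_id": panel.samples, "population_id": panel.populations}
    ).to_csv(path, sep="\t", index=False)
    if distances_path is not None and panel.distances is not None:
        panel.distances.to_csv(distances_path, sep="\t")


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """Phased biallelic 0/1 calls: rows are haploid chromosomes, columns sites.

    Sample ``i`` owns rows ``2*i`` and ``2*i + 1``.  ``positions`` are 1-based
    (VCF convention) and strictly increasing within each contig.  Missing
    calls, when explicitly allowed, are coded -1.
    """

    contigs: np.ndarray  # per-site contig name
    positions: np.ndarray  # per-site 1-based position
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray  # (2 * n_samples, n_sites) int8
    samples: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.contigs = np.asarray(self.contigs)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.calls.shape != (2 * len(self.samples), len(self.positions)):
            raise ValueError("calls shape inconsistent with samples/sites")
        for ctg in dict.fromkeys(self.contigs.tolist()):
            pos = self.positions[self.contigs == ctg]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {ctg}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_hap(self) -> int:
        return self.calls.shape[0]

    @property
    def has_missing(self) -> bool:
        return bool((self.calls < 0).any())

    def hap_indices(self, samples: list[str]) -> np.ndarray:
        idx = []
        for s in samples:
            i = self.samples.index(s)
            idx.extend((2 * i, 2 * i + 1))
        return np.asarray(idx, dtype=np.intp)

    def allele_counts(self, rows: np.ndarray | None = None):
        """Per-site (ALT count, called-chromosome count) over ``rows``."""
        c = self.calls if rows is None else self.calls[rows]
        k = (c == 1).sum(axis=0)
        m = (c >= 0).sum(axis=0)
        return k, m

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            self.contigs[index],
            self.positions[index],
            self.ref[index],
            self.alt[index],
            self.calls[:, index],
            list(self.samples),
            self.phased,
        )

    def take_samples(self, samples: list[str]) -> "HaplotypeMatrix":
        rows = self.hap_indices(samples)
        return HaplotypeMatrix(
            self.contigs,
            self.positions,
            self.ref,
            self.alt,
            self.calls[rows],
            list(samples),
            self.phased,
        )

    def sites_in(self, contig: str, start: int, end: int) -> np.ndarray:
        """Site indices with internal coordinate in [start, end) on contig."""
        pos0 = self.positions - 1
        return np.nonzero((self.contigs == contig) & (pos0 >= start) & (pos0 < end))[0]


def read_vcf(
    path,
    panel: SamplePanel | None = None,
    on_multiallelic: str = "skip",
    require_phased: bool = True,
    allow_missing: bool = False,
) -> HaplotypeMatrix:
    """Load phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Multiallelic or non-SNP records are skipped (``on_multiallelic="skip"``,
    logged) or fatal (``"error"``).  Unphased genotypes are fatal when phase is
    required; missing genotypes are fatal unless ``allow_missing``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if panel is not None:
        missing = [s for s in panel.samples if s not in vcf_samples]
        if missing:
            raise ValueError(f"panel samples absent from VCF header: {missing}")
        order = [vcf_samples.index(s) for s in panel.samples]
        samples = list(panel.samples)
    else:
        order = list(range(len(vcf_samples)))
        samples = vcf_samples

    contigs, positions, refs, alts, cols = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(
                    f"non-biallelic-SNP record at {var.CHROM}:{var.POS}"
                )
            n_skipped += 1
            continue
        g = var.genotype.array()  # (n_samples, 3): allele0, allele1, phased
        g = g[order]
        a = g[:, :2]
        if (a < 0).any():
            if not allow_missing:
                raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        if require_phased and not (g[(a >= 0).all(axis=1), 2] == 1).all():
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        contigs.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(a.astype(np.int8).reshape(-1))
    if n_skipped:
        log.warning("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        np.asarray(contigs, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.asarray(refs, dtype=object),
        np.asarray(alts, dtype=object),
        calls,
        samples,
        phased=True,
    )


def write_vcf(hm: HaplotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    sep = "|" if hm.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for ctg, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={ctg},length={ln}>\n")
        else:
            for ctg in dict.fromkeys(hm.contigs.tolist()):
                fh.write(f"##contig=<ID={ctg}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hm.samples)
            + "\n"
        )
        calls = hm.calls
        for j in range(hm.n_sites):
            col = calls[:, j]
            gts = []
            for i in range(len(hm.samples)):
                a, b = col[2 * i], col[2 * i + 1]
                gts.append(
                    f"{'.' if a < 0 else a}{sep}{'.' if b < 0 else b}"
                )
            fh.write(
                f"{hm.contigs[j]}\t{hm.positions[j]}\t.\t{hm.ref[j]}\t{hm.alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Accessibility mask
# ---------------------------------------------------------------------------


class AccessibilityMask:
    """Per-contig accessible intervals, 0-based half-open, merged and sorted."""

    def __init__(self, intervals: dict[str, np.ndarray] | None = None):
        self.intervals: dict[str, np.ndarray] = {}
        if intervals:
            for ctg, arr in intervals.items():
                self.intervals[ctg] = _normalize_intervals(arr)

    @classmethod
    def from_boolean(cls, flags: dict[str, np.ndarray]) -> "AccessibilityMask":
        out = {}
        for ctg, b in flags.items():
            b = np.asarray(b, dtype=bool)
            edges = np.flatnonzero(np.diff(np.concatenate(([0], b.view(np.int8), [0]))))
            out[ctg] = edges.reshape(-1, 2)
        return cls(out)

    def to_boolean(self, contig: str, length: int) -> np.ndarray:
        b = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(contig, np.empty((0, 2), dtype=np.int64)):
            b[s:e] = True
        return b

    def contigs(self) -> list[str]:
        return list(self.intervals)

    def accessible_length(self, contig: str, start: int = 0, end: int | None = None) -> int:
        iv = self.intervals.get(contig)
        if iv is None or len(iv) == 0:
            return 0
        if end is None:
            end = int(iv[-1, 1])
        s = np.clip(iv[:, 0], start, end)
        e = np.clip(iv[:, 1], start, end)
        return int(np.maximum(e - s, 0).sum())

    def is_accessible(self, contig: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 0-based positions."""
        iv = self.intervals.get(contig)
        pos0 = np.asarray(pos0)
        if iv is None or len(iv) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < iv[idx[ok], 1]
        return out


def _normalize_intervals(arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    if (arr[:, 1] <= arr[:, 0]).any():
        raise ValueError("empty or inverted interval")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def read_mask_bed(path, contig_lengths: dict[str, int] | None = None) -> AccessibilityMask:
    iv: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            ctg, s, e = line.split("\t")[:3]
            s, e = int(s), int(e)
            if contig_lengths is not None and e > contig_lengths.get(ctg, e):
                raise ValueError(f"BED interval {ctg}:{s}-{e} beyond contig length")
            iv.setdefault(ctg, []).append([s, e])
    return AccessibilityMask({c: np.asarray(v) for c, v in iv.items()})


def write_mask_bed(mask: AccessibilityMask, path) -> None:
    with open(path, "w") as fh:
        for ctg in sorted(mask.intervals):
            for s, e in mask.intervals[ctg]:
                fh.write(f"{ctg}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Gene models and the region mask
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    """One gene model; all coordinates 0-based half-open, exons = CDS + UTRs."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene body in {self.gene_id}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")


class GeneSet(list):
    """A list of :class:`Gene` with convenience lookups."""

    def by_contig(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self:
            out.setdefault(g.contig, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: g.start)
        return out

    def get(self, gene_id: str) -> Gene:
        for g in self:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def read_gff3(path) -> GeneSet:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = GeneSet()
    for g in db.features_of_type("gene"):
        def _coords(ftype):
            return [
                (f.start - 1, f.end) for f in db.children(g, featuretype=ftype)
            ]

        genes.append(
            Gene(
                gene_id=g.id,
                contig=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=_coords("exon"),
                cds=_coords("CDS"),
                utr5=_coords("five_prime_UTR"),
                utr3=_coords("three_prime_UTR"),
            )
        )
    return genes


def write_gff3(genes: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            def row(ftype, s, e, attrs):
                fh.write(
                    f"{g.contig}\tkrillpop\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            row("gene", g.start, g.end, f"ID={g.gene_id}")
            for i, (s, e) in enumerate(g.exons, 1):
                row("exon", s, e, f"ID={g.gene_id}.exon{i};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.cds, 1):
                row("CDS", s, e, f"ID={g.gene_id}.cds{i};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.utr5, 1):
                row("five_prime_UTR", s, e, f"ID={g.gene_id}.u5_{i};Parent={g.gene_id}")
            for i, (s, e) in enumerate(g.utr3, 1):
                row("three_prime_UTR", s, e, f"ID={g.gene_id}.u3_{i};Parent={g.gene_id}")


# region class codes
INTERGENIC, INTRON, UTR3, EXON, UTR5, CDS = 1, 2, 3, 4, 5, 6
GENIC_CODES = frozenset({INTRON, UTR3, EXON, UTR5, CDS})

# priority when features of different genes overlap: cds > UTR > exon > intron
_PRIORITY = {INTERGENIC: 0, INTRON: 1, EXON: 2, UTR3: 3, UTR5: 3, CDS: 4}


class RegionMask:
    """Per-base gene-region class codes (1=intergenic ... 6=cds).

    When built with genome sequences, carries a per-CDS-base synonymous site
    fraction (codon degeneracy: 4-fold -> 1, 2-fold -> 1/3, 0-fold -> 0) and
    can classify an observed SNP as synonymous/non-synonymous from its codon.
    """

    def __init__(self, codes: dict[str, np.ndarray]):
        self.codes = codes
        self.syn_frac: dict[str, np.ndarray] = {}
        self._codon_info: dict[str, dict[int, tuple[str, int, str]]] = {}

    def code_at(self, contig: str, pos0: np.ndarray) -> np.ndarray:
        return self.codes[contig][np.asarray(pos0)]

    def genic_fraction(self, contig: str, start: int, end: int) -> float:
        c = self.codes[contig][start:end]
        return float(np.isin(c, list(GENIC_CODES)).mean()) if len(c) else 0.0

    def synonymous_sites(self, contig: str, start: int, end: int) -> float:
        if contig not in self.syn_frac:
            raise ValueError("region mask built without genome sequences")
        f = self.syn_frac[contig][start:end]
        return float(np.nansum(f))

    def snp_is_synonymous(self, contig: str, pos0: int, alt: str) -> bool | None:
        """True/False for a CDS SNP, None outside annotated codons."""
        info = self._codon_info.get(contig, {}).get(int(pos0))
        if info is None:
            return None
        codon, offset, strand = info
        base = alt if strand == "+" else alt.translate(_COMPLEMENT)
        mutant = codon[:offset] + base.upper() + codon[offset + 1 :]
        return _translate(codon) == _translate(mutant)


def _translate(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


def build_region_mask(
    genes: GeneSet,
    contig_lengths: dict[str, int],
    genome: dict[str, str] | None = None,
) -> RegionMask:
    """Paint every base with its gene-region class.

    Overlaps across genes resolve by priority cds > UTR > exon > intron >
    intergenic; within equal priority the earlier gene (sorted by contig
    coordinate) wins.
    """
    codes = {c: np.full(n, INTERGENIC, dtype=np.uint8) for c, n in contig_lengths.items()}
    rank = {c: np.zeros(n, dtype=np.uint8) for c, n in contig_lengths.items()}
    mask = RegionMask(codes)
    if genome is not None:
        mask.syn_frac = {
            c: np.full(n, np.nan, dtype=np.float32) for c, n in contig_lengths.items()
        }

    def paint(ctg, s, e, code):
        if e > contig_lengths[ctg]:
            raise ValueError(f"feature beyond contig length on {ctg}")
        pr = _PRIORITY[code]
        upd = rank[ctg][s:e] < pr
        codes[ctg][s:e][upd] = code  # slice is a view: writes through
        rank[ctg][s:e][upd] = pr

    for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
        paint(g.contig, g.start, g.end, INTRON)
        for s, e in g.exons:
            paint(g.contig, s, e, EXON)
        for s, e in g.utr5:
            paint(g.contig, s, e, UTR5)
        for s, e in g.utr3:
            paint(g.contig, s, e, UTR3)
        for s, e in g.cds:
            paint(g.contig, s, e, CDS)
        if genome is not None and g.cds:
            _annotate_codons(mask, g, genome[g.contig])
    return mask


def _annotate_codons(mask: RegionMask, g: Gene, seq: str) -> None:
    """Per-CDS-base codon context and synonymous site fractions for one gene."""
    cds_pos = np.concatenate([np.arange(s, e) for s, e in g.cds])
    cds_seq = "".join(seq[s:e] for s, e in g.cds).upper()
    if g.strand == "-":
        cds_pos = cds_pos[::-1]
        cds_seq = cds_seq.translate(_COMPLEMENT)[::-1]
    n_codons = len(cds_seq) // 3
    info = mask._codon_info.setdefault(g.contig, {})
    for ci in range(n_codons):
        codon = cds_seq[3 * ci : 3 * ci + 3]
        aa = _translate(codon)
        for off in range(3):
            gpos = int(cds_pos[3 * ci + off])
            n_syn = sum(
                1
                for b in "ACGT"
                if b != codon[off]
                and _translate(codon[:off] + b + codon[off + 1 :]) == aa
            )
            mask.syn_frac[g.contig][gpos] = n_syn / 3.0
            info[gpos] = (codon, off, g.strand)


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Minor-allele-as-derived recoding
# ---------------------------------------------------------------------------


def recode_minor_as_derived(hm: HaplotypeMatrix, group_samples: list[str]):
    """Re-orient sites so ALT is the minor allele within ``group_samples``.

    Returns ``(recoded, swapped, monomorphic)``: a new matrix covering all
    samples with calls complemented at swapped sites, plus per-site flags.
    Ties (group ALT frequency exactly 0.5) and sites monomorphic within the
    group pass through unswapped; monomorphic sites are flagged.
    """
    rows = hm.hap_indices(group_samples)
    k, m = hm.allele_counts(rows)
    freq = np.divide(k, m, out=np.zeros(len(k)), where=m > 0)
    monomorphic = (k == 0) | (k == m)
    swap = (freq > 0.5) & ~monomorphic
    calls = hm.calls.copy()
    valid = calls[:, swap] >= 0
    block = calls[:, swap]
    block[valid] = 1 - block[valid]
    calls[:, swap] = block
    ref = hm.ref.copy()
    alt = hm.alt.copy()
    ref[swap], alt[swap] = alt[swap], ref[swap].copy()
    out = HaplotypeMatrix(
        hm.contigs, hm.positions, ref, alt, calls, list(hm.samples), hm.phased
    )
    return out, swap, monomorphic


def recode_for_groups(hm: HaplotypeMatrix, group1: list[str], group2: list[str]):
    """One recoded dataset per contrast group (minor allele of that group)."""
    hm1, _, _ = recode_minor_as_derived(hm, group1)
    hm2, _, _ = recode_minor_as_derived(hm, group2)
    return hm1, hm2


# ---------------------------------------------------------------------------
# psmcfa encoding
# ---------------------------------------------------------------------------


def het_sites_for_sample(hm: HaplotypeMatrix, sample: str) -> dict[str, np.ndarray]:
    """0-based positions where one diploid sample is heterozygous, per contig."""
    i = hm.samples.index(sample)
    het = hm.calls[2 * i] != hm.calls[2 * i + 1]
    out: dict[str, np.ndarray] = {}
    for ctg in dict.fromkeys(hm.contigs.tolist()):
        sel = (hm.contigs == ctg) & het
        out[ctg] = hm.positions[sel] - 1
    return out


def encode_psmcfa(
    het_sites: dict[str, np.ndarray],
    mask: AccessibilityMask,
    contig_lengths: dict[str, int],
    window_bp: int = 10,
    line_width: int = 60,
) -> str:
    """FASTA-like per-window encoding for sequential-coalescent input.

    Each non-overlapping ``window_bp`` window becomes "K" if it holds >= 1
    heterozygous site, else "T" if >= 1 accessible base, else "N".
    ``het_sites`` maps contig -> 0-based heterozygous positions.
    """
    if window_bp < 1:
        raise ValueError("window size must be >= 1")
    chunks = []
    for ctg in sorted(contig_lengths):
        length = contig_lengths[ctg]
        n_win = -(-length // window_bp)
        acc = mask.to_boolean(ctg, length)
        pad = n_win * window_bp - length
        if pad:
            acc = np.concatenate([acc, np.zeros(pad, dtype=bool)])
        has_acc = acc.reshape(n_win, window_bp).any(axis=1)
        symbols = np.where(has_acc, "T", "N").astype(object)
        het = np.asarray(het_sites.get(ctg, []), dtype=np.int64)
        if len(het):
            symbols[np.unique(het // window_bp)] = "K"
        body = "\n".join(textwrap.wrap("".join(symbols), line_width))
        chunks.append(f">{ctg}\n{body}\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Sweep-score tables and PHYLIP matrices
# ---------------------------------------------------------------------------


def read_sweep_scores(path, hm: HaplotypeMatrix | None = None) -> pd.DataFrame:
    """Read a per-SNP normalized score TSV (contig, position, score).

    When a haplotype matrix is given, rows are inner-joined to its sites and
    the number of unmatched rows is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    need = {"contig", "position", "score"}
    if not need <= set(df.columns):
        raise ValueError("sweep score TSV requires columns contig, position, score")
    if not pd.api.types.is_numeric_dtype(df["score"]):
        raise ValueError("non-numeric sweep score")
    if hm is not None:
        sites = pd.DataFrame(
            {"contig": hm.contigs.astype(str), "position": hm.positions}
        )
        merged = df.merge(sites, on=["contig", "position"], how="inner")
        dropped = len(df) - len(merged)
        if dropped:
            log.warning("read_sweep_scores: dropped %d unmatched positions", dropped)
        df = merged
    return df.reset_index(drop=True)


def write_sweep_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_phylip(matrix: pd.DataFrame, path) -> None:
    """Square PHYLIP distance matrix with 10-character name field."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for name, row in matrix.iterrows():
            fh.write(f"{str(name)[:10]:<10}" + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path) -> pd.DataFrame:
    with open(path) as fh:
        n = int(fh.readline())
        names, rows = [], []
        for _ in range(n):
            line = fh.readline()
            names.append(line[:10].strip())
            rows.append([float(x) for x in line[10:].split()])
    return pd.DataFrame(rows, index=names, columns=names)
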