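# Methods

This note documents the statistical models, conventions and deliberate design
choices behind `krillpop`, in the spirit of a methods supplement: enough
detail to know exactly what each number means and what passing the test suite
does and does not establish.

## Coordinates and data model

Internal coordinates are 0-based half-open everywhere; VCF positions (1-based)
and GFF3 (1-based closed) are converted at the I/O boundary, so a SNP at VCF
POS *p* occupies the internal interval [p−1, p). The core container is a
phased haplotype matrix: rows are haploid chromosomes (sample *i* owns rows
2i and 2i+1), columns are biallelic SNPs. Missing genotypes are disallowed by
default — the intended substrate is imputed and phased data — and a
permissive mode codes them as −1, with allele-count paths tracking per-site
called-chromosome numbers.

## Accessibility

The mask is defined by two filters on the summed per-base depth profile:
depth within a band around the genome-wide modal depth, and mapped-sample
count ≥ ⌈n/2⌉. The mode is located on the depth histogram after a
moving-average smooth (default 5 bins, ties resolved to the smaller depth;
edge windows are normalized by their in-range size so a flat histogram's mode
is depth 0). The band is `round(peak·(1±f))` with f = 0.5 by default. A
published band whose bounds were derived from an unrounded peak (e.g. an
upper bound of 281 where round(188·1.5) = 282) cannot be reconstructed from
the rounded peak, so explicit lower/upper/min-sample overrides are accepted
everywhere; the predicate itself (lower ≤ depth ≤ upper, inclusive, and
n_mapped ≥ min) is what all tests pin down.

## Diversity statistics

Per-site diversity uses the unbiased sample form 2·(k/n)(1−k/n)·n/(n−1),
which equals the mean pairwise Hamming distance among the sampled
chromosomes. Watterson's estimator divides the segregating-site count by
a_{n−1}·L_acc where L_acc counts accessible bases only; windows with
L_acc = 0 are emitted with missing statistics rather than dropped, and
Tajima's D (1989 constants) is missing when S = 0. Region-stratified runs
restrict both the SNPs and the L_acc denominator to bases of the requested
class, so (S, L_acc) totals over the six region classes reproduce the genome
totals exactly.

Region classes follow the 1=intergenic, 2=intron, 3=3′-UTR, 4=exon,
5=5′-UTR, 6=cds coding; where genes overlap, cds > UTR > exon > intron >
intergenic, with the earlier gene (by coordinate) winning equal-priority
ties. Synonymous/non-synonymous site counting uses plain codon degeneracy
(4-fold → 1 synonymous site, 0-fold → 0, 2- and 3-fold split fractionally as
n_syn/3); this is a deliberate simplification adequate for synthetic data —
studies using dedicated counting tools will obtain different absolute N/S
site totals, and no test asserts agreement with them.

The distance-from-gene profile assigns non-overlapping windows to 1 kb bins
of distance to the nearest gene-body edge, excludes windows overlapping any
gene body, and reports percentile-bootstrap CIs (default 200 replicates,
seeded). A window equidistant from an upstream and downstream gene is
attributed to the upstream gene; the distance, hence the bin, is unaffected.

## FST estimators

Two estimators are used in their conventional roles.

**Aggregate scopes (window, exon set, contig, genome): Reynolds (1983).**
Computed on haploid allele counts as the two-population coancestry moment
estimator in ANOVA form: with haploid sizes m₁, m₂, M = m₁+m₂,
MSP = Σ mᵢ(pᵢ−p̄)², MSG = Σ mᵢpᵢ(1−pᵢ)/(M−2) and n_c = M − (m₁²+m₂²)/M,
the per-locus numerator is a_l = (MSP−MSG)/n_c and denominator
a_l + MSG. Because the pipeline operates on phased haplotypes, the
within-individual (heterozygosity) terms of the original genotype-based
formulation do not arise. Multi-locus values are always Σnum/Σden (ratio of
sums), never a mean of ratios; aggregation is therefore exactly associative,
and loci monomorphic across both samples contribute (0, 0). Negative
estimates are reported unclamped except in exported distance matrices, where
they are floored at 0 for network-building consumers.

**Per-SNP: Weir–Cockerham (1984)** with r = 2 diploid samples and observed
heterozygote frequencies taken from the genotypes formed by consecutive
haplotype pairs. θ̂ = a/(a+b+c), undefined (NaN) when the denominator is 0.
For simulated chromosome samples, which have no diploid individuals, the
haploid allele-count form (identical to the per-locus Reynolds ratio) stands
in; the two coincide in expectation.

**A bias worth knowing about:** the *average of per-SNP ratio estimates* is
not unbiased — under panmixia it sits ≈ −0.003 below zero at the 134/14
sample configuration (Jensen's inequality on the per-locus ratio; the diploid
form shows the identical offset). The unbiasedness property belongs to the
ratio-of-sums combination, which is what every genome-wide, contig and
window value in this package is. Calibration tests therefore check the
combined estimate against zero, not the naive mean.

## Closed-form demography

T_years = D·g/(2u); N_e = θ_W/(4μ); T = −ln(1−F_ST)/2; t = T·4N_e;
r = ρ/(4N_e), with cM/Mb = r·10⁸. Generation time defaults to 1 year; the
interspecies dating example uses 1.5 years (the mean of two species' times).
Estimator/inverse pairs compose to identity within 1e−12. One published
internal inconsistency is deliberately not reproduced: for the
east/west-basin contrast, F_ST = 0.0168 implies T = 0.00847 by the formula,
while the source table prints T = 0.00825; the package reports the formula
value.

## Split-coalescent simulator

Time is in 4N₀-generation units (Hudson's ms convention): a deme with k
lineages coalesces at rate k(k−1), all deme-2 lineages join deme 1 at
`t_join`, and there is no migration, growth or recombination. Implied
physics, verified against analytic values and msprime: E[T_MRCA] = 0.5 for
two lineages and E[total length] = a_{n−1} for a single deme of n.

Mutation has two modes. *Fixed S* (the ms `-s` semantics used for FST
spectra): each of m mutations lands on a branch with probability
proportional to branch length, so every SNP is segregating by construction.
Note that this conditioning makes the class-i probability E[L_i/L_total],
which measurably over-weights singletons (≈ +5% at n = 20) relative to the
textbook 1/i law — a property of fixed-S conditioning itself, shared by ms.
*Poisson mode*: S ~ Poisson(θ_locus·L_tree), under which E[S_i] ∝ 1/i is
exact; the synthetic generator and the AFS-law tests use this mode.

Per-SNP FST spectra are binned in ten 0.1-wide bins (closed on the left,
last bin closed on both sides, negative estimates floored into the first
bin). The excess ratio is P_obs(F_ST ≥ thr)/P_sim(F_ST ≥ thr) with the
threshold exposed (default 0.5) and an infinite ratio reported, with counts,
when the simulated tail is empty. Replicate i draws from a substream derived
deterministically from (seed, i), so results are independent of evaluation
order. An optional ms-format text writer allows third-party cross-checks.

The caller supplies `t_join` verbatim (the study passed T/2 to its
simulator); the conversion from Reynolds-scaled T to simulator time units is
left outside this module because that scaling choice is a modelling
judgement, not an algebraic identity.

## Gene scan and haplotype calls

Exon-wide FST is the Reynolds ratio of sums over the SNPs in a gene's exons
(cds + UTRs), excluding SNPs at inaccessible bases. Flanking regions are one
candidate per gene side — `flank_size` (50 kb) placed `gap` (50 kb) from the
gene body — discarded if truncated by a contig edge or overlapping any gene
body, which is why usable flanks number fewer than genes. Tail thresholds
use nearest-rank percentiles (no interpolation dialect ambiguity).

Haplotype calling at divergent genes (exon FST > 0.4): diagnostic SNPs are
exonic SNPs with per-SNP Weir–Cockerham FST > 0.5 (≥4 required), oriented so
allele 1 is the group-2-enriched allele; each chromosome is assigned by
majority vote (exact ties unassigned), class A being group-1-enriched and
class B group-2-enriched. Per-population frequencies of A, B and unassigned
sum to 1. A gene is *shared* iff both classes are observed (≥1 chromosome)
in both contrast groups; otherwise it is private-to-group2 when class B is
confined to group 2 (this takes precedence, and covers the fully fixed
case), else private-to-group1.

The 2×2 enrichment test is Pearson's χ² without continuity correction
(df = 1), via scipy. Sweep-score summaries average |score| in 1 kb windows,
keep windows with ≥50% genic bases, stratify by 0.1-wide window-FST class
and attach 2000-replicate bootstrap CIs.

## Synthetic data generator

The generator emulates the study conditions at desk scale; the genome span is
the one deliberately scaled-down quantity. Defaults: 10 contigs × 150 kb,
500 genes (5′UTR 60 bp + cds 150 + intron 300 + cds 150 + 3′UTR 60, random
strand), eight populations of 10/10/10/10/10/10/7 (group 1, 67 diploids) + 7
(group 2), θ_W = 0.0162/bp, split join time 0.01443, 1,146 bp simulation
loci, depth peak 188× over 74 samples, and 20 planted divergent genes with
haplotype-class frequencies 0.10 (group 1) vs 0.90 (group 2) and ≥8
diagnostic SNPs.

Neutral SNPs: contigs are tiled into loci; each locus draws an independent
split genealogy and Poisson(θ_locus·L_tree) mutations at uniform accessible
positions, so genome-wide θ̂_W recovers the target within Monte-Carlo error.
Planted genes model ancient standing haplotype variation: *all* exonic SNPs
of a planted gene are re-coded to a per-chromosome class indicator (2%
within-class mismatch), with extra diagnostic positions added if the gene
has too few exonic SNPs. This choice — rather than a handful of isolated
diagnostic SNPs — reflects that detectable divergent genes are exon-wide
FST outliers; a few diagnostic SNPs diluted among ~40 neutral exonic SNPs
would not produce exon-wide FST > 0.4 at these frequencies. The truth file
records each planted gene's diagnostic positions, realized class frequencies
and realized exon-wide FST.

Depth tracks are negative-binomial around the peak (dispersion 50), clamped
inside the accessible band, with ≥38 mapped samples; planted inaccessible
intervals (3 × 1.5 kb per contig, intergenic) are forced below both the
depth and the sample-count thresholds. The clamping is deliberate: it makes
mask recovery from depth exact, so the accessibility stage can be tested as
an identity rather than statistically.

What the generator does **not** emulate: linkage within loci (each locus is
one independent genealogy; LD beyond locus scale is absent), migration after
the split, selection dynamics (planted frequencies are set directly, not
evolved), sequencing/genotyping error, repeat-driven mis-mapping, or
realistic gene length/density distributions. Passing the end-to-end tests
therefore demonstrates that the estimators and the scan recover the signals
the models define — not that they are robust to artefacts these synthetic
data do not contain.

## Problem sizes and numerical conventions

Default test-suite problem sizes are chosen so the whole suite runs in about
two minutes on one core: 10⁵ replicates for simulator physics and the
panmixia null, 10⁴ loci per point for split-time recovery, and the full
default synthetic genome (1.5 Mb, ~1.4×10⁵ SNPs) for end-to-end recovery.
Seeds are fixed throughout; identical seeds give byte-identical generator
output. Bootstrap CIs are percentile-method; empirical percentiles are
nearest-rank; FST bins are closed on the left with the last bin closed;
minor/major ties in allele re-orientation (frequency exactly 0.5) keep the
original orientation; sites monomorphic within a re-orientation group pass
through unswapped and flagged.

## Known limitations

- The Reynolds estimator is implemented for two populations (the only use in
  scope); multi-population coancestry is out of scope.
- The per-SNP FST ratio estimator's small negative null bias (above) is a
  property users should expect in per-SNP visualizations.
- Synonymous/non-synonymous classification is degeneracy-based, not
  annotation-based.
- The LD thinner is the greedy leftmost-survivor scan within 500-SNP
  windows; it guarantees pairwise r² ≤ the threshold among retained SNPs
  within a window, not globally.
- Flank candidates are filtered by gene-body overlap only (not repeat or
  accessibility content); their FST already reflects accessibility through
  the SNP mask.
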