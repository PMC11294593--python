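"""Two-deme split coalescent with fixed segregating sites.

Model contract (Hudson's ms semantics): time is measured in units of 4*N0
generations; within a deme holding k lineages the waiting time to the next
coalescence is Exponential(rate = k*(k-1)); there is no migration, growth or
recombination; at ``t_join`` all deme-2 lineages move into deme 1.  With a
fixed number of segregating sites, each mutation is placed on a branch chosen
with probability proportional to branch length (the per-locus theta is
irrelevant under fixed S and retained only for provenance).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SplitSimConfig:
    n1: int
    n2: int = 0
    t_join: float = 0.0
    n_loci: int = 1
    mutations_per_locus: int = 1
    theta_locus: float | None = None  # provenance only under fixed S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 + self.n2 < 2:
            raise ValueError("need >= 2 sampled chromosomes")
        if self.t_join < 0 or self.n_loci < 1:
            raise ValueError("invalid configuration")


@dataclass
class Genealogy:
    """Binary coalescent tree over n1 + n2 leaves.

    Node ids: leaves 0..n-1 (deme 1 first), internal nodes in coalescence
    order, root = 2n - 2.  ``blen[i]`` is the branch above node i (root
    excluded); ``d1``/``d2`` count descendant leaves per deme.
    """

    n1: int
    n2: int
    blen: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    tmrca: float
    children: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(self.blen.sum())


def _locus_rng(seed: int, index: int) -> random.Random:
    # per-replicate substream: reproducible regardless of evaluation order
    return random.Random((seed & 0x7FFFFFFF) * 2_654_435_761 + index)


def simulate_genealogy(n1: int, n2: int, t_join: float, rng: random.Random) -> Genealogy:
    """One genealogy under the split model (pure coalescent, no mutations)."""
    n = n1 + n2
    n_nodes = 2 * n - 1
    birth = [0.0] * n_nodes
    blen = np.zeros(n_nodes - 1)
    d1 = np.zeros(n_nodes, dtype=np.int32)
    d2 = np.zeros(n_nodes, dtype=np.int32)
    d1[:n1] = 1
    d2[n1:n] = 1
    children: list[tuple[int, int]] = []
    pool1 = list(range(n1))
    pool2 = list(range(n1, n))
    nxt = n
    t = 0.0
    expo = rng.expovariate
    rnd = rng.random

    def coalesce(pool: list[int], time: float) -> None:
        nonlocal nxt
        i = int(rnd() * len(pool))
        c1 = pool.pop(i)
        j = int(rnd() * len(pool))
        c2 = pool.pop(j)
        birth[nxt] = time
        blen[c1] = time - birth[c1]
        blen[c2] = time - birth[c2]
        d1[nxt] = d1[c1] + d1[c2]
        d2[nxt] = d2[c1] + d2[c2]
        children.append((c1, c2))
        pool.append(nxt)
        nxt += 1

    # phase 1: two isolated demes until t_join
    if t_join > 0 and n2 > 0:
        while True:
            k1, k2 = len(pool1), len(pool2)
            r1 = k1 * (k1 - 1)
            r2 = k2 * (k2 - 1)
            rate = r1 + r2
            if rate == 0:
                break
            dt = expo(rate)
            if t + dt >= t_join:
                break
            t += dt
            coalesce(pool1 if rnd() * rate < r1 else pool2, t)
        t = t_join
    # phase 2: merged ancestral population
    pool = pool1 + pool2
    while len(pool) > 1:
        k = len(pool)
        t += expo(k * (k - 1))
        coalesce(pool, t)
    return Genealogy(n1, n2, blen, d1, d2, tmrca=t, children=children)


def drop_mutations(tree: Genealogy, m: int, rng: random.Random) -> np.ndarray:
    """Place ``m`` mutations on branches chosen proportionally to length.

    Returns an (m, 2) array of derived-allele counts per deme.  Each derived
    set is the leaf set below the mutated branch, so 1 <= total < n always.
    """
    total = tree.total_length
    if total <= 0:
        raise ValueError("tree with non-positive total length")
    cum = np.cumsum(tree.blen)
    out = np.empty((m, 2), dtype=np.int64)
    for i in range(m):
        b = int(np.searchsorted(cum, rng.random() * total, side="right"))
        out[i, 0] = tree.d1[b]
        out[i, 1] = tree.d2[b]
    return out


def leaf_sets(tree: Genealogy) -> np.ndarray:
    """Boolean (n_branches, n_leaves) matrix of descendant leaves per branch."""
    n = tree.n1 + tree.n2
    n_nodes = 2 * n - 1
    below = np.zeros((n_nodes, n), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for parent_off, (c1, c2) in enumerate(tree.children):
        below[n + parent_off] = below[c1] | below[c2]
    return below[:-1]  # root carries no branch


# ---------------------------------------------------------------------------
# FST spectra
# ---------------------------------------------------------------------------

FST_BIN_EDGES = np.round(np.arange(0.0, 1.01, 0.1), 10)


def simulate_snp_counts(config: SplitSimConfig) -> np.ndarray:
    """Derived-allele counts per deme for every simulated SNP.

    Returns an (n_loci * mutations_per_locus, 2) array.  Each locus uses an
    independent substream derived from (seed, locus index).
    """
    rows = []
    for i in range(config.n_loci):
        rng = _locus_rng(config.seed, i)
        tree = simulate_genealogy(config.n1, config.n2, config.t_join, rng)
        rows.append(drop_mutations(tree, config.mutations_per_locus, rng))
    return np.concatenate(rows, axis=0)


def simulate_poisson_counts(
    n1: int, n2: int, t_join: float, theta_locus: float, n_loci: int, seed: int
) -> np.ndarray:
    """Derived-count pairs under Poisson mutation (infinite sites).

    Each locus draws Poisson(theta_locus * L_tree) mutations placed
    proportionally to branch length.  Unlike fixed-S conditioning, the
    expected unfolded class-i count here is exactly proportional to 1/i under
    neutrality, because E[S_i] = theta * E[L_i].
    """
    rows = []
    prng = np.random.default_rng([seed & 0x7FFFFFFF, 77])
    for i in range(n_loci):
        rng = _locus_rng(seed, i)
        tree = simulate_genealogy(n1, n2, t_join, rng)
        S = int(prng.poisson(theta_locus * tree.total_length))
        if S == 0:
            continue
        rows.append(drop_mutations(tree, S, rng))
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(rows, axis=0)


def fst_spectrum_from_counts(counts: np.ndarray, n1: int, n2: int):
    """Per-SNP theta-hat (haploid Weir-Cockerham moment form) and normalized
    proportions in 0.1-wide bins.

    Bins are closed on the left; the last bin [0.9, 1.0] is closed on both
    sides; negative estimates floor into the first bin.
    """
    from .divergence import wc_fst_haploid

    fst = wc_fst_haploid(counts[:, 0], n1, counts[:, 1], n2)
    fst = fst[~np.isnan(fst)]
    clipped = np.clip(fst, 0.0, 1.0)
    which = np.minimum((clipped / 0.1).astype(int), 9)
    bins = np.bincount(which, minlength=10).astype(float)
    return fst, bins / bins.sum()


def simulate_fst_spectrum(config: SplitSimConfig):
    """Simulate the neutral per-SNP FST spectrum under the split model."""
    counts = simulate_snp_counts(config)
    return fst_spectrum_from_counts(counts, config.n1, config.n2)


def excess_ratio(observed: np.ndarray, simulated: np.ndarray, threshold: float = 0.5):
    """Ratio of upper-tail proportions P_obs(FST >= thr) / P_sim(FST >= thr).

    Both spectra must be on the standard 0.1-wide bins.  Returns
    ``(ratio, obs_tail, sim_tail)``; the ratio is ``inf`` when the simulated
    tail is empty but the observed one is not.
    """
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.shape != simulated.shape or len(observed) != 10:
        raise ValueError("spectra must share the standard 10-bin layout")
    first = int(np.searchsorted(FST_BIN_EDGES[:-1], threshold, side="left"))
    obs_tail = float(observed[first:].sum())
    sim_tail = float(simulated[first:].sum())
    if sim_tail == 0.0:
        ratio = float("inf") if obs_tail > 0 else float("nan")
    else:
        ratio = obs_tail / sim_tail
    return ratio, obs_tail, sim_tail


# ---------------------------------------------------------------------------
# Optional ms-format output for third-party cross-checks
# ---------------------------------------------------------------------------


def write_ms(counts: np.ndarray, n1: int, n2: int, path, command: str = "") -> None:
    """Write fixed-S=1 loci in Hudson ms text format (one SNP per locus).

    Derived alleles are assigned to the lowest-index chromosomes of each deme;
    the within-deme ordering of an exchangeable sample carries no information.
    """
    with open(path, "w") as fh:
        fh.write((command or f"ms {n1 + n2} {len(counts)} -s 1") + "\n0 0 0\n")
        for c1, c2 in counts:
            fh.write("\n//\nsegsites: 1\npositions: 0.5000\n")
            for i in range(n1):
                fh.write("1\n" if i < c1 else "0\n")
            for i in range(n2):
                fh.write("1\n" if i < c2 else "0\n")
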