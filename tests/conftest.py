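import numpy as np
import pytest

from krillpop import divergence, popio, synth


@pytest.fixture(scope="session")
def worked_example():
    """The tiny hand-computed dataset, parsed through the package readers."""
    p = synth.worked_example_paths()
    panel = popio.read_panel(p["panel"])
    hm = popio.read_vcf(p["vcf"], panel)
    return {
        "paths": p,
        "panel": panel,
        "hm": hm,
        "mask": popio.read_mask_bed(p["mask"]),
        "genes": popio.read_gff3(p["gff"]),
        "expected": synth.worked_example_expected(),
        "contig_lengths": {"chr1": 100},
        "contrast": divergence.ContrastSpec.from_populations(
            panel, "pops", ["pop1"], ["pop2"]
        ),
    }


@pytest.fixture(scope="session")
def small_synth(tmp_path_factory):
    """A small but complete synthetic dataset shared across unit tests."""
    cfg = synth.SyntheticConfig(
        n_contigs=2, contig_length=60_000, n_genes=40, n_planted=3, seed=11
    )
    res = synth.generate(cfg, tmp_path_factory.mktemp("synth_small"))
    panel = popio.read_panel(res["paths"]["panel"], res["paths"]["distances"])
    res["read_panel"] = panel
    res["read_hm"] = popio.read_vcf(res["paths"]["vcf"], panel)
    res["read_mask"] = popio.read_mask_bed(res["paths"]["mask"])
    res["read_genes"] = popio.read_gff3(res["paths"]["gff"])
    res["config"] = cfg
    res["contrast"] = divergence.ContrastSpec.from_populations(
        panel, "atme", list(cfg.group1_pops), list(cfg.group2_pops)
    )
    return res


@pytest.fixture(scope="session")
def default_synth(tmp_path_factory):
    """The full default-scale synthetic dataset (500 genes, 20 planted)."""
    cfg = synth.SyntheticConfig(seed=7)
    res = synth.generate(cfg, tmp_path_factory.mktemp("synth_default"))
    panel = popio.read_panel(res["paths"]["panel"], res["paths"]["distances"])
    res["read_panel"] = panel
    res["read_hm"] = popio.read_vcf(res["paths"]["vcf"], panel)
    res["read_mask"] = popio.read_mask_bed(res["paths"]["mask"])
    res["read_genes"] = popio.read_gff3(res["paths"]["gff"])
    res["config"] = cfg
    res["contrast"] = divergence.ContrastSpec.from_populations(
        panel, "atme", list(cfg.group1_pops), list(cfg.group2_pops)
    )
    return res


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_haplotype_matrix(rng, n_samples=6, n_sites=30, contig="c1"):
    """Uniform random phased matrix for round-trip and invariance tests."""
    calls = rng.integers(0, 2, size=(2 * n_samples, n_sites)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10 * n_sites), size=n_sites, replace=False))
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = np.array(
        [("ACGT".replace(r, ""))[rng.integers(0, 3)] for r in ref], dtype=object
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return popio.HaplotypeMatrix(
        np.full(n_sites, contig, dtype=object), pos, ref, alt, calls, samples
    )
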