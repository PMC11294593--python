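"""Stage orchestration: each stage reads files, runs one library layer and
writes TSV/BED/VCF/JSON outputs plus a manifest tying results to inputs,
parameters and seeds."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, accessibility, coalsim, demography, divergence, genescan
from . import popio, synth, variation


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stage: str, inputs: dict, params: dict) -> Path:
    outdir = Path(outdir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "params": params,
    }
    path = outdir / f"{stage}.manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require(paths: dict, *keys):
    for k in keys:
        if k not in paths or not Path(paths[k]).exists():
            raise FileNotFoundError(f"stage requires input '{k}' ({paths.get(k)})")


def _load_common(paths):
    panel = popio.read_panel(paths["panel"], paths.get("distances"))
    hm = popio.read_vcf(paths["vcf"], panel)
    truth = json.loads(Path(paths["truth"]).read_text()) if "truth" in paths else None
    if truth:
        contig_lengths = {k: int(v) for k, v in truth["contig_lengths"].items()}
    else:
        contig_lengths = {
            c: int(hm.positions[hm.contigs == c].max()) for c in dict.fromkeys(hm.contigs.tolist())
        }
    mask = popio.read_mask_bed(paths["mask"], contig_lengths)
    return panel, hm, mask, contig_lengths


def stage_synth(outdir, seed: int = 0, **overrides) -> dict:
    cfg = synth.SyntheticConfig(seed=seed, **overrides)
    res = synth.generate(cfg, outdir)
    write_manifest(outdir, "synth", {}, {"seed": seed, **overrides})
    return res


def stage_mask(depth_path, n_samples: int, outdir, smooth_window: int = 5,
               lower=None, upper=None, min_samples=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = accessibility.read_depth_tsv(depth_path, n_samples)
    hist = accessibility.depth_histogram(profile)
    peak = accessibility.detect_peak(hist, smooth_window)
    thr = accessibility.thresholds_from_peak(
        peak, n_samples=n_samples, lower=lower, upper=upper, min_samples=min_samples
    )
    mask = accessibility.build_mask(profile, thr)
    popio.write_mask_bed(mask, outdir / "accessible.bed")
    params = {"peak": peak, "lower": thr.lower, "upper": thr.upper,
              "min_samples": thr.min_samples}
    write_manifest(outdir, "mask", {"depth": depth_path}, params)
    return {"mask": mask, "thresholds": thr, "peak": peak}


def stage_diversity(paths: dict, outdir, window: int = 1000) -> pd.DataFrame:
    _require(paths, "vcf", "panel", "mask")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, hm, mask, contig_lengths = _load_common(paths)
    stats = variation.window_diversity(hm, mask, contig_lengths, window)
    stats.to_csv(outdir / f"diversity.w{window}.tsv", sep="\t", index=False)
    afs = variation.folded_afs(hm)
    pd.DataFrame({"minor_count": np.arange(1, len(afs) + 1), "n_snps": afs}).to_csv(
        outdir / "folded_afs.tsv", sep="\t", index=False
    )
    write_manifest(outdir, "diversity",
                   {k: paths[k] for k in ("vcf", "panel", "mask")},
                   {"window": window})
    return stats


def _contrast_from_config(panel, contrast_cfg) -> divergence.ContrastSpec:
    return divergence.ContrastSpec.from_populations(
        panel, contrast_cfg["name"], contrast_cfg["group1"], contrast_cfg["group2"]
    )


def stage_divergence(paths: dict, contrast_cfg: dict, outdir, window: int = 1000,
                     seed: int = 0) -> dict:
    _require(paths, "vcf", "panel", "mask")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, hm, mask, contig_lengths = _load_common(paths)
    contrast = _contrast_from_config(panel, contrast_cfg)
    wfst = divergence.window_fst(hm, contrast, contig_lengths, window, mask)
    wfst.to_csv(outdir / f"fst.{contrast.name}.w{window}.tsv", sep="\t", index=False)
    gfst = divergence.genome_fst(hm, contrast, mask)
    snp_fst = divergence.per_snp_wc_fst(hm, contrast)
    pd.DataFrame(
        {"contig": hm.contigs, "position": hm.positions, "wc_fst": snp_fst}
    ).to_csv(outdir / f"fst.{contrast.name}.snp.tsv", sep="\t", index=False)
    fst_m, dxy_m = divergence.pairwise_matrices(hm, panel, mask, contig_lengths)
    divergence.export_distance_matrix(fst_m, outdir / "fst.pops.phylip")
    divergence.export_distance_matrix(dxy_m, outdir / "dxy.pops.phylip")
    result = {"genome_fst": gfst, "window_fst": wfst, "fst_matrix": fst_m,
              "dxy_matrix": dxy_m}
    if panel.distances is not None:
        slope, intercept, r2, p = divergence.ibd_regression(fst_m, panel.distances)
        result["ibd"] = {"slope": slope, "intercept": intercept, "r2": r2, "p": p}
    (outdir / f"fst.{contrast.name}.genome.json").write_text(
        json.dumps({"genome_fst": gfst, "ibd": result.get("ibd")}, indent=1)
    )
    write_manifest(outdir, "divergence",
                   {k: paths[k] for k in ("vcf", "panel", "mask")},
                   {"window": window, "contrast": contrast_cfg, "seed": seed})
    return result


def stage_demography(outdir, **scalars) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = demography.SplitModelParams(**scalars)
    out = demography.report(params)
    pd.DataFrame(sorted(out.items()), columns=["quantity", "value"]).to_csv(
        outdir / "demography.tsv", sep="\t", index=False
    )
    write_manifest(outdir, "demography", {}, scalars)
    return out


def stage_neutral_sim(outdir, n1: int, n2: int, t_join: float, n_loci: int,
                      seed: int = 0) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = coalsim.SplitSimConfig(n1=n1, n2=n2, t_join=t_join, n_loci=n_loci, seed=seed)
    fst, bins = coalsim.simulate_fst_spectrum(cfg)
    pd.DataFrame(
        {
            "fst_lo": coalsim.FST_BIN_EDGES[:-1],
            "fst_hi": coalsim.FST_BIN_EDGES[1:],
            "proportion": bins,
        }
    ).to_csv(outdir / "sim_fst_spectrum.tsv", sep="\t", index=False)
    write_manifest(outdir, "neutral_sim", {},
                   {"n1": n1, "n2": n2, "t_join": t_join, "n_loci": n_loci, "seed": seed})
    return {"fst": fst, "bins": bins, "mean_fst": float(np.mean(fst))}


def stage_scan(paths: dict, contrast_cfg: dict, outdir,
               flank_size: int = 50_000, gap: int = 50_000,
               levels=(0.01, 0.001)) -> dict:
    _require(paths, "vcf", "panel", "mask", "gff")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, hm, mask, contig_lengths = _load_common(paths)
    genes = popio.read_gff3(paths["gff"])
    contrast = _contrast_from_config(panel, contrast_cfg)
    records = genescan.exon_fst(hm, genes, contrast, mask)
    flanks = genescan.make_flanks(genes, contig_lengths, flank_size, gap)
    result = {"gene_records": records, "flanks": flanks}
    if len(flanks):
        ffst = genescan.flank_fst(hm, flanks, contrast, mask)
        usable_levels = [lv for lv in levels if len(ffst) * lv >= 1]
        if usable_levels:
            thr = genescan.flank_percentiles(ffst["fst"].dropna(), usable_levels)
            enr = genescan.gene_flank_enrichment(
                records["exon_fst"], ffst["fst"], thr
            )
            enr.to_csv(outdir / f"scan.{contrast.name}.enrichment.tsv", sep="\t", index=False)
            (outdir / f"scan.{contrast.name}.thresholds.json").write_text(
                json.dumps({str(k): v for k, v in thr.items()}, indent=1)
            )
            result.update({"flank_fst": ffst, "thresholds": thr, "enrichment": enr})
    records.to_csv(outdir / f"scan.{contrast.name}.genes.tsv", sep="\t", index=False)
    write_manifest(outdir, "scan",
                   {k: paths[k] for k in ("vcf", "panel", "mask", "gff")},
                   {"contrast": contrast_cfg, "flank_size": flank_size, "gap": gap})
    return result


def stage_report(stage_dir, contrast_name: str, outdir) -> pd.DataFrame:
    """Join the scan and haplotype outputs into one per-gene summary table.

    Expects the TSVs written by the ``scan`` and ``haplotypes`` stages in
    ``stage_dir``; a missing file is fatal with a hint about stage order.
    """
    stage_dir = Path(stage_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_path = stage_dir / f"scan.{contrast_name}.genes.tsv"
    hap_path = stage_dir / f"haplotypes.{contrast_name}.tsv"
    for p, stage in ((genes_path, "scan"), (hap_path, "haplotypes")):
        if not p.exists():
            raise FileNotFoundError(
                f"{p} not found: run the '{stage}' stage into {stage_dir} first"
            )
    genes = pd.read_csv(genes_path, sep="\t")
    haps = pd.read_csv(hap_path, sep="\t")
    summary = genes.merge(haps, on="gene_id", how="left")
    summary["percentile"] = genes["exon_fst"].rank(pct=True)
    summary = summary.sort_values("exon_fst", ascending=False)
    summary.to_csv(outdir / f"report.{contrast_name}.tsv", sep="\t", index=False)
    write_manifest(outdir, "report",
                   {"genes": genes_path, "haplotypes": hap_path},
                   {"contrast": contrast_name})
    return summary


def stage_haplotypes(paths: dict, contrast_cfg: dict, outdir,
                     min_diag: int = 4, diag_fst: float = 0.5,
                     divergent_fst: float = 0.4) -> pd.DataFrame:
    _require(paths, "vcf", "panel", "mask", "gff")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, hm, mask, contig_lengths = _load_common(paths)
    genes = popio.read_gff3(paths["gff"])
    contrast = _contrast_from_config(panel, contrast_cfg)
    records = genescan.exon_fst(hm, genes, contrast, mask)
    calls = genescan.call_haplotypes(
        hm, records, genes, contrast, panel,
        min_diag=min_diag, diag_fst=diag_fst, divergent_fst=divergent_fst, mask=mask,
    )
    summary = genescan.haplotype_summary(calls)
    freq_rows = []
    for c in calls:
        for pop, row in c.population_freqs.iterrows():
            freq_rows.append({"gene_id": c.gene_id, "population": pop, **row.to_dict()})
    summary.to_csv(outdir / f"haplotypes.{contrast_cfg['name']}.tsv", sep="\t", index=False)
    pd.DataFrame(freq_rows).to_csv(
        outdir / f"haplotypes.{contrast_cfg['name']}.popfreq.tsv", sep="\t", index=False
    )
    write_manifest(outdir, "haplotypes",
                   {k: paths[k] for k in ("vcf", "panel", "mask", "gff")},
                   {"contrast": contrast_cfg, "min_diag": min_diag,
                    "diag_fst": diag_fst, "divergent_fst": divergent_fst})
    return summary
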