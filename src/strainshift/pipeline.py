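"""Stage orchestration: wire the simulator and the analysis modules together
over files on disk, with a single seed fanned out to per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community as comm
from . import gene_content as gc
from . import quantification as quant
from . import snv as snvmod
from . import stats as st
from . import synthetic as syn
from .io_filters import (
    read_allele_observations,
    read_allele_observations_tsv,
    read_sample_metadata,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "load_config"]

_STAGES = ("simulate", "quantify", "community", "snv", "genecontent", "stats")


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the published thresholds."""

    outdir: str = "strainshift_out"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False, or to override)
    samples_path: str | None = None
    gene_coverage_path: str | None = None
    allele_observations_path: str | None = None  # TSV
    allele_vcf_path: str | None = None
    core_bed_path: str | None = None
    og_coverage_path: str | None = None
    qpcr_path: str | None = None
    annotations_path: str | None = None  # og_id -> cog_category
    # published default thresholds
    min_matches: int = 51
    max_mismatches: int = 5
    min_gene_cov: float = 10.0
    min_ter_cov: float = 20.0
    allele_min_reads: int = 2
    allele_min_freq: float = 0.01
    contig_min_len: int = 500
    contig_min_kcov: float = 1.0
    orf_min_len: int = 300
    blast_max_evalue: float = 1e-5
    blast_min_pident: float = 50.0
    blast_min_qcovs: float = 50.0
    norm_constant: float = 10000.0
    sig_q: float = 0.05
    min_abs_log2fc: float = 1.0
    n_perm: int = 999
    n_orders: int = 10
    # simulator overrides (passed to default_scenario)
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = [
            "min_matches", "max_mismatches", "min_gene_cov", "min_ter_cov",
            "allele_min_reads", "allele_min_freq", "contig_min_len",
            "contig_min_kcov", "orf_min_len", "blast_max_evalue",
            "blast_min_pident", "blast_min_qcovs", "norm_constant", "sig_q",
            "min_abs_log2fc", "n_perm", "n_orders",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def load_config(path, **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        stage: np.random.default_rng(child)
        for stage, child in zip(_STAGES, children)
    }


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no input configured for {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"missing input file for {what}: {p}")
    return p


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    scenario = syn.default_scenario(seed=cfg.seed, **cfg.scenario)
    bundle = syn.simulate_all(scenario)
    paths = syn.write_all(bundle, outdir / "sim")
    return paths


def stage_quantify(cfg: PipelineConfig, outdir: Path,
                   inputs: dict) -> dict[str, Path]:
    qpcr = quant.read_qpcr_csv(_require(inputs.get("qpcr"), "qPCR CSV"))
    samples = read_sample_metadata(
        _require(inputs.get("samples"), "sample metadata")
    )
    yields = {s.sample_id: s.dna_yield for s in samples}
    loads = [
        quant.bacterial_load(m.copies(), yields[m.sample_id], m.sample_id)
        for m in qpcr
        if m.target == "16S" and m.sample_id in yields
    ]
    loads_path = outdir / "bacterial_loads.tsv"
    quant.loads_to_frame(loads).to_csv(loads_path, sep="\t", index=False)
    table, mean_ratio, p = quant.compare_paired_loads(loads, samples)
    cmp_path = outdir / "load_comparison.tsv"
    table.to_csv(cmp_path, sep="\t", index=False)
    (outdir / "load_comparison_summary.json").write_text(
        json.dumps({"mean_nurse_over_forager_ratio": mean_ratio, "p": p})
    )
    return {"loads": loads_path, "load_comparison": cmp_path}


def stage_community(cfg: PipelineConfig, outdir: Path,
                    inputs: dict) -> dict[str, Path]:
    gene_cov = pd.read_csv(
        _require(inputs.get("gene_coverage"), "gene coverage table"), sep="\t"
    )
    samples = read_sample_metadata(
        _require(inputs.get("samples"), "sample metadata")
    )
    fits = comm.fit_all_termini(gene_cov)
    fits_path = outdir / "terminus_fits.tsv"
    comm.terminus_fits_to_frame(fits).to_csv(fits_path, sep="\t", index=False)
    rel = comm.relative_abundance_matrix(fits)
    rel_path = outdir / "relative_abundance.tsv"
    rel.to_csv(rel_path, sep="\t")
    out = {"terminus_fits": fits_path, "relative_abundance": rel_path}
    loads_path = inputs.get("loads")
    if loads_path and Path(loads_path).exists():
        loads_df = pd.read_csv(loads_path, sep="\t")
        loads = pd.Series(
            loads_df["copies_per_ng"].to_numpy(),
            index=loads_df["sample_id"].astype(str),
        )
        absolute = comm.absolute_abundance(rel, loads)
        abs_path = outdir / "absolute_abundance.tsv"
        absolute.to_csv(abs_path, sep="\t")
        lfc = comm.paired_log2fc(absolute, samples, alpha=cfg.sig_q)
        lfc_path = outdir / "paired_log2fc.tsv"
        lfc.to_csv(lfc_path, sep="\t", index=False)
        out.update({"absolute_abundance": abs_path, "paired_log2fc": lfc_path})
    return out


def _core_gene_intervals(core_bed: Path) -> pd.DataFrame:
    rows = []
    with open(core_bed) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append(
                {
                    "species_id": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "gene_id": f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                }
            )
    return pd.DataFrame(rows)


def stage_snv(cfg: PipelineConfig, outdir: Path, inputs: dict,
              rng: np.random.Generator) -> dict[str, Path]:
    obs_tsv = inputs.get("allele_observations")
    if obs_tsv and Path(obs_tsv).exists():
        obs = read_allele_observations_tsv(obs_tsv)
    else:
        vcf = _require(inputs.get("allele_vcf"), "allele VCF")
        regions = None
        bed = inputs.get("core_bed")
        if bed and Path(bed).exists():
            from .io_filters import read_core_regions

            regions = read_core_regions(bed)
        obs = read_allele_observations(vcf, regions)

    gene_cov = pd.read_csv(
        _require(inputs.get("gene_coverage"), "gene coverage table"), sep="\t"
    )
    fits = comm.fit_all_termini(gene_cov)
    ter = {(f.species_id, f.sample_id): f.ter_coverage for f in fits}

    bed = inputs.get("core_bed")
    intervals = (
        _core_gene_intervals(Path(bed))
        if bed and Path(bed).exists()
        else None
    )

    detected = snvmod.detect_alleles(
        obs, min_reads=cfg.allele_min_reads, min_freq=cfg.allele_min_freq
    )
    summaries = []
    dist_paths = {}
    curves = []
    for species in sorted(obs["species_id"].unique()):
        keys = [k for k in detected if k[0] == species]
        analyzed = [
            k for k in keys
            if snvmod.species_passes_coverage(
                ter.get(k, 0.0), cfg.min_ter_cov
            )
        ]
        if not analyzed:
            log.info("species %s below %.0fx terminus coverage in all "
                     "samples; skipped", species, cfg.min_ter_cov)
            continue

        # per-sample site masks / filtered core length from gene coverage
        masks: dict[str, set[int]] = {}
        core_lens: dict[str, int] = {}
        if intervals is not None:
            sp_iv = intervals[intervals["species_id"] == species]
            cov = gene_cov[
                (gene_cov["species_id"] == species)
                & gene_cov["is_core"].astype(bool)
            ]
            sites = sorted(obs.loc[obs["species_id"] == species, "site"]
                           .unique())
            for _, sample in analyzed:
                sample_cov = cov[cov["sample_id"] == sample].set_index(
                    "gene_id"
                )["coverage"]
                ok = sp_iv[
                    sp_iv["gene_id"].map(
                        lambda g: sample_cov.get(g, 0.0) >= cfg.min_gene_cov
                    )
                ]
                core_lens[sample] = int((ok["end"] - ok["start"]).sum())
                iv = list(zip(ok["start"], ok["end"]))
                masks[sample] = {
                    s for s in sites
                    if any(a <= s < b for a, b in iv)
                }
        else:
            total = int(
                obs.loc[obs["species_id"] == species, "site"].nunique()
            )
            for _, sample in analyzed:
                core_lens[sample] = max(total, 1)

        site_sets = []
        for key in analyzed:
            sample = key[1]
            mask = masks.get(sample)
            poly = snvmod.polymorphic_sites(detected[key], mask)
            site_sets.append(poly)
            if core_lens.get(sample, 0) > 0:
                summaries.append(
                    snvmod.fraction_polymorphic(
                        poly, core_lens[sample], species, sample
                    )
                )
        common_len = min(core_lens.values()) if core_lens else 0
        if common_len > 0 and site_sets:
            curves_df = snvmod.cumulative_polymorphic_curve(
                site_sets, common_len, n_orders=cfg.n_orders, rng=rng
            )
            curves_df.insert(0, "species_id", species)
            curves.append(curves_df)
        if len(analyzed) >= 3:
            dm = snvmod.snv_distance_matrix(
                {k[1]: detected[k] for k in analyzed},
                masks if masks else None,
            )
            path = outdir / f"snv_distance.{species}.tsv"
            dm.to_tsv(path)
            dist_paths[species] = path

    out = {}
    summ_path = outdir / "polymorphism_summary.tsv"
    snvmod.summaries_to_frame(summaries).to_csv(summ_path, sep="\t",
                                                index=False)
    out["polymorphism_summary"] = summ_path
    if curves:
        curve_path = outdir / "cumulative_curves.tsv"
        pd.concat(curves, ignore_index=True).to_csv(curve_path, sep="\t",
                                                    index=False)
        out["cumulative_curves"] = curve_path
    out.update({f"distance_{sp}": p for sp, p in dist_paths.items()})
    return out


def stage_genecontent(cfg: PipelineConfig, outdir: Path,
                      inputs: dict) -> dict[str, Path]:
    og_cov = pd.read_csv(
        _require(inputs.get("og_coverage"), "OG coverage table"), sep="\t"
    )
    samples = read_sample_metadata(
        _require(inputs.get("samples"), "sample metadata")
    )
    normalized = gc.normalize_og_coverage(og_cov, constant=cfg.norm_constant)
    norm_path = outdir / "og_coverage_normalized.tsv"
    normalized.to_csv(norm_path, sep="\t", index=False)
    annotations = None
    ann_path = inputs.get("annotations")
    if ann_path and Path(ann_path).exists():
        annotations = pd.read_csv(ann_path, sep="\t")
    results = gc.differential_ogs(
        normalized,
        samples,
        sig_q=cfg.sig_q,
        min_abs_log2fc=cfg.min_abs_log2fc,
        annotations=annotations,
    )
    diff_path = outdir / "differential_ogs.tsv"
    gc.differential_results_to_frame(results).to_csv(diff_path, sep="\t",
                                                     index=False)
    out = {"og_coverage_normalized": norm_path, "differential_ogs": diff_path}
    if annotations is not None and len(results):
        enr = gc.cog_enrichment(results, annotations)
        enr_path = outdir / "cog_enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        out["cog_enrichment"] = enr_path
    return out


def stage_stats(cfg: PipelineConfig, outdir: Path, inputs: dict,
                rng: np.random.Generator) -> dict[str, Path]:
    rel_path = _require(inputs.get("relative_abundance"),
                        "relative abundance matrix")
    rel = pd.read_csv(rel_path, sep="\t", index_col=0)
    samples = read_sample_metadata(
        _require(inputs.get("samples"), "sample metadata")
    )
    meta = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "Host": s.state,
             "Location": s.location_id}
            for s in samples
        ]
    )
    dm = st.bray_curtis(rel)
    dm_path = outdir / "bray_curtis.tsv"
    dm.to_tsv(dm_path)
    res = st.permanova_marginal(dm, meta, n_perm=cfg.n_perm, rng=rng)
    perm_path = outdir / "permanova.tsv"
    res.table.to_csv(perm_path, sep="\t")
    pc = st.pcoa(dm)
    pcoa_path = outdir / "pcoa_coordinates.tsv"
    pc.coordinates.to_csv(pcoa_path, sep="\t", index_label="sample_id")
    return {"bray_curtis": dm_path, "permanova": perm_path,
            "pcoa": pcoa_path}


def run(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _child_rngs(cfg.seed)

    inputs = {
        "samples": cfg.samples_path,
        "gene_coverage": cfg.gene_coverage_path,
        "allele_observations": cfg.allele_observations_path,
        "allele_vcf": cfg.allele_vcf_path,
        "core_bed": cfg.core_bed_path,
        "og_coverage": cfg.og_coverage_path,
        "qpcr": cfg.qpcr_path,
        "annotations": cfg.annotations_path,
    }
    produced: dict[str, str] = {}

    if cfg.simulate:
        sim_paths = stage_simulate(cfg, outdir)
        inputs.update(
            {
                "samples": sim_paths["samples"],
                "gene_coverage": sim_paths["gene_coverage"],
                "allele_observations": sim_paths["allele_observations"],
                "allele_vcf": sim_paths["allele_vcf"],
                "core_bed": sim_paths["core_bed"],
                "og_coverage": sim_paths["og_coverage"],
                "qpcr": sim_paths["qpcr"],
            }
        )
        produced.update({f"sim_{k}": str(v) for k, v in sim_paths.items()})

    for name, stage_paths in (
        ("quantify", stage_quantify(cfg, outdir, inputs)),
    ):
        produced.update({k: str(v) for k, v in stage_paths.items()})
        inputs["loads"] = stage_paths["loads"]

    for k, v in stage_community(cfg, outdir, inputs).items():
        produced[k] = str(v)
        inputs[k] = v
    for k, v in stage_snv(cfg, outdir, inputs, rngs["snv"]).items():
        produced[k] = str(v)
    for k, v in stage_genecontent(cfg, outdir, inputs).items():
        produced[k] = str(v)
    for k, v in stage_stats(cfg, outdir, inputs, rngs["stats"]).items():
        produced[k] = str(v)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("outdir",)
        },
        "outputs": {
            k: str(Path(v).relative_to(outdir)) for k, v in produced.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return manifest
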