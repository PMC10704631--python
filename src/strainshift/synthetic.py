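"""Ground-truth simulator for the full pipeline.

Emulates the study design the pipeline targets: a paired two-state
(nurse/forager) sampling scheme over colonies nested in locations,
per-species abundance shifts between states, V-shaped origin-to-terminus
coverage gradients, pooled allele-count pileups arising from state-biased
strain mixtures plus uniform sequencing error, strain-specific accessory
gene content with planted differential OGs, and qPCR Cts generated from the
true 16S copy loads.

Everything is driven by a single :class:`CommunityScenario`; identical
scenario + seed reproduces every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import GENE_COVERAGE_COLUMNS
from .gene_content import OG_COVERAGE_COLUMNS
from .io_filters import ALLELE_OBS_COLUMNS, SampleRecord

__all__ = [
    "SpeciesConfig",
    "StrainModel",
    "SpeciesModel",
    "PlantedOg",
    "CommunityScenario",
    "generate_species_model",
    "simulate_community",
    "simulate_gene_coverage",
    "simulate_allele_observations",
    "simulate_og_coverage",
    "simulate_qpcr",
    "simulate_all",
    "write_all",
    "write_allele_vcf",
    "default_scenario",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species generative settings."""

    species_id: str
    baseline_abundance: float = 1.0
    state_multiplier: float = 1.0  # forager relative to nurse
    genome_length: int = 500_000
    n_genes: int = 40
    n_core_genes: int = 24
    n_variant_sites: int = 150
    n_strains: int = 4
    strain_divergence: float = 0.5  # per-site prob a strain carries an alt
    n_accessory_ogs_per_strain: int = 5

    def __post_init__(self) -> None:
        if self.n_core_genes < 1:
            raise ValueError(
                f"{self.species_id}: at least one single-copy core gene "
                "is required"
            )
        if self.n_genes < self.n_core_genes:
            raise ValueError("n_genes must be >= n_core_genes")
        if self.baseline_abundance <= 0 or self.state_multiplier <= 0:
            raise ValueError("abundance and state multiplier must be positive")
        if self.n_strains < 1 or self.n_variant_sites < 0:
            raise ValueError("counts must be >= 1 (strains) / >= 0 (sites)")


@dataclass(frozen=True)
class StrainModel:
    strain_id: str
    haplotype: tuple  # one allele per variant site
    accessory_ogs: frozenset


@dataclass(frozen=True)
class SpeciesModel:
    species_id: str
    genome_length: int
    # (gene_id, start_fraction, length_bases, is_single_copy_core)
    gene_catalog: tuple
    strains: tuple
    # (position, ref_allele, alt_alleles)
    variant_sites: tuple

    @property
    def core_genes(self) -> list[tuple]:
        return [g for g in self.gene_catalog if g[3]]

    @property
    def core_length(self) -> int:
        return sum(g[2] for g in self.core_genes)

    def core_og_ids(self) -> list[str]:
        return [f"{self.species_id}:core:{g[0]}" for g in self.core_genes]


@dataclass(frozen=True)
class PlantedOg:
    species_id: str
    og_id: str
    enriched_state: str  # "nurse" | "forager"
    fold: float

    def __post_init__(self) -> None:
        if self.enriched_state not in ("nurse", "forager"):
            raise ValueError(f"unknown state {self.enriched_state!r}")
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass
class CommunityScenario:
    """Full description of one synthetic experiment."""

    species: list[SpeciesConfig]
    n_locations: int = 5
    colonies_per_location: int = 3
    strain_pool_overlap: float = 0.5
    ptr: float = 2.0  # Ori/Ter coverage ratio, >= 1
    sequencing_error: float = 0.001
    depth_scale: float = 50.0  # trough coverage per abundance unit
    snv_depth: int = 200
    coverage_noise: str = "poisson"  # "poisson" | "none"
    colony_sigma: float = 0.2  # lognormal colony effect, shared within pair
    mixture_alpha: float = 5.0  # Dirichlet concentration for strain mixtures
    og_noise_sigma: float = 0.0  # lognormal noise on OG coverage
    og_base_coverage: float = 1.0
    planted_differential_ogs: list[PlantedOg] = field(default_factory=list)
    qpcr_slope: float = -3.32
    qpcr_intercept: float = 38.0
    qpcr_sd_ct: float = 0.0
    load_scale: float = 1e5  # 16S copies per ng per abundance unit
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("scenario needs at least one species")
        if not 0.0 <= self.strain_pool_overlap <= 1.0:
            raise ValueError("strain_pool_overlap must be in [0, 1]")
        if self.ptr < 1.0:
            raise ValueError("PTR (Ori/Ter ratio) must be >= 1")
        if not 0.0 <= self.sequencing_error <= 0.05:
            raise ValueError("sequencing error rate must be in [0, 0.05]")
        if self.n_locations < 1 or self.colonies_per_location < 1:
            raise ValueError("design counts must be >= 1")
        if self.coverage_noise not in ("poisson", "none"):
            raise ValueError("coverage_noise must be 'poisson' or 'none'")


# ---------------------------------------------------------------------------
# model generation
# ---------------------------------------------------------------------------


def generate_species_model(
    config: SpeciesConfig, rng: np.random.Generator
) -> SpeciesModel:
    """Draw a reference model: gene catalog, variant sites and strains.

    Core genes are stratified over [0, 1) so they span the full position
    range (required for terminus fitting); variant sites fall inside core
    genes; each strain carries one allele per variant site and a private set
    of accessory OGs.
    """
    n_core = config.n_core_genes
    # stratified core-gene starts spanning [0, 1)
    core_starts = (np.arange(n_core) + rng.uniform(0, 1, n_core)) / n_core
    n_extra = config.n_genes - n_core
    extra_starts = rng.uniform(0, 1, n_extra)
    lengths = rng.integers(300, 1500, config.n_genes)
    catalog = []
    idx = 0
    for start in core_starts:
        catalog.append((f"{config.species_id}_g{idx:04d}", float(start),
                        int(lengths[idx]), True))
        idx += 1
    for start in extra_starts:
        catalog.append((f"{config.species_id}_g{idx:04d}", float(start),
                        int(lengths[idx]), False))
        idx += 1
    catalog.sort(key=lambda g: g[1])

    # variant sites inside core genes
    core_intervals = []
    for gid, start, length, is_core in catalog:
        if is_core:
            s = int(start * config.genome_length)
            core_intervals.append((s, min(s + length, config.genome_length)))
    core_positions = np.concatenate(
        [np.arange(s, e) for s, e in core_intervals]
    )
    n_sites = min(config.n_variant_sites, core_positions.size)
    positions = np.sort(rng.choice(core_positions, n_sites, replace=False))

    refs = rng.choice(BASES, n_sites)
    # per strain, per site: keep ref or draw one of the 3 alternates
    haplotypes = []
    for s in range(config.n_strains):
        hap = []
        for j in range(n_sites):
            if rng.random() < config.strain_divergence:
                alt_choices = [b for b in BASES if b != refs[j]]
                hap.append(alt_choices[rng.integers(0, 3)])
            else:
                hap.append(refs[j])
        haplotypes.append(tuple(hap))

    variant_sites = []
    for j in range(n_sites):
        alts = sorted(
            {hap[j] for hap in haplotypes if hap[j] != refs[j]}
        )
        variant_sites.append((int(positions[j]), str(refs[j]), tuple(alts)))

    strains = []
    for s, hap in enumerate(haplotypes):
        sid = f"{config.species_id}_s{s:02d}"
        acc = frozenset(
            f"{config.species_id}:acc:{sid}:{k}"
            for k in range(config.n_accessory_ogs_per_strain)
        )
        strains.append(StrainModel(strain_id=sid, haplotype=hap,
                                   accessory_ogs=acc))

    return SpeciesModel(
        species_id=config.species_id,
        genome_length=config.genome_length,
        gene_catalog=tuple(catalog),
        strains=tuple(strains),
        variant_sites=tuple(variant_sites),
    )


# ---------------------------------------------------------------------------
# community / design
# ---------------------------------------------------------------------------


def _strain_pools(
    strains: Sequence[StrainModel], overlap: float, rng: np.random.Generator
) -> tuple[list[StrainModel], list[StrainModel]]:
    """Split a species' strains into nurse and forager pools.

    Each pool holds ``p`` strains; ``round(overlap * p)`` are shared. Pool
    membership order is randomized by ``rng``.
    """
    m = len(strains)
    order = list(rng.permutation(m))
    p = max(1, m // 2)
    k = round(overlap * p)
    if 2 * p - k > m:
        raise ValueError(
            f"not enough strains ({m}) for pool size {p} with overlap "
            f"{overlap}"
        )
    shared = [strains[i] for i in order[:k]]
    nurse_only = [strains[i] for i in order[k: p]]
    forager_only = [strains[i] for i in order[p: 2 * p - k]]
    return shared + nurse_only, shared + forager_only


def simulate_community(
    scenario: CommunityScenario, rng: np.random.Generator
) -> tuple[list[SpeciesModel], list[SampleRecord], pd.DataFrame, pd.DataFrame]:
    """Generate species models, the paired sample design, true abundances and
    per-sample strain mixtures.

    Returns ``(models, samples, true_abundance, strain_mixture)`` where
    ``true_abundance`` is a samples x species table and ``strain_mixture``
    has columns sample_id, species_id, strain_id, proportion.
    """
    models = [generate_species_model(cfg, rng) for cfg in scenario.species]
    pools = {
        m.species_id: _strain_pools(m.strains, scenario.strain_pool_overlap, rng)
        for m in models
    }

    samples: list[SampleRecord] = []
    abun_rows: dict[str, dict[str, float]] = {}
    mix_rows: list[dict] = []
    for loc in range(scenario.n_locations):
        for col in range(scenario.colonies_per_location):
            colony = f"L{loc + 1}C{col + 1}"
            location = f"L{loc + 1}"
            dna_yield = float(rng.uniform(20, 60))
            colony_noise = {
                cfg.species_id: float(
                    rng.lognormal(0.0, scenario.colony_sigma)
                )
                if scenario.colony_sigma > 0
                else 1.0
                for cfg in scenario.species
            }
            for state, prefix in (("nurse", "N"), ("forager", "F")):
                sid = f"{prefix}_{colony}"
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        state=state,
                        colony_id=colony,
                        location_id=location,
                        n_guts=10,
                        pool_mass=float(rng.uniform(50, 150)),
                        dna_yield=dna_yield,
                    )
                )
                abun_rows[sid] = {}
                for cfg in scenario.species:
                    mult = (
                        cfg.state_multiplier if state == "forager" else 1.0
                    )
                    abun_rows[sid][cfg.species_id] = (
                        cfg.baseline_abundance
                        * mult
                        * colony_noise[cfg.species_id]
                    )
                for model in models:
                    pool = pools[model.species_id][0 if state == "nurse" else 1]
                    props = rng.dirichlet(
                        np.full(len(pool), scenario.mixture_alpha)
                    )
                    for strain, prop in zip(pool, props):
                        mix_rows.append(
                            {
                                "sample_id": sid,
                                "species_id": model.species_id,
                                "strain_id": strain.strain_id,
                                "proportion": float(prop),
                            }
                        )
    true_abundance = pd.DataFrame(abun_rows).T
    true_abundance.index.name = "sample_id"
    true_abundance = true_abundance[[c.species_id for c in scenario.species]]
    strain_mixture = pd.DataFrame(mix_rows)
    return models, samples, true_abundance, strain_mixture


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def expected_gene_coverage(position_fraction: float, trough: float,
                           ptr: float) -> float:
    """V-shaped Ori->Ter expectation: linear from ptr*trough at positions
    0 and 1 down to ``trough`` at 0.5."""
    return trough * (1.0 + (ptr - 1.0) * 2.0 * abs(position_fraction - 0.5))


def simulate_gene_coverage(
    model: SpeciesModel,
    true_abundance: Mapping[str, float],
    ptr: float,
    noise: str,
    rng: np.random.Generator,
    depth_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-gene read coverage for one species across samples.

    The trough (terminus) coverage is ``abundance * depth_scale``; expected
    per-gene coverage follows the symmetric V in position fraction; with
    ``noise="poisson"`` the observed value is a Poisson draw.
    """
    if ptr < 1.0:
        raise ValueError("ptr must be >= 1")
    rows = []
    for sample_id, abundance in true_abundance.items():
        if abundance < 0:
            raise ValueError(f"negative abundance for sample {sample_id!r}")
        trough = abundance * depth_scale
        for gene_id, start, length, is_core in model.gene_catalog:
            mu = expected_gene_coverage(start, trough, ptr)
            cov = float(rng.poisson(mu)) if noise == "poisson" else mu
            rows.append(
                (model.species_id, gene_id, start, is_core, sample_id, cov)
            )
    return pd.DataFrame(rows, columns=GENE_COVERAGE_COLUMNS)


# ---------------------------------------------------------------------------
# allele observations
# ---------------------------------------------------------------------------


def simulate_allele_observations(
    model: SpeciesModel,
    strain_mixture: pd.DataFrame,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled per-site allele read counts for one species.

    ``strain_mixture`` holds columns sample_id, strain_id, proportion for
    this species (proportions per sample must sum to 1). At each variant
    site the allele probabilities mix the strain haplotypes, with the
    sequencing error mass ``error_rate`` spread uniformly over the other 3
    bases; counts are one Multinomial(depth, p) draw. Rows with zero counts
    are omitted.
    """
    if strain_mixture.empty:
        raise ValueError("empty strain mixture")
    strain_by_id = {s.strain_id: s for s in model.strains}
    base_idx = {b: i for i, b in enumerate(BASES)}
    rows = []
    for sample_id, grp in strain_mixture.groupby("sample_id", sort=True):
        props = grp["proportion"].to_numpy(dtype=float)
        if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(
                f"strain proportions for {sample_id!r} sum to {props.sum()}"
            )
        haps = [strain_by_id[s].haplotype for s in grp["strain_id"]]
        for j, (pos, ref, _alts) in enumerate(model.variant_sites):
            p = np.zeros(4)
            for prop, hap in zip(props, haps):
                template = base_idx[hap[j]]
                p[template] += prop * (1.0 - error_rate)
                for b in range(4):
                    if b != template:
                        p[b] += prop * error_rate / 3.0
            counts = rng.multinomial(depth, p / p.sum())
            for b, count in zip(BASES, counts):
                if count > 0:
                    rows.append(
                        (model.species_id, pos, ref, sample_id, b, int(count))
                    )
    return pd.DataFrame(rows, columns=ALLELE_OBS_COLUMNS)


def write_allele_vcf(
    observations: pd.DataFrame, models: Sequence[SpeciesModel], path
) -> None:
    """Write allele observations as a minimal VCF v4.2.

    One record per (species contig, site); per-sample RO (reference count)
    and AO (per-alternate counts) FORMAT fields. Sites are written 1-based.
    A site with no observed alternate gets a placeholder alternate with
    zero counts so that reference counts survive the round trip.
    """
    model_by_id = {m.species_id: m for m in models}
    sample_ids = sorted(observations["sample_id"].unique())
    lines = ["##fileformat=VCFv4.2"]
    for m in models:
        lines.append(f"##contig=<ID={m.species_id},length={m.genome_length}>")
    lines.append(
        '##FORMAT=<ID=RO,Number=1,Type=Integer,'
        'Description="Reference allele observation count">'
    )
    lines.append(
        '##FORMAT=<ID=AO,Number=A,Type=Integer,'
        'Description="Alternate allele observation count">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    for (species, site, ref), grp in observations.groupby(
        ["species_id", "site", "ref_allele"], sort=True
    ):
        alts = sorted(set(grp["allele"]) - {ref})
        if not alts:  # keep monomorphic-reference sites round-trippable
            alts = [next(b for b in BASES if b != ref)]
        counts = {
            (r.sample_id, r.allele): int(r.count)
            for r in grp.itertuples(index=False)
        }
        fields = [
            str(species),
            str(int(site) + 1),
            ".",
            str(ref),
            ",".join(alts),
            ".",
            ".",
            ".",
            "RO:AO",
        ]
        for sid in sample_ids:
            ro = counts.get((sid, ref), 0)
            ao = ",".join(str(counts.get((sid, a), 0)) for a in alts)
            fields.append(f"{ro}:{ao}")
        lines.append("\t".join(fields))
        _ = model_by_id  # contigs already declared
    Path(path).write_text("\n".join(lines) + "\n")


def write_core_bed(models: Sequence[SpeciesModel], path) -> None:
    """BED (0-based half-open) of single-copy core gene regions per species."""
    with open(path, "w") as fh:
        for m in models:
            for gene_id, start, length, is_core in m.gene_catalog:
                if not is_core:
                    continue
                s = int(start * m.genome_length)
                e = min(s + length, m.genome_length)
                fh.write(f"{m.species_id}\t{s}\t{e}\t{gene_id}\n")


# ---------------------------------------------------------------------------
# OG coverage
# ---------------------------------------------------------------------------


def simulate_og_coverage(
    models: Sequence[SpeciesModel],
    true_abundance: pd.DataFrame,
    strain_mixture: pd.DataFrame,
    planted: Sequence[PlantedOg],
    samples: Sequence[SampleRecord],
    rng: np.random.Generator,
    og_base_coverage: float = 1.0,
    noise_sigma: float = 0.0,
) -> pd.DataFrame:
    """Raw OG coverage table (species_id, og_id, is_core, sample_id, coverage).

    Core OGs are carried by every strain and track species abundance;
    accessory OG coverage is the species abundance times the summed
    proportion of the strains carrying the OG. Planted differential OGs are
    carried by all strains and multiplied by their fold in the enriched
    state. Optional multiplicative lognormal noise.
    """
    state_by_sample = {s.sample_id: s.state for s in samples}
    planted_by_species: dict[str, list[PlantedOg]] = {}
    for p in planted:
        if p.species_id not in {m.species_id for m in models}:
            raise ValueError(f"planted OG references unknown species "
                             f"{p.species_id!r}")
        planted_by_species.setdefault(p.species_id, []).append(p)

    mix = strain_mixture.set_index(["species_id", "sample_id"]).sort_index()
    rows = []
    for model in models:
        accessory: dict[str, set[str]] = {}
        for strain in model.strains:
            for og in strain.accessory_ogs:
                accessory.setdefault(og, set()).add(strain.strain_id)
        for sample_id in true_abundance.index:
            abundance = float(true_abundance.loc[sample_id, model.species_id])
            state = state_by_sample[sample_id]

            def noisy(value: float) -> float:
                if noise_sigma > 0:
                    return value * float(rng.lognormal(0.0, noise_sigma))
                return value

            for og in model.core_og_ids():
                rows.append(
                    (model.species_id, og, True, sample_id,
                     noisy(abundance * og_base_coverage))
                )
            try:
                sub = mix.loc[(model.species_id, sample_id)]
                carried_prop = dict(
                    zip(sub["strain_id"], sub["proportion"])
                )
            except KeyError:
                carried_prop = {}
            for og, carriers in sorted(accessory.items()):
                prop = sum(carried_prop.get(s, 0.0) for s in carriers)
                cov = abundance * og_base_coverage * prop
                if cov > 0 or noise_sigma == 0:
                    rows.append(
                        (model.species_id, og, False, sample_id, noisy(cov))
                    )
            for p in planted_by_species.get(model.species_id, []):
                fold = p.fold if state == p.enriched_state else 1.0
                rows.append(
                    (model.species_id, p.og_id, False, sample_id,
                     noisy(abundance * og_base_coverage * fold))
                )
    return pd.DataFrame(rows, columns=OG_COVERAGE_COLUMNS)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_16s_copies: Mapping[str, float],
    slope: float,
    intercept: float,
    sd_ct: float,
    rng: np.random.Generator,
    n_replicates: int = 3,
):
    """Triplicate Cts from true copy numbers via the standard curve:
    Ct = intercept + slope * log10(copies) + Normal(0, sd_ct)."""
    from .quantification import QpcrMeasurement

    if slope == 0:
        raise ValueError("slope must be non-zero")
    out = []
    for sample_id, copies in true_16s_copies.items():
        if copies <= 0:
            raise ValueError(f"copies must be positive ({sample_id!r})")
        mu = intercept + slope * math.log10(copies)
        cts = tuple(
            float(mu + (rng.normal(0.0, sd_ct) if sd_ct > 0 else 0.0))
            for _ in range(n_replicates)
        )
        out.append(
            QpcrMeasurement(
                sample_id=sample_id,
                target="16S",
                ct_replicates=cts,
                slope=slope,
                intercept=intercept,
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def default_scenario(seed: int = 0, **overrides) -> CommunityScenario:
    """A small default scenario: 5 locations x 3 colonies, 4 species with
    state-dependent abundance shifts, one planted differential OG."""
    species = [
        SpeciesConfig("sp01", baseline_abundance=2.0, state_multiplier=0.4),
        SpeciesConfig("sp02", baseline_abundance=1.0, state_multiplier=0.25),
        SpeciesConfig("sp03", baseline_abundance=0.8, state_multiplier=1.0),
        SpeciesConfig("sp04", baseline_abundance=0.5, state_multiplier=1.6),
    ]
    planted = [PlantedOg("sp01", "sp01:planted:og1", "forager", 4.0)]
    params = dict(species=species, planted_differential_ogs=planted, seed=seed)
    params.update(overrides)
    return CommunityScenario(**params)


def simulate_all(scenario: CommunityScenario,
                 rng: np.random.Generator | None = None) -> dict:
    """Run every generator and return a bundle of tables + ground truth."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    models, samples, true_abundance, strain_mixture = simulate_community(
        scenario, rng
    )
    gene_cov = pd.concat(
        [
            simulate_gene_coverage(
                m,
                true_abundance[m.species_id].to_dict(),
                scenario.ptr,
                scenario.coverage_noise,
                rng,
                depth_scale=scenario.depth_scale,
            )
            for m in models
        ],
        ignore_index=True,
    )
    allele_obs = pd.concat(
        [
            simulate_allele_observations(
                m,
                strain_mixture[strain_mixture["species_id"] == m.species_id],
                scenario.snv_depth,
                scenario.sequencing_error,
                rng,
            )
            for m in models
        ],
        ignore_index=True,
    )
    og_cov = simulate_og_coverage(
        models,
        true_abundance,
        strain_mixture,
        scenario.planted_differential_ogs,
        samples,
        rng,
        og_base_coverage=scenario.og_base_coverage,
        noise_sigma=scenario.og_noise_sigma,
    )
    dna_yield = {s.sample_id: s.dna_yield for s in samples}
    copies = {
        sid: float(true_abundance.loc[sid].sum())
        * scenario.load_scale
        * dna_yield[sid]
        for sid in true_abundance.index
    }
    qpcr = simulate_qpcr(
        copies,
        scenario.qpcr_slope,
        scenario.qpcr_intercept,
        scenario.qpcr_sd_ct,
        rng,
    )
    return {
        "scenario": scenario,
        "models": models,
        "samples": samples,
        "true_abundance": true_abundance,
        "strain_mixture": strain_mixture,
        "gene_coverage": gene_cov,
        "allele_observations": allele_obs,
        "og_coverage": og_cov,
        "qpcr": qpcr,
        "true_16s_copies": copies,
    }


def write_all(bundle: dict, outdir) -> dict[str, Path]:
    """Write every simulated table to ``outdir``; returns name -> path."""
    from .io_filters import write_sample_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["samples"] = outdir / "samples.tsv"
    write_sample_metadata(bundle["samples"], paths["samples"])

    paths["gene_coverage"] = outdir / "gene_coverage.tsv"
    bundle["gene_coverage"].to_csv(paths["gene_coverage"], sep="\t",
                                   index=False)

    paths["allele_observations"] = outdir / "allele_observations.tsv"
    bundle["allele_observations"].to_csv(
        paths["allele_observations"], sep="\t", index=False
    )
    paths["allele_vcf"] = outdir / "allele_observations.vcf"
    write_allele_vcf(
        bundle["allele_observations"], bundle["models"], paths["allele_vcf"]
    )
    paths["core_bed"] = outdir / "core_genes.bed"
    write_core_bed(bundle["models"], paths["core_bed"])

    paths["og_coverage"] = outdir / "og_coverage.tsv"
    bundle["og_coverage"].to_csv(paths["og_coverage"], sep="\t", index=False)

    paths["qpcr"] = outdir / "qpcr.csv"
    qpcr_rows = []
    for m in bundle["qpcr"]:
        row = {"sample_id": m.sample_id, "target": m.target}
        for i, ct in enumerate(m.ct_replicates, 1):
            row[f"ct_{i}"] = ct
        row["slope"] = m.slope
        row["intercept"] = m.intercept
        qpcr_rows.append(row)
    pd.DataFrame(qpcr_rows).to_csv(paths["qpcr"], index=False)

    scenario = bundle["scenario"]
    truth = {
        "seed": scenario.seed,
        "scenario": _scenario_to_dict(scenario),
        "true_abundance": {
            sid: bundle["true_abundance"].loc[sid].to_dict()
            for sid in bundle["true_abundance"].index
        },
        "true_16s_copies": bundle["true_16s_copies"],
        "strain_mixture": bundle["strain_mixture"].to_dict(orient="records"),
        "planted_differential_ogs": [
            dataclasses.asdict(p) for p in scenario.planted_differential_ogs
        ],
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    return paths


def _scenario_to_dict(scenario: CommunityScenario) -> dict:
    d = dataclasses.asdict(scenario)
    return d
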