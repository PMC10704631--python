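"""Intraspecific gene-content analysis.

Assembled contigs are binned to species by majority vote over their ORFs'
sequence-similarity hits; ORF coverage is summed into orthologous groups
(OGs), normalized so that each species' single-copy core OGs sum to a fixed
constant per sample, and differential OGs between the two host states are
called with paired Wilcoxon tests, q-values and a fold-change threshold.
Functional category enrichment among significant OGs uses Fisher's exact
test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filters import SampleRecord, validate_paired_design
from .stats import fisher_exact_2x2, qvalues, wilcoxon_signed_rank_paired

log = logging.getLogger(__name__)

__all__ = [
    "OrfRecord",
    "ContigRecord",
    "DifferentialOgResult",
    "filter_contigs",
    "filter_orfs",
    "assign_contig",
    "aggregate_og_coverage",
    "normalize_og_coverage",
    "differential_ogs",
    "cog_enrichment",
]

NORM_CONSTANT = 10_000.0
SIG_Q = 0.05
SIG_ABS_LOG2FC = 1.0

OG_COVERAGE_COLUMNS = ["species_id", "og_id", "is_core", "sample_id", "coverage"]


@dataclass(frozen=True)
class OrfRecord:
    orf_id: str
    length: int
    partial_flag: str = "00"  # "00" means a complete ORF
    species_hits: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    length: int
    kmer_coverage: float
    orfs: tuple = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("contig length must be positive")


@dataclass(frozen=True)
class DifferentialOgResult:
    species_id: str
    og_id: str
    mean_nurse: float
    mean_forager: float
    log2fc: float  # forager over nurse
    p: float
    q: float
    significant: bool
    enriched_state: str | None
    cog_category: str | None = None


def filter_contigs(
    contigs, min_len: int = 500, min_kcov: float = 1.0
) -> list[ContigRecord]:
    """Keep contigs of at least ``min_len`` bp and k-mer coverage of at
    least ``min_kcov`` (inclusive thresholds)."""
    return [
        c for c in contigs if c.length >= min_len and c.kmer_coverage >= min_kcov
    ]


def filter_orfs(orfs, min_len: int = 300) -> list[OrfRecord]:
    """Keep complete ORFs (partial flag "00") of at least ``min_len`` bp.

    Partial gene calls and short ORFs are removed before orthology-based
    analysis.
    """
    return [o for o in orfs if o.partial_flag == "00" and o.length >= min_len]


def assign_contig(
    contig: ContigRecord,
    majority_fraction: float = 0.8,
    exclusive_fraction: float = 0.1,
    strict_majority: bool = False,
) -> str | None:
    """Assign a contig to a species from its ORFs' similarity hits.

    Rule A: a species hit by at least ``majority_fraction`` (80%) of the
    ORFs wins; by default other species may receive minority hits
    (``strict_majority=False``), matching the tolerant reading. Rule B: a
    species hit by at least ``exclusive_fraction`` (10%) of the ORFs wins
    when no ORF hits any other species. Contigs satisfying neither rule, or
    tied between species, are non-unanimous and return ``None``.
    """
    orfs = contig.orfs
    if not orfs:
        raise ValueError(f"contig {contig.contig_id!r} has no ORFs")
    n = len(orfs)
    counts: dict[str, int] = {}
    for orf in orfs:
        for sp in orf.species_hits:
            counts[sp] = counts.get(sp, 0) + 1

    winners = [
        sp for sp, c in counts.items() if c / n >= majority_fraction
    ]
    if strict_majority:
        winners = [
            sp for sp in winners
            if all(other == sp for other, c in counts.items() if c > 0)
        ]
    if len(winners) == 1:
        return winners[0]
    if len(winners) > 1:
        log.info(
            "contig %s: tie between %s, left unassigned",
            contig.contig_id,
            winners,
        )
        return None

    if len(counts) == 1:
        sp, c = next(iter(counts.items()))
        if c / n >= exclusive_fraction:
            return sp
    return None


def aggregate_og_coverage(
    orf_coverage: pd.DataFrame,
    og_membership: pd.DataFrame,
    contig_assignments: dict[str, str | None],
    orf_contigs: dict[str, str],
) -> pd.DataFrame:
    """Sum ORF read coverage into per-(species, OG, sample) values.

    ``orf_coverage``: columns orf_id, sample_id, coverage. ``og_membership``:
    columns orf_id, og_id and optionally is_core; an ORF appearing under two
    OGs is an input error. ORFs on unassigned contigs are excluded. Returns
    the OG coverage table (species_id, og_id, is_core, sample_id, coverage).
    """
    dup = og_membership["orf_id"][og_membership["orf_id"].duplicated()]
    if len(dup):
        raise ValueError(
            f"ORFs assigned to more than one OG: {sorted(set(dup))[:5]}"
        )
    memb = og_membership.copy()
    if "is_core" not in memb.columns:
        memb["is_core"] = False
    merged = orf_coverage.merge(memb, on="orf_id", how="inner")
    merged["contig_id"] = merged["orf_id"].map(orf_contigs)
    merged["species_id"] = merged["contig_id"].map(
        lambda c: contig_assignments.get(c)
    )
    merged = merged[merged["species_id"].notna()]
    out = (
        merged.groupby(
            ["species_id", "og_id", "is_core", "sample_id"], sort=True
        )["coverage"]
        .sum()
        .reset_index()
    )
    return out[OG_COVERAGE_COLUMNS]


def normalize_og_coverage(
    matrix: pd.DataFrame, constant: float = NORM_CONSTANT
) -> pd.DataFrame:
    """Rescale coverage so each (species, sample)'s single-copy core OGs sum
    to ``constant``.

    (species, sample) groups whose core OGs have zero summed coverage are
    dropped with a warning. Idempotent: normalizing twice equals once.
    """
    df = matrix.copy()
    core = df[df["is_core"].astype(bool)]
    core_sums = core.groupby(["species_id", "sample_id"])["coverage"].sum()
    keys = pd.MultiIndex.from_frame(df[["species_id", "sample_id"]])
    sums = core_sums.reindex(keys).to_numpy()
    bad = ~(sums > 0)
    if bad.any():
        dropped = sorted(set(map(tuple, df.loc[bad, ["species_id", "sample_id"]]
                                 .itertuples(index=False))))
        warnings.warn(
            f"zero core-OG coverage; dropped (species, sample) groups: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    df = df.loc[~bad].copy()
    df["coverage"] = df["coverage"].to_numpy() * (constant / sums[~bad])
    return df


def _log2fc(mean_f: float, mean_n: float) -> float:
    if mean_n == 0 and mean_f == 0:
        return 0.0
    if mean_n == 0:
        return math.inf
    if mean_f == 0:
        return -math.inf
    return math.log2(mean_f / mean_n)


def differential_ogs(
    normalized: pd.DataFrame,
    samples: list[SampleRecord],
    sig_q: float = SIG_Q,
    min_abs_log2fc: float = SIG_ABS_LOG2FC,
    annotations: pd.DataFrame | None = None,
) -> list[DifferentialOgResult]:
    """Call OGs with differential normalized coverage between host states.

    Per OG: a paired Wilcoxon signed-rank test over the colony pairs
    (missing observations count as zero coverage), log2 fold change of mean
    forager over mean nurse coverage, and q-values computed jointly across
    all OGs of all species. Significant iff q < ``sig_q`` and |log2fc| >=
    ``min_abs_log2fc`` (infinite fold changes — presence/absence OGs —
    satisfy the fold threshold by convention).
    """
    validate_paired_design(samples)
    by_colony: dict[str, dict[str, str]] = {}
    for s in samples:
        by_colony.setdefault(s.colony_id, {})[s.state] = s.sample_id
    colonies = sorted(by_colony)
    nurse_ids = [by_colony[c]["nurse"] for c in colonies]
    forager_ids = [by_colony[c]["forager"] for c in colonies]
    all_ids = nurse_ids + forager_ids

    cog_map: dict[tuple[str, str], str] = {}
    if annotations is not None:
        key_cols = (
            ["species_id", "og_id"]
            if "species_id" in annotations.columns
            else ["og_id"]
        )
        for r in annotations.itertuples(index=False):
            key = (
                (str(r.species_id), str(r.og_id))
                if len(key_cols) == 2
                else (None, str(r.og_id))
            )
            cog_map[key] = str(r.cog_category)

    wide = normalized.pivot_table(
        index=["species_id", "og_id"],
        columns="sample_id",
        values="coverage",
        aggfunc="sum",
        fill_value=0.0,
    )
    for sid in all_ids:
        if sid not in wide.columns:
            wide[sid] = 0.0

    partial: list[dict] = []
    for (species, og), row in wide.iterrows():
        nurse_vals = row[nurse_ids].to_numpy(dtype=float)
        forager_vals = row[forager_ids].to_numpy(dtype=float)
        _, p = wilcoxon_signed_rank_paired(forager_vals, nurse_vals)
        mean_n = float(nurse_vals.mean())
        mean_f = float(forager_vals.mean())
        partial.append(
            {
                "species_id": str(species),
                "og_id": str(og),
                "mean_nurse": mean_n,
                "mean_forager": mean_f,
                "log2fc": _log2fc(mean_f, mean_n),
                "p": p,
            }
        )
    if not partial:
        return []
    qs = qvalues([r["p"] for r in partial])
    results = []
    for r, q in zip(partial, qs):
        lfc = r["log2fc"]
        passes_fold = abs(lfc) >= min_abs_log2fc  # inf passes
        significant = bool(q < sig_q and passes_fold)
        enriched = None
        if significant:
            enriched = "forager" if lfc > 0 else "nurse"
        cog = cog_map.get((r["species_id"], r["og_id"])) or cog_map.get(
            (None, r["og_id"])
        )
        results.append(
            DifferentialOgResult(
                species_id=r["species_id"],
                og_id=r["og_id"],
                mean_nurse=r["mean_nurse"],
                mean_forager=r["mean_forager"],
                log2fc=lfc,
                p=r["p"],
                q=float(q),
                significant=significant,
                enriched_state=enriched,
                cog_category=cog,
            )
        )
    return results


def differential_results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "og_id": r.og_id,
                "enriched_state": r.enriched_state or "",
                "mean_nurse": r.mean_nurse,
                "mean_forager": r.mean_forager,
                "log2fc": r.log2fc,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
                "cog_category": r.cog_category or "",
            }
            for r in results
        ]
    )


def cog_enrichment(
    results: list[DifferentialOgResult],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Fisher-exact enrichment of functional categories among significant OGs.

    For every (species, category): a 2x2 table of {significant vs not} x
    {category vs other} over that species' OGs, two-sided Fisher p, and
    q-values across all (species, category) tests. ``annotations`` maps
    og_id (optionally per species) to a one-letter cog_category.
    """
    if "cog_category" not in annotations.columns:
        raise ValueError("annotation table needs a cog_category column")
    has_species = "species_id" in annotations.columns
    cat_map: dict[tuple, str] = {}
    for r in annotations.itertuples(index=False):
        key = (str(r.species_id), str(r.og_id)) if has_species else (str(r.og_id),)
        cat_map[key] = str(r.cog_category)

    def lookup(res: DifferentialOgResult) -> str | None:
        if res.cog_category:
            return res.cog_category
        key = (res.species_id, res.og_id) if has_species else (res.og_id,)
        return cat_map.get(key)

    rows = []
    by_species: dict[str, list[DifferentialOgResult]] = {}
    for res in results:
        by_species.setdefault(res.species_id, []).append(res)
    for species, group in sorted(by_species.items()):
        cats = sorted({c for c in (lookup(r) for r in group) if c})
        for cat in cats:
            sig_cat = sum(
                1 for r in group if r.significant and lookup(r) == cat
            )
            sig_other = sum(
                1 for r in group if r.significant and lookup(r) != cat
            )
            not_cat = sum(
                1 for r in group if not r.significant and lookup(r) == cat
            )
            not_other = sum(
                1 for r in group if not r.significant and lookup(r) != cat
            )
            odds, p = fisher_exact_2x2(
                [[sig_cat, sig_other], [not_cat, not_other]]
            )
            rows.append(
                {
                    "species_id": species,
                    "cog_category": cat,
                    "n_significant_in_category": sig_cat,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = qvalues(table["p"].to_numpy())
    return table
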