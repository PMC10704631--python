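"""Species abundance profiling from single-copy core-gene coverage.

Replicating bacteria show a coverage gradient from the replication origin
(position fraction 0/1) to the terminus (mid-genome); the read depth at the
terminus is therefore used as the abundance proxy. A two-segment continuous
piecewise-linear regression is fitted over gene position fraction; when the
fit is implausible (breakpoint far from mid-genome, or origin coverage below
terminus coverage) the median core-gene coverage is used instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_filters import SampleRecord, validate_paired_design
from .quantification import BacterialLoad
from .stats import qvalues, wilcoxon_signed_rank_paired

log = logging.getLogger(__name__)

__all__ = [
    "TerminusFit",
    "GENE_COVERAGE_COLUMNS",
    "fit_terminus_coverage",
    "fit_all_termini",
    "relative_abundance",
    "relative_abundance_matrix",
    "absolute_abundance",
    "paired_log2fc",
    "phylotype_aggregate",
    "shannon_within_phylotype",
]

GENE_COVERAGE_COLUMNS = [
    "species_id",
    "gene_id",
    "position_fraction",
    "is_core",
    "sample_id",
    "coverage",
]

MIN_FIT_POINTS = 8
BREAKPOINT_WINDOW = (0.3, 0.7)
BREAKPOINT_GRID_STEP = 0.01


@dataclass(frozen=True)
class TerminusFit:
    species_id: str
    sample_id: str
    ter_coverage: float
    ori_coverage: float
    method: str  # "segmented" | "median"
    valid: bool
    breakpoint: float | None = None


def _segment_fit(x: np.ndarray, y: np.ndarray, b: float):
    """Least-squares fit of a continuous two-segment line with hinge at b.

    Basis: [1, x, max(0, x - b)]. Returns (beta, sse).
    """
    X = np.column_stack([np.ones_like(x), x, np.clip(x - b, 0.0, None)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _predict(beta: np.ndarray, b: float, x: np.ndarray) -> np.ndarray:
    return beta[0] + beta[1] * x + beta[2] * np.clip(x - b, 0.0, None)


def fit_terminus_coverage(
    positions,
    coverages,
    species_id: str = "",
    sample_id: str = "",
    grid_step: float = BREAKPOINT_GRID_STEP,
    window: tuple[float, float] = BREAKPOINT_WINDOW,
) -> TerminusFit:
    """Infer terminus read depth for one species in one sample.

    A continuous two-segment line is fitted by least squares over gene
    position fractions, with the breakpoint searched on a grid (step 0.01)
    and refined by bounded minimization around the best grid cell.
    ``ter_coverage`` is the fitted value at the breakpoint; ``ori_coverage``
    the mean of the fitted values at positions 0 and 1. The segmented fit is
    declared invalid — falling back to the median of the core-family
    coverages — when the breakpoint leaves the central window or the origin
    coverage does not exceed the terminus coverage. Fewer than 8 gene
    families also trigger the median fallback (with a warning).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(coverages, dtype=float)
    if x.size != y.size:
        raise ValueError("positions and coverages must align")
    median_cov = float(np.median(y)) if y.size else 0.0
    if x.size < MIN_FIT_POINTS:
        warnings.warn(
            f"{species_id}/{sample_id}: only {x.size} gene families, "
            "using median coverage",
            stacklevel=2,
        )
        return TerminusFit(
            species_id, sample_id, median_cov, median_cov, "median", False
        )

    lo, hi = x.min() + grid_step, x.max() - grid_step
    grid = np.arange(max(0.05, lo), min(0.95, hi) + 1e-12, grid_step)
    if grid.size == 0:
        grid = np.array([0.5])
    sses = np.array([_segment_fit(x, y, b)[1] for b in grid])
    best = int(np.argmin(sses))
    b0 = float(grid[best])
    # refine continuously within the neighbouring grid cells
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid.size - 1)]
    if hi_b > lo_b:
        res = minimize_scalar(
            lambda b: _segment_fit(x, y, b)[1],
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun <= sses[best] + 1e-12:
            b0 = float(res.x)
    beta, _ = _segment_fit(x, y, b0)
    ter = float(_predict(beta, b0, np.array([b0]))[0])
    ori = float(np.mean(_predict(beta, b0, np.array([0.0, 1.0]))))
    if window[0] <= b0 <= window[1] and ori > ter and ter >= 0:
        return TerminusFit(
            species_id, sample_id, ter, ori, "segmented", True, b0
        )
    return TerminusFit(
        species_id, sample_id, median_cov, median_cov, "median", False
    )


def fit_all_termini(
    gene_coverage: pd.DataFrame, core_only: bool = True
) -> list[TerminusFit]:
    """Fit terminus coverage for every (species, sample) in a coverage table."""
    df = gene_coverage
    if core_only:
        df = df[df["is_core"].astype(bool)]
    fits = []
    for (species, sample), grp in df.groupby(
        ["species_id", "sample_id"], sort=True
    ):
        fits.append(
            fit_terminus_coverage(
                grp["position_fraction"].to_numpy(),
                grp["coverage"].to_numpy(),
                species_id=str(species),
                sample_id=str(sample),
            )
        )
    return fits


def terminus_fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": f.species_id,
                "sample_id": f.sample_id,
                "ter_coverage": f.ter_coverage,
                "ori_coverage": f.ori_coverage,
                "method": f.method,
                "valid": f.valid,
                "breakpoint": f.breakpoint if f.breakpoint is not None
                else np.nan,
            }
            for f in fits
        ]
    )


def relative_abundance(fits) -> pd.Series:
    """Relative abundance of species within one sample from terminus fits."""
    ter = pd.Series(
        {f.species_id: f.ter_coverage for f in fits}, dtype=float
    ).sort_index()
    total = ter.sum()
    if total <= 0:
        raise ValueError("sample has no species with positive terminus coverage")
    return ter / total


def relative_abundance_matrix(fits) -> pd.DataFrame:
    """Samples x species relative abundance matrix (rows sum to 1)."""
    by_sample: dict[str, list[TerminusFit]] = {}
    for f in fits:
        by_sample.setdefault(f.sample_id, []).append(f)
    rows = {s: relative_abundance(fs) for s, fs in sorted(by_sample.items())}
    mat = pd.DataFrame(rows).T.fillna(0.0)
    mat.index.name = "sample_id"
    return mat


def absolute_abundance(
    relative: pd.DataFrame, loads: dict[str, BacterialLoad] | pd.Series
) -> pd.DataFrame:
    """Proportions scaled by each sample's bacterial load (copies per ng)."""
    if isinstance(loads, dict):
        loads = pd.Series(
            {sid: l.copies_per_ng for sid, l in loads.items()}, dtype=float
        )
    missing = [s for s in relative.index if s not in loads.index]
    if missing:
        raise ValueError(f"bacterial load missing for samples: {missing}")
    return relative.mul(loads.loc[relative.index], axis=0)


def _colony_pairs(samples) -> list[tuple[str, str, str]]:
    """(colony_id, nurse_sample, forager_sample) triples, sorted by colony."""
    validate_paired_design(samples)
    by_colony: dict[str, dict[str, str]] = {}
    for s in samples:
        by_colony.setdefault(s.colony_id, {})[s.state] = s.sample_id
    return [
        (colony, states["nurse"], states["forager"])
        for colony, states in sorted(by_colony.items())
    ]


def paired_log2fc(
    absolute: pd.DataFrame, samples: list[SampleRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-species paired forager-vs-nurse log2 fold changes.

    For every colony, log2(forager / nurse) of the absolute abundance;
    infinite values (a zero nurse abundance with non-zero forager, or the
    converse) are excluded from the reported median with a warning. Per
    species a paired Wilcoxon test is run on the abundances and q-values are
    computed across species.
    """
    pairs = _colony_pairs(samples)
    rows = []
    for species in absolute.columns:
        lfcs = []
        nurse_vals, forager_vals = [], []
        for colony, nurse, forager in pairs:
            n_val = float(absolute.loc[nurse, species])
            f_val = float(absolute.loc[forager, species])
            nurse_vals.append(n_val)
            forager_vals.append(f_val)
            if n_val == 0 and f_val == 0:
                lfc = np.nan
            elif n_val == 0:
                lfc = np.inf
            elif f_val == 0:
                lfc = -np.inf
            else:
                lfc = np.log2(f_val / n_val)
            lfcs.append(lfc)
        lfcs = np.asarray(lfcs, dtype=float)
        finite = lfcs[np.isfinite(lfcs)]
        if finite.size < lfcs.size:
            warnings.warn(
                f"{species}: {lfcs.size - finite.size} infinite/undefined "
                "log2FC value(s) excluded from the median",
                stacklevel=2,
            )
        _, p = wilcoxon_signed_rank_paired(forager_vals, nurse_vals)
        rows.append(
            {
                "species_id": species,
                "median_log2fc": float(np.median(finite))
                if finite.size
                else np.nan,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = qvalues(result["p"].to_numpy())
    result["significant"] = result["q"] < alpha
    return result


def paired_log2fc_values(
    absolute: pd.DataFrame, samples: list[SampleRecord]
) -> pd.DataFrame:
    """Per-colony log2(F/N) values (species x colony), infinities kept."""
    pairs = _colony_pairs(samples)
    data = {}
    for colony, nurse, forager in pairs:
        with np.errstate(divide="ignore", invalid="ignore"):
            data[colony] = np.log2(
                absolute.loc[forager].to_numpy()
                / absolute.loc[nurse].to_numpy()
            )
    return pd.DataFrame(data, index=absolute.columns)


def phylotype_aggregate(
    species_matrix: pd.DataFrame, species_to_phylotype: dict[str, str]
) -> pd.DataFrame:
    """Sum species columns into phylotype columns (row sums preserved)."""
    unmapped = [s for s in species_matrix.columns if s not in species_to_phylotype]
    if unmapped:
        raise ValueError(f"species without phylotype mapping: {unmapped}")
    return species_matrix.T.groupby(
        species_matrix.columns.map(species_to_phylotype)
    ).sum().T


def shannon_within_phylotype(
    species_matrix: pd.DataFrame,
    phylotype: str,
    species_to_phylotype: dict[str, str],
    samples: list[SampleRecord] | None = None,
) -> tuple[pd.Series, float | None]:
    """Shannon diversity over one phylotype's renormalized species proportions.

    H = -sum p ln p per sample; samples where the phylotype is entirely
    absent are excluded. If sample records are given, a paired nurse/forager
    Wilcoxon p-value on H is returned as the second element.
    """
    members = [
        s for s in species_matrix.columns
        if species_to_phylotype.get(s) == phylotype
    ]
    if len(members) < 2:
        raise ValueError(
            f"phylotype {phylotype!r} has fewer than 2 species in the matrix"
        )
    sub = species_matrix[members]
    totals = sub.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        warnings.warn(
            f"{(~keep).sum()} sample(s) lack phylotype {phylotype!r}; "
            "Shannon index undefined, excluded",
            stacklevel=2,
        )
    props = sub.loc[keep].div(totals[keep], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(props > 0, np.log(props.to_numpy(dtype=float)), 0.0)
    h = pd.Series(
        -(props.to_numpy() * logs).sum(axis=1), index=props.index, name="H"
    )
    p = None
    if samples is not None:
        pairs = _colony_pairs(samples)
        nurse = [h[n] for _, n, f in pairs if n in h.index and f in h.index]
        forager = [h[f] for _, n, f in pairs if n in h.index and f in h.index]
        if nurse:
            _, p = wilcoxon_signed_rank_paired(nurse, forager)
    return h, p
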