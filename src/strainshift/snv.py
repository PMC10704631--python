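"""Strain-level diversity statistics from pooled allele observations.

An allele is detected at a core-genome site when at least 2 reads support it
and its within-sample frequency is at least 0.01; a site is polymorphic when
two or more alleles are detected, regardless of the reference base. Pairwise
sample distances are one minus the fraction of shared polymorphic sites,
where a site is shared only when the two samples' detected allele sets
intersect in at least two alleles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "PolymorphismSummary",
    "detect_alleles",
    "polymorphic_sites",
    "fraction_polymorphic",
    "cumulative_polymorphic_curve",
    "shared_fraction",
    "snv_distance_matrix",
]

MIN_READS = 2
MIN_FREQ = 0.01
MIN_TER_COVERAGE = 20.0


@dataclass(frozen=True)
class PolymorphismSummary:
    species_id: str
    sample_id: str
    n_polymorphic: int
    core_len_filtered: int
    fraction: float  # percent


DetectedMap = dict[int, frozenset]  # site -> detected alleles


def detect_alleles(
    observations: pd.DataFrame,
    min_reads: int = MIN_READS,
    min_freq: float = MIN_FREQ,
) -> dict[tuple[str, str], DetectedMap]:
    """Detected allele sets per (species, sample).

    ``observations`` is the long-format allele observation table (columns
    species_id, site, ref_allele, sample_id, allele, count). An allele is
    detected iff its read count is >= ``min_reads`` AND its frequency —
    count over the total site depth in that sample — is >= ``min_freq``.
    The reference allele is treated exactly like any alternate.
    """
    obs = observations
    depth = obs.groupby(["species_id", "sample_id", "site"])["count"].transform(
        "sum"
    )
    with np.errstate(invalid="ignore"):
        freq = obs["count"] / depth
    hit = (obs["count"] >= min_reads) & (freq >= min_freq)
    detected: dict[tuple[str, str], dict[int, set]] = {}
    sub = obs[hit]
    for row in sub.itertuples(index=False):
        key = (row.species_id, row.sample_id)
        detected.setdefault(key, {}).setdefault(int(row.site), set()).add(
            row.allele
        )
    return {
        key: {site: frozenset(al) for site, al in sites.items()}
        for key, sites in detected.items()
    }


def polymorphic_sites(
    detected: DetectedMap,
    site_mask: set[int] | None = None,
) -> set[int]:
    """Sites with >= 2 detected alleles, optionally restricted to a mask of
    adequately covered sites."""
    poly = {site for site, alleles in detected.items() if len(alleles) >= 2}
    if site_mask is not None:
        poly &= site_mask
    return poly


def species_passes_coverage(ter_coverage: float,
                            min_ter_coverage: float = MIN_TER_COVERAGE) -> bool:
    """Species are analyzed only above the terminus-coverage floor
    (strictly more than 20x by default)."""
    return ter_coverage > min_ter_coverage


def fraction_polymorphic(
    sites: set[int],
    core_len_filtered: int,
    species_id: str = "",
    sample_id: str = "",
) -> PolymorphismSummary:
    """Polymorphic sites as a percentage of the filtered core-genome length.

    ``core_len_filtered`` counts only bases of single-copy core genes that
    passed the per-gene coverage floor (>= 10x).
    """
    if core_len_filtered <= 0:
        raise ValueError("filtered core length must be positive")
    return PolymorphismSummary(
        species_id=species_id,
        sample_id=sample_id,
        n_polymorphic=len(sites),
        core_len_filtered=int(core_len_filtered),
        fraction=100.0 * len(sites) / core_len_filtered,
    )


def cumulative_polymorphic_curve(
    site_sets: list[set[int]],
    core_len_filtered: int,
    n_orders: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean cumulative polymorphic-site fraction over random sample orders.

    For each of ``n_orders`` random permutations of the samples, the running
    union of polymorphic sites is converted to a percent fraction of the
    filtered core length; the curves are averaged pointwise. The final point
    is order-invariant (the union over all samples).
    """
    if not site_sets:
        raise ValueError("need at least one sample")
    if core_len_filtered <= 0:
        raise ValueError("filtered core length must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n = len(site_sets)
    curves = np.zeros((n_orders, n), dtype=float)
    for o in range(n_orders):
        order = rng.permutation(n)
        running: set[int] = set()
        for k, idx in enumerate(order):
            running |= site_sets[idx]
            curves[o, k] = 100.0 * len(running) / core_len_filtered
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n + 1),
            "mean_cumulative_fraction": curves.mean(axis=0),
        }
    )


def shared_fraction(
    detected1: DetectedMap,
    detected2: DetectedMap,
    mask1: set[int] | None = None,
    mask2: set[int] | None = None,
) -> tuple[int, int, float]:
    """Shared polymorphic sites between two samples of one species.

    The universe is the set of sites polymorphic (>= 2 detected alleles) in
    at least one of the two samples; a site is *shared* iff the two detected
    allele sets intersect in at least two alleles. When coverage masks are
    given, sites lacking adequate coverage in either sample are excluded
    from the universe. Returns ``(n_shared, n_union, shared_fraction)``;
    with an empty universe the shared fraction is defined as 1 (distance 0)
    with a warning.
    """
    poly1 = polymorphic_sites(detected1, mask1)
    poly2 = polymorphic_sites(detected2, mask2)
    union = poly1 | poly2
    if mask1 is not None:
        union &= mask1
    if mask2 is not None:
        union &= mask2
    if not union:
        warnings.warn(
            "no polymorphic site in either sample: shared fraction set to 1 "
            "(no evidence of difference)",
            stacklevel=2,
        )
        return 0, 0, 1.0
    n_shared = sum(
        1
        for site in union
        if len(detected1.get(site, frozenset()) & detected2.get(site, frozenset()))
        >= 2
    )
    return n_shared, len(union), n_shared / len(union)


def snv_distance_matrix(
    detected_by_sample: dict[str, DetectedMap],
    masks: dict[str, set[int]] | None = None,
) -> DistanceMatrix:
    """Pairwise 1 - shared-fraction distances across samples of one species.

    Symmetric with zero diagonal, values in [0, 1]. The triangle inequality
    is not guaranteed (Jaccard-type on allele sets need not be metric).
    """
    labels = sorted(detected_by_sample)
    if len(labels) < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            m1 = masks.get(labels[i]) if masks else None
            m2 = masks.get(labels[j]) if masks else None
            _, _, frac = shared_fraction(
                detected_by_sample[labels[i]],
                detected_by_sample[labels[j]],
                m1,
                m2,
            )
            d[i, j] = d[j, i] = 1.0 - frac
    return DistanceMatrix(labels, d)


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "sample_id": s.sample_id,
                "n_polymorphic": s.n_polymorphic,
                "core_len_filtered": s.core_len_filtered,
                "fraction": s.fraction,
            }
            for s in summaries
        ]
    )
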