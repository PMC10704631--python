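"""qPCR copy-number computation and normalized bacterial loads.

Copy numbers come from the standard-curve transform
``copies = 10 ** ((Ct - intercept) / slope)`` with replicate Cts averaged
before the power transform; loads are 16S copies normalized per ng of total
DNA extracted from the pooled gut sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_filters import SampleRecord, validate_paired_design
from .stats import wilcoxon_signed_rank_paired

__all__ = [
    "QpcrMeasurement",
    "BacterialLoad",
    "gene_copy_number",
    "bacterial_load",
    "compare_paired_loads",
    "read_qpcr_csv",
    "loads_to_frame",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target: str  # "16S" | "actin"
    ct_replicates: tuple[float, ...]
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if len(self.ct_replicates) < 1:
            raise ValueError("need at least one Ct replicate")
        if self.slope == 0:
            raise ValueError("slope must be non-zero")

    @property
    def ct_mean(self) -> float:
        return float(np.mean(self.ct_replicates))

    @property
    def ct_sd(self) -> float:
        return float(np.std(self.ct_replicates, ddof=1)) if len(
            self.ct_replicates
        ) > 1 else 0.0

    def copies(self) -> float:
        return gene_copy_number(self.ct_replicates, self.slope, self.intercept)


@dataclass(frozen=True)
class BacterialLoad:
    sample_id: str
    copies_16s: float
    copies_per_ng: float

    def __post_init__(self) -> None:
        if self.copies_16s < 0 or self.copies_per_ng < 0:
            raise ValueError("loads must be non-negative")


def gene_copy_number(
    ct: float | Iterable[float], slope: float, intercept: float
) -> float:
    """Absolute gene copy number from cycle threshold(s).

    ``copies = 10 ** ((Ct - intercept) / slope)``; an iterable of replicate
    Cts is averaged before the transform.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    ct_val = float(np.mean(np.asarray(list(ct) if np.iterable(ct) else [ct],
                                      dtype=float)))
    return float(10.0 ** ((ct_val - intercept) / slope))


def bacterial_load(copies_16s: float, dna_ng: float,
                   sample_id: str = "") -> BacterialLoad:
    """Normalize 16S copies by total DNA yield (ng)."""
    if dna_ng <= 0:
        raise ValueError("DNA yield must be positive")
    if copies_16s < 0:
        raise ValueError("copy number must be non-negative")
    return BacterialLoad(
        sample_id=sample_id,
        copies_16s=float(copies_16s),
        copies_per_ng=float(copies_16s) / float(dna_ng),
    )


def compare_paired_loads(
    loads: Sequence[BacterialLoad], samples: Sequence[SampleRecord]
) -> tuple[pd.DataFrame, float, float]:
    """Per-colony nurse/forager load ratios and a paired Wilcoxon test.

    Returns ``(ratio table, mean ratio, p)``. The ratio is nurse over
    forager copies-per-ng, i.e. the factor by which the forager load is
    reduced (a planted 2.6x nurse excess gives mean ratio 2.6).
    """
    validate_paired_design(samples)
    by_id = {l.sample_id: l for l in loads}
    missing = [s.sample_id for s in samples if s.sample_id not in by_id]
    if missing:
        raise ValueError(f"loads missing for samples: {missing}")
    pairs: dict[str, dict[str, float]] = {}
    for s in samples:
        pairs.setdefault(s.colony_id, {})[s.state] = by_id[
            s.sample_id
        ].copies_per_ng
    rows = []
    for colony, states in sorted(pairs.items()):
        nurse, forager = states["nurse"], states["forager"]
        ratio = np.inf if forager == 0 else nurse / forager
        rows.append(
            {"colony_id": colony, "nurse": nurse, "forager": forager,
             "ratio": ratio}
        )
    table = pd.DataFrame(rows)
    finite = table["ratio"][np.isfinite(table["ratio"])]
    mean_ratio = float(finite.mean()) if len(finite) else np.nan
    _, p = wilcoxon_signed_rank_paired(
        table["nurse"].to_numpy(), table["forager"].to_numpy()
    )
    return table, mean_ratio, p


def read_qpcr_csv(path) -> list[QpcrMeasurement]:
    """Read qPCR exports: sample_id, target, ct_1..ct_k, slope, intercept."""
    df = pd.read_csv(path)
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    required = {"sample_id", "target", "slope", "intercept"}
    missing = required - set(df.columns)
    if missing or not ct_cols:
        raise ValueError(
            f"qPCR table needs columns {sorted(required)} plus ct_* replicates"
        )
    out = []
    for r in df.itertuples(index=False):
        cts = tuple(
            float(getattr(r, c)) for c in ct_cols
            if np.isfinite(getattr(r, c))
        )
        out.append(
            QpcrMeasurement(
                sample_id=str(r.sample_id),
                target=str(r.target),
                ct_replicates=cts,
                slope=float(r.slope),
                intercept=float(r.intercept),
            )
        )
    return out


def loads_to_frame(loads: Sequence[BacterialLoad]) -> pd.DataFrame:
    return pd.DataFrame(
        [l.__dict__ for l in loads],
        columns=["sample_id", "copies_16s", "copies_per_ng"],
    )
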