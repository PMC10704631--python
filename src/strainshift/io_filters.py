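"""Readers/writers for the standard formats touched by the pipeline, and the
alignment / blast-hit filtering rules applied before any quantification.

Coordinate conventions: 0-based half-open everywhere internally; VCF is
1-based at the boundary (converted on read/write); BED-like tables are
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "AlignmentRecord",
    "BlastHitRecord",
    "SampleRecord",
    "cigar_match_length",
    "filter_alignments",
    "filter_blast_hits",
    "read_sam",
    "read_blast_hits",
    "read_core_regions",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_allele_observations",
]

SUPPLEMENTARY_FLAG = 0x800

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL = re.compile(r"^(?:\d+[MIDNSHP=X])+$")

#: columns of the long-format allele observation table
ALLELE_OBS_COLUMNS = [
    "species_id",
    "site",
    "ref_allele",
    "sample_id",
    "allele",
    "count",
]


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    target_id: str
    cigar: str
    flags: int = 0
    nm: int | None = None


@dataclass(frozen=True)
class BlastHitRecord:
    query_orf: str
    subject_gene: str
    subject_species: str
    evalue: float
    pident: float
    qcovs: float


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    state: str  # "nurse" | "forager"
    colony_id: str
    location_id: str
    n_guts: int = 1
    pool_mass: float = 1.0  # mg
    dna_yield: float = 1.0  # ng

    def __post_init__(self) -> None:
        if self.state not in ("nurse", "forager"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.pool_mass <= 0 or self.dna_yield <= 0:
            raise ValueError("pool mass and DNA yield must be positive")


def cigar_match_length(cigar: str) -> int:
    """Total length of alignment-match operations (M, =, X) in a CIGAR.

    Clipping, insertions, deletions and skips do not count. Raises
    ``ValueError`` on a malformed or unavailable ('*') CIGAR string.
    """
    if not isinstance(cigar, str) or not _CIGAR_FULL.match(cigar):
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return sum(
        int(n) for n, op in _CIGAR_TOKEN.findall(cigar) if op in "M=X"
    )


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_matches: int = 51,
    max_mismatches: int | None = None,
    drop_supplementary: bool = True,
) -> list[AlignmentRecord]:
    """Apply the alignment filters used before coverage/variant analysis.

    Keeps records whose CIGAR match length is at least ``min_matches``
    (default 51, i.e. alignments with 50 matches or fewer are removed).
    When ``max_mismatches`` is set (SNV mode uses 5) the NM edit-distance tag
    must be present and <= the threshold. Supplementary/chimeric alignments
    (flag 0x800) are removed by default.
    """
    kept = []
    for rec in records:
        if drop_supplementary and rec.flags & SUPPLEMENTARY_FLAG:
            continue
        if cigar_match_length(rec.cigar) < min_matches:
            continue
        if max_mismatches is not None:
            if rec.nm is None:
                raise ValueError(
                    f"record {rec.read_id!r} lacks NM tag but a mismatch "
                    "filter was requested"
                )
            if rec.nm > max_mismatches:
                continue
        kept.append(rec)
    return kept


def filter_blast_hits(
    records: Iterable[BlastHitRecord],
    max_evalue: float = 1e-5,
    min_pident: float = 50.0,
    min_qcovs: float = 50.0,
) -> list[BlastHitRecord]:
    """Keep hits with evalue < max_evalue, pident > min_pident and
    qcovs > min_qcovs (all strict inequalities)."""
    return [
        r
        for r in records
        if r.evalue < max_evalue and r.pident > min_pident and r.qcovs > min_qcovs
    ]


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM/BAM file (unmapped reads skipped)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigarstring is None:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            yield AlignmentRecord(
                read_id=aln.query_name,
                target_id=aln.reference_name,
                cigar=aln.cigarstring,
                flags=aln.flag,
                nm=nm,
            )


def read_blast_hits(path) -> list[BlastHitRecord]:
    """Read a tabular blast-hit file.

    Expected header: query_orf, subject_gene, subject_species, evalue,
    pident, qcovs (extra columns ignored).
    """
    df = pd.read_csv(path, sep="\t")
    required = [
        "query_orf",
        "subject_gene",
        "subject_species",
        "evalue",
        "pident",
        "qcovs",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"blast hit table missing columns: {missing}")
    return [
        BlastHitRecord(
            query_orf=str(r.query_orf),
            subject_gene=str(r.subject_gene),
            subject_species=str(r.subject_species),
            evalue=float(r.evalue),
            pident=float(r.pident),
            qcovs=float(r.qcovs),
        )
        for r in df.itertuples(index=False)
    ]


def read_core_regions(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file of single-copy-core gene regions.

    Returns chrom -> sorted list of (start, end), 0-based half-open.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"empty/inverted BED interval: {line!r}")
            regions.setdefault(chrom, []).append((start, end))
    for chrom in regions:
        regions[chrom].sort()
    return regions


def _in_regions(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    for start, end in intervals:
        if start <= pos < end:
            return True
        if start > pos:
            break
    return False


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id",
    "state",
    "colony_id",
    "location_id",
    "n_guts",
    "pool_mass",
    "dna_yield",
]


def read_sample_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    records = [
        SampleRecord(
            sample_id=str(r.sample_id),
            state=str(r.state),
            colony_id=str(r.colony_id),
            location_id=str(r.location_id),
            n_guts=int(r.n_guts),
            pool_mass=float(r.pool_mass),
            dna_yield=float(r.dna_yield),
        )
        for r in df.itertuples(index=False)
    ]
    validate_paired_design(records)
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records])[_META_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def validate_paired_design(records: Sequence[SampleRecord]) -> None:
    """Each colony must contribute exactly one nurse and one forager sample."""
    by_colony: dict[str, list[str]] = {}
    for r in records:
        by_colony.setdefault(r.colony_id, []).append(r.state)
    for colony, states in by_colony.items():
        if sorted(states) != ["forager", "nurse"]:
            raise ValueError(
                f"colony {colony!r} is not a nurse/forager pair: {states}"
            )


def samples_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])[_META_COLUMNS]


# ---------------------------------------------------------------------------
# VCF -> allele observations
# ---------------------------------------------------------------------------

_BASES = frozenset("ACGT")


def _primitive_snvs(ref: str, alt: str) -> list[tuple[int, str, str]]:
    """Decompose an equal-length REF/ALT pair into primitive SNVs.

    Returns (offset, ref_base, alt_base) for every position where the
    alleles differ. Length-changing (indel) alleles yield nothing.
    """
    if len(ref) != len(alt):
        return []
    out = []
    for i, (rb, ab) in enumerate(zip(ref.upper(), alt.upper())):
        if rb != ab and rb in _BASES and ab in _BASES:
            out.append((i, rb, ab))
    return out


def read_allele_observations(
    vcf_path,
    core_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Build a long-format allele observation table from a VCF.

    Requires per-sample RO (reference observation count) and AO (per-alt
    observation counts) FORMAT fields. Multi-allelic records are decomposed
    into one observation per alternate allele; complex equal-length alleles
    are reduced to primitive SNVs (the alt count is attributed to each
    differing position); indel alleles are dropped. When ``core_regions`` is
    given only sites inside those (0-based half-open) intervals are kept.

    Returns a DataFrame with columns ``species_id, site, ref_allele,
    sample_id, allele, count`` — one row per (site, sample, allele) with
    the reference allele included. Sites are 0-based.
    """
    rows: list[tuple] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_names = list(vcf.header.samples)
        if not sample_names:
            raise ValueError(f"VCF {vcf_path} has no samples")
        for rec in vcf:
            chrom = rec.chrom
            pos0 = rec.pos - 1  # 1-based VCF -> 0-based internal
            ref = rec.ref
            alts = rec.alts or ()
            for name in sample_names:
                fmt = rec.samples[name]
                if "RO" not in fmt or "AO" not in fmt:
                    raise ValueError(
                        f"VCF record {chrom}:{rec.pos} lacks RO/AO counts"
                    )
                ro = fmt["RO"]
                ao = fmt["AO"]
                if not isinstance(ao, tuple):
                    ao = (ao,)
                # per-site accumulation: position -> allele -> count
                per_site: dict[int, dict[str, int]] = {}
                if len(ref) == 1 and ref.upper() in _BASES:
                    per_site.setdefault(pos0, {})[ref.upper()] = int(ro or 0)
                for alt, count in zip(alts, ao):
                    if alt is None or count is None:
                        continue
                    for off, rb, ab in _primitive_snvs(ref, alt):
                        site = pos0 + off
                        site_map = per_site.setdefault(site, {})
                        site_map.setdefault(rb, int(ro or 0))
                        site_map[ab] = site_map.get(ab, 0) + int(count)
                for site, allele_map in per_site.items():
                    if core_regions is not None:
                        intervals = core_regions.get(chrom, ())
                        if not _in_regions(site, intervals):
                            continue
                    ref_base = ref[site - pos0].upper()
                    for allele, count in allele_map.items():
                        rows.append(
                            (chrom, site, ref_base, name, allele, count)
                        )
    return pd.DataFrame(rows, columns=ALLELE_OBS_COLUMNS)


def read_allele_observations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"allele observation table missing columns: {missing}")
    return df[ALLELE_OBS_COLUMNS]
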