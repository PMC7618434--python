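"""Single-molecule 6mA density within CDRs and target-over-IgG enrichment.

For every read overlapping a CDR interval by at least 10 kb (on a
non-excluded contig), the 6mA sites falling inside the half-open overlap
are counted and expressed per 10 kb of overlapping CDR sequence. Enrichment
divides the mean target density by the mean IgG control density per CDR; a
control mean of zero yields an explicitly undefined ratio, never a silent
infinity. Density is depth-free by construction, so no library-size
normalization is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import GenomicInterval, MoleculeRead

__all__ = [
    "DensityParams",
    "DensityRecord",
    "EnrichmentRecord",
    "per_read_density",
    "enrichment",
]

#: contigs dropped from all density analyses; an entry without a haplotype
#: suffix (e.g. "chr18") excludes every haplotype of that chromosome
DEFAULT_EXCLUDED = frozenset({"chr4_2", "chr18", "chrX_2", "chr13_2", "chr21_2"})


@dataclass(frozen=True)
class DensityParams:
    min_overlap: int = 10_000  # bp of read/CDR overlap required
    density_unit: int = 10_000  # report sites per this many bp
    excluded_chroms: frozenset[str] = DEFAULT_EXCLUDED

    def __post_init__(self):
        if self.min_overlap < 1 or self.density_unit < 1:
            raise ValueError("min_overlap and density_unit must be >= 1")

    def is_excluded(self, chrom: str) -> bool:
        return any(
            chrom == name or chrom.startswith(name + "_")
            for name in self.excluded_chroms
        )


@dataclass(frozen=True)
class DensityRecord:
    read_id: str
    cdr_id: str
    overlap_len: int
    n_mods: int
    density: float  # sites per density_unit bp


@dataclass(frozen=True)
class EnrichmentRecord:
    cdr_id: str
    target_mean_density: float
    control_mean_density: float
    enrichment_ratio: float | None  # None when the control mean is zero/absent

    @property
    def defined(self) -> bool:
        return self.enrichment_ratio is not None


def per_read_density(
    reads: Iterable[MoleculeRead],
    cdrs: Sequence[tuple[GenomicInterval, str]],
    params: DensityParams = DensityParams(),
) -> list[DensityRecord]:
    """Per-molecule 6mA density over read/CDR overlaps.

    ``cdrs`` is a sequence of (interval, cdr_id) pairs, typically merged
    locus spans. A mod site at the CDR end coordinate is outside (half-open
    intersection). Reads on excluded contigs never produce records.
    """
    records = []
    for read in reads:
        if params.is_excluded(read.chrom):
            continue
        positions = read.mod_positions()
        for iv, cdr_id in cdrs:
            ov = read.interval.overlap(iv)
            if ov < params.min_overlap:
                continue
            lo, hi = max(read.start, iv.start), min(read.end, iv.end)
            n = int(np.count_nonzero((positions >= lo) & (positions < hi)))
            records.append(
                DensityRecord(
                    read_id=read.read_id,
                    cdr_id=cdr_id,
                    overlap_len=ov,
                    n_mods=n,
                    density=n * params.density_unit / ov,
                )
            )
    return records


def enrichment(
    target: Sequence[DensityRecord],
    control: Sequence[DensityRecord],
    pooled: bool = False,
) -> list[EnrichmentRecord]:
    """Target-over-control ratio of mean per-read densities.

    Grouped per cdr_id by default (matched controls); ``pooled=True``
    collapses everything into a single group "all". CDRs absent from the
    control, or with a zero control mean, are reported with an undefined
    ratio.
    """

    def group(recs):
        out: dict[str, list[float]] = {}
        for r in recs:
            key = "all" if pooled else r.cdr_id
            out.setdefault(key, []).append(r.density)
        return out

    tgt, ctl = group(target), group(control)
    records = []
    for cdr_id in sorted(tgt):
        t_mean = float(np.mean(tgt[cdr_id]))
        c_vals = ctl.get(cdr_id)
        c_mean = float(np.mean(c_vals)) if c_vals else 0.0
        ratio = t_mean / c_mean if c_mean > 0 else None
        records.append(
            EnrichmentRecord(
                cdr_id=cdr_id,
                target_mean_density=t_mean,
                control_mean_density=c_mean,
                enrichment_ratio=ratio,
            )
        )
    return records


def density_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    """Per-read densities as a DataFrame (box-plot ready)."""
    return pd.DataFrame(
        [
            (r.read_id, r.cdr_id, r.overlap_len, r.n_mods, r.density)
            for r in records
        ],
        columns=["read_id", "cdr_id", "overlap_len", "n_mods", "density"],
    )
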