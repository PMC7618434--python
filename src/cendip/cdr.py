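"""Centromere dip region (CDR) detection and classification.

CDRs are localized dips in the 5mCG fraction-modified track within an
otherwise hypermethylated active alpha-satellite HOR array. Detection works
on a binned 5mCG track restricted to one active HOR:

1. smooth with a centered rolling mean (default 5-kb window);
2. find local minima of the smoothed trace;
3. keep a minimum when its depth below the regional median is at least
   ``height_perc_valley_threshold`` (default 0.39) times the median and its
   topographic prominence is at least ``prom_perc_valley_threshold``
   (default 0.45) times the median;
4. the valley extent is the maximal interval around the minimum where the
   smoothed signal stays below ``median - depth/2`` (half-depth recovery).

Both percentage thresholds are interpreted as fractions of the regional
median signal. Detected valleys within 500 kb of each other are merged into
one centromere locus; loci are classified as primary (match an annotated
parent CDR), new (carry CENP-A but match no parent CDR) or discarded (no
CENP-A anywhere — the deterministic stand-in for manual curation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigurationError, NoDataError, UndefinedRatioError
from .tracks import BinnedTrack, GenomicInterval

__all__ = [
    "ValleyParams",
    "CdrCall",
    "CdrLocus",
    "CdrSizeReport",
    "detect_valleys",
    "merge_into_loci",
    "classify_loci",
    "cdr_size_change",
]


@dataclass(frozen=True)
class ValleyParams:
    smooth_window: int = 5_000  # bp
    height_perc_valley_threshold: float = 0.39
    prom_perc_valley_threshold: float = 0.45
    merge_distance: int = 500_000  # bp

    def __post_init__(self):
        if not (0.0 < self.height_perc_valley_threshold < 1.0):
            raise ConfigurationError("height threshold must be in (0, 1)")
        if not (0.0 < self.prom_perc_valley_threshold < 1.0):
            raise ConfigurationError("prominence threshold must be in (0, 1)")
        if self.smooth_window < 1 or self.merge_distance < 0:
            raise ConfigurationError("invalid smoothing/merge parameters")


@dataclass(frozen=True)
class CdrCall:
    """One detected 5mCG valley."""

    interval: GenomicInterval
    depth: float  # signal units below regional median
    prominence: float
    contains_cenpa: bool = False

    def __post_init__(self):
        if self.depth < 0 or self.prominence < 0:
            raise ValueError("depth and prominence must be >= 0")


@dataclass(frozen=True)
class CdrLocus:
    """CDR calls within merge distance of each other, one centromere locus."""

    member_cdrs: tuple[CdrCall, ...]
    span: GenomicInterval
    status: str | None = None  # primary | new | discarded | None (unclassified)

    @property
    def total_cdr_bp(self) -> int:
        return sum(len(c.interval) for c in self.member_cdrs)


@dataclass(frozen=True)
class CdrSizeReport:
    """Per-centromere CDR length comparison against a parent sample."""

    entries: tuple[tuple[str, int, int, float], ...]  # (id, parent, sample, ratio)
    mean_percent_change: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            list(self.entries),
            columns=["centromere", "parent_bp", "sample_bp", "ratio"],
        )
        df["percent_change"] = (df["ratio"] - 1.0) * 100.0
        return df


def detect_valleys(
    track_5mcg: BinnedTrack, params: ValleyParams = ValleyParams()
) -> list[CdrCall]:
    """Detect CDR valleys in a fraction-valued 5mCG track over one HOR."""
    vals = track_5mcg.values
    n_ok = int(np.sum(~np.isnan(vals)))
    if n_ok == 0:
        raise NoDataError("track is entirely missing")
    if n_ok < 3:
        raise NoDataError(f"need >= 3 non-missing bins, have {n_ok}")
    w = max(1, round(params.smooth_window / track_5mcg.bin_size))
    smoothed = (
        pd.Series(vals).rolling(w, center=True, min_periods=1).mean().to_numpy()
    )
    median = float(np.nanmedian(smoothed))
    # bins still missing after smoothing are pinned at the median so they can
    # neither form nor extend a valley
    filled = np.where(np.isnan(smoothed), median, smoothed)

    minima, props = find_peaks(-filled, prominence=0.0)
    raw_calls: list[CdrCall] = []
    for idx, prom in zip(minima, props["prominences"]):
        depth = median - filled[idx]
        if depth < params.height_perc_valley_threshold * median:
            continue
        if prom < params.prom_perc_valley_threshold * median:
            continue
        cut = median - 0.5 * depth
        lo = idx
        while lo > 0 and filled[lo - 1] < cut:
            lo -= 1
        hi = idx
        while hi < len(filled) - 1 and filled[hi + 1] < cut:
            hi += 1
        iv = GenomicInterval(
            track_5mcg.chrom,
            track_5mcg.bin_start(lo),
            track_5mcg.bin_start(hi) + track_5mcg.bin_size,
        )
        raw_calls.append(CdrCall(interval=iv, depth=float(depth), prominence=float(prom)))

    # two qualifying minima can share a half-depth basin; merge overlapping
    # extents keeping the deeper call's depth/prominence
    raw_calls.sort(key=lambda c: c.interval.start)
    merged: list[CdrCall] = []
    for call in raw_calls:
        if merged and call.interval.start < merged[-1].interval.end:
            prev = merged[-1]
            deeper = max(prev, call, key=lambda c: c.depth)
            merged[-1] = CdrCall(
                interval=GenomicInterval(
                    call.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, call.interval.end),
                ),
                depth=deeper.depth,
                prominence=deeper.prominence,
            )
        else:
            merged.append(call)
    return merged


def merge_into_loci(
    cdrs: Sequence[CdrCall], merge_distance: int = 500_000
) -> list[CdrLocus]:
    """Merge CDR calls whose gaps are under ``merge_distance`` into loci."""
    cdrs = sorted(cdrs, key=lambda c: c.interval.start)
    if not cdrs:
        return []
    chroms = {c.interval.chrom for c in cdrs}
    if len(chroms) > 1:
        raise ConfigurationError(f"calls span multiple contigs: {sorted(chroms)}")
    loci: list[CdrLocus] = []
    members = [cdrs[0]]
    for call in cdrs[1:]:
        gap = call.interval.start - members[-1].interval.end
        if gap < merge_distance:
            members.append(call)
        else:
            loci.append(_make_locus(members))
            members = [call]
    loci.append(_make_locus(members))
    return loci


def _make_locus(members: list[CdrCall]) -> CdrLocus:
    return CdrLocus(
        member_cdrs=tuple(members),
        span=GenomicInterval(
            members[0].interval.chrom,
            min(c.interval.start for c in members),
            max(c.interval.end for c in members),
        ),
    )


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on one contig (0 if they overlap)."""
    return max(a.start - b.end, b.start - a.end, 0)


def classify_loci(
    loci: Sequence[CdrLocus],
    parent_primary: Sequence[GenomicInterval],
    cenpa_domains: Sequence[GenomicInterval],
    merge_distance: int = 500_000,
    parent_match: str = "overlap_or_distance",
) -> list[CdrLocus]:
    """Assign primary / new / discarded status to each locus.

    A locus matching a parent primary CDR is primary; otherwise a locus
    intersecting a CENP-A domain is newly formed; a locus with no CENP-A is
    discarded. ``parent_match`` selects whether a parent match means
    overlapping or lying within ``merge_distance`` of a parent interval
    (default) or the distance rule alone (``"distance_only"``).
    """
    if parent_match not in ("overlap_or_distance", "distance_only"):
        raise ConfigurationError(f"unknown parent_match {parent_match!r}")
    out = []
    for locus in loci:
        members = tuple(
            replace(
                c,
                contains_cenpa=any(c.interval.overlap(d) > 0 for d in cenpa_domains),
            )
            for c in locus.member_cdrs
        )
        has_cenpa = any(m.contains_cenpa for m in members)
        if parent_match == "overlap_or_distance":
            is_primary = any(
                locus.span.overlap(p) > 0 or _gap(locus.span, p) < merge_distance
                for p in parent_primary
                if p.chrom == locus.span.chrom
            )
        else:
            is_primary = any(
                _gap(locus.span, p) < merge_distance
                for p in parent_primary
                if p.chrom == locus.span.chrom
            )
        if is_primary:
            status = "primary"
        elif has_cenpa:
            status = "new"
        else:
            status = "discarded"
        out.append(CdrLocus(member_cdrs=members, span=locus.span, status=status))
    return out


def cdr_size_change(
    sample_primary: Mapping[str, Sequence[GenomicInterval]],
    parent_primary: Mapping[str, Sequence[GenomicInterval]],
    excluded: Iterable[str] = (),
) -> CdrSizeReport:
    """Compare summed primary-CDR length per centromere against the parent.

    ``sample_primary``/``parent_primary`` map a centromere id to its primary
    CDR intervals. Centromeres in ``excluded`` are dropped before
    comparison. The report carries per-centromere sample/parent length
    ratios and the mean percent change across centromeres.
    """
    excluded = set(excluded)
    ids = sorted(set(parent_primary) - excluded)
    missing = [i for i in ids if i not in sample_primary]
    if missing:
        raise ConfigurationError(f"centromeres missing from sample: {missing}")
    entries = []
    changes = []
    for cen in ids:
        parent_bp = sum(len(iv) for iv in parent_primary[cen])
        sample_bp = sum(len(iv) for iv in sample_primary[cen])
        if parent_bp == 0:
            raise UndefinedRatioError(f"parent CDR total is zero for {cen}")
        ratio = sample_bp / parent_bp
        entries.append((cen, parent_bp, sample_bp, ratio))
        changes.append((ratio - 1.0) * 100.0)
    return CdrSizeReport(
        entries=tuple(entries),
        mean_percent_change=float(np.mean(changes)) if changes else float("nan"),
    )
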