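"""Length-normalized meta-region matrices and aggregate profiles.

Regions of differing length (active HORs, CDRs) are rescaled onto a fixed
number of bins so they can be stacked into heat-map matrices or averaged
into aggregate traces. Two presets mirror the two standard schemes:

* HOR rows: body normalized to 1,000 bins, ±1-Mb pericentromeric flanks in
  500 bins each (row length 2,000);
* CDR rows: body 200 bins, ±125-kb flanks in 125 bins each (row length 450).

Midpoint-centered aggregate traces use 100 bins per region with ±250-kb
flanks. Every output bin is the mean of covered track positions (overlap
weighted); bins with no data are NaN, and all means skip NaN. Heat-map
rows are sorted numerically by (chromosome, haplotype), e.g. chr1_hap1,
chr1_hap2, chr2_hap1, ...
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CendipError, CoordinateError, UndefinedRatioError
from .tracks import BinnedTrack, GenomicInterval

__all__ = [
    "ScalingScheme",
    "HOR_SCHEME",
    "CDR_SCHEME",
    "AGGREGATE_BINS",
    "AGGREGATE_FLANK_BP",
    "HeatmapMatrix",
    "AggregateProfile",
    "scale_region",
    "build_heatmap",
    "aggregate_profile",
    "inside_outside_ratio",
]


@dataclass(frozen=True)
class ScalingScheme:
    body_bins: int
    flank_bp: int
    flank_bins: int

    def __post_init__(self):
        if min(self.body_bins, self.flank_bins) < 1 or self.flank_bp < 1:
            raise ValueError("scheme counts and flank_bp must be >= 1")

    @property
    def row_length(self) -> int:
        return self.body_bins + 2 * self.flank_bins


HOR_SCHEME = ScalingScheme(body_bins=1_000, flank_bp=1_000_000, flank_bins=500)
CDR_SCHEME = ScalingScheme(body_bins=200, flank_bp=125_000, flank_bins=125)
AGGREGATE_BINS = 100
AGGREGATE_FLANK_BP = 250_000


@dataclass(frozen=True)
class HeatmapMatrix:
    row_labels: tuple[str, ...]
    matrix: np.ndarray  # shape (n_regions, row_length)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.row_labels))


@dataclass(frozen=True)
class AggregateProfile:
    center_definition: str  # "cdr_midpoint" | "cdr_boundary" | "point"
    flank_bp: int
    offsets_bp: np.ndarray  # bin-center offsets relative to the center
    mean: np.ndarray
    n: np.ndarray  # per-bin count of contributing regions
    per_region: np.ndarray  # shape (n_centers, n_bins)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _mean_or_nan(track: BinnedTrack, start: int, end: int) -> float:
    start = max(0, start)
    if end <= start:
        return float("nan")
    try:
        return track.mean_in(GenomicInterval(track.chrom, start, end))
    except (CoordinateError, ValueError):
        return float("nan")


def _resample_span(track: BinnedTrack, start: int, end: int, n_bins: int) -> np.ndarray:
    length = end - start
    edges = [_round_half_up(start + i * length / n_bins) for i in range(n_bins + 1)]
    return np.array(
        [_mean_or_nan(track, edges[i], edges[i + 1]) for i in range(n_bins)]
    )


def resample(track: BinnedTrack, region: GenomicInterval, n_bins: int) -> np.ndarray:
    """Uniformly rebin ``region`` of ``track`` into ``n_bins`` mean values.

    Fractional bin edges are resolved by rounding half-up to integer bp,
    which partitions the region without gaps or overlaps. Spans outside
    the track's coverage come back as NaN.
    """
    return _resample_span(track, region.start, region.end, n_bins)


def scale_region(
    track: BinnedTrack, region: GenomicInterval, scheme: ScalingScheme
) -> np.ndarray:
    """One heat-map row: left flank + scaled body + right flank."""
    left = _resample_span(
        track, region.start - scheme.flank_bp, region.start, scheme.flank_bins
    )
    body = _resample_span(track, region.start, region.end, scheme.body_bins)
    right = _resample_span(
        track, region.end, region.end + scheme.flank_bp, scheme.flank_bins
    )
    return np.concatenate([left, body, right])


_LABEL_RE = re.compile(r"chr(\w+?)_(?:hap)?(\d+)$", re.IGNORECASE)
_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def _label_key(label: str):
    m = _LABEL_RE.match(label)
    if not m:
        return (np.inf, 0, label)
    chrom, hap = m.groups()
    num = _SPECIAL.get(chrom.upper(), None)
    if num is None:
        try:
            num = int(chrom)
        except ValueError:
            return (np.inf, int(hap), label)
    return (num, int(hap), label)


def build_heatmap(
    tracks: Mapping[str, BinnedTrack],
    regions: Mapping[str, GenomicInterval],
    scheme: ScalingScheme,
) -> HeatmapMatrix:
    """Stack scaled rows for all regions, sorted numerically by label.

    ``tracks`` maps a region label to its signal track; a label present in
    ``regions`` but absent from ``tracks`` yields an all-NaN row (retained).
    """
    labels = list(regions)
    if len(set(labels)) != len(labels):
        raise CendipError("duplicate region labels")
    labels.sort(key=_label_key)
    rows = []
    for label in labels:
        track = tracks.get(label)
        if track is None:
            rows.append(np.full(scheme.row_length, np.nan))
        else:
            rows.append(scale_region(track, regions[label], scheme))
    return HeatmapMatrix(row_labels=tuple(labels), matrix=np.vstack(rows))


def aggregate_profile(
    track_or_tracks,
    centers: Sequence,
    flank_bp: int = AGGREGATE_FLANK_BP,
    n_bins: int = AGGREGATE_BINS,
    center_definition: str = "cdr_midpoint",
    flip: Sequence[bool] | None = None,
) -> AggregateProfile:
    """Mean trace over ±``flank_bp`` around each center, in ``n_bins`` bins.

    ``centers`` holds either intervals (their midpoints are used) or bp
    positions (e.g. CDR boundaries). ``track_or_tracks`` is a single track
    shared by all centers or one track per center. ``flip`` optionally
    mirrors individual traces before averaging so that, for boundary-
    centered profiles, the CDR interior always lies on the same side. The
    mean skips missing values and carries a per-bin contributing count.
    """
    if not centers:
        raise CendipError("need at least one center")
    if isinstance(track_or_tracks, BinnedTrack):
        tracks = [track_or_tracks] * len(centers)
    else:
        tracks = list(track_or_tracks)
        if len(tracks) != len(centers):
            raise CendipError("one track per center required")
    traces = []
    for i, (track, center) in enumerate(zip(tracks, centers)):
        point = center.midpoint if isinstance(center, GenomicInterval) else int(center)
        region = GenomicInterval(
            track.chrom, max(0, point - flank_bp), point + flank_bp
        )
        trace = resample(track, region, n_bins)
        if flip is not None and flip[i]:
            trace = trace[::-1]
        traces.append(trace)
    per_region = np.vstack(traces)
    n = np.sum(~np.isnan(per_region), axis=0)
    sums = np.nansum(np.where(np.isnan(per_region), 0.0, per_region), axis=0)
    mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    offsets = (np.arange(n_bins) + 0.5) * (2 * flank_bp / n_bins) - flank_bp
    return AggregateProfile(
        center_definition=center_definition,
        flank_bp=flank_bp,
        offsets_bp=offsets,
        mean=mean,
        n=n,
        per_region=per_region,
    )


def inside_outside_ratio(
    track: BinnedTrack, cdr: GenomicInterval, flank_bp: int = 100_000
) -> float | None:
    """Mean signal within the CDR over the pooled ±flank mean.

    Returns None (undefined-ratio flag) when the pooled flank mean is zero.
    A strictly positive constant track gives exactly 1.0.
    """
    inside = track.mean_in(cdr)
    left = GenomicInterval(cdr.chrom, max(0, cdr.start - flank_bp), cdr.start)
    right = GenomicInterval(cdr.chrom, cdr.end, cdr.end + flank_bp)
    flank_means, flank_weights = [], []
    for iv in (left, right):
        m = _mean_or_nan(track, iv.start, iv.end)
        if not np.isnan(m):
            flank_means.append(m)
            flank_weights.append(len(iv))
    if not flank_means:
        raise UndefinedRatioError("no flank data")
    pooled = float(np.average(flank_means, weights=flank_weights))
    if pooled <= 0:
        return None
    return float(inside / pooled)
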