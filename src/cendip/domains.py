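"""Seeded-expansion CENP-A/CENP-C domain calling.

A domain is called from a 6mA fraction track and one annotated CDR seed:
the threshold is 1% of the mean signal within the CDR; a window extending
30 kb beyond the CDR boundaries is loaded and smoothed with a 2-kb centered
rolling average; starting from the bin containing the CDR midpoint,
boundaries expand left and right until the smoothed signal first falls
below the threshold, or the window edge is reached (recorded in the
truncation flags). Expansion is contiguous — a single sub-threshold
smoothed bin terminates that side.

The 1% threshold is deliberately permissive; in practice the 30-kb window
is what bounds the call, which is why truncation flags are part of the
result rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDomainError, NoSignalError
from .tracks import BinnedTrack, GenomicInterval

__all__ = ["ExpansionParams", "DomainCall", "call_domain", "smooth_track"]


@dataclass(frozen=True)
class ExpansionParams:
    window_extension: int = 30_000  # bp beyond the CDR on each side
    smooth_window: int = 2_000  # bp rolling average
    threshold_fraction: float = 0.01  # of the within-CDR mean

    def __post_init__(self):
        if self.window_extension <= 0 or self.smooth_window <= 0:
            raise ConfigurationError("window/smoothing must be positive")
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ConfigurationError("threshold_fraction must be in (0, 1)")


@dataclass(frozen=True)
class DomainCall:
    interval: GenomicInterval
    seed_cdr_id: str
    threshold_value: float
    truncated_left: bool
    truncated_right: bool


def smooth_track(track: BinnedTrack, smooth_window: int) -> np.ndarray:
    """Centered rolling mean in track bins; edge bins use shrinking windows."""
    w = max(1, round(smooth_window / track.bin_size))
    return (
        pd.Series(track.values)
        .rolling(w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def call_domain(
    track: BinnedTrack,
    cdr: GenomicInterval,
    params: ExpansionParams = ExpansionParams(),
    seed_cdr_id: str = "",
) -> DomainCall:
    """Call one CENP-A/CENP-C domain by seeded expansion from ``cdr``.

    ``track`` must cover ``cdr`` extended by ``params.window_extension`` on
    each side (clipped at coordinate 0). Raises :class:`NoSignalError` when
    the CDR carries no positive signal and :class:`DegenerateDomainError`
    (with a zero-width interval at the midpoint) when even the midpoint bin
    is below threshold.
    """
    window = cdr.padded(params.window_extension)
    sub = track.slice(window)
    if not sub.region.contains(window):
        raise ConfigurationError(
            f"track {sub.region} does not cover expansion window {window}"
        )
    cdr_mean = track.mean_in(cdr)
    if np.isnan(cdr_mean) or cdr_mean <= 0:
        raise NoSignalError(f"zero or missing signal within CDR {cdr}")
    threshold = params.threshold_fraction * cdr_mean

    smoothed = smooth_track(sub, params.smooth_window)
    mid_idx = sub.bin_index(cdr.midpoint)
    if np.isnan(smoothed[mid_idx]) or smoothed[mid_idx] < threshold:
        raise DegenerateDomainError(
            f"midpoint bin below threshold for CDR {cdr}",
            interval=GenomicInterval(cdr.chrom, cdr.midpoint, cdr.midpoint + 1),
        )

    above = ~np.isnan(smoothed) & (smoothed >= threshold)
    lo = mid_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = mid_idx
    while hi < sub.n_bins - 1 and above[hi + 1]:
        hi += 1
    return DomainCall(
        interval=GenomicInterval(
            sub.chrom, sub.bin_start(lo), sub.bin_start(hi) + sub.bin_size
        ),
        seed_cdr_id=seed_cdr_id,
        threshold_value=float(threshold),
        truncated_left=(lo == 0),
        truncated_right=(hi == sub.n_bins - 1),
    )


def call_domain_bruteforce(
    track: BinnedTrack,
    cdr: GenomicInterval,
    params: ExpansionParams = ExpansionParams(),
) -> tuple[int, int, bool, bool]:
    """Independent oracle: full-mask scan with no early exit.

    Computes the above-threshold boolean mask over the whole window, then
    takes the maximal contiguous run of True containing the midpoint bin.
    Returns (start_bp, end_bp, truncated_left, truncated_right). Kept free
    of the expansion loop so tests can cross-check :func:`call_domain`.
    """
    window = cdr.padded(params.window_extension)
    sub = track.slice(window)
    cdr_mean = track.mean_in(cdr)
    threshold = params.threshold_fraction * cdr_mean
    smoothed = smooth_track(sub, params.smooth_window)
    above = ~np.isnan(smoothed) & (smoothed >= threshold)
    mid = sub.bin_index(cdr.midpoint)
    if not above[mid]:
        raise DegenerateDomainError("midpoint below threshold")
    # label contiguous runs and pick the one containing mid
    runs = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, ends = runs[::2], runs[1::2]
    sel = (starts <= mid) & (mid < ends)
    lo, hi = int(starts[sel][0]), int(ends[sel][0]) - 1
    return (
        sub.bin_start(lo),
        sub.bin_start(hi) + sub.bin_size,
        lo == 0,
        hi == sub.n_bins - 1,
    )
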