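"""Modification-call thresholding and fraction-modified pileups.

Per-base modification probabilities (from a modification-aware basecaller)
are classified as MODIFIED, CANONICAL or FILTERED under a dual-threshold
scheme: a call is modified when its probability clears the per-mod
threshold (6mA: 0.98, 5mCG: 0.8), canonical when the complementary
canonical-base confidence clears the base filter threshold (0.8 for both A
and C), and filtered otherwise. Filtered calls are removed from both the
numerator and the denominator of the fraction-modified pileup, so the
fraction is over confidently-called bases only.

The 256-bin integer (ML) encoding of probabilities is provided for
interoperability: the default thresholds 0.98 and 0.8 correspond exactly to
integer cutoffs 250 and 204.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, RangeError
from .tracks import GenomicInterval, ModPileupRecord

__all__ = [
    "CallOutcome",
    "ThresholdScheme",
    "ml_from_prob",
    "classify_call",
    "pileup_molecules",
]

#: canonical base underlying each modification code
CANONICAL_BASE = {"a": "A", "m": "C"}


class CallOutcome(enum.Enum):
    MODIFIED = "modified"
    CANONICAL = "canonical"
    FILTERED = "filtered"


@dataclass(frozen=True)
class ThresholdScheme:
    """Probability thresholds for modified and canonical calls."""

    mod_threshold: Mapping[str, float] = field(
        default_factory=lambda: {"a": 0.98, "m": 0.8}
    )
    base_filter_threshold: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.8, "C": 0.8}
    )

    def __post_init__(self):
        for code, t in self.mod_threshold.items():
            if not (0.5 <= t <= 1.0):
                raise ConfigurationError(
                    f"mod_threshold[{code!r}] must be in [0.5, 1], got {t}"
                )
        for base, t in self.base_filter_threshold.items():
            if not (0.0 < t <= 1.0):
                raise ConfigurationError(
                    f"base_filter_threshold[{base!r}] must be in (0, 1], got {t}"
                )


DEFAULT_SCHEME = ThresholdScheme()


def ml_from_prob(p: float) -> int:
    """Map a probability to its 256-bin integer (ML) encoding.

    ``floor(p * 256)`` capped at 255; 0.98 -> 250 and 0.8 -> 204.
    """
    if not (0.0 <= p <= 1.0):
        raise RangeError(f"probability outside [0, 1]: {p}")
    return min(255, int(p * 256))


def classify_call(
    p_mod: float, mod_code: str, scheme: ThresholdScheme = DEFAULT_SCHEME
) -> CallOutcome:
    """Classify one base call from its modification probability."""
    if not (0.0 <= p_mod <= 1.0):
        raise RangeError(f"probability outside [0, 1]: {p_mod}")
    if mod_code not in scheme.mod_threshold:
        raise ConfigurationError(f"unknown mod code {mod_code!r}")
    base = CANONICAL_BASE.get(mod_code)
    if base is None or base not in scheme.base_filter_threshold:
        raise ConfigurationError(f"no canonical base threshold for {mod_code!r}")
    if p_mod >= scheme.mod_threshold[mod_code]:
        return CallOutcome.MODIFIED
    if (1.0 - p_mod) >= scheme.base_filter_threshold[base]:
        return CallOutcome.CANONICAL
    return CallOutcome.FILTERED


def pileup_molecules(
    calls: Iterable[tuple[int, CallOutcome]],
    region: GenomicInterval,
    mod_code: str = "a",
) -> list[ModPileupRecord]:
    """Aggregate per-position call outcomes into fraction-modified records.

    ``calls`` yields (position, outcome) pairs; positions must lie inside
    ``region``. Filtered calls count toward neither numerator nor
    denominator; positions whose every call was filtered are omitted.
    Records are returned sorted by position.
    """
    n_mod: dict[int, int] = defaultdict(int)
    n_valid: dict[int, int] = defaultdict(int)
    for pos, outcome in calls:
        if not (region.start <= pos < region.end):
            raise RangeError(
                f"call position {pos} outside region "
                f"[{region.start}, {region.end})"
            )
        if outcome is CallOutcome.FILTERED:
            continue
        n_valid[pos] += 1
        if outcome is CallOutcome.MODIFIED:
            n_mod[pos] += 1
    records = []
    for pos in sorted(n_valid):
        records.append(
            ModPileupRecord(
                position=GenomicInterval(region.chrom, pos, pos + 1),
                mod_code=mod_code,
                n_valid=n_valid[pos],
                frac_modified=n_mod[pos] / n_valid[pos],
            )
        )
    return records
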