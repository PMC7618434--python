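"""Genomic interval / track containers and file I/O.

All coordinates are 0-based half-open (BED convention). Strand is ignored
throughout: modification fractions and densities in this package are
strand-collapsed. Missing data in binned tracks is an explicit NaN, never
zero, and every mean skips missing values.

Supported formats (plain or gzip-compressed, detected by ``.gz`` suffix):

* bedmethyl-dialect pileup tables (column 11 = fraction modified),
* BED3/BED4 interval annotations,
* 12-column BED single-molecule records where block count/sizes/starts
  encode per-read modified-base positions,
* 4-column bedGraph for binned tracks (canonical interchange format here).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    CoordinateError,
    NoDataError,
    ParseError,
    RangeError,
)

__all__ = [
    "GenomicInterval",
    "ModPileupRecord",
    "BinnedTrack",
    "MoleculeRead",
    "read_pileup",
    "read_molecules",
    "write_molecules",
    "read_bed",
    "write_bed",
    "bin_track",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on a (haplotype-resolved) contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the half-open intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    def padded(self, pad: int) -> "GenomicInterval":
        """Interval extended by ``pad`` bp each side (clipped at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)


@dataclass(frozen=True)
class ModPileupRecord:
    """One pileup position: fraction of valid calls that are modified."""

    position: GenomicInterval
    mod_code: str  # "a" (6mA) or "m" (5mCG)
    n_valid: int
    frac_modified: float

    def __post_init__(self):
        if len(self.position) != 1:
            raise ValueError("pileup position must have width 1")
        if self.n_valid < 0:
            raise ValueError("n_valid must be >= 0")
        if not (0.0 <= self.frac_modified <= 1.0):
            raise RangeError(
                f"frac_modified outside [0, 1]: {self.frac_modified}"
            )


@dataclass
class BinnedTrack:
    """Equal-width binned signal over one contig.

    ``values[i]`` covers ``[origin + i*bin_size, origin + (i+1)*bin_size)``;
    NaN marks a bin with no data.
    """

    chrom: str
    bin_size: int
    origin: int
    values: np.ndarray

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.origin, self.origin + self.n_bins * self.bin_size
        )

    def bin_index(self, position: int) -> int:
        return (position - self.origin) // self.bin_size

    def bin_start(self, index: int) -> int:
        return self.origin + index * self.bin_size

    def slice(self, region: GenomicInterval) -> "BinnedTrack":
        """Sub-track covering ``region`` (bins clipped to whole bins)."""
        if region.chrom != self.chrom:
            raise CoordinateError(
                f"region on {region.chrom} but track on {self.chrom}"
            )
        lo = max(0, (region.start - self.origin) // self.bin_size)
        hi = min(
            self.n_bins,
            -((region.end - self.origin) // -self.bin_size),  # ceil div
        )
        if hi <= lo:
            raise CoordinateError("region does not overlap track")
        return BinnedTrack(
            self.chrom,
            self.bin_size,
            self.origin + lo * self.bin_size,
            self.values[lo:hi].copy(),
        )

    def mean_in(self, region: GenomicInterval) -> float:
        """Overlap-weighted mean of non-missing bins inside ``region``."""
        sub = self.slice(region)
        weights = np.full(sub.n_bins, float(sub.bin_size))
        # partial first/last bins
        weights[0] -= max(0, region.start - sub.origin)
        weights[-1] -= max(0, sub.region.end - region.end)
        ok = ~np.isnan(sub.values)
        if not ok.any() or weights[ok].sum() == 0:
            return float("nan")
        return float(np.average(sub.values[ok], weights=weights[ok]))


@dataclass(frozen=True)
class MoleculeRead:
    """One long read with offsets of its modified bases.

    ``mod_offsets`` are 0-based bp offsets relative to ``start``, strictly
    increasing, each in ``[0, end - start)``.
    """

    chrom: str
    start: int
    end: int
    read_id: str
    mod_offsets: tuple[int, ...]

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("read end must be > start")
        span = self.end - self.start
        prev = -1
        for off in self.mod_offsets:
            if not (0 <= off < span):
                raise CoordinateError(
                    f"mod offset {off} outside read span [0, {span}) "
                    f"for read {self.read_id}"
                )
            if off <= prev:
                raise ConsistencyError(
                    f"mod offsets not strictly increasing for read {self.read_id}"
                )
            prev = off

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def mod_positions(self) -> np.ndarray:
        """Absolute genomic positions of modified bases."""
        return self.start + np.asarray(self.mod_offsets, dtype=int)


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_pileup(path, mod_code: str = "m", dialect: str = "percent"):
    """Read a bedmethyl-dialect pileup into ``ModPileupRecord`` objects.

    Column 11 carries the modified fraction; under the default ``percent``
    dialect it is divided by 100, under ``fraction`` taken as-is. Column 10
    (valid coverage) is used for ``n_valid`` where present and numeric.
    Records are returned sorted by (chrom, start).
    """
    if dialect not in ("percent", "fraction"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hi = 100.0 if dialect == "percent" else 1.0
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(
                    f"expected >= 11 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                raw = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            if not (0.0 <= raw <= hi):
                raise RangeError(
                    f"line {lineno}: column-11 value {raw} outside [0, {hi:g}] "
                    f"for dialect {dialect!r}"
                )
            try:
                n_valid = int(fields[9])
            except (ValueError, IndexError):
                n_valid = 1
            records.append(
                ModPileupRecord(
                    position=GenomicInterval(fields[0], start, end),
                    mod_code=mod_code,
                    n_valid=n_valid,
                    frac_modified=raw / hi,
                )
            )
    records.sort(key=lambda r: (r.position.chrom, r.position.start))
    return records


def read_molecules(path) -> list[MoleculeRead]:
    """Read 12-column BED single-molecule records.

    Column 10 is the number of modified sites, column 12 the comma-separated
    offsets of those sites relative to the read start (block sizes in column
    11 are typically all 1 for point modifications and are not used).
    """
    reads = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                block_count = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"non-numeric field ({exc})", lineno) from None
            starts_field = fields[11].rstrip(",")
            offsets = (
                tuple(int(x) for x in starts_field.split(","))
                if starts_field
                else ()
            )
            if block_count != len(offsets):
                raise ConsistencyError(
                    f"line {lineno}: block count {block_count} != "
                    f"{len(offsets)} listed block starts"
                )
            reads.append(
                MoleculeRead(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    read_id=fields[3],
                    mod_offsets=offsets,
                )
            )
    return reads


def write_molecules(reads: Iterable[MoleculeRead], path) -> None:
    """Write reads as 12-column BED (inverse of :func:`read_molecules`)."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            n = len(r.mod_offsets)
            sizes = ",".join("1" for _ in range(n))
            starts = ",".join(str(o) for o in r.mod_offsets)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t.\t"
                f"{r.start}\t{r.end}\t0,0,0\t{n}\t{sizes}\t{starts}\n"
            )


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED4 annotations as (interval, name) pairs.

    The name is the 4th column where present, else an empty string.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 columns", lineno)
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
            name = fields[3] if len(fields) > 3 else ""
            out.append((iv, name))
    return out


def write_bed(entries, path) -> None:
    """Write (interval, name) pairs (or extra trailing columns) as BED."""
    with _open_text(path, "wt") as fh:
        for entry in entries:
            iv, *rest = entry
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            cols.extend(str(x) for x in rest)
            fh.write("\t".join(cols) + "\n")


def bin_track(
    records,
    region: GenomicInterval,
    bin_size: int,
    aggregator: str = "mean",
) -> BinnedTrack:
    """Bin per-position values over ``region`` into a :class:`BinnedTrack`.

    ``records`` is a sequence of ``ModPileupRecord`` or ``(position,
    value)`` pairs. Each bin value is the mean over covered positions; bins
    with no covered position are NaN. The number of bins is
    ``ceil(len(region) / bin_size)``.
    """
    if aggregator != "mean":
        raise ValueError(f"unsupported aggregator {aggregator!r}")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = math.ceil(len(region) / bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for rec in records:
        if isinstance(rec, ModPileupRecord):
            chrom, pos, val = rec.position.chrom, rec.position.start, rec.frac_modified
        else:
            pos, val = rec
            chrom = region.chrom
        if chrom != region.chrom or not (region.start <= pos < region.end):
            continue
        idx = (pos - region.start) // bin_size
        sums[idx] += val
        counts[idx] += 1
    values = np.full(n_bins, np.nan)
    covered = counts > 0
    values[covered] = sums[covered] / counts[covered]
    return BinnedTrack(region.chrom, bin_size, region.start, values)


def write_bedgraph(track: BinnedTrack, path, precision: int = 6) -> None:
    """Write a track as 4-column bedGraph; missing (NaN) bins are omitted."""
    rows = []
    for i, v in enumerate(track.values):
        if np.isnan(v):
            continue
        s = track.bin_start(i)
        rows.append((track.chrom, s, s + track.bin_size, round(float(v), precision)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, region: GenomicInterval | None = None, bin_size: int | None = None) -> BinnedTrack:
    """Read a 4-column bedGraph written with a uniform bin width.

    If ``region``/``bin_size`` are omitted they are inferred from the file
    (bin width from the first line, region as the hull of entries on the
    first contig). Bins absent from the file are NaN.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    if df.empty:
        raise NoDataError(f"empty bedGraph: {path}")
    if region is None:
        chrom = df["chrom"].iloc[0]
        df = df[df["chrom"] == chrom]
        region = GenomicInterval(chrom, int(df["start"].min()), int(df["end"].max()))
    else:
        df = df[df["chrom"] == region.chrom]
    if bin_size is None:
        bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    n_bins = math.ceil(len(region) / bin_size)
    values = np.full(n_bins, np.nan)
    starts = df["start"].to_numpy()
    sel = (starts >= region.start) & (starts < region.end)
    idx = (starts[sel] - region.start) // bin_size
    values[idx] = df["value"].to_numpy()[sel]
    return BinnedTrack(region.chrom, bin_size, region.start, values)
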