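"""Synthetic centromere-epigenome generator with recorded ground truth.

Emulates the data shapes of antibody-directed methyltransferase labeling
(DiMeLo-seq style) on a haplotype-resolved centromere: a hypermethylated
alpha-satellite HOR whose 5mCG track dips at the CDR(s), CENP-A/CENP-C
6mA occupancy confined to those dips, H3K9me3 high across HOR and
pericentromere with a dip at the CDR, nonspecific IgG background
molecules, knockout-style H3K9me3 erosion (global, HOR-restricted, or
combined), optional seeding of a distal new CDR, and gradual domain drift
across clonal generations.

Modification opportunities sit on a fixed 200-bp site lattice (one
candidate site per nucleosome-scale unit). Each simulated molecule samples
a start and a lognormal length, then a per-site modification probability
from a two-component Beta noise model (mean 0.995 for truly modified
sites, 0.005 otherwise, concentration ``call_noise``), so the downstream
dual-threshold call scheme is meaningfully exercised. Emitted fraction
tracks are the exact expectation of the generative model, not an empirical
pileup; molecule sets and pileups carry the sampling noise.

Everything is deterministic given the seed; independent sub-streams per
target keep each target's output stable when others are regenerated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calling import CallOutcome, ThresholdScheme, pileup_molecules
from .errors import ConfigurationError
from .tracks import (
    BinnedTrack,
    GenomicInterval,
    MoleculeRead,
    write_bed,
    write_bedgraph,
    write_molecules,
)

__all__ = [
    "CdrSpec",
    "ContigSpec",
    "DriftParams",
    "SimConfig",
    "SyntheticTruth",
    "SimBundle",
    "TimecourseResult",
    "simulate",
    "simulate_timecourse",
]

SITE_SPACING = 200  # bp between candidate modification sites (~1 nucleosome)
TARGETS = ("cenpa", "cenpc", "h3k9me3", "igg", "mcg")
GENOTYPES = ("parental", "suv39_like", "setdb1_like", "triple_like")


@dataclass(frozen=True)
class CdrSpec:
    """One ground-truth CDR: a 5mCG dip carrying a CENP-A domain."""

    interval: GenomicInterval
    cenpa_occupancy: float = 0.05  # fraction of lattice sites labeled
    mcg_dip_level: float = 0.10
    h3k9me3_dip_level: float = 0.02
    is_new: bool = False  # seeded distal to the primary CDR


@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int
    hor: GenomicInterval
    pericentromere: tuple[GenomicInterval, ...]


def _default_contig() -> ContigSpec:
    hor = GenomicInterval("chr1_hap1", 3_000_000, 5_000_000)
    return ContigSpec(
        name="chr1_hap1",
        length=8_000_000,
        hor=hor,
        pericentromere=(
            GenomicInterval("chr1_hap1", 2_000_000, 3_000_000),
            GenomicInterval("chr1_hap1", 5_000_000, 6_000_000),
        ),
    )


def _default_cdrs() -> tuple[CdrSpec, ...]:
    return (
        CdrSpec(interval=GenomicInterval("chr1_hap1", 3_900_000, 4_020_000)),
    )


@dataclass(frozen=True)
class DriftParams:
    """Per-generation center displacement of the CENP-A domain.

    ``sd_kb`` is the standard deviation of the zero-mean per-generation
    step; ``programmed_shift_kb`` (if set) replaces the random step with a
    deterministic displacement. The domain width is held constant.
    """

    sd_kb: float = 2.8
    programmed_shift_kb: float | None = None
    domain_width: int = 90_000


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    contig: ContigSpec = field(default_factory=_default_contig)
    truth_cdrs: tuple[CdrSpec, ...] = field(default_factory=_default_cdrs)
    # a shallow dip below the valley-caller thresholds, with no CENP-A:
    # must never be called
    decoy_dips: tuple[tuple[GenomicInterval, float], ...] = (
        (GenomicInterval("chr1_hap1", 4_500_000, 4_560_000), 0.55),
    )
    mcg_high: float = 0.80
    h3k9me3_level: float = 0.30
    h3k9me3_outside: float = 0.05  # beyond HOR + pericentromere
    cenpa_rate: float = 0.05  # in-domain 6mA rate per lattice site
    igg_rate: float = 0.005  # nonspecific background rate
    read_length_median: int = 50_000
    read_length_sigma: float = 0.4  # lognormal sigma
    call_noise: float = 200.0  # Beta concentration of per-site probabilities
    genotype: str = "parental"
    new_cdr: tuple[int, float] | None = None  # (distance from primary, occupancy)
    n_reads: int = 800  # molecules per target (~10x coverage over the ROI)
    drift: DriftParams = field(default_factory=DriftParams)

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ConfigurationError(f"unknown genotype {self.genotype!r}")
        for level in (self.mcg_high, self.h3k9me3_level, self.cenpa_rate, self.igg_rate):
            if not (0.0 <= level <= 1.0):
                raise ConfigurationError(f"rate/level outside [0, 1]: {level}")
        if self.new_cdr is not None and self.new_cdr[0] < 500_000:
            raise ConfigurationError("new CDR distance must be >= 500 kb")
        for spec in self.truth_cdrs:
            if not self.contig.hor.contains(spec.interval):
                raise ConfigurationError(
                    f"truth CDR {spec.interval} outside HOR {self.contig.hor}"
                )
            if spec.interval.end > self.contig.length:
                raise ConfigurationError("truth CDR outside contig")

    def effective_cdrs(self) -> tuple[CdrSpec, ...]:
        """Truth CDRs plus the optional seeded new CDR."""
        cdrs = list(self.truth_cdrs)
        if self.new_cdr is not None:
            distance, occupancy = self.new_cdr
            primary = self.truth_cdrs[0]
            width = len(primary.interval)
            start = primary.interval.start + distance
            iv = GenomicInterval(self.contig.name, start, start + width)
            if not self.contig.hor.contains(iv):
                raise ConfigurationError(
                    f"new CDR {iv} falls outside the HOR {self.contig.hor}"
                )
            cdrs.append(replace(primary, interval=iv, cenpa_occupancy=occupancy, is_new=True))
        return tuple(cdrs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded before noise injection."""

    cdrs: tuple[CdrSpec, ...]
    decoy_dips: tuple[tuple[GenomicInterval, float], ...]
    genotype: str
    hor: GenomicInterval
    pericentromere: tuple[GenomicInterval, ...]


@dataclass
class SimBundle:
    """Everything one simulated sample produces."""

    config: SimConfig
    truth: SyntheticTruth
    tracks: dict[str, BinnedTrack]  # per target, expectation fraction tracks
    molecules: dict[str, list[MoleculeRead]]
    pileups: dict[str, list]  # per target, ModPileupRecord lists
    roi: GenomicInterval  # HOR +- 1 Mb, the simulated window

    def write(self, outdir) -> dict[str, str]:
        """Write the bundle in the formats the readers consume.

        Returns a name -> path map: BED annotations, bedGraph tracks,
        12-column BED molecules and a tab-separated truth file.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def _p(name):
            paths[name] = str(outdir / name)
            return outdir / name

        write_bed([(self.truth.hor, "active_hor")], _p("hors.bed"))
        write_bed(
            [
                (c.interval, "new" if c.is_new else "primary")
                for c in self.truth.cdrs
            ],
            _p("truth_cdrs.bed"),
        )
        for target, track in self.tracks.items():
            write_bedgraph(track, _p(f"{target}.bedgraph"))
        for target, reads in self.molecules.items():
            if reads:
                write_molecules(reads, _p(f"{target}.molecules.bed"))
        with open(_p("truth.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tkind\toccupancy\n")
            for c in self.truth.cdrs:
                kind = "new_cdr" if c.is_new else "primary_cdr"
                fh.write(
                    f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                    f"\t{kind}\t{c.cenpa_occupancy}\n"
                )
            for iv, level in self.truth.decoy_dips:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tdecoy_dip\t{level}\n")
        return paths


def _h3k9_factor(genotype: str, in_hor: np.ndarray, in_peri: np.ndarray) -> np.ndarray:
    """Genotype-dependent multiplier on the H3K9me3 rate, per position."""
    factor = np.ones(in_hor.shape)
    if genotype == "suv39_like":
        factor[:] = 0.3
    elif genotype == "setdb1_like":
        factor[in_hor] = 0.4
    elif genotype == "triple_like":
        factor[in_hor] = 0.05
        factor[in_peri] = 0.3
    return factor


def _member_mask(positions: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(positions.shape, dtype=bool)
    for iv in intervals:
        mask |= (positions >= iv.start) & (positions < iv.end)
    return mask


def site_rate(positions: np.ndarray, target: str, config: SimConfig) -> np.ndarray:
    """True per-site modification rate at each position, for one target."""
    cdrs = config.effective_cdrs()
    cdr_ivs = [c.interval for c in cdrs]
    in_hor = _member_mask(positions, [config.contig.hor])
    in_peri = _member_mask(positions, config.contig.pericentromere)
    if target == "mcg":
        rate = np.full(positions.shape, config.mcg_high)
        for c in cdrs:
            sel = (positions >= c.interval.start) & (positions < c.interval.end)
            rate[sel] = c.mcg_dip_level
        for iv, level in config.decoy_dips:
            sel = (positions >= iv.start) & (positions < iv.end)
            rate[sel] = level
    elif target == "h3k9me3":
        rate = np.full(positions.shape, config.h3k9me3_outside)
        rate[in_hor | in_peri] = config.h3k9me3_level
        for c in cdrs:
            sel = (positions >= c.interval.start) & (positions < c.interval.end)
            rate[sel] = c.h3k9me3_dip_level
        rate = rate * _h3k9_factor(config.genotype, in_hor, in_peri)
    elif target in ("cenpa", "cenpc"):
        rate = np.full(positions.shape, config.igg_rate)
        for c in cdrs:
            sel = (positions >= c.interval.start) & (positions < c.interval.end)
            rate[sel] = c.cenpa_occupancy
    elif target == "igg":
        rate = np.full(positions.shape, config.igg_rate)
    else:
        raise ConfigurationError(f"unknown target {target!r}")
    return rate


def _roi(config: SimConfig) -> GenomicInterval:
    hor = config.contig.hor
    return GenomicInterval(
        config.contig.name,
        max(0, hor.start - 1_000_000),
        min(config.contig.length, hor.end + 1_000_000),
    )


def _expectation_track(target: str, config: SimConfig, bin_size: int) -> BinnedTrack:
    roi = _roi(config)
    n_bins = len(roi) // bin_size
    mids = roi.start + (np.arange(n_bins) + 0.5) * bin_size
    return BinnedTrack(
        roi.chrom, bin_size, roi.start, site_rate(mids, target, config)
    )


def _simulate_target_molecules(
    target: str, config: SimConfig, rng: np.random.Generator
):
    """Sample molecules and per-site calls for one target.

    Returns (reads, pileup_records). Reads record the MODIFIED site
    offsets (what a thresholded single-molecule extract reports); the
    pileup aggregates MODIFIED/CANONICAL over all molecules, excluding
    FILTERED calls from both counts.
    """
    roi = _roi(config)
    scheme = ThresholdScheme()
    mod_thr = scheme.mod_threshold["m" if target == "mcg" else "a"]
    base_thr = scheme.base_filter_threshold["C" if target == "mcg" else "A"]
    kappa = config.call_noise
    mu_mod, mu_can = 0.995, 0.005

    reads: list[MoleculeRead] = []
    calls: list[tuple[int, CallOutcome]] = []
    lengths = np.maximum(
        5_000,
        rng.lognormal(
            mean=np.log(config.read_length_median),
            sigma=config.read_length_sigma,
            size=config.n_reads,
        ).astype(int),
    )
    starts = rng.integers(
        max(0, roi.start - int(lengths.max())), roi.end, size=config.n_reads
    )
    for i in range(config.n_reads):
        start = int(starts[i])
        end = min(int(start + lengths[i]), config.contig.length)
        if end - start < 1_000:
            continue
        first = -(start // -SITE_SPACING) * SITE_SPACING  # first lattice site
        sites = np.arange(first, end, SITE_SPACING)
        if sites.size == 0:
            reads.append(
                MoleculeRead(roi.chrom, start, end, f"{target}_read_{i}", ())
            )
            continue
        rates = site_rate(sites.astype(float), target, config)
        truly = rng.random(sites.size) < rates
        probs = np.where(
            truly,
            rng.beta(mu_mod * kappa, (1 - mu_mod) * kappa, sites.size),
            rng.beta(mu_can * kappa, (1 - mu_can) * kappa, sites.size),
        )
        modified = probs >= mod_thr
        canonical = ~modified & ((1.0 - probs) >= base_thr)
        offsets = tuple(int(s - start) for s in sites[modified])
        reads.append(
            MoleculeRead(roi.chrom, start, end, f"{target}_read_{i}", offsets)
        )
        for s in sites[modified]:
            calls.append((int(s), CallOutcome.MODIFIED))
        for s in sites[canonical]:
            calls.append((int(s), CallOutcome.CANONICAL))
    region = GenomicInterval(roi.chrom, 0, config.contig.length)
    pileup = pileup_molecules(
        calls, region, mod_code="m" if target == "mcg" else "a"
    )
    return reads, pileup


def simulate(config: SimConfig = SimConfig()) -> SimBundle:
    """Generate one synthetic sample bundle (deterministic given the seed).

    Tracks: 5mCG expectation at 1-kb bins, 6mA targets at 100-bp bins,
    both over the HOR ±1 Mb. Molecules and pileups are sampled per target
    from independent sub-streams of the seeded generator.
    """
    truth = SyntheticTruth(
        cdrs=config.effective_cdrs(),
        decoy_dips=config.decoy_dips,
        genotype=config.genotype,
        hor=config.contig.hor,
        pericentromere=config.contig.pericentromere,
    )
    tracks = {}
    molecules = {}
    pileups = {}
    for idx, target in enumerate(TARGETS):
        bin_size = 1_000 if target == "mcg" else 100
        tracks[target] = _expectation_track(target, config, bin_size)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))
        molecules[target], pileups[target] = _simulate_target_molecules(
            target, config, rng
        )
    return SimBundle(
        config=config,
        truth=truth,
        tracks=tracks,
        molecules=molecules,
        pileups=pileups,
        roi=_roi(config),
    )


def simulate_null_reads(
    n_reads: int,
    rate: float,
    region: GenomicInterval,
    seed: int,
    min_overlap: int = 10_000,
    read_length_median: int = 50_000,
    read_length_sigma: float = 0.4,
    call_noise: float = 200.0,
    label: str = "null",
) -> list[MoleculeRead]:
    """Reads with a uniform 6mA rate, each overlapping ``region`` >= ``min_overlap``.

    A calibration utility for enrichment null experiments: every molecule
    qualifies for density scoring against ``region``, and its modified
    sites pass through the same two-component Beta noise model and 6mA
    threshold as the full simulator.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    mu_mod, mu_can = 0.995, 0.005
    reads = []
    for i in range(n_reads):
        length = int(
            max(
                min_overlap + SITE_SPACING,
                rng.lognormal(np.log(read_length_median), read_length_sigma),
            )
        )
        lo = max(0, region.start - (length - min_overlap))
        hi = max(lo + 1, region.end - min_overlap)
        start = int(rng.integers(lo, hi))
        end = start + length
        first = -(start // -SITE_SPACING) * SITE_SPACING
        sites = np.arange(first, end, SITE_SPACING)
        truly = rng.random(sites.size) < rate
        probs = np.where(
            truly,
            rng.beta(mu_mod * call_noise, (1 - mu_mod) * call_noise, sites.size),
            rng.beta(mu_can * call_noise, (1 - mu_can) * call_noise, sites.size),
        )
        offsets = tuple(int(s - start) for s in sites[probs >= 0.98])
        reads.append(
            MoleculeRead(region.chrom, start, end, f"{label}_{i}", offsets)
        )
    return reads


# ---------------------------------------------------------------------------
# drift time course


@dataclass(frozen=True)
class TimecourseResult:
    reference: "object"  # BinnedProfile
    clones: list  # one final-generation BinnedProfile per clone
    truth_centers: np.ndarray  # (n_clones, n_generations + 1), bp
    region: GenomicInterval


def _domain_profile(
    region: GenomicInterval,
    center: float,
    width: int,
    rng: np.random.Generator | None,
    bin_size: int = 1_000,
    peak_counts: float = 200.0,
    background_counts: float = 2.0,
    edge_bp: int = 10_000,
):
    """Expected CENP-A enrichment: flat-top domain with cosine shoulders.

    With ``rng`` given, per-bin counts are Poisson-sampled around the
    expectation; otherwise the noiseless expectation is returned.
    """
    from .drift import BinnedProfile, cpm_normalize

    n_bins = len(region) // bin_size
    x = region.start + (np.arange(n_bins) + 0.5) * bin_size
    half = width / 2.0
    d = np.abs(x - center)
    shoulder = np.clip((d - (half - edge_bp)) / edge_bp, 0.0, 1.0)
    shape = 0.5 * (1.0 + np.cos(np.pi * shoulder))
    expected = background_counts + peak_counts * shape
    counts = rng.poisson(expected).astype(float) if rng is not None else expected
    return cpm_normalize(
        BinnedProfile(region.chrom, bin_size, region.start, counts)
    )


def simulate_timecourse(
    config: SimConfig = SimConfig(),
    n_clones: int = 9,
    n_generations: int = 10,
    region: GenomicInterval = GenomicInterval("chr4_hap2", 42_750_000, 43_050_000),
    initial_center: int = 42_912_500,  # bin-centered within the initial window
    noisy: bool = True,
) -> TimecourseResult:
    """Clonal drift time course: the domain center random-walks, width fixed.

    Each clone's center performs ``n_generations`` independent steps of the
    configured displacement distribution (or the programmed deterministic
    shift); a 1-kb binned CPM-scaled profile is emitted for each clone's
    final generation alongside the true center at every generation.
    """
    drift = config.drift
    centers = np.zeros((n_clones, n_generations + 1))
    centers[:, 0] = initial_center
    rng_walk = np.random.default_rng(np.random.SeedSequence([config.seed, 1001]))
    for g in range(1, n_generations + 1):
        if drift.programmed_shift_kb is not None:
            step = np.full(n_clones, drift.programmed_shift_kb * 1_000.0)
        else:
            step = rng_walk.normal(0.0, drift.sd_kb * 1_000.0, size=n_clones)
        centers[:, g] = centers[:, g - 1] + step

    rng_prof = np.random.default_rng(np.random.SeedSequence([config.seed, 1002]))
    reference = _domain_profile(
        region, initial_center, drift.domain_width,
        rng_prof if noisy else None,
    )
    clones = [
        _domain_profile(
            region, centers[i, -1], drift.domain_width,
            rng_prof if noisy else None,
        )
        for i in range(n_clones)
    ]
    return TimecourseResult(
        reference=reference, clones=clones, truth_centers=centers, region=region
    )
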