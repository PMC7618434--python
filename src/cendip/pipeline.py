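"""End-to-end analyses: centromere survey and neocentromere drift.

``run_centromere_survey`` wires the stages in pipeline order: CDR valley
detection on the 5mCG track over each active HOR, merging into centromere
loci, classification against a parent CDR database plus CENP-A evidence,
seeded-expansion domain calling per retained locus, single-molecule 6mA
density with IgG normalization, CDR size comparison against the parent,
and meta-region summaries. ``run_drift_analysis`` compares clone profiles
against an early-passage reference: per-clone peak-center shifts, their
absolute mean, and window enrichment over the initial locus and flanks.

Reports are plain DataFrames plus a machine-readable manifest; warnings
(truncated domains, undefined ratios) are carried in the report, never
silently dropped. Given identical inputs and configuration the reports
are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import ThresholdScheme
from .cdr import (
    CdrLocus,
    ValleyParams,
    cdr_size_change,
    classify_loci,
    detect_valleys,
    merge_into_loci,
)
from .density import DensityParams, enrichment, per_read_density
from .domains import DomainCall, ExpansionParams, call_domain, smooth_track
from .drift import (
    DEFAULT_FLANK,
    DEFAULT_WINDOW,
    BinnedProfile,
    mean_abs_shift,
    window_enrichment,
)
from .errors import CendipError, ConfigurationError, DegenerateDomainError, NoSignalError
from .scaling import CDR_SCHEME, HOR_SCHEME, inside_outside_ratio
from .tracks import BinnedTrack, GenomicInterval, MoleculeRead, read_bed, read_bedgraph, read_molecules

__all__ = [
    "EXCLUDED_CENTROMERES",
    "AnalysisConfig",
    "RunReport",
    "pipeline_defaults",
    "cenpa_evidence_intervals",
    "run_centromere_survey",
    "run_drift_analysis",
]

#: centromeres dropped from all CDR analyses (neocentromere haplotype,
#: absent haplotype, poorly defined CDRs)
EXCLUDED_CENTROMERES = ("Cen4_Hap2", "CENX_Hap2", "Cen18_Hap1", "Cen18_Hap2")


def pipeline_defaults() -> dict[str, object]:
    """Every configurable default, read from the parameter objects.

    A single audit point: each value here is taken from the module that
    owns it, not restated.
    """
    vp = ValleyParams()
    ep = ExpansionParams()
    dp = DensityParams()
    ts = ThresholdScheme()
    return {
        "height_perc_valley_threshold": vp.height_perc_valley_threshold,
        "prom_perc_valley_threshold": vp.prom_perc_valley_threshold,
        "merge_distance_bp": vp.merge_distance,
        "expansion_threshold_fraction": ep.threshold_fraction,
        "expansion_smooth_window_bp": ep.smooth_window,
        "expansion_window_extension_bp": ep.window_extension,
        "density_min_overlap_bp": dp.min_overlap,
        "density_unit_bp": dp.density_unit,
        "density_excluded_chroms": frozenset(dp.excluded_chroms),
        "profile_bin_size_bp": 1_000,
        "initial_window": (DEFAULT_WINDOW.start, DEFAULT_WINDOW.end),
        "initial_window_flank_bp": DEFAULT_FLANK,
        "hor_scheme_bins": (HOR_SCHEME.flank_bins, HOR_SCHEME.body_bins, HOR_SCHEME.flank_bins),
        "hor_flank_bp": HOR_SCHEME.flank_bp,
        "cdr_scheme_bins": (CDR_SCHEME.flank_bins, CDR_SCHEME.body_bins, CDR_SCHEME.flank_bins),
        "cdr_flank_bp": CDR_SCHEME.flank_bp,
        "mod_threshold_a": ts.mod_threshold["a"],
        "mod_threshold_m": ts.mod_threshold["m"],
        "filter_threshold_A": ts.base_filter_threshold["A"],
        "filter_threshold_C": ts.base_filter_threshold["C"],
        "excluded_centromeres": EXCLUDED_CENTROMERES,
    }


@dataclass
class AnalysisConfig:
    """File-based configuration for the survey pipeline.

    Paths may be None when the corresponding stage is skipped. Parameter
    blocks default to the standard values.
    """

    mcg_track: str | None = None  # bedGraph, 5mCG fraction
    cenpa_track: str | None = None  # bedGraph, CENP-A 6mA fraction
    hors_bed: str | None = None
    parent_cdrs_bed: str | None = None
    cenpa_domains_bed: str | None = None  # optional explicit CENP-A evidence
    cenpa_molecules: str | None = None  # 12-col BED
    igg_molecules: str | None = None
    valley: ValleyParams = field(default_factory=ValleyParams)
    expansion: ExpansionParams = field(default_factory=ExpansionParams)
    density: DensityParams = field(default_factory=DensityParams)
    excluded_centromeres: tuple[str, ...] = EXCLUDED_CENTROMERES
    seed: int = 0

    def validate(self) -> None:
        required = {"mcg_track": self.mcg_track, "hors_bed": self.hors_bed}
        for name, path in required.items():
            if path is None:
                raise ConfigurationError(f"missing required input: {name}")
        for name in (
            "mcg_track",
            "cenpa_track",
            "hors_bed",
            "parent_cdrs_bed",
            "cenpa_domains_bed",
            "cenpa_molecules",
            "igg_molecules",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name} does not exist: {path}")


@dataclass
class RunReport:
    loci: pd.DataFrame  # one row per CDR locus with status
    domains: pd.DataFrame
    size_report: pd.DataFrame
    mean_percent_change: float
    enrichment: pd.DataFrame
    inside_outside: pd.DataFrame
    drift: pd.DataFrame
    window_enrichment: pd.DataFrame
    parameters: dict
    warnings: tuple[str, ...] = ()
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "loci",
            "domains",
            "size_report",
            "enrichment",
            "inside_outside",
            "drift",
            "window_enrichment",
        ):
            df = getattr(self, name)
            if df is not None and len(df):
                df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        manifest = {
            "version": self.version,
            "parameters": {
                k: sorted(v) if isinstance(v, frozenset) else v
                for k, v in self.parameters.items()
            },
            "mean_percent_change": self.mean_percent_change,
            "warnings": list(self.warnings),
            "input_checksums": self.input_checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def cenpa_evidence_intervals(
    track: BinnedTrack, factor: float = 5.0, smooth_window: int = 2_000
) -> list[GenomicInterval]:
    """Intervals where smoothed CENP-A signal exceeds ``factor``x its median.

    Deterministic stand-in for a curated CENP-A domain annotation when none
    is supplied: the track median over the analyzed window approximates the
    nonspecific background, and contiguous runs above ``factor`` times it
    are taken as CENP-A-occupied.
    """
    smoothed = smooth_track(track, smooth_window)
    med = float(np.nanmedian(smoothed))
    if not np.isfinite(med):
        return []
    mask = np.nan_to_num(smoothed, nan=-np.inf) >= factor * max(med, 1e-12)
    out = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append(
                GenomicInterval(
                    track.chrom, track.bin_start(start), track.bin_start(i)
                )
            )
            start = None
    if start is not None:
        out.append(
            GenomicInterval(
                track.chrom, track.bin_start(start), track.region.end
            )
        )
    return out


def _log(verbose: bool, stage: str, message: str) -> None:
    if verbose:
        print(f"[cendip:{stage}] {message}", file=sys.stderr)


def run_centromere_survey(
    config: AnalysisConfig | None = None,
    *,
    bundle=None,
    parent_cdrs: Mapping[str, Sequence[GenomicInterval]] | None = None,
    verbose: bool = False,
) -> RunReport:
    """Run the canonical-centromere survey.

    Inputs come either from ``config`` (file paths) or from an in-memory
    simulator ``bundle``. ``parent_cdrs`` maps centromere id (contig name)
    to the parent sample's primary CDR intervals; when omitted and a
    bundle is given, the bundle's truth primaries are used (a
    self-comparison).
    """
    warnings: list[str] = []
    checksums: dict[str, str] = {}

    if (config is None) == (bundle is None):
        raise ConfigurationError("provide exactly one of config or bundle")

    if config is not None:
        config.validate()
        for name in ("mcg_track", "cenpa_track", "cenpa_molecules", "igg_molecules"):
            path = getattr(config, name)
            if path is not None:
                checksums[name] = _checksum(path)
        mcg = read_bedgraph(config.mcg_track)
        hors = [iv for iv, _ in read_bed(config.hors_bed)]
        cenpa_track = (
            read_bedgraph(config.cenpa_track) if config.cenpa_track else None
        )
        cenpa_reads = (
            read_molecules(config.cenpa_molecules) if config.cenpa_molecules else []
        )
        igg_reads = (
            read_molecules(config.igg_molecules) if config.igg_molecules else []
        )
        if config.parent_cdrs_bed:
            parent_cdrs = {}
            for iv, _name in read_bed(config.parent_cdrs_bed):
                parent_cdrs.setdefault(iv.chrom, []).append(iv)
        cenpa_domains = (
            [iv for iv, _ in read_bed(config.cenpa_domains_bed)]
            if config.cenpa_domains_bed
            else None
        )
        valley, expansion, density_params = (
            config.valley,
            config.expansion,
            config.density,
        )
        excluded = config.excluded_centromeres
    else:
        mcg = bundle.tracks["mcg"]
        hors = [bundle.truth.hor]
        cenpa_track = bundle.tracks.get("cenpa")
        cenpa_reads = bundle.molecules.get("cenpa", [])
        igg_reads = bundle.molecules.get("igg", [])
        cenpa_domains = None
        valley, expansion, density_params = (
            ValleyParams(),
            ExpansionParams(),
            DensityParams(),
        )
        excluded = EXCLUDED_CENTROMERES
        if parent_cdrs is None:
            parent_cdrs = {
                bundle.truth.hor.chrom: [
                    c.interval for c in bundle.truth.cdrs if not c.is_new
                ]
            }

    # stage 1: CDR detection per HOR, merge, classify
    all_loci: list[CdrLocus] = []
    for hor in hors:
        _log(verbose, "cdr_detection", f"scanning HOR {hor}")
        track = mcg.slice(hor)
        calls = detect_valleys(track, valley)
        loci = merge_into_loci(calls, valley.merge_distance)
        if cenpa_domains is not None:
            evidence = [d for d in cenpa_domains if d.chrom == hor.chrom]
        elif cenpa_track is not None:
            evidence = cenpa_evidence_intervals(cenpa_track.slice(hor.padded(200_000)))
        else:
            evidence = []
            warnings.append(f"no CENP-A evidence for {hor.chrom}; all loci need a parent match")
        parents = (parent_cdrs or {}).get(hor.chrom, [])
        all_loci.extend(
            classify_loci(loci, parents, evidence, valley.merge_distance)
        )

    loci_rows = []
    for i, locus in enumerate(all_loci):
        loci_rows.append(
            {
                "locus_id": f"{locus.span.chrom}:cdr{i}",
                "chrom": locus.span.chrom,
                "start": locus.span.start,
                "end": locus.span.end,
                "n_members": len(locus.member_cdrs),
                "total_cdr_bp": locus.total_cdr_bp,
                "status": locus.status,
            }
        )
    loci_df = pd.DataFrame(
        loci_rows,
        columns=["locus_id", "chrom", "start", "end", "n_members", "total_cdr_bp", "status"],
    )

    # stage 2: seeded domain expansion for retained loci
    domain_rows = []
    if cenpa_track is not None:
        for row, locus in zip(loci_rows, all_loci):
            if locus.status == "discarded":
                continue
            try:
                call = call_domain(
                    cenpa_track, locus.span, expansion, seed_cdr_id=row["locus_id"]
                )
            except (NoSignalError, DegenerateDomainError) as exc:
                warnings.append(f"domain call failed for {row['locus_id']}: {exc}")
                continue
            if call.truncated_left or call.truncated_right:
                warnings.append(f"domain truncated at window edge: {row['locus_id']}")
            domain_rows.append(
                {
                    "locus_id": row["locus_id"],
                    "chrom": call.interval.chrom,
                    "start": call.interval.start,
                    "end": call.interval.end,
                    "threshold": call.threshold_value,
                    "truncated_left": call.truncated_left,
                    "truncated_right": call.truncated_right,
                }
            )
    domains_df = pd.DataFrame(
        domain_rows,
        columns=["locus_id", "chrom", "start", "end", "threshold", "truncated_left", "truncated_right"],
    )

    # stage 3: per-read density and IgG enrichment over retained locus spans
    cdr_spans = [
        (locus.span, row["locus_id"])
        for row, locus in zip(loci_rows, all_loci)
        if locus.status in ("primary", "new")
    ]
    target_density = per_read_density(cenpa_reads, cdr_spans, density_params)
    control_density = per_read_density(igg_reads, cdr_spans, density_params)
    enr = enrichment(target_density, control_density)
    for rec in enr:
        if not rec.defined:
            warnings.append(f"undefined IgG enrichment for {rec.cdr_id}")
    enr_df = pd.DataFrame(
        [
            (r.cdr_id, r.target_mean_density, r.control_mean_density, r.enrichment_ratio)
            for r in enr
        ],
        columns=["cdr_id", "target_mean_density", "control_mean_density", "enrichment_ratio"],
    )

    # stage 4: inside/outside CDR ratio per retained locus
    io_rows = []
    if cenpa_track is not None:
        for span, locus_id in cdr_spans:
            try:
                ratio = inside_outside_ratio(cenpa_track, span)
            except CendipError as exc:
                warnings.append(f"inside/outside ratio failed for {locus_id}: {exc}")
                continue
            io_rows.append({"locus_id": locus_id, "ratio": ratio})
    io_df = pd.DataFrame(io_rows, columns=["locus_id", "ratio"])

    # stage 5: CDR size change vs parent per centromere
    sample_primary: dict[str, list[GenomicInterval]] = {}
    for locus in all_loci:
        if locus.status == "primary":
            sample_primary.setdefault(locus.span.chrom, []).extend(
                c.interval for c in locus.member_cdrs
            )
    size_df = pd.DataFrame(
        columns=["centromere", "parent_bp", "sample_bp", "ratio", "percent_change"]
    )
    mean_change = float("nan")
    if parent_cdrs:
        comparable = {
            cen: ivs
            for cen, ivs in parent_cdrs.items()
            if cen in sample_primary and cen not in excluded
        }
        if comparable:
            report = cdr_size_change(
                sample_primary, comparable, excluded=excluded
            )
            size_df = report.to_frame()
            mean_change = report.mean_percent_change

    return RunReport(
        loci=loci_df,
        domains=domains_df,
        size_report=size_df,
        mean_percent_change=mean_change,
        enrichment=enr_df,
        inside_outside=io_df,
        drift=pd.DataFrame(),
        window_enrichment=pd.DataFrame(),
        parameters=pipeline_defaults(),
        warnings=tuple(warnings),
        input_checksums=checksums,
    )


def run_drift_analysis(
    reference: BinnedProfile,
    clones: Sequence[BinnedProfile],
    window: GenomicInterval = DEFAULT_WINDOW,
    flank_bp: int = DEFAULT_FLANK,
    verbose: bool = False,
) -> RunReport:
    """Neocentromere drift analysis on an early-passage reference and clones."""
    if not clones:
        raise ConfigurationError("need at least one clone profile")
    _log(verbose, "drift", f"{len(clones)} clones vs reference {reference.region}")
    report = mean_abs_shift(reference, list(clones))
    drift_rows = [
        {"clone": i + 1, "shift_kb": s} for i, s in enumerate(report.clone_shifts_kb)
    ]
    drift_df = pd.DataFrame(drift_rows)
    drift_df.attrs["mean_abs_shift_kb"] = report.mean_abs_shift_kb

    warnings = []
    we_rows = []
    for i, clone in enumerate(clones):
        we = window_enrichment(clone, reference, window, flank_bp)
        for key, val in we.as_dict().items():
            if val is None:
                warnings.append(f"undefined window ratio ({key}) for clone {i + 1}")
        we_rows.append(
            {
                "clone": i + 1,
                "left": we.ratio_left,
                "initial": we.ratio_initial,
                "right": we.ratio_right,
            }
        )
    return RunReport(
        loci=pd.DataFrame(),
        domains=pd.DataFrame(),
        size_report=pd.DataFrame(),
        mean_percent_change=float("nan"),
        enrichment=pd.DataFrame(),
        inside_outside=pd.DataFrame(),
        drift=drift_df,
        window_enrichment=pd.DataFrame(we_rows),
        parameters=pipeline_defaults(),
        warnings=tuple(warnings),
    )
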