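# Methods

## Coordinate and data conventions

All coordinates are 0-based half-open (BED convention) on haplotype-
resolved contigs (`chr4_hap2` style). Strand is ignored throughout:
modification fractions and densities are strand-collapsed. Missing data in
binned tracks is an explicit NaN, never zero; every mean skips missing
values and a bin with no covered position stays missing through rescaling
and aggregation. Pileup column 11 defaults to the percent dialect (0–100,
divided by 100 on read) because the common pileup emitters write percent
even though the column is named "fraction modified"; a `fraction` dialect
accepts 0–1 values as-is. bedGraph is the canonical binned-track
interchange format here; BigWig binary I/O is intentionally out of scope.

## Modification calling

Per-base modification probabilities are classified under a dual-threshold
scheme: MODIFIED when p ≥ the per-mod threshold (6mA 0.98, 5mCG 0.8),
CANONICAL when the canonical-base confidence 1 − p ≥ 0.8 (A and C alike),
FILTERED otherwise. Filtered calls are removed from both the numerator and
denominator of the fraction-modified pileup — the only reading under which
the fraction is "modified among confidently called bases". The ambiguous
middle band maps to FILTERED, not CANONICAL, because that is what the
filter thresholds exist to remove. The 256-bin integer (ML) encoding
`floor(p·256)` capped at 255 is provided for interoperability; under it
the two probability cutoffs are exactly the integers 250 and 204.

Whether production pileups additionally applied a per-position valid-
coverage floor is not knowable from the published parameters; no coverage
floor is applied by default.

## CDR detection

Input is a fraction-valued 5mCG track binned over one active HOR (1-kb
bins in all shipped workflows). The trace is smoothed with a centered
rolling mean (default window 5 kb; edge bins use shrinking windows), and
local minima are found on the smoothed trace (bins still missing after
smoothing are pinned at the regional median so they can neither form nor
extend a valley). A minimum is kept when

- depth = median − value ≥ `height_perc_valley_threshold` · median
  (default 0.39), and
- topographic prominence ≥ `prom_perc_valley_threshold` · median
  (default 0.45),

where the median is taken over the smoothed regional trace. Both
thresholds are interpreted as fractions of the regional median; the
upstream tool that inspired the parameter names does not publish its exact
semantics, and the "perc" naming supports the fraction-of-median reading.
The valley extent is the maximal interval around the minimum where the
smoothed signal stays below median − depth/2. Half-depth recovery is a
repository decision: CDR edges have no published definition and the
original workflow relied on manual curation; half-depth is deterministic
and curation-free. Two qualifying minima can share a half-depth basin;
overlapping extents are merged into one call that keeps the deeper
minimum's depth and prominence, which also guarantees the documented
non-overlap of output calls.

Calls with gaps under 500 kb merge into one centromere locus (transitive
closure; a gap of exactly 500 kb does not merge). Loci are then
classified: a locus overlapping, or within the merge distance of, a
parent-database primary CDR is *primary*; otherwise a locus intersecting a
CENP-A domain is *new*; a locus with no CENP-A anywhere is *discarded* —
the deterministic replacement for manual curation. Whether the original
"not present in the parent database" test was by overlap or by distance
alone is ambiguous; both are exposed (`parent_match="overlap_or_distance"`
default, `"distance_only"` optional).

CDR size reports sum primary-CDR length per centromere and compare
sample/parent as a ratio; the mean percent change is the mean of
(ratio − 1)·100 over non-excluded centromeres. The default exclusion list
(Cen4 Hap2, CENX Hap2, Cen18 Hap1/2) mirrors the standard curation of the
neocentromere-bearing haplotype, an absent haplotype and two poorly
defined CDR sets.

## Seeded domain expansion

`call_domain` takes a 6mA fraction track and a CDR seed. The threshold is
`threshold_fraction` (default 0.01) times the mean track value within the
CDR — the "1% of the mean" rule implemented literally. It is permissive by
construction: with any appreciable nonspecific background the smoothed
signal rarely falls below 1% of the in-CDR mean, so in practice the ±30-kb
window bounds the call. This mirrors the published procedure; the
truncation flags make the behavior explicit rather than hiding it.
Smoothing is a 2-kb centered rolling mean on the track's own grid (100-bp
bins in shipped workflows; edge bins shrink). Expansion starts at the bin
containing the CDR midpoint and is contiguous: a single sub-threshold
smoothed bin terminates that side. Degenerate seeds (midpoint bin below
threshold) raise an error carrying a zero-width interval at the midpoint;
zero/missing signal in the CDR raises a no-signal error.

An independent brute-force oracle (`call_domain_bruteforce`) computes the
full above-threshold mask and takes the run containing the midpoint with
no early exit; the test suite and acceptance script verify bin-for-bin
agreement on 1,000 random tracks.

Whether the 1% threshold should apply to the fraction-modified signal or
a coverage-normalized one is not stated upstream; the fraction reading is
used.

## Single-molecule 6mA density

For every (read, CDR) pair on a non-excluded contig with half-open overlap
≥ 10 kb, the 6mA sites inside the overlap are counted and expressed per
10 kb of overlap. A site at the CDR end coordinate is outside. The default
excluded-contig list is {chr4_2, chr18, chrX_2, chr13_2, chr21_2}; an
entry without a haplotype suffix (chr18) excludes every haplotype of that
chromosome (`chr18_1`, `chr18_2`, ...). Reads are scored against merged
locus spans, so a read crossing two member CDRs of one locus contributes
once. Enrichment divides mean target density by mean IgG density per CDR
(a pooled mode exists but is non-default; whether the original box plots
pooled reads or centromere means first is ambiguous, and per-CDR means are
the closer reading of "corresponding ... densities"). A zero or absent
control mean yields an explicitly undefined ratio. Density is depth-free
by construction, so no library-size normalization is applied.

## Drift metrics

Profiles are non-negative 1-kb binned enrichment tracks; `cpm_normalize`
provides counts-per-million scaling and window ratios additionally
self-normalize, so all reported quantities are invariant to common
rescaling. The peak center is defined as the signal-weighted centroid of
the maximal contiguous run of bins ≥ 10% of the profile maximum that
contains the global maximum, reported as the bp midpoint of the centroid
bin — a repository definition, since "peak center" has no published one; a
midpoint-of-run alternative is exposed for sensitivity checks. Shifts are
(sample − reference)/1,000 kb, positive toward increasing coordinates; the
clone summary reports the mean of absolute shifts, since drift occurs in
either direction yet is summarized as a positive magnitude.

Window enrichment sums sample and control bins over the initial locus
window (default 42,868,000–42,958,000, exactly 90 kb) and its ±90-kb
flanks and reports the per-window ratio, with a zero control sum flagged
undefined. The profile must cover the flanked window; note the default
90-kb left flank extends below 42.8 Mb, so profiles restricted to the
42.8–43.0 Mb viewing region cannot evaluate it — simulated time-course
profiles therefore span 42.75–43.05 Mb.

## Meta-region scaling

`scale_region` partitions a region body into `body_bins` equal sub-bins
and each flank into `flank_bins`; fractional boundaries are computed in
real arithmetic and rounded half-up to integer bp, which guarantees a
partition with no gaps or overlaps. Every output bin is the overlap-
weighted mean of covered track bins, or NaN if uncovered. Mean, not sum,
per output bin; missing propagates. Presets: HOR rows 500 + 1,000 + 500 =
2,000 bins (±1-Mb flanks), CDR rows 125 + 200 + 125 = 450 bins (±125-kb
flanks). Heat-map rows are sorted numerically by (chromosome, haplotype),
X/Y mapping to 23/24. Midpoint-centered aggregate traces default to 100
bins over ±250 kb — the figure-legend scheme — while CDR heat maps use the
±125-kb scheme; the two flank conventions coexist upstream and both are
honored. Boundary-centered aggregates accept per-center flip flags so the
CDR interior always lies on the same side of the composite.

## Synthetic epigenome generator

The generator emulates the statistical structure of the real data, not its
sequence: a single 8-Mb contig with a 2-Mb HOR (3–5 Mb) flanked by 1-Mb
pericentromeres, chosen small enough for seconds-scale tests. Candidate
modification sites sit on a 200-bp lattice approximating nucleosome
spacing (the biology is reasoned about in nucleosome counts — on the order
of a hundred CENP-A nucleosomes in a ~100-kb domain, about one in five
nucleosomes). Default generating rates: 5mCG 0.80 across HOR and
pericentromere dipping to 0.10 in the 120-kb CDR; H3K9me3 0.30 across HOR
and pericentromere dipping to 0.02 in the CDR (no quantitative occupancy
is published for HOR H3K9me3; these are placeholders chosen for
detectability, not biological estimates); CENP-A/CENP-C 6mA 0.05 per site
inside truth domains; IgG background 0.005 everywhere. Genotypes scale
H3K9me3: `suv39_like` ×0.3 globally, `setdb1_like` ×0.4 inside the HOR
only, `triple_like` ×0.05 in the HOR and ×0.3 in the pericentromere —
matching the observed erosion patterns qualitatively. A shallow decoy dip
(0.80 → 0.55, depth below the valley thresholds, no CENP-A) is included by
default and must never be called.

Molecules sample a start uniformly over the HOR ±1 Mb and a lognormal
length (median 50 kb, σ 0.4); each covered site is truly modified with its
generating rate, then receives a call probability from a two-component
Beta noise model (mean 0.995 for modified sites, 0.005 otherwise,
concentration 200). Under the default thresholds this classifies ~98% of
truly modified 6mA sites as MODIFIED (~2% filtered) and essentially all
unmodified sites as CANONICAL, so empirical pileup fractions converge on
the generating rates to within the small filtering bias (<0.005 at rate
0.05). The default 800 molecules per target give ~10× site coverage over
the region of interest, enough for the binomial-consistency checks (≥2,000
site-calls inside the default domain). Emitted fraction tracks are the
exact expectation of the generative model (5mCG at 1-kb bins, 6mA targets
at 100-bp bins); molecules and pileups carry the sampling noise. All
randomness flows from one seed through fixed per-target sub-streams, so a
bundle is byte-stable and individual targets are stable when others
change.

The drift time course holds the 90-kb domain width constant while the
center random-walks with per-generation steps of sd 2.8 kb over 10
generations by default (total sd ≈ 9 kb, matching the observed magnitude
of long-term drift), or a programmed deterministic step. Clone profiles
are flat-top domains with 10-kb cosine shoulders, Poisson count noise and
CPM scaling, emitted over 42.75–43.05 Mb at 1-kb bins with the initial
center aligned to a bin center (42,912,500) so that centroid rounding does
not inject spurious ±1-bin jitter into null comparisons.

What the simulator does not model: alpha-satellite sequence (no FASTA),
basecalling error profiles, mappability artifacts, coverage
heterogeneity beyond uniform read starts, inter-centromere variation in
dip shape, or biological coupling between marks (each target is generated
independently given the shared truth intervals). Passing truth-recovery
tests therefore demonstrates the correctness and calibration of the
algorithms under the stated generative model, not performance on real
nanopore data.

## Pipeline and reports

The survey runs detection → merging → classification → seeded expansion →
density/enrichment → size comparison, accepting either file paths (the
same loaders the CLI uses; inputs are checksummed into the report) or an
in-memory simulator bundle. When no curated CENP-A domain annotation is
supplied, CENP-A evidence intervals are derived from the CENP-A track as
contiguous runs of 2-kb-smoothed signal ≥ 5× the regional median (the
median approximates nonspecific background) — a deterministic stand-in for
the manual curation step, and the one place a heuristic replaces a curated
input. Reports are plain DataFrames/TSVs plus a JSON manifest with the
parameter echo, package version and input checksums; truncated domains and
undefined ratios are carried as warnings, never dropped. Identical inputs
produce identical reports.

## Problem sizes

Shipped workflows and checks run on the 8-Mb single-contig simulation
(4-Mb region of interest, 800 molecules/target, ~20,000 sites per track),
1,000 random 100-kb tracks for the oracle comparison, 9 clones × 10
generations for drift, and 500 reads/group for the density null. These
sizes give the statistical power the calibration checks need (binomial and
Poisson standard errors small relative to the tested effects) while
keeping any single stage in the seconds range.
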