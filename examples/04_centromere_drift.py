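"""Quantify CENP-A domain drift across simulated 100-day clones.

Nine clones inherit a 90-kb domain whose center random-walks a little
each generation. Peak centers are the signal-weighted centroid of the
above-background run in each 1-kb binned profile; shifts are reported in
kb (positive toward increasing coordinates), plus enrichment in the
initial 90-kb locus window and its +/-90-kb flanks relative to the
early-passage reference (baseline 1).
"""

from cendip.pipeline import run_drift_analysis
from cendip.simulate import DriftParams, SimConfig, simulate_timecourse

tc = simulate_timecourse(
    SimConfig(seed=4, drift=DriftParams(sd_kb=2.8)), n_clones=9, n_generations=10
)
report = run_drift_analysis(tc.reference, tc.clones)

for _, row in report.drift.iterrows():
    print(f"clone {int(row['clone'])}: shift {row['shift_kb']:+.1f} kb")
print(f"mean |shift|: {report.drift.attrs['mean_abs_shift_kb']:.2f} kb")
print(report.window_enrichment.round(2).to_string(index=False))
# Shifts occur in either direction while the domain width stays fixed;
# window ratios near 1 show occupancy redistributing rather than growing.
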