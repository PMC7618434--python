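"""Per-read 6mA density inside CDRs, normalized to an IgG control.

Reads overlapping a CDR by at least 10 kb are scored as 6mA sites per
10 kb of overlapping sequence; CENP-A densities divided by matched IgG
densities give the enrichment per centromere.
"""

import numpy as np

from cendip import enrichment, per_read_density
from cendip.density import DensityParams
from cendip.simulate import SimConfig, simulate

bundle = simulate(SimConfig(seed=1))
cdrs = [(c.interval, f"cdr{i}") for i, c in enumerate(bundle.truth.cdrs)]
params = DensityParams()

target = per_read_density(bundle.molecules["cenpa"], cdrs, params)
control = per_read_density(bundle.molecules["igg"], cdrs, params)

print(f"{len(target)} CENP-A reads and {len(control)} IgG reads qualify "
      f"(>= {params.min_overlap:,} bp overlap)")
print(f"mean CENP-A density: {np.mean([r.density for r in target]):.2f} sites/10 kb")
print(f"mean IgG density:    {np.mean([r.density for r in control]):.2f} sites/10 kb")
for rec in enrichment(target, control):
    print(f"{rec.cdr_id}: enrichment {rec.enrichment_ratio:.1f}x over IgG")
# In-domain CENP-A labeling (rate 0.05/site) over nonspecific background
# (0.005/site) yields roughly tenfold IgG-normalized enrichment.
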