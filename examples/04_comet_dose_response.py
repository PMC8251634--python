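"""Score a synthetic comet-chip study and test its concentration trend.

Simulates 300 cells per culture across a five-level concentration
series (four replicate cultures each), scores %DNA in Tail per cell,
aggregates per culture, and feeds the summaries to the linear trend
test — the wiring used for DNA-damage dose-response analysis.
"""

import numpy as np

from duplexmut.comet import CometSimConfig, score_study, simulate_comets
from duplexmut.dose_response import endpoint_table, linear_trend

config = CometSimConfig(cells_per_culture=300, rng_seed=3)
cells = simulate_comets(config, replicates=4)
summaries = score_study(cells)

print("mean %DNA in Tail per concentration (4 replicate cultures):")
by_conc = {}
for s in summaries:
    by_conc.setdefault(s.concentration, []).append(s.mean_percent_tail)
for conc, vals in sorted(by_conc.items()):
    prog = config.programmed_tail_fractions[conc]
    print(f"  {conc:>6.2f} ug/mL: scored {np.mean(vals):5.1f} "
          f"(programmed {100 * prog:.1f})")

table = endpoint_table([s.concentration for s in summaries],
                       [s.mean_percent_tail for s in summaries])
res = linear_trend(table)
print(f"\nlinear trend: slope {res.slope:.3f} %/ (ug/mL), "
      f"p = {res.p_value:.2e}")
print("The scorer recovers the programmed damage levels and the trend")
print("test detects the concentration-dependent increase.")
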