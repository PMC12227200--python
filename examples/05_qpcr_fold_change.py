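"""Relative galanin expression by the ddCt method.

Simulates a Ct panel (target *gal*, references *actb1*/*tbp*/*rpl13a*,
technical triplicates, three pools per condition) with a known 15.4-fold
upregulation plus realistic Ct noise, and recovers the fold change.
Also shows primer-efficiency checking from a dilution series.
"""

import numpy as np

from calseize import primer_efficiency, relative_expression, simulate_qpcr

# dilution series: Ct rises ~3.32 cycles per 10-fold dilution for a
# perfectly doubling primer pair
dilutions = np.array([0.0, -1.0, -2.0, -3.0])
cts = 21.0 - 3.34 * dilutions
eff = primer_efficiency(dilutions, cts)
print(f"primer efficiency: {eff['efficiency']:.3f} "
      f"(slope {eff['slope']:.3f}, acceptable={eff['acceptable']})")

panel = simulate_qpcr(true_fold_change=15.4, ct_noise_sd=0.15, n_pools=3, seed=4)
rel = relative_expression(panel)
print(f"recovered fold change: {rel.fold_change:.2f} (ddCt {rel.ddct:+.2f})")
spread = sorted(rel.per_sample_fold.values())
print(f"per-pool fold range (control pools sit near 1): "
      f"{spread[0]:.2f} .. {spread[-1]:.2f}")
# With noiseless Cts the recovery is exact; 0.15-cycle noise leaves the
# estimate within a few percent of the true 15.4-fold change.
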