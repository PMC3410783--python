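"""qPCR validation arithmetic: 2^−ΔΔCT and a standard curve.

A miRNA measured at CT 22 in treated tissue vs 24.5 in control, with the
reference gene steady at CT 20, and an mRNA quantified against a
five-point 10-fold dilution series.
"""

import numpy as np

from hyperomir.pcr import absolute_quantify, delta_delta_ct, fit_standard_curve

fold = delta_delta_ct(target_ct_treated=22.0, ref_ct_treated=20.0,
                      target_ct_control=24.5, ref_ct_control=20.0)
print(f"2^-ddCT fold change: {fold:.2f}  "
      "(CT fell 2.5 cycles relative to the reference -> ~5.7-fold up)\n")

log10_q = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
ct = np.array([33.1, 29.8, 26.4, 23.1, 19.7])  # near-ideal dilution series
curve = fit_standard_curve(log10_q, ct)
print(f"Standard curve: slope {curve.slope:.2f} cycles/decade, "
      f"efficiency {100 * curve.efficiency:.1f}% "
      f"({'plausible' if curve.plausible else 'suspect'}), R^2 {curve.r_squared:.4f}")
sample_ct = 25.0
print(f"A sample at CT {sample_ct} contains {absolute_quantify(sample_ct, curve):.0f} "
      "units by inverting the curve.")
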