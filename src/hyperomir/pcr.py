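"""qPCR quantification: relative 2^−ΔΔCT and standard-curve absolute.

The ΔΔCT method reports the fold change of a target between a treated
and a control condition, each normalized to a reference gene measured in
the same sample, assuming perfect doubling per cycle.  Standard-curve
quantification fits CT against log10 input quantity of a dilution
series; the slope gives the amplification efficiency
(10^(−1/slope) − 1; −3.32 cycles/decade ≈ 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "delta_delta_ct", "fit_standard_curve", "absolute_quantify"]

#: efficiency window considered physically plausible for a real assay
PLAUSIBLE_EFFICIENCY = (0.7, 1.3)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line CT = slope · log10(Q) + intercept."""

    slope: float        # cycles per log10 quantity; negative
    intercept: float    # cycles at Q = 1
    efficiency: float   # 10^(-1/slope) - 1; 1.0 = perfect doubling
    r_squared: float

    @property
    def plausible(self) -> bool:
        lo, hi = PLAUSIBLE_EFFICIENCY
        return lo <= self.efficiency <= hi


def delta_delta_ct(target_ct_treated: float, ref_ct_treated: float,
                   target_ct_control: float, ref_ct_control: float) -> float:
    """Fold change 2^−ΔΔCT between treated and control conditions.

    ΔΔCT = (target − reference)_treated − (target − reference)_control;
    invariant to adding a constant to all four CT inputs.
    """
    cts = (target_ct_treated, ref_ct_treated, target_ct_control, ref_ct_control)
    if not all(np.isfinite(cts)):
        raise ValueError("all CT inputs must be finite")
    ddct = (target_ct_treated - ref_ct_treated) - (target_ct_control - ref_ct_control)
    return float(2.0 ** -ddct)


def fit_standard_curve(log10_quantities, ct_values) -> StandardCurve:
    """Fit a dilution series; raises when the quantities do not vary."""
    x = np.asarray(log10_quantities, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >=2 (quantity, CT) points of equal length")
    if np.unique(x).size < 2:
        raise ValueError("standard quantities are all equal; slope undefined")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative (CT falls with input)")
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0)
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        efficiency=efficiency,
        r_squared=float(res.rvalue**2),
    )


def absolute_quantify(ct: float, curve: StandardCurve) -> float:
    """Quantity from a sample CT by inverting the standard curve."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))
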