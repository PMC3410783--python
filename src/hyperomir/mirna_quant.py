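"""TaqMan low-density-array miRNA quantification.

Raw real-time PCR cycle-threshold (CT) tables are transformed in three
steps: a detectability ceiling (undetected reactions and CT > 35 are set
to 35 cycles), normalization against the endogenous small nuclear U6 RNA
control (ΔCT = CT_miRNA − CT_U6, per sample), and absolute quantification
as copies per cell via ``10^((40 − CT)/3.34) / 22``, which assumes 30 pg
of total RNA per cell and near-ideal PCR efficiency (a 3.34-cycle shift
corresponds to a 10-fold abundance change).

Higher ΔCT means lower expression; downstream differential-expression
statistics therefore run on −ΔCT so that positive effects mean
up-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantConstants",
    "DEFAULT_CONSTANTS",
    "apply_ct_ceiling",
    "normalize_delta_ct",
    "ct_to_copy_number",
    "copy_number_to_ct",
    "detect_expressed",
    "mean_copy_number",
]

#: Accepted spellings of an undetected reaction in TLDA exports.  All are
#: mapped to NaN by the readers and then to the ceiling CT.
UNDETECTED_MARKERS = frozenset({"", "na", "n/a", "undetermined", "undetected"})


@dataclass(frozen=True)
class QuantConstants:
    """Constants of the CT → copy-number transformation.

    ``rna_per_cell_pg`` is carried as provenance only: the divisor 22
    already embodies the 30 pg-per-cell assumption in the closed formula.
    """

    ceiling_ct: float = 35.0      # cycles; detectability ceiling
    max_cycles: float = 40.0      # cycles; PCR run length
    log10_slope: float = 3.34     # cycles per 10-fold abundance change
    per_cell_divisor: float = 22.0
    rna_per_cell_pg: float = 30.0

    def __post_init__(self) -> None:
        for name in ("ceiling_ct", "max_cycles", "log10_slope", "per_cell_divisor", "rna_per_cell_pg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ceiling_ct >= self.max_cycles:
            raise ValueError("ceiling_ct must be below max_cycles")


DEFAULT_CONSTANTS = QuantConstants()


def apply_ct_ceiling(table: pd.DataFrame, constants: QuantConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Clamp CT values at the detectability ceiling.

    Values above ``constants.ceiling_ct`` and undetected reactions (NaN)
    are replaced by the ceiling; everything else is untouched.  Negative
    CT values are physically impossible and raise.
    """
    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative CT values are invalid")
    clipped = np.where(np.isnan(values) | (values > constants.ceiling_ct), constants.ceiling_ct, values)
    return pd.DataFrame(clipped, index=table.index, columns=table.columns)


def normalize_delta_ct(table: pd.DataFrame, control_id: str = "U6") -> pd.DataFrame:
    """Per-sample ΔCT = CT_miRNA − CT_control; the control row is removed.

    ΔCT is invariant to per-sample additive shifts (plate effects on a
    whole sample column cancel).  Raises if the control row is absent or
    duplicated.
    """
    hits = (table.index == control_id).sum()
    if hits == 0:
        raise ValueError(f"endogenous control row {control_id!r} not found in CT table")
    if hits > 1:
        raise ValueError(f"endogenous control row {control_id!r} appears {hits} times")
    control = table.loc[control_id].astype(float)
    delta = table.drop(index=control_id).astype(float).sub(control, axis=1)
    if not np.isfinite(delta.to_numpy()).all():
        raise ValueError("non-finite delta-CT values; apply the CT ceiling first")
    return delta


def ct_to_copy_number(ct, constants: QuantConstants = DEFAULT_CONSTANTS):
    """Copies per cell from a CT value: ``10^((max_cycles − ct)/slope) / divisor``.

    Strictly decreasing in ct; a ``log10_slope``-cycle decrease multiplies
    the copy number by exactly 10.  Accepts scalars or arrays.
    """
    arr = np.asarray(ct, dtype=float)
    if np.any(arr <= 0) or np.any(arr > constants.max_cycles):
        raise ValueError(f"CT out of range (0, {constants.max_cycles}]")
    copies = np.power(10.0, (constants.max_cycles - arr) / constants.log10_slope) / constants.per_cell_divisor
    if np.isscalar(ct):
        return float(copies)
    return copies


def copy_number_to_ct(copies, constants: QuantConstants = DEFAULT_CONSTANTS):
    """Algebraic inverse of :func:`ct_to_copy_number`."""
    arr = np.asarray(copies, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("copy number must be strictly positive")
    ct = constants.max_cycles - constants.log10_slope * np.log10(arr * constants.per_cell_divisor)
    if np.isscalar(copies):
        return float(ct)
    return ct


def detect_expressed(
    table: pd.DataFrame,
    design: pd.DataFrame,
    constants: QuantConstants = DEFAULT_CONSTANTS,
    min_fraction: float = 0.5,
    control_id: str = "U6",
) -> set[str]:
    """miRNAs detected in at least one design cell.

    A miRNA counts as detected when its CT is strictly below the ceiling
    in at least ``min_fraction`` of the samples of at least one
    (timepoint, treatment) cell.  The ceiling must already be applied.
    The control row, if present, is never reported.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if table.empty:
        return set()
    rows = table.drop(index=control_id, errors="ignore")
    detected: set[str] = set()
    for (_, _), cell in design.groupby(["timepoint", "treatment"], sort=False):
        samples = [s for s in cell["sample_id"] if s in rows.columns]
        if not samples:
            continue
        frac_below = (rows[samples] < constants.ceiling_ct).mean(axis=1)
        detected.update(rows.index[frac_below >= min_fraction])
    return detected


def mean_copy_number(table: pd.DataFrame, constants: QuantConstants = DEFAULT_CONSTANTS,
                     control_id: str = "U6") -> pd.Series:
    """Per-miRNA mean copies per cell across samples (control excluded)."""
    rows = table.drop(index=control_id, errors="ignore")
    copies = ct_to_copy_number(rows.to_numpy(dtype=float), constants)
    return pd.Series(copies.mean(axis=1), index=rows.index, name="copy_number")
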