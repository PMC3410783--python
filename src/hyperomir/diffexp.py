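"""Per-probe two-factor differential expression over the hyperoxia design.

The design is an incomplete timepoint × treatment layout (no P1-O2 cell),
so each probe is fit with a cell-means model: per-cell sample means plus
a residual variance pooled across all cells, with N − k residual degrees
of freedom.  The three contrasts of interest are

* group A — developmental: (P29, RA) vs (P14, RA)
* group B — early hyperoxia: (P14, O2) vs (P14, RA)
* group C — late hyperoxia: (P29, O2) vs (P29, RA)

each tested with a two-sided pooled-variance t statistic (the group
comparison a factorial ANOVA package performs inside the fitted model).
Significance combines a signed fold-change gate with a
Benjamini–Hochberg FDR gate, and `bh_p_cutoff` recovers the raw-p
threshold equivalent to the FDR gate — the mechanism behind reporting
"FDR < 0.05" as a plain p cutoff.  Probes significant in at least one
contrast are then partitioned into the cross-group expression patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONTRASTS",
    "CellMeansFit",
    "fit_two_factor_model",
    "contrast_test",
    "signed_fold_change",
    "bh_adjust",
    "bh_p_cutoff",
    "run_contrasts",
    "select_significant",
    "classify_patterns",
    "MRNA_PATTERNS",
    "MIRNA_PATTERNS",
    "DISCORDANT",
]

#: group label -> (numerator cell, denominator cell); cells are (timepoint, treatment)
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "A": (("P29", "RA"), ("P14", "RA")),
    "B": (("P14", "O2"), ("P14", "RA")),
    "C": (("P29", "O2"), ("P29", "RA")),
}

DISCORDANT = "discordant"

# pattern label -> (membership, sign); membership is the B/C occupancy for
# hyperoxia patterns or "A" for the developmental contrast
MRNA_PATTERNS = {
    ("A", "up"): "1", ("A", "down"): "2",
    ("B", "up"): "3", ("B", "down"): "4",
    ("BC", "up"): "5", ("BC", "down"): "6",
    ("C", "up"): "7", ("C", "down"): "8",
}
MIRNA_PATTERNS = {
    ("A", "down"): "1", ("A", "up"): "2",
    ("B", "up"): "3", ("B", "down"): "4",
    ("BC", "up"): "5",
    ("C", "up"): "6",
}


@dataclass
class CellMeansFit:
    """Per-probe cell means with a pooled residual variance.

    ``means`` is probes × cells (columns labelled "P14:RA" etc.),
    ``s2`` the pooled residual variance per probe, ``df_resid`` the
    shared residual degrees of freedom and ``n_per_cell`` the replicate
    count per cell.  ``degenerate`` flags probes with zero residual
    variance, whose p-values are undefined.
    """

    means: pd.DataFrame
    s2: pd.Series
    df_resid: int
    n_per_cell: dict[str, int]

    @property
    def degenerate(self) -> pd.Series:
        return self.s2 == 0.0


def _cell_label(timepoint: str, treatment: str) -> str:
    return f"{timepoint}:{treatment}"


def fit_two_factor_model(matrix: pd.DataFrame, design: pd.DataFrame) -> CellMeansFit:
    """Fit the cell-means model to every probe at once.

    Residual variance is the within-cell sum of squares pooled over all
    cells divided by N − k; this equals the df-weighted mean of per-cell
    sample variances.  Requires ≥2 replicates per cell so the variance
    is estimable, and a strictly positive residual df.
    """
    missing = set(design["sample_id"]) - set(matrix.columns)
    if missing:
        raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
    cells = design.groupby(["timepoint", "treatment"], sort=False)["sample_id"].apply(list)
    n_total = 0
    means = {}
    sse = np.zeros(matrix.shape[0])
    n_per_cell: dict[str, int] = {}
    for (tp, tr), samples in cells.items():
        if len(samples) < 2:
            raise ValueError(f"design cell ({tp}, {tr}) has {len(samples)} replicate(s); need >=2")
        sub = matrix[samples].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        label = _cell_label(tp, tr)
        means[label] = mu
        n_per_cell[label] = len(samples)
        sse += ((sub - mu[:, None]) ** 2).sum(axis=1)
        n_total += len(samples)
    df_resid = n_total - len(n_per_cell)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    means_df = pd.DataFrame(means, index=matrix.index)
    s2 = pd.Series(sse / df_resid, index=matrix.index, name="s2")
    return CellMeansFit(means=means_df, s2=s2, df_resid=df_resid, n_per_cell=n_per_cell)


def contrast_test(fit: CellMeansFit, group: str) -> pd.DataFrame:
    """Two-sided pooled-variance t-test of one contrast for every probe.

    Returns a frame with ``log2_diff`` (numerator − denominator cell
    mean) and ``p_raw``.  Degenerate probes (zero pooled variance) get
    p = NaN and ``degenerate`` = True rather than a spurious certainty.
    """
    num_cell, den_cell = CONTRASTS[group]
    num, den = _cell_label(*num_cell), _cell_label(*den_cell)
    for label in (num, den):
        if label not in fit.means.columns:
            raise ValueError(f"cell {label} absent from fit")
    diff = fit.means[num] - fit.means[den]
    inv_n = 1.0 / fit.n_per_cell[num] + 1.0 / fit.n_per_cell[den]
    se = np.sqrt(fit.s2 * inv_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    degenerate = fit.degenerate.to_numpy()
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {"log2_diff": diff, "p_raw": p, "degenerate": degenerate},
        index=fit.means.index,
    )


def signed_fold_change(log2_diff):
    """Reciprocal-negative fold change: 2^d for d ≥ 0, −2^(−d) otherwise.

    |signed_fc| ≥ 1 always; the sign matches the direction of change and
    the magnitude is the linear-scale ratio, the convention behind
    "fold change > |2|" cutoffs.
    """
    arr = np.asarray(log2_diff, dtype=float)
    fc = np.where(arr >= 0, np.power(2.0, arr), -np.power(2.0, -arr))
    if np.isscalar(log2_diff):
        return float(fc)
    return fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_p_cutoff(p_values, fdr: float) -> float:
    """Raw-p threshold equivalent to the BH gate at level ``fdr``.

    Returns the largest order statistic p_(i) with p_(i) ≤ fdr·i/m, or
    0.0 when nothing passes.  Selecting p ≤ cutoff reproduces exactly
    the set with BH-adjusted q ≤ fdr — this is how an FDR criterion
    gets reported as a plain raw-p cutoff.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        return 0.0
    thresholds = fdr * np.arange(1, p.size + 1) / p.size
    passing = np.nonzero(p <= thresholds)[0]
    if passing.size == 0:
        return 0.0
    return float(p[passing[-1]])


def run_contrasts(matrix: pd.DataFrame, design: pd.DataFrame,
                  groups: tuple[str, ...] = ("A", "B", "C")) -> pd.DataFrame:
    """Fit once, test every contrast, attach fold changes and per-group BH q.

    Returns a long frame indexed by (probe_id, group) with columns
    log2_diff, signed_fc, p_raw, q_bh, degenerate.  BH adjustment is
    applied within each contrast across probes.
    """
    fit = fit_two_factor_model(matrix, design)
    frames = []
    for group in groups:
        res = contrast_test(fit, group)
        res["group"] = group
        res["signed_fc"] = signed_fold_change(res["log2_diff"].to_numpy())
        ok = ~res["degenerate"].to_numpy()
        q = np.full(len(res), np.nan)
        if ok.any():
            q[ok] = bh_adjust(res.loc[ok, "p_raw"].to_numpy())
        res["q_bh"] = q
        frames.append(res)
    out = pd.concat(frames)
    out.index.name = "probe_id"
    return out.reset_index().set_index(["probe_id", "group"])


def select_significant(results: pd.DataFrame, fc_cutoff: float, fdr: float) -> dict[str, dict[str, str]]:
    """Per group, probes passing both gates, tagged "up"/"down".

    A probe is significant when |signed_fc| > fc_cutoff and q_bh < fdr.
    Raising fc_cutoff or lowering fdr never adds probes.
    """
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    sig: dict[str, dict[str, str]] = {}
    for group, sub in results.groupby(level="group", sort=False):
        sub = sub.droplevel("group")
        mask = (sub["signed_fc"].abs() > fc_cutoff) & (sub["q_bh"] < fdr)
        sig[group] = {
            probe: ("up" if fc > 0 else "down")
            for probe, fc in sub.loc[mask, "signed_fc"].items()
        }
    return sig


def _membership(sig: dict[str, dict[str, str]], probe: str) -> str | None:
    in_b = probe in sig.get("B", {})
    in_c = probe in sig.get("C", {})
    if in_b and in_c:
        return "BC"
    if in_b:
        return "B"
    if in_c:
        return "C"
    return None


def classify_patterns(sig: dict[str, dict[str, str]], platform: str) -> dict[str, str]:
    """Assign every significant probe one cross-group expression pattern.

    Hyperoxia membership (B, C, or both) takes precedence over the
    developmental contrast A; probes significant only in A get the A
    patterns.  B∩C probes with opposite signs — and, for miRNAs,
    sign/membership combinations outside the printed pattern set —
    land in the explicit "discordant" bucket so the partition stays
    complete and auditable.
    """
    if platform not in ("mRNA", "miRNA"):
        raise ValueError("platform must be 'mRNA' or 'miRNA'")
    table = MRNA_PATTERNS if platform == "mRNA" else MIRNA_PATTERNS
    labels: dict[str, str] = {}
    probes = set(sig.get("A", {})) | set(sig.get("B", {})) | set(sig.get("C", {}))
    for probe in probes:
        member = _membership(sig, probe)
        if member == "BC" and sig["B"][probe] != sig["C"][probe]:
            labels[probe] = DISCORDANT
            continue
        if member is not None:
            sign = sig["B" if member in ("B", "BC") else "C"][probe]
            labels[probe] = table.get((member, sign), DISCORDANT)
        else:
            labels[probe] = table[("A", sig["A"][probe])]
    return labels
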