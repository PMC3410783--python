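"""Anti-correlation × predicted-target miRNA–mRNA pairing.

A miRNA up-regulated under hyperoxia is a candidate repressor of every
mRNA probe down-regulated in the same contrast group; crossing those
candidates with a computational target-prediction database keeps only
pairs the database also predicts.  Pair counts are reported at probe
level (collapsed over groups B and C) and unique targets at gene level,
mirroring the distinct "probe pairs" vs "unique mRNAs" bookkeeping of
array-era integration studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetPredictionDB",
    "PairSet",
    "candidate_pairs",
    "intersect_predictions",
    "cross_database_overlap",
    "per_mirna_target_table",
]


@dataclass(frozen=True)
class TargetPredictionDB:
    """One source's miRNA → predicted-target-gene mapping.

    ``probe_map`` translates array probe ids to the gene ids the
    database speaks (the ID-conversion step between platforms); probes
    it does not cover are dropped, with a logged count, when
    intersecting.
    """

    source: str
    entries: dict[str, frozenset[str]]
    probe_map: dict[str, str] = field(default_factory=dict)

    def n_entries(self) -> int:
        return sum(len(genes) for genes in self.entries.values())

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((m, g) for m, genes in self.entries.items() for g in genes)


@dataclass(frozen=True)
class PairSet:
    """Candidate pairs retained by one prediction database.

    ``pairs`` keeps (mirna, probe, group) provenance; ``n_pairs`` counts
    distinct (mirna, probe) pairs pooled over the hyperoxia groups;
    ``unique_mrnas`` is the gene-level image of the retained probes.
    """

    source: str
    pairs: frozenset[tuple[str, str, str]]
    n_pairs: int
    unique_mrnas: frozenset[str]
    n_unmapped_probes: int = 0


def candidate_pairs(
    sig_mirna: dict[str, dict[str, str]],
    sig_mrna: dict[str, dict[str, str]],
    groups: tuple[str, ...] = ("B", "C"),
) -> set[tuple[str, str, str]]:
    """Cartesian product, per group, of up-miRNAs × down-mRNA probes.

    The same-group requirement encodes the anti-correlation logic: the
    repressor must rise in the same contrast where its putative target
    falls.  Empty inputs yield an empty set.
    """
    out: set[tuple[str, str, str]] = set()
    for group in groups:
        ups = [m for m, s in sig_mirna.get(group, {}).items() if s == "up"]
        downs = [p for p, s in sig_mrna.get(group, {}).items() if s == "down"]
        out.update((m, p, group) for m in ups for p in downs)
    return out


def intersect_predictions(candidates: set[tuple[str, str, str]], db: TargetPredictionDB) -> PairSet:
    """Keep candidates whose (miRNA, mapped gene) the database predicts."""
    kept: set[tuple[str, str, str]] = set()
    unmapped: set[str] = set()
    for mirna, probe, group in candidates:
        gene = db.probe_map.get(probe)
        if gene is None:
            unmapped.add(probe)
            continue
        if gene in db.entries.get(mirna, frozenset()):
            kept.add((mirna, probe, group))
    if unmapped:
        logger.info("%s: dropped %d candidate probes with no gene mapping", db.source, len(unmapped))
    collapsed = {(m, p) for m, p, _ in kept}
    unique = frozenset(db.probe_map[p] for _, p in collapsed)
    return PairSet(
        source=db.source,
        pairs=frozenset(kept),
        n_pairs=len(collapsed),
        unique_mrnas=unique,
        n_unmapped_probes=len(unmapped),
    )


def cross_database_overlap(a: PairSet, b: PairSet) -> frozenset[str]:
    """Genes called as targets by both prediction sources."""
    return a.unique_mrnas & b.unique_mrnas


def per_mirna_target_table(pairs: PairSet, copy_numbers: pd.Series) -> pd.DataFrame:
    """Per-miRNA summary: mean copies per cell and predicted-target count.

    One row per miRNA appearing in ``pairs``, sorted by copy number
    descending; miRNAs without a copy-number estimate keep their row
    with a missing value and sort last.
    """
    counts: dict[str, set[str]] = {}
    for mirna, probe in {(m, p) for m, p, _ in pairs.pairs}:
        counts.setdefault(mirna, set()).add(probe)
    table = pd.DataFrame(
        {
            "mirna_id": list(counts),
            "copy_number": [copy_numbers.get(m) for m in counts],
            "n_predicted_targets": [len(v) for v in counts.values()],
        }
    )
    return (
        table.sort_values(["copy_number", "mirna_id"], ascending=[False, True], na_position="last")
        .reset_index(drop=True)
    )
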