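"""Synthetic study generator with planted ground truth.

Emulates the data of a neonatal-hyperoxia (BPD-model) profiling study:
a 3-timepoint × 2-treatment design with no (P1, O2) cell, a log2 mRNA
array matrix with Gaussian probe noise, a TaqMan low-density-array CT
table derived from planted miRNA abundances (one PCR cycle per 2-fold
change, detection ceiling at 35 cycles), target-prediction databases
containing the planted repression edges plus random decoys, and a
gene-set annotation with one over-represented term.  Every planted item
is recorded in a :class:`GroundTruth`, giving downstream statistics an
exact oracle.

All generators are deterministic given their arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .integration import TargetPredictionDB

__all__ = [
    "GroundTruth",
    "generate_design",
    "generate_mrna_matrix",
    "generate_mirna_ct",
    "generate_prediction_db",
    "generate_annotation",
    "sample_gene_list",
    "link_ground_truths",
    "gene_for_probe",
    "default_probe_map",
    "generate_study",
]

TIMEPOINTS = ("P1", "P14", "P29")
RA_CELLS = (("P1", "RA"), ("P14", "RA"), ("P29", "RA"))
O2_CELLS = (("P14", "O2"), ("P29", "O2"))

#: log2-intensity range for null probe baselines (typical array range)
BASELINE_RANGE = (4.0, 12.0)
#: planted probes draw baselines from this sub-range so a default
#: low-expression filter cannot silently remove them
PLANTED_BASELINE_RANGE = (7.0, 11.0)
#: baseline ΔCT range for expressed miRNAs (CT comfortably below ceiling)
BASELINE_DCT_RANGE = (2.0, 10.0)

CONTROL_ID = "U6"


@dataclass(frozen=True)
class GroundTruth:
    """Record of everything the generators planted.

    ``de_mrna`` and ``de_mirna`` map contrast group → {feature id →
    signed log2 effect}; positive means up-regulated in that group's
    numerator cell.  ``edges`` holds planted (miRNA, gene) repressions:
    each edge's miRNA is planted up and its gene down in the same
    hyperoxia group, so the anti-correlation pairing can recover it.
    """

    de_mrna: dict[str, dict[str, float]] = field(default_factory=dict)
    de_mirna: dict[str, dict[str, float]] = field(default_factory=dict)
    edges: frozenset[tuple[str, str]] = frozenset()
    enriched_term: str | None = None
    seed: int = 0

    def as_significant_sets(self, platform: str) -> dict[str, dict[str, str]]:
        """Planted memberships in the shape of a significance call."""
        source = self.de_mrna if platform == "mRNA" else self.de_mirna
        return {
            group: {fid: ("up" if eff > 0 else "down") for fid, eff in plants.items()}
            for group, plants in source.items()
        }

    def to_json(self) -> str:
        payload = {
            "de_mrna": self.de_mrna,
            "de_mirna": self.de_mirna,
            "edges": sorted(list(e) for e in self.edges),
            "enriched_term": self.enriched_term,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            de_mrna=payload["de_mrna"],
            de_mirna=payload["de_mirna"],
            edges=frozenset(tuple(e) for e in payload["edges"]),
            enriched_term=payload["enriched_term"],
            seed=payload["seed"],
        )


def generate_design(reps_ra: int = 2, reps_o2: int = 3, seed: int = 0) -> pd.DataFrame:
    """Sample sheet for the incomplete timepoint × treatment layout.

    Normoxia (RA) cells exist at P1, P14 and P29 with ``reps_ra``
    replicates each; hyperoxia (O2) cells only at P14 and P29 with
    ``reps_o2`` replicates — newborn pups cannot have been exposed by
    P1.  Fewer than 2 replicates anywhere leaves the residual variance
    inestimable and raises.
    """
    if reps_ra < 2 or reps_o2 < 2:
        raise ValueError("need >=2 replicates per design cell (variance inestimable)")
    rows = []
    for (tp, tr), reps in [(c, reps_ra) for c in RA_CELLS] + [(c, reps_o2) for c in O2_CELLS]:
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"{tp}_{tr}_{r}", "timepoint": tp, "treatment": tr, "replicate": r})
    return pd.DataFrame(rows)


def _plant_layout(n_features: int, n_de_per_group: int, n_shared_bc: int,
                  ids: list[str]) -> dict[str, dict[str, int]]:
    """Assign disjoint feature blocks to groups A, B, C and shared B∩C.

    Within each block the first half is planted up (+1) and the rest
    down (−1); shared B∩C plants carry the same sign in both cells.
    """
    needed = 3 * n_de_per_group + n_shared_bc
    if needed > n_features:
        raise ValueError(
            f"requested {needed} planted features but only {n_features} available (plants must be disjoint)"
        )
    layout: dict[str, dict[str, int]] = {"A": {}, "B": {}, "C": {}, "BC": {}}
    cursor = 0
    for group in ("A", "B", "C"):
        block = ids[cursor:cursor + n_de_per_group]
        cursor += n_de_per_group
        half = (len(block) + 1) // 2
        for i, fid in enumerate(block):
            layout[group][fid] = 1 if i < half else -1
    block = ids[cursor:cursor + n_shared_bc]
    half = (len(block) + 1) // 2
    for i, fid in enumerate(block):
        layout["BC"][fid] = 1 if i < half else -1
    return layout


# columns of the design whose cell means a group's plant shifts.  Group A
# (developmental) shifts the whole P29 timepoint, both treatments, so the
# P14-RA vs P29-RA difference appears without contaminating contrast C
# (which compares the two P29 cells against each other).
_PLANT_CELLS = {
    "A": [("P29", "RA"), ("P29", "O2")],
    "B": [("P14", "O2")],
    "C": [("P29", "O2")],
}


def _effect_table(layout: dict[str, dict[str, int]], effect: float) -> dict[str, dict[str, float]]:
    """Signed per-group effects, with shared B∩C plants entered in both groups."""
    truth: dict[str, dict[str, float]] = {g: {} for g in ("A", "B", "C")}
    for group in ("A", "B", "C"):
        for fid, sign in layout[group].items():
            truth[group][fid] = sign * effect
    for fid, sign in layout["BC"].items():
        truth["B"][fid] = sign * effect
        truth["C"][fid] = sign * effect
    truth = {g: plants for g, plants in truth.items() if plants}
    return truth


def generate_mrna_matrix(
    design: pd.DataFrame,
    n_probes: int = 2000,
    n_de_per_group: int = 50,
    effect_log2: float = 2.5,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_shared_bc: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """log2 expression matrix with planted group-specific shifts.

    Null probes draw baselines uniform on [4, 12] log2 units; planted
    probes on [7, 11] so default low-expression filtering cannot erase
    them.  A group's plant shifts the relevant cell means by
    ±``effect_log2``: group A between P29-RA and P14-RA, group B in
    P14-O2, group C in P29-O2; shared B∩C plants shift both O2 cells.
    Gaussian noise with sd ``noise_sd`` is added everywhere.
    """
    if effect_log2 < 0 or noise_sd <= 0:
        raise ValueError("effect_log2 must be >=0 and noise_sd > 0")
    rng = np.random.default_rng(seed)
    probe_ids = [f"probe_{i:05d}" for i in range(n_probes)]
    layout = _plant_layout(n_probes, n_de_per_group, n_shared_bc, probe_ids)

    baseline = rng.uniform(*BASELINE_RANGE, size=n_probes)
    planted_idx = [int(fid.split("_")[1]) for grp in layout.values() for fid in grp]
    baseline[planted_idx] = rng.uniform(*PLANTED_BASELINE_RANGE, size=len(planted_idx))

    samples = design["sample_id"].tolist()
    matrix = np.tile(baseline[:, None], (1, len(samples)))
    cell_of = {row.sample_id: (row.timepoint, row.treatment) for row in design.itertuples()}
    index_of = {fid: i for i, fid in enumerate(probe_ids)}
    for group, members in layout.items():
        target_cells = set(_PLANT_CELLS[group]) if group != "BC" else {("P14", "O2"), ("P29", "O2")}
        cols = [j for j, s in enumerate(samples) if cell_of[s] in target_cells]
        for fid, sign in members.items():
            matrix[index_of[fid], cols] += sign * effect_log2
    matrix += rng.normal(0.0, noise_sd, size=matrix.shape)

    truth = GroundTruth(de_mrna=_effect_table(layout, effect_log2), seed=seed)
    return pd.DataFrame(matrix, index=pd.Index(probe_ids, name="probe_id"), columns=samples), truth


def generate_mirna_ct(
    design: pd.DataFrame,
    n_mirnas: int = 521,
    n_de_per_group: int = 8,
    effect_log2: float = 2.5,
    noise_sd: float = 0.25,
    u6_ct: float = 20.0,
    ceiling_fraction: float = 0.0,
    seed: int = 0,
    n_shared_bc: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw TLDA-style CT table generated from planted abundances.

    CT = u6_ct + baseline ΔCT − planted effect (in cycles), assuming
    ideal PCR efficiency: one cycle per 2-fold abundance change, the
    same assumption the copy-number formula's 3.34 cycles/decade
    encodes.  ``ceiling_fraction`` of the miRNAs (never the planted
    ones) are forced above 35 cycles in every sample to exercise the
    ceiling rule, and a U6 control row at ``u6_ct`` ± noise is included.
    """
    if not 0 < u6_ct < 40:
        raise ValueError("u6_ct must lie in (0, 40)")
    if not 0 <= ceiling_fraction <= 1:
        raise ValueError("ceiling_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(n_mirnas)]
    n_ceiling = int(round(ceiling_fraction * n_mirnas))
    n_planted = 3 * n_de_per_group + n_shared_bc
    if n_planted + n_ceiling > n_mirnas:
        raise ValueError("planted and forced-ceiling miRNAs cannot overlap; reduce one of them")
    layout = _plant_layout(n_mirnas - n_ceiling, n_de_per_group, n_shared_bc, mirna_ids)

    base_dct = rng.uniform(*BASELINE_DCT_RANGE, size=n_mirnas)
    samples = design["sample_id"].tolist()
    ct = u6_ct + np.tile(base_dct[:, None], (1, len(samples)))
    cell_of = {row.sample_id: (row.timepoint, row.treatment) for row in design.itertuples()}
    index_of = {fid: i for i, fid in enumerate(mirna_ids)}
    for group, members in layout.items():
        target_cells = set(_PLANT_CELLS[group]) if group != "BC" else {("P14", "O2"), ("P29", "O2")}
        cols = [j for j, s in enumerate(samples) if cell_of[s] in target_cells]
        for fid, sign in members.items():
            # expression up (sign +) lowers CT by effect_log2 cycles
            ct[index_of[fid], cols] -= sign * effect_log2
    ct += rng.normal(0.0, noise_sd, size=ct.shape)

    if n_ceiling:
        forced = np.arange(n_mirnas - n_ceiling, n_mirnas)
        high = rng.uniform(36.0, 39.0, size=(n_ceiling, len(samples)))
        ct[forced, :] = np.maximum(high + rng.normal(0.0, noise_sd, size=high.shape), 35.01)
    ct = np.minimum(ct, 39.99)

    u6_row = u6_ct + rng.normal(0.0, noise_sd, size=len(samples))
    table = pd.DataFrame(
        np.vstack([ct, u6_row]),
        index=pd.Index(mirna_ids + [CONTROL_ID], name="mirna_id"),
        columns=samples,
    )
    truth = GroundTruth(de_mirna=_effect_table(layout, effect_log2), seed=seed)
    return table, truth


def generate_prediction_db(
    truth: GroundTruth,
    decoys_per_mirna: int,
    miss_rate: float,
    universe: set[str],
    seed: int,
    source_name: str,
    probe_map: dict[str, str] | None = None,
) -> TargetPredictionDB:
    """Prediction database = planted edges thinned at ``miss_rate`` plus decoys.

    Each true (miRNA, gene) edge appears with probability 1 − miss_rate;
    each miRNA additionally predicts ``decoys_per_mirna`` random genes
    that are not its true targets.  No duplicate entries.
    """
    if not 0 <= miss_rate <= 1:
        raise ValueError("miss_rate must lie in [0, 1]")
    true_targets: dict[str, set[str]] = {}
    for mirna, gene in truth.edges:
        true_targets.setdefault(mirna, set()).add(gene)
    all_true_genes = set().union(*true_targets.values()) if true_targets else set()
    if not all_true_genes <= set(universe):
        raise ValueError("universe must contain every gene in truth.edges")
    rng = np.random.default_rng(seed)
    pool = np.array(sorted(universe))
    entries: dict[str, frozenset[str]] = {}
    for mirna in sorted(true_targets):
        kept = {g for g in sorted(true_targets[mirna]) if rng.random() < 1.0 - miss_rate}
        non_targets = pool[~np.isin(pool, sorted(true_targets[mirna]))]
        n_decoys = min(decoys_per_mirna, non_targets.size)
        decoys = rng.choice(non_targets, size=n_decoys, replace=False) if n_decoys else []
        entries[mirna] = frozenset(kept) | frozenset(str(g) for g in decoys)
    return TargetPredictionDB(source=source_name, entries=entries, probe_map=dict(probe_map or {}))


def generate_annotation(
    universe: set[str],
    n_terms: int = 50,
    planted_term_size: int = 40,
    planted_list_bias: float = 8.0,
    seed: int = 0,
) -> tuple[AnnotationSet, str]:
    """Random gene-set annotation plus one designated enrichable term.

    Returns the annotation and the planted term's id.  The bias factor
    takes effect only when :func:`sample_gene_list` composes a query
    list; at bias 1 the planted term is indistinguishable from the
    random ones.
    """
    if planted_term_size > len(universe):
        raise ValueError("planted_term_size exceeds the universe")
    if planted_list_bias < 1:
        raise ValueError("planted_list_bias must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.array(sorted(universe))
    terms: dict[str, frozenset[str]] = {}
    for i in range(n_terms):
        members = rng.choice(pool, size=planted_term_size, replace=False)
        terms[f"GO:{i + 1:07d}"] = frozenset(str(g) for g in members)
    planted_id = "GO:9000000"
    planted = rng.choice(pool, size=planted_term_size, replace=False)
    terms[planted_id] = frozenset(str(g) for g in planted)
    return AnnotationSet(terms=terms, universe=frozenset(str(g) for g in pool)), planted_id


def sample_gene_list(
    annotation: AnnotationSet,
    term_id: str,
    bias: float,
    list_size: int,
    seed: int,
) -> set[str]:
    """Draw an "interesting" gene list over-sampling one term's members.

    Weighted sampling without replacement from the universe, members of
    ``term_id`` weighted ``bias`` against 1 for everything else; bias 1
    is a uniform draw.
    """
    members = annotation.terms[term_id]
    pool = np.array(sorted(annotation.universe))
    weights = np.where(np.isin(pool, sorted(members)), bias, 1.0)
    rng = np.random.default_rng(seed)
    picked = rng.choice(pool, size=list_size, replace=False, p=weights / weights.sum())
    return {str(g) for g in picked}


def gene_for_probe(probe_id: str) -> str:
    """Canonical synthetic probe → gene mapping (1:1)."""
    return probe_id.replace("probe_", "gene_")


def default_probe_map(probe_ids) -> dict[str, str]:
    return {p: gene_for_probe(p) for p in probe_ids}


def link_ground_truths(
    mrna_truth: GroundTruth,
    mirna_truth: GroundTruth,
    targets_per_mirna: int,
    seed: int,
    probe_map: dict[str, str] | None = None,
) -> GroundTruth:
    """Combine platform truths and plant miRNA→gene repression edges.

    For each hyperoxia group (B, C), every miRNA planted up acquires up
    to ``targets_per_mirna`` targets sampled from the probes planted
    down in the same group, so each edge satisfies the anti-correlation
    requirement by construction.
    """
    rng = np.random.default_rng(seed)
    probe_map = probe_map or {}
    edges: set[tuple[str, str]] = set()
    for group in ("B", "C"):
        ups = sorted(m for m, eff in mirna_truth.de_mirna.get(group, {}).items() if eff > 0)
        downs = sorted(p for p, eff in mrna_truth.de_mrna.get(group, {}).items() if eff < 0)
        genes = [probe_map.get(p, gene_for_probe(p)) for p in downs]
        for mirna in ups:
            k = min(targets_per_mirna, len(genes))
            if k == 0:
                continue
            chosen = rng.choice(len(genes), size=k, replace=False)
            edges.update((mirna, genes[i]) for i in chosen)
    return GroundTruth(
        de_mrna=mrna_truth.de_mrna,
        de_mirna=mirna_truth.de_mirna,
        edges=frozenset(edges),
        enriched_term=mrna_truth.enriched_term or mirna_truth.enriched_term,
        seed=mrna_truth.seed,
    )


def generate_study(seed: int = 0, **overrides) -> dict:
    """Generate a full coherent study: design, both platforms, truth, databases, annotation.

    Returns a dict with keys design, mrna, ct, truth, probe_map, dbs
    (two sources with different miss rates), annotation, planted_term.
    Keyword overrides are forwarded to the individual generators (see
    their signatures); independent sub-seeds are derived from ``seed``.
    """
    params = {
        "reps_ra": 2, "reps_o2": 3,
        "n_probes": 2000, "mrna_de_per_group": 50, "mrna_shared_bc": 25,
        "n_mirnas": 521, "mirna_de_per_group": 8, "mirna_shared_bc": 20,
        "effect_log2": 2.5, "noise_sd": 0.25, "u6_ct": 20.0, "ceiling_fraction": 0.2,
        "targets_per_mirna": 10, "decoys_per_mirna": 30,
        "miss_rate_db1": 0.2, "miss_rate_db2": 0.35,
        "n_terms": 50, "planted_term_size": 40, "planted_list_bias": 8.0,
    }
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
    params.update(overrides)
    sub = [int(s) for s in np.random.SeedSequence(seed).generate_state(6)]

    design = generate_design(params["reps_ra"], params["reps_o2"], seed)
    mrna, mrna_truth = generate_mrna_matrix(
        design, params["n_probes"], params["mrna_de_per_group"], params["effect_log2"],
        params["noise_sd"], seed=sub[0], n_shared_bc=params["mrna_shared_bc"],
    )
    ct, mirna_truth = generate_mirna_ct(
        design, params["n_mirnas"], params["mirna_de_per_group"], params["effect_log2"],
        params["noise_sd"], params["u6_ct"], params["ceiling_fraction"],
        seed=sub[1], n_shared_bc=params["mirna_shared_bc"],
    )
    probe_map = default_probe_map(mrna.index)
    truth = link_ground_truths(mrna_truth, mirna_truth, params["targets_per_mirna"], sub[2], probe_map)
    universe = set(probe_map.values())
    db1 = generate_prediction_db(truth, params["decoys_per_mirna"], params["miss_rate_db1"],
                                 universe, sub[3], "synthetic-db-A", probe_map)
    db2 = generate_prediction_db(truth, params["decoys_per_mirna"], params["miss_rate_db2"],
                                 universe, sub[4], "synthetic-db-B", probe_map)
    annotation, planted_term = generate_annotation(
        universe, params["n_terms"], params["planted_term_size"], params["planted_list_bias"], sub[5],
    )
    truth = GroundTruth(de_mrna=truth.de_mrna, de_mirna=truth.de_mirna, edges=truth.edges,
                        enriched_term=planted_term, seed=seed)
    return {
        "design": design, "mrna": mrna, "ct": ct, "truth": truth,
        "probe_map": probe_map, "dbs": [db1, db2],
        "annotation": annotation, "planted_term": planted_term,
        "params": params,
    }
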