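"""End-to-end orchestration: data → normalization → statistics → pairing → enrichment.

A run is driven by a :class:`RunConfig` (hand-editable YAML) holding
either input-file paths or a synthetic-generation block, plus the
significance thresholds (mRNA fold change 2, miRNA fold change 4, FDR
0.05 by default).  Stages execute in a fixed order, write every
intermediate table to the output directory, log their funnel sizes
(input → retained → significant → pairs), and produce a machine-readable
report whose counts mirror the summary numbers such a study prints:
per-group significant probes, pattern memberships, detected miRNAs,
per-database pair counts, the cross-database overlap, derived raw-p
cutoffs, and top enriched terms.  Identical config + seed reproduces
the report bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexp, enrichment, io, mirna_quant, mrna_norm, synthetic
from .integration import (PairSet, candidate_pairs, cross_database_overlap,
                          intersect_predictions, per_mirna_target_table)

logger = logging.getLogger(__name__)

__all__ = ["Thresholds", "RunConfig", "StageError", "run_pipeline", "validate_report", "REPORT_SCHEMA"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class Thresholds:
    mrna_fc: float = 2.0
    mirna_fc: float = 4.0
    fdr: float = 0.05
    low_expression_min_log2: float = 5.0
    detection_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mrna_fc < 1 or self.mirna_fc < 1:
            raise ValueError("fold-change cutoffs must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0 < self.detection_min_fraction <= 1:
            raise ValueError("detection_min_fraction must lie in (0, 1]")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``inputs``/``synthetic`` is set.

    ``inputs`` holds file paths (mrna, design, ct, predictions list,
    probe_map, annotation); ``synthetic`` holds keyword overrides for
    :func:`hyperomir.synthetic.generate_study`.
    """

    outdir: str
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be configured")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)

    def echo(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "synthetic": self.synthetic,
            "inputs": self.inputs,
            "thresholds": vars(self.thresholds) | {},
        }


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _load_or_generate(config: RunConfig, outdir: Path) -> dict:
    if config.synthetic is not None:
        study = synthetic.generate_study(seed=config.seed, **config.synthetic)
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        io.write_expression_tsv(study["mrna"], inputs_dir / "mrna_expression.tsv")
        io.write_ct_tsv(study["ct"], inputs_dir / "mirna_ct.tsv")
        io.write_design_csv(study["design"], inputs_dir / "design.csv")
        for db in study["dbs"]:
            io.write_predictions_tsv(db, inputs_dir / f"predictions_{db.source}.tsv")
        io.write_probe_map_tsv(study["probe_map"], inputs_dir / "probe_map.tsv")
        io.write_gmt(study["annotation"], inputs_dir / "annotation.gmt")
        (inputs_dir / "ground_truth.json").write_text(study["truth"].to_json())
        return study
    paths = config.inputs
    mrna = io.read_expression_tsv(paths["mrna"])
    design = io.read_design_csv(paths["design"])
    ct = io.read_ct_tsv(paths["ct"])
    probe_map = io.read_probe_map_tsv(paths["probe_map"]) if paths.get("probe_map") else {}
    dbs = []
    for p in paths.get("predictions", []):
        db = io.read_predictions_tsv(p)
        dbs.append(type(db)(source=db.source, entries=db.entries, probe_map=probe_map))
    annotation = None
    if paths.get("annotation"):
        universe = set(probe_map.values()) if probe_map else None
        annotation = io.read_gmt(paths["annotation"], universe=universe)
    return {"design": design, "mrna": mrna, "ct": ct, "probe_map": probe_map,
            "dbs": dbs, "annotation": annotation, "truth": None}


def _sig_summary(sig: dict[str, dict[str, str]]) -> dict:
    return {
        group: {
            "up": sum(1 for s in members.values() if s == "up"),
            "down": sum(1 for s in members.values() if s == "down"),
        }
        for group, members in sig.items()
    }


def _pattern_counts(labels: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for label in labels.values():
        counts[label] = counts.get(label, 0) + 1
    return dict(sorted(counts.items()))


def _cutoffs(results: pd.DataFrame, fdr: float) -> dict[str, float]:
    out = {}
    for group, sub in results.groupby(level="group", sort=False):
        p = sub["p_raw"].dropna().to_numpy()
        out[group] = diffexp.bh_p_cutoff(p, fdr) if p.size else 0.0
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    with _stage("load"):
        study = _load_or_generate(config, outdir)
        design = study["design"]

    with _stage("mrna_norm"):
        mrna_raw = study["mrna"]
        normalized = mrna_norm.quantile_normalize(mrna_raw)
        filtered = mrna_norm.low_expression_filter(normalized, th.low_expression_min_log2)
        logger.info("mrna_norm: %d probes in, %d after low-expression filter",
                    len(mrna_raw), len(filtered))
        io.write_expression_tsv(filtered, outdir / "mrna_normalized_filtered.tsv")

    with _stage("mirna_quant"):
        ct = mirna_quant.apply_ct_ceiling(study["ct"])
        detected = mirna_quant.detect_expressed(ct, design, min_fraction=th.detection_min_fraction)
        delta = mirna_quant.normalize_delta_ct(ct)
        delta = delta.loc[sorted(detected)]
        mirna_expr = -delta  # higher ΔCT = lower expression; flip so + means up
        copies = mirna_quant.mean_copy_number(ct)
        logger.info("mirna_quant: %d assays in, %d detected", len(study["ct"]) - 1, len(detected))
        io.write_ct_tsv(delta, outdir / "mirna_delta_ct.tsv")
        copies.to_csv(outdir / "mirna_copy_number.tsv", sep="\t", header=True)

    with _stage("diffexp"):
        mrna_results = diffexp.run_contrasts(filtered, design)
        mirna_results = diffexp.run_contrasts(mirna_expr, design)
        sig_mrna = diffexp.select_significant(mrna_results, th.mrna_fc, th.fdr)
        sig_mirna = diffexp.select_significant(mirna_results, th.mirna_fc, th.fdr)
        patterns_mrna = diffexp.classify_patterns(sig_mrna, "mRNA")
        patterns_mirna = diffexp.classify_patterns(sig_mirna, "miRNA")
        for name, res, sig, pats in (("mrna", mrna_results, sig_mrna, patterns_mrna),
                                     ("mirna", mirna_results, sig_mirna, patterns_mirna)):
            table = res.reset_index()
            table["sign"] = [sig.get(g, {}).get(p, "") for p, g in zip(table["probe_id"], table["group"])]
            table["pattern"] = [pats.get(p, "") if s else "" for p, s in zip(table["probe_id"], table["sign"])]
            table.to_csv(outdir / f"diffexp_{name}.tsv", sep="\t", index=False, float_format="%.6g")

    with _stage("integration"):
        candidates = candidate_pairs(sig_mirna, sig_mrna)
        pair_sets: list[PairSet] = []
        for db in study["dbs"]:
            ps = intersect_predictions(candidates, db)
            pair_sets.append(ps)
            pd.DataFrame(sorted(ps.pairs), columns=["mirna_id", "probe_id", "group"]).to_csv(
                outdir / f"pairs_{ps.source}.tsv", sep="\t", index=False)
            per_mirna_target_table(ps, copies).to_csv(
                outdir / f"per_mirna_targets_{ps.source}.tsv", sep="\t", index=False, float_format="%.3f")
        overlap = (sorted(cross_database_overlap(pair_sets[0], pair_sets[1]))
                   if len(pair_sets) >= 2 else [])
        logger.info("integration: %d candidate triples, %s pairs kept, %d genes in cross-db overlap",
                    len(candidates), [ps.n_pairs for ps in pair_sets], len(overlap))

    with _stage("enrichment"):
        enrich_report = {"top_terms_targeted": [], "comparison_top": []}
        annotation = study.get("annotation")
        if annotation is not None and pair_sets:
            targeted = set().union(*(ps.unique_mrnas for ps in pair_sets))
            down_genes = {
                study["probe_map"].get(p, p)
                for group in ("B", "C")
                for p, s in sig_mrna.get(group, {}).items()
                if s == "down"
            }
            untargeted = down_genes - targeted
            if targeted:
                records = enrichment.hypergeometric_enrichment(targeted, annotation)
                top = enrichment.top_terms(records, alpha=0.05, max_n=10)
                top.to_csv(outdir / "enrichment_targeted.tsv", sep="\t", index=False, float_format="%.4g")
                enrich_report["top_terms_targeted"] = [
                    {"term": r.term, "overlap_count": int(r.overlap_count), "p": float(r.p)}
                    for r in top.itertuples()
                ]
            if targeted and untargeted:
                comparison = enrichment.compare_term_enrichment(targeted, untargeted, annotation)
                comparison.head(10).to_csv(outdir / "enrichment_comparison.tsv", sep="\t",
                                           index=False, float_format="%.4g")
                enrich_report["comparison_top"] = [
                    {"term": r.term, "spread": float(r.spread)}
                    for r in comparison.head(10).itertuples()
                ]

    with _stage("report"):
        report = {
            "seed": config.seed,
            "config": config.echo(),
            "mrna": {
                "n_probes_input": int(len(mrna_raw)),
                "n_probes_after_filter": int(len(filtered)),
                "raw_p_cutoffs": _cutoffs(mrna_results, th.fdr),
                "significant": _sig_summary(sig_mrna),
                "n_significant_union": len(set().union(*sig_mrna.values())) if sig_mrna else 0,
                "patterns": _pattern_counts(patterns_mrna),
            },
            "mirna": {
                "n_assays_input": int(len(study["ct"]) - 1),
                "n_detected": int(len(detected)),
                "raw_p_cutoffs": _cutoffs(mirna_results, th.fdr),
                "significant": _sig_summary(sig_mirna),
                "n_significant_union": len(set().union(*sig_mirna.values())) if sig_mirna else 0,
                "patterns": _pattern_counts(patterns_mirna),
            },
            "integration": {
                "n_candidate_triples": len(candidates),
                "databases": [
                    {"source": ps.source, "n_pairs": ps.n_pairs,
                     "n_unique_mrnas": len(ps.unique_mrnas)}
                    for ps in pair_sets
                ],
                "n_overlap_mrnas": len(overlap),
            },
            "enrichment": enrich_report,
        }
        validate_report(report)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# report schema (published copy lives at docs/report.schema.json)

REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["seed", "config", "mrna", "mirna", "integration", "enrichment"],
    "properties": {
        "seed": {"type": "integer"},
        "config": {"type": "object", "required": ["outdir", "seed", "thresholds"]},
        "mrna": {
            "type": "object",
            "required": ["n_probes_input", "n_probes_after_filter", "raw_p_cutoffs",
                         "significant", "n_significant_union", "patterns"],
            "properties": {
                "n_probes_input": {"type": "integer"},
                "n_probes_after_filter": {"type": "integer"},
                "raw_p_cutoffs": {"type": "object"},
                "significant": {"type": "object"},
                "n_significant_union": {"type": "integer"},
                "patterns": {"type": "object"},
            },
        },
        "mirna": {
            "type": "object",
            "required": ["n_assays_input", "n_detected", "raw_p_cutoffs",
                         "significant", "n_significant_union", "patterns"],
        },
        "integration": {
            "type": "object",
            "required": ["n_candidate_triples", "databases", "n_overlap_mrnas"],
            "properties": {
                "n_candidate_triples": {"type": "integer"},
                "databases": {"type": "array"},
                "n_overlap_mrnas": {"type": "integer"},
            },
        },
        "enrichment": {
            "type": "object",
            "required": ["top_terms_targeted", "comparison_top"],
            "properties": {
                "top_terms_targeted": {"type": "array"},
                "comparison_top": {"type": "array"},
            },
        },
    },
}

_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "string": lambda v: isinstance(v, str),
    "boolean": lambda v: isinstance(v, bool),
}


def _check_schema(value, schema: dict, path: str) -> None:
    expected = schema.get("type")
    if expected is not None and not _TYPE_CHECKS[expected](value):
        raise ValueError(f"report{path}: expected {expected}, found {type(value).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"report{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check_schema(value[key], sub, f"{path}.{key}")


def validate_report(report: dict) -> None:
    """Structural validation of a run report against :data:`REPORT_SCHEMA`."""
    _check_schema(report, REPORT_SCHEMA, "")
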