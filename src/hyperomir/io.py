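"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with a header row; the first column holds
feature ids.  Parsers validate shape line by line so malformed files
fail with the offending line number, and every writer/reader pair
round-trips losslessly (byte-stable under a fixed seed).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .integration import TargetPredictionDB
from .mirna_quant import UNDETECTED_MARKERS

__all__ = [
    "ParseError",
    "read_expression_tsv", "write_expression_tsv",
    "read_ct_tsv", "write_ct_tsv",
    "read_design_csv", "write_design_csv",
    "read_predictions_tsv", "write_predictions_tsv",
    "read_probe_map_tsv", "write_probe_map_tsv",
    "read_gmt", "write_gmt",
]

FLOAT_FORMAT = "%.6f"


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _read_delimited(path, sep: str) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: file is empty")
    header = lines[0].split(sep)
    width = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != width:
            raise ParseError(f"{path}: line {lineno}: expected {width} fields, found {len(fields)}")
        rows.append(fields)
    return header, rows


def _numeric_table(path, allow_markers: bool) -> pd.DataFrame:
    header, rows = _read_delimited(path, "\t")
    ids = [r[0] for r in rows]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dupes):
        raise ParseError(f"{path}: duplicate row ids: {sorted(set(dupes))}")
    values = np.empty((len(rows), len(header) - 1))
    for i, row in enumerate(rows):
        for j, raw in enumerate(row[1:]):
            token = raw.strip()
            if allow_markers and token.lower() in UNDETECTED_MARKERS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError as exc:
                raise ParseError(f"{path}: line {i + 2}: non-numeric value {raw!r}") from exc
    return pd.DataFrame(values, index=pd.Index(ids, name=header[0]), columns=header[1:])


def read_expression_tsv(path) -> pd.DataFrame:
    """Probes × samples log2 matrix; duplicate probe ids or ragged rows raise."""
    matrix = _numeric_table(path, allow_markers=False)
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "probe_id",
                  float_format=FLOAT_FORMAT)


def read_ct_tsv(path, control_id: str = "U6") -> pd.DataFrame:
    """miRNAs × samples raw CT table; undetected markers become NaN.

    Accepts empty fields, "NA", "Undetermined" and similar spellings as
    undetected.  Requires the endogenous-control row.
    """
    table = _numeric_table(path, allow_markers=True)
    if control_id not in table.index:
        raise ParseError(f"{path}: endogenous control row {control_id!r} is missing")
    return table


def write_ct_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label=table.index.name or "mirna_id",
                 float_format=FLOAT_FORMAT)


def read_design_csv(path) -> pd.DataFrame:
    header, rows = _read_delimited(path, ",")
    expected = ["sample_id", "timepoint", "treatment", "replicate"]
    if header != expected:
        raise ParseError(f"{path}: header must be {','.join(expected)}")
    design = pd.DataFrame(rows, columns=header)
    design["replicate"] = design["replicate"].astype(int)
    if design["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return design


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_predictions_tsv(path) -> TargetPredictionDB:
    """Prediction database TSV with columns source, mirna_id, gene_id.

    The file must hold a single source; duplicate (miRNA, gene) entries
    raise.
    """
    header, rows = _read_delimited(path, "\t")
    if header != ["source", "mirna_id", "gene_id"]:
        raise ParseError(f"{path}: header must be source\\tmirna_id\\tgene_id")
    sources = {r[0] for r in rows}
    if len(sources) > 1:
        raise ParseError(f"{path}: multiple sources in one file: {sorted(sources)}")
    seen: set[tuple[str, str]] = set()
    entries: dict[str, set[str]] = {}
    for lineno, (_, mirna, gene) in enumerate(rows, start=2):
        if (mirna, gene) in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate entry ({mirna}, {gene})")
        seen.add((mirna, gene))
        entries.setdefault(mirna, set()).add(gene)
    source = sources.pop() if sources else Path(path).stem
    return TargetPredictionDB(source=source,
                              entries={m: frozenset(g) for m, g in entries.items()})


def write_predictions_tsv(db: TargetPredictionDB, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\tmirna_id\tgene_id\n")
        for mirna in sorted(db.entries):
            for gene in sorted(db.entries[mirna]):
                fh.write(f"{db.source}\t{mirna}\t{gene}\n")


def read_probe_map_tsv(path) -> dict[str, str]:
    header, rows = _read_delimited(path, "\t")
    if header != ["probe_id", "gene_id"]:
        raise ParseError(f"{path}: header must be probe_id\\tgene_id")
    mapping: dict[str, str] = {}
    for lineno, (probe, gene) in enumerate(rows, start=2):
        if probe in mapping:
            raise ParseError(f"{path}: line {lineno}: probe {probe!r} mapped twice")
        mapping[probe] = gene
    return mapping


def write_probe_map_tsv(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_id\n")
        for probe in sorted(mapping):
            fh.write(f"{probe}\t{mapping[probe]}\n")


def read_gmt(path, universe: set[str] | None = None) -> AnnotationSet:
    """GMT gene-set file: term, description, then tab-separated members.

    The universe defaults to the union of all members; pass the array's
    full gene list to test against the proper reference.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: need term, description and >=1 member")
        term = fields[0]
        if term in terms:
            raise ParseError(f"{path}: line {lineno}: duplicate term {term!r}")
        terms[term] = frozenset(fields[2:])
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return AnnotationSet(terms=terms, universe=frozenset(universe))


def write_gmt(annotation: AnnotationSet, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            members = "\t".join(sorted(annotation.terms[term]))
            fh.write(f"{term}\t{descriptions.get(term, 'synthetic gene set')}\t{members}\n")
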