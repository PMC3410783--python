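"""Hypergeometric gene-set over-representation and two-list comparison.

For a gene list drawn from a reference universe, each annotated term is
tested with the one-sided hypergeometric tail P(X ≥ overlap) — the urn
model behind DAVID-style GO over-representation.  Reporting follows the
array-literature convention of ranking passing terms by overlap count,
and the two-list comparison ranks terms by the spread of their −log10 p
values between the lists (the population standard deviation of the two
values, |x − y| / 2), so the top terms are those enriched most
differently in the two lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "hypergeometric_enrichment",
    "top_terms",
    "compare_term_enrichment",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Term → gene-set annotation against a fixed reference universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe is empty")
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} contains genes outside the universe")


def hypergeometric_enrichment(gene_list: set[str], annotation: AnnotationSet) -> pd.DataFrame:
    """One-sided over-representation p for every term.

    Genes outside the universe are dropped (and logged); an empty list
    after filtering raises.  For each term, p = P(X ≥ k) with X
    hypergeometric(universe, term, list); fold enrichment is the ratio
    of observed to expected overlap fractions.
    """
    inside = set(gene_list) & annotation.universe
    dropped = len(set(gene_list)) - len(inside)
    if dropped:
        logger.info("dropped %d query genes outside the annotation universe", dropped)
    if not inside:
        raise ValueError("gene list is empty (after removing genes outside the universe)")
    m_univ = len(annotation.universe)
    n_list = len(inside)
    records = []
    for term, genes in annotation.terms.items():
        k = len(inside & genes)
        k_term = len(genes)
        p = float(stats.hypergeom.sf(k - 1, m_univ, k_term, n_list))
        expected = k_term / m_univ
        fold = (k / n_list) / expected if expected > 0 else np.nan
        records.append(
            {
                "term": term,
                "overlap_count": k,
                "list_size": n_list,
                "term_size": k_term,
                "universe_size": m_univ,
                "p": min(p, 1.0),
                "fold_enrichment": fold,
            }
        )
    return pd.DataFrame.from_records(records)


def top_terms(records: pd.DataFrame, alpha: float = 0.05, max_n: int = 10) -> pd.DataFrame:
    """Terms with p < alpha, ranked by overlap count (ties: smaller p, then id)."""
    passing = records[records["p"] < alpha]
    return (
        passing.sort_values(["overlap_count", "p", "term"], ascending=[False, True, True])
        .head(max_n)
        .reset_index(drop=True)
    )


def compare_term_enrichment(list_a: set[str], list_b: set[str], annotation: AnnotationSet) -> pd.DataFrame:
    """Differential enrichment of two gene lists over the same annotation.

    Returns one row per term with −log10 p for each list and
    ``spread`` = |x − y| / 2, sorted by spread descending; equally
    enriched terms rank last.
    """
    rec_a = hypergeometric_enrichment(list_a, annotation).set_index("term")
    rec_b = hypergeometric_enrichment(list_b, annotation).set_index("term")
    common = rec_a.index.intersection(rec_b.index)
    skipped = set(rec_a.index).symmetric_difference(rec_b.index)
    if skipped:
        logger.info("skipped %d terms absent from one computation", len(skipped))
    neglog_a = -np.log10(rec_a.loc[common, "p"].to_numpy())
    neglog_b = -np.log10(rec_b.loc[common, "p"].to_numpy())
    out = pd.DataFrame(
        {
            "term": common,
            "neglog10_p_a": neglog_a,
            "neglog10_p_b": neglog_b,
            "spread": np.abs(neglog_a - neglog_b) / 2.0,
        }
    )
    return out.sort_values(["spread", "term"], ascending=[False, True]).reset_index(drop=True)
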