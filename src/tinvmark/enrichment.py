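"""Over-representation analysis against a user-supplied annotation catalog.

One-sided hypergeometric test per term (probability of observing at least
the actual overlap between the query set and the term's gene set, given
the universe), with Bonferroni correction over the tested terms. The
catalog is a generic term -> gene table (for instance gene-disease sets);
no particular database is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCatalog:
    """Term-to-gene annotation sets over a gene universe.

    ``terms`` maps term_id -> (term_name, gene set). The universe defaults
    to all annotated genes and may be overridden (e.g. to the platform's
    measured genes).
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"catalog: term {term_id} has no genes")
            stray = genes - self.universe
            if stray:
                raise ValidationError(
                    f"catalog: term {term_id} annotates genes outside the "
                    f"universe: {sorted(stray)}"
                )

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, universe: Iterable[str] | None = None
    ) -> "AnnotationCatalog":
        missing = {"term_id", "term_name", "gene_symbol"} - set(table.columns)
        if missing:
            raise ValidationError(f"catalog: missing columns {sorted(missing)}")
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, group in table.groupby("term_id", sort=True):
            names = group["term_name"].unique()
            terms[str(term_id)] = (str(names[0]), frozenset(group["gene_symbol"]))
        if universe is None:
            universe = frozenset(table["gene_symbol"])
        return cls(terms, frozenset(universe))


def read_catalog(
    path: Path | str, universe: Iterable[str] | None = None
) -> AnnotationCatalog:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationCatalog.from_table(table, universe=universe)


def enrich(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set, Bonferroni-corrected.

    Query genes outside the universe are dropped and logged; an empty
    query after filtering is an error. Returns one row per term, sorted by
    corrected p-value, with columns ``term_id, term_name, overlap_genes,
    overlap, term_size, raw_p, corrected_p, significant``.
    """
    query_set = set(query)
    kept = query_set & catalog.universe
    dropped = sorted(query_set - kept)
    if dropped:
        logger.info("enrich: dropped %d gene(s) outside the universe: %s",
                    len(dropped), dropped)
    if not kept:
        raise ValidationError("enrich: query empty after universe filtering")

    n_universe = len(catalog.universe)
    n_query = len(kept)
    n_terms = len(catalog.terms)
    rows = []
    for term_id in sorted(catalog.terms):
        term_name, genes = catalog.terms[term_id]
        overlap = sorted(kept & genes)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N=universe, K=term, n=query)
        raw_p = float(stats.hypergeom.sf(k - 1, n_universe, len(genes), n_query))
        raw_p = min(1.0, max(0.0, raw_p))
        corrected = min(1.0, raw_p * n_terms)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "overlap_genes": ",".join(overlap),
                "overlap": k,
                "term_size": len(genes),
                "raw_p": raw_p,
                "corrected_p": corrected,
                "significant": corrected < alpha,
            }
        )
    result = pd.DataFrame(rows)
    return result.sort_values(
        ["corrected_p", "raw_p", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
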