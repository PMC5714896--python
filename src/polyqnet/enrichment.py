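"""Over-representation analysis of gene sets against a GMT annotation.

Each term is tested with the hypergeometric upper tail against the supplied
background universe, adjusted across all tested terms with
Benjamini-Hochberg.  A term passes when the adjusted p-value is below
``enrich_alpha`` and at least ``min_genes_per_term`` query genes hit it.
This is a plain hypergeometric test, not the EASE-modified score of online
annotation services, so absolute p-values differ from theirs; the
downstream shared-term counts only require a consistent definition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import GeneSetCollection

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "overlap_count",
    "term_size_in_background",
    "raw_p",
    "adjusted_p",
    "passes",
    "overlap_genes",
]


def enrich(
    gene_set: set[str],
    background: set[str],
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Enrichment of ``gene_set`` over every term of the collection.

    Terms are intersected with the background before testing; only terms
    with at least one background member are tested, and BH adjustment runs
    across all of them.
    """
    config = config or AnalysisConfig()
    gene_set = set(gene_set)
    background = set(background)
    stray = gene_set - background
    if stray:
        raise ValueError(
            f"{len(stray)} query genes absent from background, e.g. "
            f"{sorted(stray)[:3]}"
        )
    if not gene_set:
        warnings.warn("empty query gene set; no terms tested")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    restricted = collection.restricted_to(background)
    n_bg = len(background)
    n_query = len(gene_set)
    records = []
    for term_id in sorted(restricted.terms):
        name, members = restricted.terms[term_id]
        overlap = gene_set & members
        k, m = len(overlap), len(members)
        raw_p = float(stats.hypergeom.sf(k - 1, n_bg, m, n_query)) if k else 1.0
        records.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap_count": k,
                "term_size_in_background": m,
                "raw_p": min(raw_p, 1.0),
                "overlap_genes": ";".join(sorted(overlap)),
            }
        )
    if not records:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    table = pd.DataFrame.from_records(records)
    table["adjusted_p"] = multipletests(table["raw_p"], method="fdr_bh")[1]
    table["passes"] = (table["adjusted_p"] < config.enrich_alpha) & (
        table["overlap_count"] >= config.min_genes_per_term
    )
    return table[RESULT_COLUMNS]


def passing_terms(result: pd.DataFrame) -> set[str]:
    if not len(result):
        return set()
    return set(result.loc[result["passes"], "term_id"])


def term_sets_for_polyq(
    partner_sets: dict[str, set[str]],
    background: set[str],
    collection: GeneSetCollection,
    config: AnalysisConfig | None = None,
) -> tuple[dict[str, set[str]], dict[str, pd.DataFrame]]:
    """Passing term-id set per seed gene, plus the full enrichment tables."""
    config = config or AnalysisConfig()
    term_sets: dict[str, set[str]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for gene in sorted(partner_sets):
        partners = set(partner_sets[gene]) & background
        if partners:
            table = enrich(partners, background, collection, config)
        else:
            table = pd.DataFrame(columns=RESULT_COLUMNS)
        tables[gene] = table
        term_sets[gene] = passing_terms(table)
    return term_sets, tables
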