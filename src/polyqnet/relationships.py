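"""Three-tier relationships between the polyglutamine genes.

For each unordered pair of the nine seed genes a region yields: (1) direct
co-expression, the consensus r with a strict-threshold flag; (2) shared
partners, the overlap of the two partner sets with a one-tailed Fisher
(hypergeometric upper-tail) p-value against the gene universe; (3)
functional overlap, the number of enriched annotation terms the two partner
sets share, flagged at a configurable floor.  Gene-family overlaps count
partners inside a named family (e.g. ubiquitin-conjugating enzymes).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datatypes import ConsensusMatrix


def direct_coexpression(
    consensus: ConsensusMatrix, pair: tuple[str, str], threshold: float = 0.5
) -> tuple[float, bool]:
    """Consensus r of a seed-gene pair and its strict-threshold flag."""
    a, b = pair
    if a == b:
        raise ValueError(f"pair must be two distinct genes, got ({a!r}, {b!r})")
    r = consensus.r(a, b)
    return r, bool(r > threshold)


def shared_partner_test(
    set_a: set[str], set_b: set[str], background_n: int
) -> tuple[int, float]:
    """Overlap of two partner sets and its one-tailed Fisher p-value.

    The p-value is P(X >= overlap) for X hypergeometric with population
    ``background_n``, ``|A|`` successes and ``|B|`` draws (the enrichment
    tail); overlap 0 gives p = 1.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if background_n < len(union):
        raise ValueError(
            f"background ({background_n}) smaller than |A ∪ B| ({len(union)})"
        )
    overlap = len(set_a & set_b)
    p = float(stats.hypergeom.sf(overlap - 1, background_n, len(set_a), len(set_b)))
    return overlap, min(p, 1.0)


def functional_overlap(
    terms_a: set[str], terms_b: set[str], min_shared_terms: int = 10
) -> tuple[int, bool]:
    """Count of shared enriched terms and the at-least-``min_shared_terms`` flag."""
    count = len(set(terms_a) & set(terms_b))
    return count, count >= min_shared_terms


def relationship_table(
    consensus: ConsensusMatrix,
    partner_sets: dict[str, set[str]],
    term_sets: dict[str, set[str]],
    universe: set[str],
    config: AnalysisConfig | None = None,
    polyq_genes: list[str] | None = None,
) -> pd.DataFrame:
    """All 36 pairwise relationship records for one region.

    ``partner_sets`` and ``term_sets`` map each of the nine seed genes (by
    the identifier used in the consensus matrix) to its partner genes and
    passing term ids; ``universe`` is the full post-probe-selection gene
    set.  For each pair the two seed genes are excluded from both partner
    sets and from the Fisher background (switchable via config).
    """
    config = config or AnalysisConfig()
    genes = polyq_genes if polyq_genes is not None else sorted(partner_sets)
    missing = [g for g in genes if g not in partner_sets or g not in term_sets]
    if missing:
        raise KeyError(f"partner/term sets missing for genes: {missing}")
    records = []
    for a, b in combinations(genes, 2):
        r, direct_flag = direct_coexpression(consensus, (a, b), config.coexpr_threshold)
        if config.exclude_pair_from_partner_sets:
            set_a = set(partner_sets[a]) - {a, b}
            set_b = set(partner_sets[b]) - {a, b}
            background_n = len(universe - {a, b})
        else:
            set_a, set_b = set(partner_sets[a]), set(partner_sets[b])
            background_n = len(universe)
        overlap, fisher_p = shared_partner_test(set_a, set_b, background_n)
        shared_terms, functional_flag = functional_overlap(
            term_sets[a], term_sets[b], config.min_shared_terms
        )
        records.append(
            {
                "region": consensus.region_name,
                "gene_a": a,
                "gene_b": b,
                "direct_r": r,
                "direct_flag": direct_flag,
                "shared_count": overlap,
                "fisher_p": fisher_p,
                "shared_terms": shared_terms,
                "functional_flag": functional_flag,
            }
        )
    table = pd.DataFrame.from_records(records)
    if config.bh_over_pairs:
        table["fisher_p_adj"] = multipletests(table["fisher_p"], method="fdr_bh")[1]
        table["shared_flag"] = table["fisher_p_adj"] < config.fisher_alpha
    else:
        table["shared_flag"] = table["fisher_p"] < config.fisher_alpha
    return table


def gene_family_overlap(
    partner_set: set[str], family_members: set[str]
) -> tuple[list[str], int]:
    """Partners that belong to a gene family, with the count."""
    family_members = set(family_members)
    if not family_members:
        raise ValueError("gene family is empty")
    members = sorted(set(partner_set) & family_members)
    return members, len(members)


def polyq_mean_expression(
    gene_exprs, region_samples: pd.DataFrame, polyq_ids: list[str]
) -> pd.Series:
    """Mean regional expression of each seed gene.

    Averaged across a region's samples per donor first, then across donors
    (donors without samples in the region are skipped).
    """
    per_donor = []
    for donor_id in sorted(gene_exprs):
        ids = list(
            region_samples.loc[region_samples["donor_id"] == donor_id, "sample_id"]
        )
        if not ids:
            continue
        expr = gene_exprs[donor_id].expression.loc[polyq_ids, ids]
        per_donor.append(expr.mean(axis=1))
    if not per_donor:
        raise ValueError("no donor has samples in the region")
    return pd.concat(per_donor, axis=1).mean(axis=1)
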