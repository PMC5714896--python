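"""Consensus differential expression between a region and the rest of the brain.

Each donor is tested separately with two one-tailed Mann-Whitney U tests
(inside greater / inside less than outside).  A gene is called
differentially expressed when at least ``min_brains`` donors are significant
at ``de_alpha`` in the *same* tail; genes significant in opposing tails
across donors are not called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import GeneExpression, RegionAssignment


def mannwhitney_one_tailed(
    values_in, values_out, exact_cap: int = 12
) -> tuple[float, float]:
    """Two one-tailed Mann-Whitney p-values for one gene.

    Returns ``(p_upper, p_lower)``: the upper tail tests "inside
    stochastically greater than outside", the lower tail the reverse.  The
    exact null distribution is used when the combined sample size is at most
    ``exact_cap`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(values_in, dtype=float)
    y = np.asarray(values_out, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= exact_cap and no_ties) else "asymptotic"
    p_upper = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    p_lower = stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    return float(p_upper), float(p_lower)


def call_consensus(n_up: int, n_down: int, min_brains: int) -> str:
    """Consensus direction from per-donor same-tail significance counts."""
    if n_up >= min_brains and n_down < min_brains:
        return "up"
    if n_down >= min_brains and n_up < min_brains:
        return "down"
    if n_up >= min_brains and n_down >= min_brains:
        # cannot happen when min_brains > n_brains / 2; kept for safety
        return "none"
    return "none"


def consensus_de(
    gene_exprs: dict[str, GeneExpression],
    assignment: RegionAssignment,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene consensus differential-expression table.

    One row per gene with per-donor p-values and directions, the counts of
    donors significant in each tail, and the consensus direction under the
    same-tail ``min_brains`` rule.  With ``config.bonferroni_de`` the
    per-donor alpha is divided by the number of genes.
    """
    config = config or AnalysisConfig()
    donors = sorted(gene_exprs)
    first = gene_exprs[donors[0]]
    genes = list(first.expression.index)
    alpha = config.de_alpha / (len(genes) if config.bonferroni_de else 1)

    inside_ids = {
        (d, s)
        for d, s in assignment.inside_samples()[["donor_id", "sample_id"]].itertuples(
            index=False
        )
    }

    usable_donors = []
    p_up: dict[str, np.ndarray] = {}
    p_lo: dict[str, np.ndarray] = {}
    for donor in donors:
        ge = gene_exprs[donor]
        if list(ge.expression.index) != genes:
            raise ValueError("gene indices differ across donors")
        mask_in = np.array(
            [(donor, s) in inside_ids for s in ge.expression.columns], dtype=bool
        )
        n_in, n_out = int(mask_in.sum()), int((~mask_in).sum())
        if n_in == 0 or n_out == 0:
            continue
        usable_donors.append(donor)
        values = ge.expression.to_numpy(dtype=float)
        x, y = values[:, mask_in], values[:, ~mask_in]
        if n_in + n_out <= config.mw_exact_cap:
            pu = np.empty(len(genes))
            pl = np.empty(len(genes))
            for i in range(len(genes)):
                pu[i], pl[i] = mannwhitney_one_tailed(x[i], y[i], config.mw_exact_cap)
        else:
            pu = stats.mannwhitneyu(
                x, y, alternative="greater", method="asymptotic", axis=1
            ).pvalue
            pl = stats.mannwhitneyu(
                x, y, alternative="less", method="asymptotic", axis=1
            ).pvalue
        p_up[donor], p_lo[donor] = pu, pl

    if len(usable_donors) < config.min_brains:
        raise ValueError(
            f"only {len(usable_donors)} donors have samples on both sides of "
            f"the region; min_brains={config.min_brains}"
        )

    table = pd.DataFrame({"gene_id": genes})
    n_up = np.zeros(len(genes), dtype=int)
    n_down = np.zeros(len(genes), dtype=int)
    for donor in usable_donors:
        up = p_up[donor] < alpha
        down = p_lo[donor] < alpha
        n_up += up
        n_down += down
        table[f"p_upper_{donor}"] = p_up[donor]
        table[f"p_lower_{donor}"] = p_lo[donor]
        table[f"direction_{donor}"] = np.where(up, "up", np.where(down, "down", "none"))
    table["n_up"] = n_up
    table["n_down"] = n_down
    table["consensus_direction"] = [
        call_consensus(u, d, config.min_brains) for u, d in zip(n_up, n_down)
    ]
    table["n_significant_brains"] = np.where(
        table["consensus_direction"] == "up",
        n_up,
        np.where(table["consensus_direction"] == "down", n_down, np.maximum(n_up, n_down)),
    )
    return table


def de_gene_sets(de_table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(upregulated, downregulated) gene-id sets from a consensus DE table."""
    up = set(de_table.loc[de_table["consensus_direction"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["consensus_direction"] == "down", "gene_id"])
    return up, down
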