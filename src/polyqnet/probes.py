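"""Collapse multiple microarray probes per gene to a single representative.

The three-case rule: a gene measured by one probe keeps it; with two probes
the one with the higher variance wins (sample variance per donor, averaged
across donors); with three or more probes the one with the highest
connectivity wins (per donor, the sum of its Pearson correlations with
probes of other genes, averaged across donors).  Ties go to the
lexicographically smallest probe id so selection is order-independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import DonorExpression, GeneExpression


def probe_variance_score(probe_id: str, donors: list[DonorExpression]) -> float:
    """Mean across donors of the per-donor sample variance (n-1 denominator)."""
    variances = []
    for donor in donors:
        if probe_id not in donor.expression.index:
            raise KeyError(f"probe {probe_id!r} missing in donor {donor.donor_id}")
        values = donor.expression.loc[probe_id].to_numpy(dtype=float)
        variances.append(float(np.var(values, ddof=1)))
    return float(np.mean(variances))


def _safe_corr_vector(x: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Pearson r of vector x against each row of others; flat vectors give 0."""
    n = x.shape[0]
    xc = x - x.mean()
    oc = others - others.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    so = np.sqrt((oc ** 2).sum(axis=1))
    denom = sx * so
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (oc @ xc) / denom
    r[~np.isfinite(r)] = 0.0
    if sx == 0:
        r[:] = 0.0
    return r


def probe_connectivity_score(
    probe_id: str,
    donors: list[DonorExpression],
    probe_annotation: pd.DataFrame,
    signed: bool = True,
    scope: str = "other_genes",
) -> float:
    """Connectivity of one probe: summed correlations, averaged over donors.

    Per donor, the Pearson correlation of this probe with every probe of a
    different gene (or all other probes, with ``scope="all_probes"``) is
    summed; zero-variance probes contribute r = 0.  With ``signed=False``
    absolute correlations are summed.
    """
    gene_of = dict(zip(probe_annotation["probe_id"], probe_annotation["gene_id"]))
    own_gene = gene_of[probe_id]
    per_donor = []
    for donor in donors:
        if probe_id not in donor.expression.index:
            raise KeyError(f"probe {probe_id!r} missing in donor {donor.donor_id}")
        idx = donor.expression.index
        if scope == "other_genes":
            others = [p for p in idx if p != probe_id and gene_of.get(p) != own_gene]
        else:
            others = [p for p in idx if p != probe_id]
        if not others:
            per_donor.append(0.0)
            continue
        x = donor.expression.loc[probe_id].to_numpy(dtype=float)
        mat = donor.expression.loc[others].to_numpy(dtype=float)
        r = _safe_corr_vector(x, mat)
        per_donor.append(float(np.sum(np.abs(r) if not signed else r)))
    return float(np.mean(per_donor))


def _donor_corr_matrix(values: np.ndarray) -> np.ndarray:
    """Probe x probe Pearson correlations; zero-variance probes get r = 0."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    flat = norms == 0
    norms[flat] = 1.0
    normed = centered / norms[:, None]
    corr = normed @ normed.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def select_probes(
    donors: list[DonorExpression],
    probe_annotation: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[dict[str, GeneExpression], pd.DataFrame]:
    """Pick one probe per gene and return gene-level expression per donor.

    Returns the per-donor :class:`GeneExpression` objects (all sharing the
    same selected probe per gene) and a selection report with one row per
    gene: the case applied (1, 2 or 3+), the winning probe and its score.
    """
    config = config or AnalysisConfig()
    if not donors:
        raise ValueError("no donors given")
    common = set(donors[0].expression.index)
    for donor in donors[1:]:
        common &= set(donor.expression.index)
    ann = probe_annotation[probe_annotation["probe_id"].isin(common)].reset_index(drop=True)
    if not len(ann):
        raise ValueError("no probes present in all donors")

    probe_order = list(ann["probe_id"])
    gene_of = dict(zip(ann["probe_id"], ann["gene_id"]))
    pos = {p: i for i, p in enumerate(probe_order)}
    gene_codes = pd.Categorical(ann["gene_id"]).codes

    # accumulate per-donor variance and connectivity for all probes at once
    var_sum = np.zeros(len(probe_order))
    conn_sum = np.zeros(len(probe_order))
    needs_conn = ann.groupby("gene_id")["probe_id"].transform("count").to_numpy() > 2
    for donor in donors:
        values = donor.expression.loc[probe_order].to_numpy(dtype=float)
        var_sum += values.var(axis=1, ddof=1)
        if needs_conn.any():
            corr = _donor_corr_matrix(values)
            if not config.connectivity_absolute:
                work = corr
            else:
                work = np.abs(corr)
                np.fill_diagonal(work, 1.0)
            totals = work.sum(axis=1) - np.diag(work)
            if config.connectivity_scope == "other_genes":
                codes = np.asarray(gene_codes)
                n_genes = codes.max() + 1
                for g in range(n_genes):
                    rows = codes == g
                    if rows.sum() < 2:
                        continue
                    sub = work[np.ix_(rows, rows)]
                    within = sub.sum(axis=1) - np.diag(sub)
                    totals[rows] -= within
            conn_sum += totals
    var_score = var_sum / len(donors)
    conn_score = conn_sum / len(donors)

    records = []
    selected: dict[str, str] = {}
    for gene_id, grp in ann.groupby("gene_id", sort=True):
        probe_ids = sorted(grp["probe_id"])
        if len(probe_ids) == 1:
            winner, case, score = probe_ids[0], "1", var_score[pos[probe_ids[0]]]
        elif len(probe_ids) == 2:
            scores = {p: var_score[pos[p]] for p in probe_ids}
            best = max(scores.values())
            winner = min(p for p in probe_ids if scores[p] == best)
            case, score = "2", best
        else:
            scores = {p: conn_score[pos[p]] for p in probe_ids}
            best = max(scores.values())
            winner = min(p for p in probe_ids if scores[p] == best)
            case, score = "3+", best
        selected[str(gene_id)] = winner
        records.append(
            {
                "gene_id": str(gene_id),
                "case": case,
                "selected_probe": winner,
                "n_probes": len(probe_ids),
                "score": float(score),
            }
        )
    report = pd.DataFrame.from_records(records).sort_values("gene_id").reset_index(drop=True)

    gene_ids = sorted(selected)
    chosen_probes = [selected[g] for g in gene_ids]
    gene_exprs: dict[str, GeneExpression] = {}
    for donor in donors:
        expr = donor.expression.loc[chosen_probes].copy()
        expr.index = pd.Index(gene_ids, name="gene_id")
        gene_exprs[donor.donor_id] = GeneExpression(
            donor_id=donor.donor_id,
            expression=expr,
            samples=donor.samples,
            selected_probe=dict(selected),
        )
    return gene_exprs, report
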