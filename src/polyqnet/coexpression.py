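"""Region-specific consensus co-expression.

Per donor, pairwise Pearson correlations are computed over the region's
sample subset; the consensus matrix is the entry-wise arithmetic mean across
donors (optionally on the Fisher z scale).  A gene is a co-expression
partner of a seed gene when the consensus r strictly exceeds the threshold.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datatypes import ConsensusMatrix, GeneExpression

logger = logging.getLogger(__name__)


def donor_correlation_matrix(
    gene_expression: GeneExpression, sample_ids
) -> np.ndarray:
    """Gene x gene Pearson correlations over one donor's region samples.

    Genes with zero variance on the subset get r = 0 against all others
    (and 1 with themselves); they are logged.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 3:
        raise ValueError(f"need >= 3 samples for correlations, got {len(sample_ids)}")
    values = gene_expression.expression[sample_ids].to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        logger.warning(
            "donor %s: %d zero-variance gene(s) on subset, correlations set to 0",
            gene_expression.donor_id,
            int(flat.sum()),
        )
    norms[flat] = 1.0
    normed = centered / norms[:, None]
    corr = normed @ normed.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def consensus_matrix(
    donor_matrices: dict[str, np.ndarray],
    genes: pd.Index,
    region_name: str = "region",
    fisher_z: bool = False,
) -> ConsensusMatrix:
    """Entry-wise mean of per-donor correlation matrices.

    With ``fisher_z`` the donor correlations are averaged on the
    arctanh scale and transformed back (r clipped away from +-1 first).
    """
    if not donor_matrices:
        raise ValueError("no donor matrices to average")
    mats = [np.asarray(m, dtype=float) for m in donor_matrices.values()]
    if fisher_z:
        zs = [np.arctanh(np.clip(m, -0.999999, 0.999999)) for m in mats]
        mean = np.tanh(np.mean(zs, axis=0))
    else:
        mean = np.mean(mats, axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 1.0)
    return ConsensusMatrix(
        genes=pd.Index(genes),
        values=mean,
        n_donors_used=len(donor_matrices),
        region_name=region_name,
        donors_used=tuple(sorted(donor_matrices)),
    )


def region_consensus(
    gene_exprs: dict[str, GeneExpression],
    region_samples: pd.DataFrame,
    region_name: str,
    config: AnalysisConfig | None = None,
) -> ConsensusMatrix:
    """Consensus matrix for one region's sample subset.

    Donors contribute only if they have at least ``min_region_samples``
    samples in the subset; the roster of used donors is recorded on the
    result.
    """
    config = config or AnalysisConfig()
    donor_mats: dict[str, np.ndarray] = {}
    genes = None
    for donor_id in sorted(gene_exprs):
        ge = gene_exprs[donor_id]
        ids = list(
            region_samples.loc[region_samples["donor_id"] == donor_id, "sample_id"]
        )
        if len(ids) < config.min_region_samples:
            logger.info(
                "region %s: donor %s excluded (%d samples < %d)",
                region_name,
                donor_id,
                len(ids),
                config.min_region_samples,
            )
            continue
        if genes is None:
            genes = ge.expression.index
        donor_mats[donor_id] = donor_correlation_matrix(ge, ids)
    if not donor_mats:
        raise ValueError(f"region {region_name}: no donor has enough samples")
    return consensus_matrix(
        donor_mats, genes, region_name, fisher_z=config.fisher_z_consensus
    )


def coexpression_partners(
    consensus: ConsensusMatrix, gene: str, threshold: float
) -> set[str]:
    """Genes whose consensus r with the seed gene strictly exceeds threshold."""
    if gene not in consensus.genes:
        raise KeyError(f"gene {gene!r} not in consensus matrix")
    row = consensus.row(gene)
    partners = set(row.index[row > threshold])
    partners.discard(gene)
    return partners


def build_network(
    consensus: ConsensusMatrix,
    polyq_genes: list[str],
    threshold: float,
) -> nx.Graph:
    """Seed-gene network: polyQ genes plus their partners.

    Edges connect each polyQ gene to its partners and to other polyQ genes
    when the consensus r strictly exceeds the threshold; partner-partner
    edges are not included.  Node attribute ``is_polyq`` marks seeds and
    ``partner_of`` lists (semicolon-joined) the polyQ genes a partner
    attaches to.
    """
    missing = [g for g in polyq_genes if g not in consensus.genes]
    if missing:
        raise KeyError(f"polyQ genes missing from consensus matrix: {missing}")
    graph = nx.Graph(region=consensus.region_name, threshold=float(threshold))
    partner_of: dict[str, set[str]] = {}
    for pq in polyq_genes:
        graph.add_node(pq, is_polyq=True)
    for pq in polyq_genes:
        for partner in sorted(coexpression_partners(consensus, pq, threshold)):
            if partner in polyq_genes:
                continue
            partner_of.setdefault(partner, set()).add(pq)
            graph.add_edge(pq, partner, weight=consensus.r(pq, partner), polyq=pq)
    for i, a in enumerate(polyq_genes):
        for b in polyq_genes[i + 1:]:
            r = consensus.r(a, b)
            if r > threshold:
                graph.add_edge(a, b, weight=r, polyq=";".join(sorted((a, b))))
    for node in graph.nodes:
        if node in partner_of:
            graph.nodes[node]["is_polyq"] = False
            graph.nodes[node]["partner_of"] = ";".join(sorted(partner_of[node]))
        elif graph.nodes[node].get("is_polyq"):
            graph.nodes[node]["partner_of"] = ""
    return graph


def threshold_sweep(
    consensus: ConsensusMatrix, polyq_genes: list[str], thresholds
) -> pd.DataFrame:
    """Partner counts per polyQ gene at each threshold (genes x thresholds)."""
    data = {
        float(t): [
            len(coexpression_partners(consensus, g, float(t))) for g in polyq_genes
        ]
        for t in thresholds
    }
    return pd.DataFrame(data, index=pd.Index(polyq_genes, name="gene"))


def save_consensus(consensus: ConsensusMatrix, stem) -> None:
    """Persist a consensus matrix as a dense .npy plus a gene-index sidecar."""
    from pathlib import Path

    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), consensus.values)
    stem.with_suffix(".genes.txt").write_text("\n".join(consensus.genes) + "\n")


def load_consensus(stem, region_name: str = "region") -> ConsensusMatrix:
    from pathlib import Path

    stem = Path(stem)
    values = np.load(stem.with_suffix(".npy"))
    genes = stem.with_suffix(".genes.txt").read_text().splitlines()
    return ConsensusMatrix(
        genes=pd.Index(genes),
        values=values,
        n_donors_used=0,
        region_name=region_name,
    )
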