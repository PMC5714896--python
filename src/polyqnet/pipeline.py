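"""End-to-end orchestration and standard-format exports.

``run_pipeline`` chains probe collapse, mask assignment, consensus
differential expression (mask region vs rest of brain), per-region
consensus co-expression, enrichment and the three-tier seed-gene
relationship analysis, writing TSV tables, GEXF/GraphML networks, dense
consensus matrices and a manifest with config and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .coexpression import (
    build_network,
    coexpression_partners,
    region_consensus,
    save_consensus,
)
from .datatypes import GeneSetCollection, RegionMask, symbol_to_gene_id
from .de import consensus_de
from .enrichment import term_sets_for_polyq
from .io import read_gmt, read_mask, write_table
from .probes import select_probes
from .regions import assign_samples, region_sample_counts, structure_subset
from .relationships import (
    gene_family_overlap,
    polyq_mean_expression,
    relationship_table,
)
from .synthetic import MASK_REGION, load_dataset_dir

logger = logging.getLogger(__name__)

FAMILY_PREFIX = "FAMILY_"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise StageError(name, exc) from exc


def export_network(network: nx.Graph, path: str | Path, format: str = "GEXF") -> Path:
    """Write a network as GEXF or GraphML with node/edge attributes intact."""
    path = Path(path)
    fmt = format.strip().lower()
    if fmt == "gexf":
        nx.write_gexf(network, path)
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unsupported network format {format!r}; use GEXF or GraphML")
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    mask_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
    structures: list[str] | None = None,
    mask_region_name: str = MASK_REGION,
) -> Path:
    """Run the full analysis on a dataset directory.

    ``data_dir`` holds per-donor ``donor_<id>/`` CSV triplets (and by
    default ``mask.nii``/``genesets.gmt``, overridable).  ``structures``
    names the anatomical structures to analyse alongside the mask region;
    by default all structure labels present in the annotation.  Regions in
    which no donor reaches ``min_region_samples`` are skipped with a logged
    reason.
    """
    config = config or AnalysisConfig()
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        donors, probes, samples, default_mask = load_dataset_dir(data_dir)
        mask: RegionMask = read_mask(mask_path) if mask_path else default_mask
        collection: GeneSetCollection | None = None
        gmt_file = Path(gmt_path) if gmt_path else data_dir / "genesets.gmt"
        if gmt_file.exists():
            collection = read_gmt(gmt_file)

    with _stage("select_probes"):
        gene_exprs, report = select_probes(list(donors.values()), probes, config)
        write_table(report, out_dir / "probe_selection.tsv")
        universe = set(next(iter(gene_exprs.values())).expression.index)
        sym_map = symbol_to_gene_id(probes)
        missing = [s for s in config.polyq_genes if s not in sym_map]
        if missing:
            raise ValueError(f"polyQ symbols not in annotation: {missing}")
        polyq_ids = [sym_map[s] for s in config.polyq_genes]
        id_to_sym = {sym_map[s]: s for s in config.polyq_genes}

    with _stage("map_region"):
        assignment = assign_samples(samples, mask, mask_region_name)
        region_subsets: dict[str, pd.DataFrame] = {
            mask_region_name: assignment.inside_samples().merge(
                samples, on=["donor_id", "sample_id"], how="left"
            )
        }
        if structures is None:
            structures = sorted(
                s for s in samples["structure_label"].unique() if s != mask_region_name
            )
        for name in structures:
            region_subsets[name] = structure_subset(samples, name)
        counts = region_sample_counts(region_subsets, donor_ids=sorted(donors))
        counts.reset_index().rename(columns={"index": "donor"}).to_csv(
            out_dir / "region_counts.tsv", sep="\t", index=False
        )

    with _stage("differential_expression"):
        de_table = consensus_de(gene_exprs, assignment, config)
        write_table(de_table, out_dir / "de_table.tsv")

    partner_counts: dict[str, dict[str, int]] = {s: {} for s in config.polyq_genes}
    relationship_frames = []
    manifest_regions: dict[str, dict] = {}
    family_records = []
    expr_records = []

    families: dict[str, frozenset[str]] = {}
    if collection is not None:
        families = {
            t: collection.members(t) for t in collection if t.startswith(FAMILY_PREFIX)
        }

    for region_name, subset in region_subsets.items():
        with _stage(f"coexpression[{region_name}]"):
            try:
                consensus = region_consensus(gene_exprs, subset, region_name, config)
            except ValueError as exc:
                logger.warning("region %s skipped: %s", region_name, exc)
                continue
            partner_sets = {
                pid: coexpression_partners(consensus, pid, config.coexpr_threshold)
                for pid in polyq_ids
            }
            for pid in polyq_ids:
                partner_counts[id_to_sym[pid]][region_name] = len(partner_sets[pid])
            save_consensus(consensus, out_dir / f"consensus_{region_name}")

        with _stage(f"enrichment[{region_name}]"):
            if collection is not None:
                term_sets, tables = term_sets_for_polyq(
                    {pid: partner_sets[pid] for pid in polyq_ids},
                    universe,
                    collection,
                    config,
                )
                for pid, table in tables.items():
                    write_table(
                        table,
                        out_dir / f"enrichment_{region_name}_{id_to_sym[pid]}.tsv",
                    )
            else:
                term_sets = {pid: set() for pid in polyq_ids}

        with _stage(f"relationships[{region_name}]"):
            rel = relationship_table(
                consensus,
                {pid: partner_sets[pid] for pid in polyq_ids},
                term_sets,
                universe,
                config,
                polyq_genes=polyq_ids,
            )
            rel.insert(1, "symbol_a", rel["gene_a"].map(id_to_sym))
            rel.insert(2, "symbol_b", rel["gene_b"].map(id_to_sym))
            relationship_frames.append(rel)
            for pid in polyq_ids:
                for fam_id, members in sorted(families.items()):
                    hits, count = gene_family_overlap(partner_sets[pid], members)
                    family_records.append(
                        {
                            "region": region_name,
                            "gene": id_to_sym[pid],
                            "family": fam_id,
                            "count": count,
                            "members": ";".join(hits),
                        }
                    )
            mean_expr = polyq_mean_expression(gene_exprs, subset, polyq_ids)
            for pid in polyq_ids:
                expr_records.append(
                    {
                        "region": region_name,
                        "gene": id_to_sym[pid],
                        "mean_expression": float(mean_expr[pid]),
                    }
                )

        with _stage(f"network[{region_name}]"):
            network = build_network(consensus, polyq_ids, config.coexpr_threshold)
            for node in network.nodes:
                network.nodes[node]["gene_symbol"] = id_to_sym.get(node, node)
                if network.nodes[node].get("is_polyq"):
                    network.nodes[node]["mean_expression"] = float(mean_expr[node])
            export_network(network, out_dir / f"network_{region_name}.gexf", "GEXF")
            export_network(
                network, out_dir / f"network_{region_name}.graphml", "GraphML"
            )
            manifest_regions[region_name] = {
                "donors_used": list(consensus.donors_used),
                "n_network_nodes": network.number_of_nodes(),
                "n_network_edges": network.number_of_edges(),
            }

    with _stage("report"):
        pc = pd.DataFrame(partner_counts).T
        pc.index.name = "gene"
        pc.reset_index().to_csv(
            out_dir / "partner_counts.tsv", sep="\t", index=False
        )
        if relationship_frames:
            combined = pd.concat(relationship_frames, ignore_index=True)
            write_table(combined, out_dir / "relationships.tsv")
        if family_records:
            write_table(family_records, out_dir / "family_overlap.tsv")
        write_table(expr_records, out_dir / "polyq_expression.tsv")

        outputs = sorted(
            p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "seed": config.rng_seed,
            "donors": sorted(donors),
            "regions": manifest_regions,
            "checksums": {p.name: _sha256(p) for p in outputs},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir
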