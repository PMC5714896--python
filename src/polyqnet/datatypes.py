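"""Core in-memory containers shared by all pipeline stages.

Expression matrices are pandas DataFrames (rows = probes or genes, columns =
samples); annotations are DataFrames with fixed column names; the binary
region-of-interest mask pairs a 3-D volume with a voxel-to-MNI-mm affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a probe annotation table.
PROBE_COLUMNS = ("probe_id", "gene_id", "gene_symbol")

#: Required columns of a sample annotation table.
SAMPLE_COLUMNS = ("sample_id", "donor_id", "structure_label", "mni_x", "mni_y", "mni_z")


@dataclass
class DonorExpression:
    """One donor's probe-level expression matrix with aligned annotations.

    ``expression`` is probes x samples on a log-intensity scale; its index
    holds probe ids and its columns sample ids, in the order given by the
    sample annotation.
    """

    donor_id: str
    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples["sample_id"]):
            raise ValueError(
                f"donor {self.donor_id}: expression has "
                f"{self.expression.shape[1]} samples but annotation lists "
                f"{len(self.samples)}; ids/order must match"
            )
        if self.expression.isna().any().any():
            raise ValueError(f"donor {self.donor_id}: missing values in expression")
        if self.expression.index.has_duplicates:
            raise ValueError(f"donor {self.donor_id}: duplicate probe ids")

    @property
    def n_probes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class GeneExpression:
    """Gene-level expression for one donor: one selected probe per gene.

    ``expression`` is genes x samples; ``selected_probe`` maps each gene_id
    to the probe chosen for it (the same probe across all donors).
    """

    donor_id: str
    expression: pd.DataFrame
    samples: pd.DataFrame
    selected_probe: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValueError(f"donor {self.donor_id}: duplicate gene ids")


@dataclass
class RegionMask:
    """Binary 3-D region-of-interest volume in MNI space.

    ``affine`` maps homogeneous voxel indices (i, j, k, 1) to MNI millimetre
    coordinates (x, y, z, 1).
    """

    volume: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("mask volume must be 3-D")
        vals = np.unique(self.volume)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask volume must be binary (values in {0, 1})")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        self.volume = self.volume.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass
class RegionAssignment:
    """Inside/outside classification of every sample against one mask.

    ``table`` has one row per sample with columns ``donor_id``, ``sample_id``
    and boolean ``inside``.
    """

    region_name: str
    table: pd.DataFrame

    def inside_samples(self) -> pd.DataFrame:
        return self.table[self.table["inside"]].reset_index(drop=True)

    def outside_samples(self) -> pd.DataFrame:
        return self.table[~self.table["inside"]].reset_index(drop=True)


@dataclass
class ConsensusMatrix:
    """Gene x gene mean Pearson correlation across donors for one region."""

    genes: pd.Index
    values: np.ndarray
    n_donors_used: int
    region_name: str
    donors_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("consensus matrix shape does not match gene index")

    def r(self, gene_a: str, gene_b: str) -> float:
        ia = self.genes.get_loc(gene_a)
        ib = self.genes.get_loc(gene_b)
        return float(self.values[ia, ib])

    def row(self, gene: str) -> pd.Series:
        i = self.genes.get_loc(gene)
        return pd.Series(self.values[i], index=self.genes, name=gene)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


class GeneSetCollection:
    """Mapping term_id -> (term_name, member gene ids)."""

    def __init__(self, terms: dict[str, tuple[str, frozenset[str]]] | None = None):
        self.terms: dict[str, tuple[str, frozenset[str]]] = {}
        if terms:
            for term_id, (name, members) in terms.items():
                self.add(term_id, name, members)

    def add(self, term_id: str, name: str, members) -> None:
        if term_id in self.terms:
            raise ValueError(f"duplicate term id {term_id!r}")
        members = frozenset(members)
        if not members:
            raise ValueError(f"term {term_id!r} has no members")
        self.terms[term_id] = (name, members)

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self):
        return iter(self.terms)

    def restricted_to(self, background: set[str]) -> "GeneSetCollection":
        """Intersect every term with a background universe, dropping empties."""
        out = GeneSetCollection()
        for term_id, (name, members) in self.terms.items():
            kept = members & frozenset(background)
            if kept:
                out.add(term_id, name, kept)
        return out


def validate_probe_annotation(probes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe annotation missing columns {missing}")
    if probes["probe_id"].duplicated().any():
        dup = probes.loc[probes["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in probe annotation")
    # a probe maps to exactly one gene by construction of the table
    return probes.reset_index(drop=True)


def validate_sample_annotation(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample annotation missing columns {missing}")
    if samples.duplicated(subset=["donor_id", "sample_id"]).any():
        raise ValueError("(donor_id, sample_id) pairs must be unique")
    coords = samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("sample MNI coordinates must be finite")
    return samples.reset_index(drop=True)


def symbol_to_gene_id(probes: pd.DataFrame) -> dict[str, str]:
    """Case-sensitive gene_symbol -> gene_id map from a probe annotation."""
    mapping: dict[str, str] = {}
    for sym, gid in zip(probes["gene_symbol"], probes["gene_id"]):
        prev = mapping.setdefault(str(sym), str(gid))
        if prev != str(gid):
            raise ValueError(f"gene symbol {sym!r} maps to multiple gene ids")
    return mapping
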