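"""Synthetic multi-donor spatial expression data with planted structure.

The generator emulates the statistical shape of the public six-donor brain
atlas: donors with unequal sample counts per anatomical region, genes
measured by one to four probes of varying noise, co-expressed gene blocks
built from a shared latent factor (population within-block correlation
exactly rho), and location shifts planted inside a binary MNI-space mask
region.  The default conditions use the published per-donor sample counts
for the mask region and the seven anatomical structures, plus a
rest-of-brain filler bringing the grand total to 3,702 samples.

Ground truth (block memberships, shifted genes, per-region counts) is
returned alongside the data so every downstream stage has a recoverable
target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import POLYQ_GENES
from .datatypes import DonorExpression, GeneSetCollection, RegionMask
from . import io as pio

DONOR_IDS: tuple[str, ...] = ("9861", "10021", "12876", "14380", "15496", "15697")

#: Published per-donor sample counts: mask region and seven structures.
TABLE1_REGION_COUNTS: dict[str, tuple[int, ...]] = {
    "HD_region": (280, 183, 99, 139, 125, 147),
    "frontal_lobe": (161, 135, 47, 70, 64, 60),
    "parietal_lobe": (81, 57, 37, 42, 32, 41),
    "striatum": (48, 46, 16, 24, 18, 18),
    "hypothalamus": (9, 22, 17, 20, 16, 18),
    "mesencephalon": (48, 61, 9, 22, 24, 18),
    "cerebellar_cortex": (41, 76, 40, 44, 60, 76),
    "pons": (52, 50, 6, 26, 29, 26),
}

#: Filler counts so each donor's total lands in the atlas's 363-946 range
#: and the grand total is the atlas's 3,702 samples.
REST_COUNTS: tuple[int, ...] = (226, 160, 92, 130, 130, 184)

MASK_REGION = "HD_region"
REST_REGION = "rest_of_brain"


@dataclass
class RegionSpec:
    """One synthetic region: name, per-donor sample counts, mask membership."""

    name: str
    donor_counts: tuple[int, ...]
    in_mask: bool = False


@dataclass
class BlockSpec:
    """A planted co-expression block of ``size`` genes at correlation rho.

    ``seed_symbols`` are gene symbols (typically polyQ genes) forced into
    the block; the rest is filled with background genes.
    """

    label: str
    size: int
    rho: float
    seed_symbols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"block rho must be in [0, 1), got {self.rho}")
        if self.size < len(self.seed_symbols) or self.size < 2:
            raise ValueError(f"block size {self.size} too small")


@dataclass
class DEShiftSpec:
    """Planted regional shift: ``n_genes`` genes moved by ``delta`` noise SDs."""

    n_genes: int
    delta: float
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.n_genes < 0 or self.delta < 0:
            raise ValueError("n_genes and delta must be nonnegative")


def default_regions() -> tuple[RegionSpec, ...]:
    regions = [
        RegionSpec(name, counts, in_mask=(name == MASK_REGION))
        for name, counts in TABLE1_REGION_COUNTS.items()
    ]
    regions.append(RegionSpec(REST_REGION, REST_COUNTS))
    return tuple(regions)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    donor_ids: tuple[str, ...] = DONOR_IDS
    n_genes: int = 1000
    probes_per_gene_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.25, 3: 0.15, 4: 0.10}
    )
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec("coexp_A", 40, 0.7, ("ATN1", "ATXN2", "HTT")),
        BlockSpec("coexp_B", 30, 0.6, ("ATXN1",)),
    )
    de_shifts: tuple[DEShiftSpec, ...] = (
        DEShiftSpec(60, 1.0, "up"),
        DEShiftSpec(120, 1.0, "down"),
    )
    mask_shape: tuple[int, int, int] = (30, 36, 30)
    voxel_size_mm: float = 2.0
    mask_box: tuple[tuple[int, int], ...] = ((5, 13), (6, 14), (5, 13))
    coordinate_jitter_mm: float = 0.8
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    probe_noise_sd_range: tuple[float, float] = (0.1, 0.5)
    polyq_symbols: tuple[str, ...] = POLYQ_GENES

    def validate(self) -> None:
        nd = len(self.donor_ids)
        for region in self.regions:
            if len(region.donor_counts) != nd:
                raise ValueError(
                    f"region {region.name}: {len(region.donor_counts)} counts "
                    f"for {nd} donors"
                )
            if any(c < 0 for c in region.donor_counts):
                raise ValueError(f"region {region.name}: negative counts")
        probs = self.probes_per_gene_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(
            k not in (1, 2, 3, 4) for k in probs
        ):
            raise ValueError("probes_per_gene_probs must be a distribution over 1..4")
        needed = sum(b.size for b in self.blocks) + sum(
            d.n_genes for d in self.de_shifts
        )
        if self.n_genes < needed + len(self.polyq_symbols):
            raise ValueError(
                f"n_genes={self.n_genes} too small for blocks + shifts + polyQ genes"
            )
        if self.coordinate_jitter_mm >= self.voxel_size_mm / 2:
            raise ValueError("coordinate jitter must stay below half a voxel")
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError("block labels must be unique")

    @property
    def affine(self) -> np.ndarray:
        v = self.voxel_size_mm
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = -np.asarray(self.mask_shape) / 2.0 * v
        return aff


@dataclass
class PlantedTruth:
    """Ground truth of one generated dataset."""

    block_assignments: dict[str, str | None]
    block_correlation: dict[str, float]
    de_genes: dict[str, tuple[str, float]]
    region_counts: pd.DataFrame
    seed: int
    latent: dict[str, pd.DataFrame] | None = None

    def block_members(self, label: str) -> set[str]:
        return {g for g, b in self.block_assignments.items() if b == label}


@dataclass
class SyntheticDataset:
    donors: dict[str, DonorExpression]
    probes: pd.DataFrame
    samples: pd.DataFrame
    mask: RegionMask
    truth: PlantedTruth
    genes: pd.DataFrame


def generate_mask(shape, affine, region_voxel_set) -> RegionMask:
    """Binary mask volume that is 1 exactly on ``region_voxel_set``."""
    region_voxel_set = [tuple(int(c) for c in v) for v in region_voxel_set]
    if not region_voxel_set:
        raise ValueError("region voxel set is empty")
    volume = np.zeros(shape, dtype=np.uint8)
    for i, j, k in region_voxel_set:
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            raise ValueError(f"voxel {(i, j, k)} outside volume shape {tuple(shape)}")
        volume[i, j, k] = 1
    return RegionMask(volume=volume, affine=np.asarray(affine, dtype=float))


def _box_voxels(box) -> list[tuple[int, int, int]]:
    (i0, i1), (j0, j1), (k0, k1) = box
    return [
        (i, j, k)
        for i in range(i0, i1)
        for j in range(j0, j1)
        for k in range(k0, k1)
    ]


def generate_dataset(
    spec: SyntheticSpec | None = None,
    seed: int = 0,
    keep_latent: bool = False,
) -> SyntheticDataset:
    """Generate one dataset; identical (spec, seed) give identical output."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    # ----- gene and probe tables -----------------------------------------
    n_genes = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    symbols = list(spec.polyq_symbols) + [
        f"GENE{i:05d}" for i in range(len(spec.polyq_symbols), n_genes)
    ]
    sym_index = {s: i for i, s in enumerate(symbols)}

    block_of: list[str | None] = [None] * n_genes
    assigned = set()
    for block in spec.blocks:
        members = []
        for sym in block.seed_symbols:
            idx = sym_index[sym]
            if idx in assigned:
                raise ValueError(f"gene {sym} assigned to multiple blocks")
            members.append(idx)
        fill_pool = [
            i
            for i in range(len(spec.polyq_symbols), n_genes)
            if i not in assigned and i not in members
        ]
        fill = rng.choice(fill_pool, size=block.size - len(members), replace=False)
        members.extend(int(i) for i in fill)
        for i in members:
            block_of[i] = block.label
            assigned.add(i)

    de_pool = [
        i
        for i in range(len(spec.polyq_symbols), n_genes)
        if i not in assigned
    ]
    rng.shuffle(de_pool)
    de_dir = np.zeros(n_genes)
    de_genes: dict[str, tuple[str, float]] = {}
    cursor = 0
    for shift in spec.de_shifts:
        chosen = de_pool[cursor: cursor + shift.n_genes]
        cursor += shift.n_genes
        sign = 1.0 if shift.direction == "up" else -1.0
        for i in chosen:
            de_dir[i] = sign * shift.delta
            de_genes[gene_ids[i]] = (shift.direction, shift.delta)

    probe_records = []
    probes_per_gene = rng.choice(
        list(spec.probes_per_gene_probs),
        size=n_genes,
        p=list(spec.probes_per_gene_probs.values()),
    )
    lo, hi = spec.probe_noise_sd_range
    for i, gid in enumerate(gene_ids):
        for j in range(int(probes_per_gene[i])):
            probe_records.append(
                {
                    "probe_id": f"{gid}_p{j}",
                    "gene_id": gid,
                    "gene_symbol": symbols[i],
                    "noise_sd": float(rng.uniform(lo, hi)),
                }
            )
    probe_table = pd.DataFrame.from_records(probe_records)
    probes = probe_table[["probe_id", "gene_id", "gene_symbol"]].copy()
    gene_table = pd.DataFrame({"gene_id": gene_ids, "gene_symbol": symbols})

    # ----- mask and coordinates ------------------------------------------
    affine = spec.affine
    mask_voxels = _box_voxels(spec.mask_box)
    mask = generate_mask(spec.mask_shape, affine, mask_voxels)
    all_voxels = {
        (i, j, k)
        for i in range(spec.mask_shape[0])
        for j in range(spec.mask_shape[1])
        for k in range(spec.mask_shape[2])
    }
    outside_voxels = sorted(all_voxels - set(mask_voxels))
    if not outside_voxels:
        raise ValueError("mask covers the whole volume; no outside voxels")
    mask_voxel_arr = np.asarray(mask_voxels)
    outside_voxel_arr = np.asarray(outside_voxels)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)

    donors: dict[str, DonorExpression] = {}
    latent: dict[str, pd.DataFrame] = {}
    count_rows = []
    block_labels = [b.label for b in spec.blocks]
    block_rho = {b.label: b.rho for b in spec.blocks}
    block_idx = {
        lab: np.array([i for i in range(n_genes) if block_of[i] == lab])
        for lab in block_labels
    }

    for d, donor_id in enumerate(spec.donor_ids):
        sample_records = []
        serial = 0
        inside_flags = []
        for region in spec.regions:
            count = int(region.donor_counts[d])
            if count == 0:
                continue
            pool = mask_voxel_arr if region.in_mask else outside_voxel_arr
            picks = pool[rng.integers(0, len(pool), size=count)]
            centers = (affine @ np.hstack(
                [picks, np.ones((count, 1))]
            ).T).T[:, :3]
            jitter = rng.uniform(
                -spec.coordinate_jitter_mm, spec.coordinate_jitter_mm, size=(count, 3)
            )
            coords = centers + jitter
            for c in range(count):
                sample_records.append(
                    {
                        "sample_id": f"{donor_id}_s{serial:04d}",
                        "donor_id": donor_id,
                        "structure_label": region.name,
                        "mni_x": coords[c, 0],
                        "mni_y": coords[c, 1],
                        "mni_z": coords[c, 2],
                    }
                )
                inside_flags.append(region.in_mask)
                serial += 1
        samples_df = pd.DataFrame.from_records(sample_records)
        inside = np.asarray(inside_flags, dtype=float)
        n_s = len(samples_df)

        noise = rng.standard_normal((n_genes, n_s))
        signal = noise.copy()
        for lab in block_labels:
            factor = rng.standard_normal(n_s)
            rho = block_rho[lab]
            idx = block_idx[lab]
            signal[idx] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise[idx]
        gene_values = baseline[:, None] + signal + de_dir[:, None] * inside[None, :]

        probe_rows = np.empty((len(probe_table), n_s))
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for p, (gid, sd) in enumerate(
            zip(probe_table["gene_id"], probe_table["noise_sd"])
        ):
            probe_rows[p] = gene_values[gene_pos[gid]] + rng.normal(0.0, sd, size=n_s)

        expr = pd.DataFrame(
            probe_rows,
            index=pd.Index(probe_table["probe_id"], name="probe_id"),
            columns=pd.Index(samples_df["sample_id"], name="sample_id"),
        )
        donors[donor_id] = DonorExpression(
            donor_id=donor_id, expression=expr, samples=samples_df
        )
        if keep_latent:
            latent[donor_id] = pd.DataFrame(
                gene_values,
                index=pd.Index(gene_ids, name="gene_id"),
                columns=expr.columns,
            )
        row = {"donor": donor_id}
        for region in spec.regions:
            row[region.name] = int(region.donor_counts[d])
        count_rows.append(row)

    region_counts = pd.DataFrame(count_rows).set_index("donor")
    block_assignments = {gene_ids[i]: block_of[i] for i in range(n_genes)}
    truth = PlantedTruth(
        block_assignments=block_assignments,
        block_correlation=dict(block_rho),
        de_genes=de_genes,
        region_counts=region_counts,
        seed=seed,
        latent=latent if keep_latent else None,
    )
    all_samples = pd.concat(
        [donors[d].samples for d in spec.donor_ids], ignore_index=True
    )
    return SyntheticDataset(
        donors=donors,
        probes=probes,
        samples=all_samples,
        mask=mask,
        truth=truth,
        genes=gene_table,
    )


def generate_genesets(
    dataset: SyntheticDataset,
    seed: int = 0,
    n_planted_terms: int = 15,
    planted_block: str = "coexp_A",
    n_random_terms: int = 60,
    random_term_size: tuple[int, int] = (10, 40),
    family_sizes: dict[str, int] | None = None,
) -> GeneSetCollection:
    """Annotation collection over the dataset's gene ids.

    Planted terms sample their members from one co-expression block, so
    seed genes inside that block accumulate shared enriched terms; random
    terms are drawn from the whole universe.  Family sets (ubiquitin
    conjugating enzymes, DNA repair, ubiquitination: 41, 125 and 40 genes)
    mimic curated gene families, with a handful of members forced into the
    planted block so family-overlap counts are nonzero.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(dataset.genes["gene_id"])
    block_members = sorted(dataset.truth.block_members(planted_block))
    collection = GeneSetCollection()
    for t in range(n_planted_terms):
        size = int(rng.integers(8, min(16, len(block_members) + 1)))
        members = rng.choice(block_members, size=size, replace=False)
        collection.add(f"PLANTED{t:03d}", f"planted block term {t}", members)
    lo, hi = random_term_size
    for t in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        collection.add(f"RAND{t:03d}", f"random term {t}", members)
    family_sizes = family_sizes or {
        "FAMILY_UBE2": 41,
        "FAMILY_DNA_REPAIR": 125,
        "FAMILY_UBIQUITINATION": 40,
    }
    n_forced = min(8, len(block_members))
    for name, size in family_sizes.items():
        if size > len(gene_ids):
            raise ValueError(
                f"family {name} of size {size} exceeds the {len(gene_ids)}-gene universe"
            )
        forced = list(rng.choice(block_members, size=n_forced, replace=False))
        pool = [g for g in gene_ids if g not in forced]
        rest = rng.choice(pool, size=max(0, size - n_forced), replace=False)
        collection.add(name, name.replace("FAMILY_", "").lower(), [*forced, *rest])
    return collection


def write_dataset(
    dataset: SyntheticDataset, out_dir: str | Path, genesets: GeneSetCollection | None = None
) -> dict[str, Path]:
    """Write the dataset in the same dialect the loaders read.

    Per-donor directories ``donor_<id>/`` with MicroarrayExpression.csv,
    Probes.csv and SampleAnnot.csv; the mask as uncompressed NIfTI; ground
    truth as JSON; optionally the annotation collection as GMT.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for donor_id in sorted(dataset.donors):
        paths[f"donor_{donor_id}"] = pio.write_donor(
            dataset.donors[donor_id], dataset.probes, out_dir / f"donor_{donor_id}"
        )
    paths["mask"] = pio.write_mask(dataset.mask, out_dir / "mask.nii")
    truth = dataset.truth
    truth_json = {
        "seed": truth.seed,
        "block_correlation": truth.block_correlation,
        "block_assignments": {
            g: b for g, b in truth.block_assignments.items() if b is not None
        },
        "de_genes": {g: list(v) for g, v in truth.de_genes.items()},
        "region_counts": truth.region_counts.to_dict(orient="index"),
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    if genesets is not None:
        paths["gmt"] = pio.write_gmt(genesets, out_dir / "genesets.gmt")
    return paths


def load_dataset_dir(data_dir: str | Path):
    """Read back a directory written by :func:`write_dataset`.

    Returns (donors dict, probe annotation, combined sample annotation, mask).
    """
    data_dir = Path(data_dir)
    donors: dict[str, DonorExpression] = {}
    probes = None
    sample_frames = []
    donor_dirs = sorted(p for p in data_dir.glob("donor_*") if p.is_dir())
    if not donor_dirs:
        raise FileNotFoundError(f"no donor_* directories under {data_dir}")
    for ddir in donor_dirs:
        donor_id = ddir.name.removeprefix("donor_")
        donor, probe_ann, samples = pio.read_donor(
            ddir / "MicroarrayExpression.csv",
            ddir / "Probes.csv",
            ddir / "SampleAnnot.csv",
            donor_id=donor_id,
        )
        donors[donor_id] = donor
        probes = probe_ann if probes is None else probes
        sample_frames.append(samples)
    mask = pio.read_mask(data_dir / "mask.nii")
    return donors, probes, pd.concat(sample_frames, ignore_index=True), mask
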