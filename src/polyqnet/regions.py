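"""Assign samples to brain regions.

A sample is inside the region of interest iff its MNI coordinate, mapped
through the inverse of the mask affine and rounded to the nearest voxel
(half away from zero), lands on an in-bounds voxel with value 1.  Anatomical
structures are selected by exact match of the structure label, optionally
through a label-to-structure lookup table.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import RegionAssignment, RegionMask

logger = logging.getLogger(__name__)


def mni_to_voxel(xyz_mm, affine: np.ndarray) -> tuple[int, int, int]:
    """Map an MNI mm coordinate to 0-based voxel indices.

    Applies the inverse affine and rounds each coordinate to the nearest
    integer, halves away from zero.
    """
    xyz = np.asarray(xyz_mm, dtype=float)
    hom = np.append(xyz, 1.0)
    ijk = np.linalg.solve(np.asarray(affine, dtype=float), hom)[:3]
    rounded = np.trunc(ijk + np.copysign(0.5, ijk))
    return tuple(int(v) for v in rounded)


def _voxel_indices(samples: pd.DataFrame, affine: np.ndarray) -> np.ndarray:
    coords = samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    hom = np.hstack([coords, np.ones((len(coords), 1))])
    ijk = np.linalg.solve(np.asarray(affine, dtype=float), hom.T).T[:, :3]
    return np.trunc(ijk + np.copysign(0.5, ijk)).astype(int)


def assign_samples(
    samples: pd.DataFrame, mask: RegionMask, region_name: str = "region"
) -> RegionAssignment:
    """Classify every sample as inside/outside the mask.

    Samples whose voxel falls outside the volume bounding box are outside;
    no interpolation is performed on the binary mask.
    """
    table = samples[["donor_id", "sample_id"]].copy()
    if len(samples):
        ijk = _voxel_indices(samples, mask.affine)
        shape = np.asarray(mask.volume.shape)
        in_bounds = ((ijk >= 0) & (ijk < shape)).all(axis=1)
        inside = np.zeros(len(samples), dtype=bool)
        ib = ijk[in_bounds]
        inside[in_bounds] = mask.volume[ib[:, 0], ib[:, 1], ib[:, 2]] == 1
        table["inside"] = inside
    else:
        table["inside"] = pd.Series([], dtype=bool)
    return RegionAssignment(region_name=region_name, table=table.reset_index(drop=True))


def structure_subset(
    samples: pd.DataFrame,
    structure_names,
    label_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Samples whose structure label matches any of the requested structures.

    ``label_map`` maps a structure name to the annotation labels it covers;
    by default each structure name matches its own label exactly.  An
    unknown structure name is an error listing the known ones; an empty
    match is allowed with a warning.
    """
    if isinstance(structure_names, str):
        structure_names = [structure_names]
    known_labels = set(samples["structure_label"].unique())
    wanted: list[str] = []
    for name in structure_names:
        if label_map is not None:
            if name not in label_map:
                raise KeyError(
                    f"unknown structure {name!r}; known structures: "
                    f"{sorted(label_map)}"
                )
            wanted.extend(label_map[name])
        else:
            if name not in known_labels:
                raise KeyError(
                    f"unknown structure {name!r}; known labels: "
                    f"{sorted(known_labels)}"
                )
            wanted.append(name)
    subset = samples[samples["structure_label"].isin(wanted)].reset_index(drop=True)
    if not len(subset):
        warnings.warn(f"no samples matched structures {list(structure_names)}")
    return subset


def region_sample_counts(
    subsets: dict[str, pd.DataFrame], donor_ids: list[str] | None = None
) -> pd.DataFrame:
    """Donor x region sample-count table with a final "Total samples" row.

    ``subsets`` maps a region name either to a sample-annotation subset or
    to a :class:`RegionAssignment` (whose inside samples are counted).
    """
    columns = list(subsets)
    resolved: dict[str, pd.DataFrame] = {}
    for name, sub in subsets.items():
        if isinstance(sub, RegionAssignment):
            sub = sub.inside_samples()
        resolved[name] = sub
    if donor_ids is None:
        donor_ids = sorted(
            {d for sub in resolved.values() for d in sub["donor_id"].unique()}
        )
    counts = pd.DataFrame(0, index=pd.Index(donor_ids, name="donor"), columns=columns)
    for name, sub in resolved.items():
        per_donor = sub.groupby("donor_id")["sample_id"].count()
        for donor, n in per_donor.items():
            if donor in counts.index:
                counts.loc[donor, name] = int(n)
    total = counts.sum(axis=0)
    counts.loc["Total samples"] = total
    return counts


def donors_passing(
    subset: pd.DataFrame, donor_ids, min_region_samples: int
) -> tuple[list[str], list[str]]:
    """Split donors into those with enough samples in a region and the rest."""
    per_donor = subset.groupby("donor_id")["sample_id"].count()
    included, excluded = [], []
    for donor in donor_ids:
        if int(per_donor.get(donor, 0)) >= min_region_samples:
            included.append(donor)
        else:
            excluded.append(donor)
    if excluded:
        logger.info(
            "donors %s excluded (fewer than %d samples in region)",
            excluded,
            min_region_samples,
        )
    return included, excluded
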