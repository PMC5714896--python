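"""Readers and writers for the external file formats.

The expression dialect follows the public multi-donor brain atlas
distribution: per donor, a headerless expression CSV whose first column is
the probe id and whose remaining columns are samples in the order of the
sample-annotation CSV; a probe annotation CSV; and a sample annotation CSV
with anatomical structure labels and MNI millimetre coordinates.  Column
aliases used by the public distribution (``probe_name``, ``well_id``,
``structure_name``) are accepted.  Gene sets travel as GMT, masks as NIfTI,
and tabular outputs as TSV.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    DonorExpression,
    GeneSetCollection,
    RegionMask,
    validate_probe_annotation,
    validate_sample_annotation,
)

logger = logging.getLogger(__name__)

_PROBE_ALIASES = {"probe_name": "probe_id", "entrez_id": "gene_id"}
_SAMPLE_ALIASES = {"well_id": "sample_id", "structure_name": "structure_label"}


def _apply_aliases(df: pd.DataFrame, aliases: dict[str, str]) -> pd.DataFrame:
    renames = {old: new for old, new in aliases.items()
               if old in df.columns and new not in df.columns}
    return df.rename(columns=renames)


def read_donor(
    expr_file: str | Path,
    probe_file: str | Path,
    sample_file: str | Path,
    donor_id: str | None = None,
) -> tuple[DonorExpression, pd.DataFrame, pd.DataFrame]:
    """Load one donor's expression matrix plus probe and sample annotations.

    Rows of the expression matrix with any unparseable value are dropped
    with a logged count.  A mismatch between the number of expression
    columns and annotated samples is a hard error.

    Returns
    -------
    (DonorExpression, probe annotation, sample annotation)
    """
    expr_file, probe_file, sample_file = Path(expr_file), Path(probe_file), Path(sample_file)
    for f in (expr_file, probe_file, sample_file):
        if not f.exists():
            raise FileNotFoundError(str(f))

    probes = _apply_aliases(pd.read_csv(probe_file, dtype=str), _PROBE_ALIASES)
    probes = validate_probe_annotation(probes)

    samples = _apply_aliases(pd.read_csv(sample_file, dtype=str), _SAMPLE_ALIASES)
    if donor_id is not None:
        samples = samples.copy()
        samples["donor_id"] = str(donor_id)
    elif "donor_id" not in samples.columns:
        raise ValueError(
            f"{sample_file}: no donor_id column and no donor_id argument given"
        )
    for c in ("mni_x", "mni_y", "mni_z"):
        samples[c] = pd.to_numeric(samples[c], errors="raise")
    samples = validate_sample_annotation(samples)
    donor = str(samples["donor_id"].iloc[0])

    raw = pd.read_csv(expr_file, header=None, dtype=str)
    n_cols = raw.shape[1] - 1
    if n_cols != len(samples):
        raise ValueError(
            f"{expr_file}: expression matrix has {n_cols} sample columns but "
            f"annotation lists {len(samples)} samples"
        )
    probe_ids = raw.iloc[:, 0].astype(str)
    values = raw.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: dropped %d probe row(s) with unparseable values", expr_file, int(bad.sum())
        )
    expr = pd.DataFrame(
        values.loc[~bad].to_numpy(dtype=float),
        index=pd.Index(probe_ids[~bad], name="probe_id"),
        columns=pd.Index(samples["sample_id"], name="sample_id"),
    )
    # keep only annotated probes, in annotation order
    keep = probes["probe_id"].isin(expr.index)
    expr = expr.loc[[p for p in probes.loc[keep, "probe_id"]]]
    return DonorExpression(donor_id=donor, expression=expr, samples=samples), probes, samples


def write_donor(donor: DonorExpression, probes: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write one donor back out in the same dialect ``read_donor`` expects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr = donor.expression
    with open(out_dir / "MicroarrayExpression.csv", "w") as fh:
        for probe_id, row in zip(expr.index, expr.to_numpy()):
            fh.write(probe_id + "," + ",".join(format(v, ".17g") for v in row) + "\n")
    probes.to_csv(out_dir / "Probes.csv", index=False)
    donor.samples.to_csv(out_dir / "SampleAnnot.csv", index=False)
    return out_dir


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated gene-set file (term, description, members...).

    Duplicate members within a term are deduplicated; lines with fewer than
    three fields are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    collection = GeneSetCollection()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            warnings.warn(f"{path}:{lineno}: skipped line with <3 fields")
            continue
        term_id, name, *members = fields
        members = [m for m in members if m]
        collection.add(term_id, name, members)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term_id in sorted(collection.terms):
            name, members = collection.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")
    return path


def write_table(records, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write records as a TSV with header, sorted by the first column.

    ``records`` may be a DataFrame or a list of dicts; an empty record list
    with explicit ``columns`` yields a header-only file.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if columns is not None:
            df = df[columns]
    else:
        records = list(records)
        if not records and columns is None:
            raise ValueError("empty record list needs explicit columns")
        df = pd.DataFrame(records, columns=columns or list(records[0].keys()))
    if len(df):
        df = df.sort_values(df.columns[0], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_mask(path: str | Path) -> RegionMask:
    """Read a binary NIfTI region mask (values above 0.5 count as inside)."""
    img = nib.load(str(path))
    volume = (np.asanyarray(img.dataobj) > 0.5).astype(np.uint8)
    return RegionMask(volume=volume, affine=np.asarray(img.affine))


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.volume.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path
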