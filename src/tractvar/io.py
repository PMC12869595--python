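"""NIfTI volume and CSV table I/O.

Volumes are NIfTI-1 with an isotropic-voxel diagonal affine; displacement
fields are 4D with a trailing axis of length 3 (mm vectors). Tables are
plain CSV with documented headers; lines starting with ``#`` carry
provenance (config hash, seed) and are skipped on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .spatial import BinaryMask, DisplacementField, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "read_tables",
]

FEATURE_COLUMNS = ["subject_id", "pathway", "feature", "value"]
SUBJECT_COLUMNS = ["subject_id", "age", "sex", "cohort", "epoch"]


def write_volume(obj: VolumeGrid | DisplacementField | BinaryMask, path) -> None:
    """Write a grid object as NIfTI-1; masks as uint8, the rest float64."""
    data = obj.data
    if isinstance(obj, BinaryMask):
        data = data.astype(np.uint8)
    affine = np.diag([obj.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_volume(path, kind: str | None = None):
    """Read a NIfTI file, dispatching on shape (and ``kind`` if given).

    4D with a trailing axis of 3 parses as a :class:`DisplacementField`;
    3D parses as a :class:`VolumeGrid`, or a :class:`BinaryMask` when
    ``kind='mask'`` (values must then be exactly {0, 1}).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    voxel_size = float(zooms[0])
    if data.ndim == 4 and data.shape[-1] == 3:
        return DisplacementField(data.astype(float), voxel_size)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D or 4D(x3) volume, got {data.shape}")
    if kind == "mask":
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{path}: mask contains non-binary values {vals[:5]}")
        return BinaryMask(data, voxel_size)
    return VolumeGrid(data.astype(float), voxel_size)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_tables(directory):
    """Load a fixture directory: features.csv, subjects.csv, behavior.csv.

    Returns (feature_table joined with demographics, subjects, behaviour).
    Subjects present in one table but not another are reported as orphans;
    duplicated (subject, pathway, feature) rows are an error.
    """
    directory = Path(directory)
    features = read_table(directory / "features.csv")
    subjects = read_table(directory / "subjects.csv")
    _require_columns(features, FEATURE_COLUMNS, "features.csv")
    _require_columns(subjects, SUBJECT_COLUMNS, "subjects.csv")
    dup = features.duplicated(subset=["subject_id", "pathway", "feature"])
    if dup.any():
        first = features[dup].iloc[0]
        raise ValueError(
            "features.csv: duplicated (subject, pathway, feature) row, first at "
            f"({first['subject_id']}, {first['pathway']}, {first['feature']})"
        )
    behavior = None
    beh_path = directory / "behavior.csv"
    if beh_path.exists():
        behavior = read_table(beh_path)
        _require_columns(behavior, ["subject_id"], "behavior.csv")

    feat_ids = set(features["subject_id"])
    subj_ids = set(subjects["subject_id"])
    orphans = feat_ids - subj_ids
    if orphans:
        logger.warning("%d subject(s) in features but not demographics", len(orphans))
    if behavior is not None:
        orphans_b = set(behavior["subject_id"]) - feat_ids
        if orphans_b:
            logger.warning(
                "%d subject(s) in behaviour but not features: %s",
                len(orphans_b), sorted(orphans_b)[:5],
            )
    drop = [c for c in SUBJECT_COLUMNS[1:] if c in features.columns]
    joined = features.drop(columns=drop).merge(subjects, on="subject_id", how="inner")
    return joined, subjects, behavior
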