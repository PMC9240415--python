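"""Readers and writers for the pipeline's external formats.

Transcript manifests are TSV (participant_id, group, task, file) with one
UTF-8 text file per response; lesion stacks are directories of NIfTI images
on a common grid; maps go back out as NIfTI with the input affine passed
through untouched.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .coherence import GROUPS, TASKS, ResponseRecord
from .lesion_mapping import ClusterSet, LesionDataset, StatMap

__all__ = [
    "read_manifest",
    "read_lesion_stack",
    "write_nifti",
    "write_statmap",
    "write_cluster_table",
]

MANIFEST_COLUMNS = ("participant_id", "group", "task", "file")


def read_manifest(path: str | Path) -> list[ResponseRecord]:
    """Read a transcript manifest and its response files.

    Validates columns, group/task labels, uniqueness of participant x task,
    and existence of every referenced file (errors name the offending row).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["participant_id", "task"])
    if dup.any():
        rows = df.loc[dup, ["participant_id", "task"]].to_records(index=False)
        raise ValueError(f"duplicate participant x task rows: {list(rows)}")
    records = []
    for i, row in df.iterrows():
        if row["task"] not in TASKS:
            raise ValueError(
                f"row {i}: unknown task {row['task']!r}; allowed: {list(TASKS)}")
        if row["group"] not in GROUPS:
            raise ValueError(
                f"row {i}: unknown group {row['group']!r}; allowed: {list(GROUPS)}")
        fpath = path.parent / row["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"row {i} ({row['participant_id']}/{row['task']}): "
                f"missing file {fpath}")
        records.append(ResponseRecord(
            participant_id=row["participant_id"], group=row["group"],
            task=row["task"], raw_text=fpath.read_text(encoding="utf-8")))
    return records


def read_lesion_stack(
    directory: str | Path,
    behaviour: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    mask: np.ndarray | None = None,
) -> LesionDataset:
    """Stack all NIfTI images in a directory (sorted by filename) into a
    :class:`LesionDataset`. All images must share one grid; non-finite
    voxels are an error."""
    directory = Path(directory)
    files = sorted(directory.glob("*.nii")) + sorted(directory.glob("*.nii.gz"))
    if not files:
        raise FileNotFoundError(f"no NIfTI images in {directory}")
    arrays, shapes = [], {}
    affine = None
    voxel_size = None
    for f in files:
        img = nib.load(str(f))
        arr = np.asarray(img.get_fdata(), dtype=float)
        shapes[f.name] = arr.shape
        if not np.isfinite(arr).all():
            raise ValueError(f"{f.name}: non-finite voxel values")
        arrays.append(arr)
        if affine is None:
            affine = img.affine
            voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(set(shapes.values())) > 1:
        raise ValueError(f"lesion images disagree on grid shape: {shapes}")
    images = np.stack(arrays)
    if mask is not None and np.asarray(mask).shape != images.shape[1:]:
        raise ValueError("user mask shape differs from image grid")
    return LesionDataset(images=images, behaviour=np.asarray(behaviour, float),
                         covariates=covariates.reset_index(drop=True),
                         mask=mask, voxel_size=voxel_size, affine=affine)


def _default_affine(voxel_size) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


def write_nifti(array: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None, voxel_size=2.0) -> None:
    if affine is None:
        affine = _default_affine(voxel_size)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine),
             str(path))


def write_statmap(stat_map: StatMap, clusters: ClusterSet, out_dir: str | Path,
                  prefix: str, affine: np.ndarray | None = None,
                  voxel_size=2.0) -> None:
    """Write statistic/p volumes, a binary mask of FWE-significant clusters,
    and the cluster table CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_nifti(stat_map.statistic, out_dir / f"{prefix}_stat.nii", affine, voxel_size)
    write_nifti(stat_map.p_voxel, out_dir / f"{prefix}_p.nii", affine, voxel_size)
    sig = np.zeros(stat_map.statistic.shape)
    cluster_p = stat_map.meta.get("cluster_p", 0.05)
    for c in clusters.significant(cluster_p):
        sig[tuple(c.voxels.T)] = 1.0
    write_nifti(sig, out_dir / f"{prefix}_sig_clusters.nii", affine, voxel_size)
    write_cluster_table(clusters, out_dir / f"{prefix}_clusters.csv")


def write_cluster_table(clusters: ClusterSet, path: str | Path) -> None:
    clusters.to_table().to_csv(path, index=False)
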