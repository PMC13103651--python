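"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI (written uncompressed so outputs are byte-stable),
surfaces and surface maps are GIFTI, tabular data are TSV with named
columns (confounds follow the trans_x..rot_z / global_signal /
white_matter / csf convention), and sidecars are JSON with sorted keys.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputOutputError
from .geometry import SurfaceMesh, VolumeGrid
from .preprocess import BoldRun, MOTION_COLUMNS, TISSUE_COLUMNS
from .synth import MotionParams

__all__ = [
    "write_json", "write_table", "read_table",
    "write_bold_nifti", "read_bold_nifti",
    "write_map_nifti", "read_map_nifti",
    "write_labels_nifti", "read_labels_nifti",
    "write_mesh_gifti", "read_mesh_gifti",
    "write_surface_map_gifti", "read_surface_map_gifti",
    "write_confounds_tsv", "read_confounds_tsv",
    "load_subject_dir",
]

_FLOAT_FORMAT = "%.10g"


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
    return path


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing table: {path}")
    return pd.read_csv(path, sep="\t")


def _nifti(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm", "sec")
    return img


def write_bold_nifti(run: BoldRun, grid: VolumeGrid, path) -> Path:
    """4D NIfTI (x, y, z, t) from a frames x voxels run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vols = run.data.T.reshape(grid.shape + (run.n_frames,))
    img = _nifti(vols, grid.affine)
    img.header["pixdim"][4] = run.tr
    nib.save(img, path)
    return path


def read_bold_nifti(path, tr: float | None = None) -> tuple[BoldRun, VolumeGrid]:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing BOLD volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    grid = VolumeGrid(data.shape[:3], img.affine)
    frames = data.reshape(-1, data.shape[3]).T
    tr = float(img.header["pixdim"][4]) if tr is None else tr
    return BoldRun(frames, tr, np.ones(frames.shape[0], dtype=bool), grid), grid


def write_map_nifti(values: np.ndarray, grid: VolumeGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(np.asarray(values).reshape(grid.shape), grid.affine), path)
    return path


def read_map_nifti(path) -> tuple[np.ndarray, VolumeGrid]:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing map volume: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    return data.reshape(-1), VolumeGrid(data.shape, img.affine)


def write_labels_nifti(grid: VolumeGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(grid.labels, dtype=np.int16), grid.affine)
    nib.save(img, path)
    return path


def read_labels_nifti(path) -> VolumeGrid:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing label volume: {path}")
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.int32)
    return VolumeGrid(labels.shape, img.affine, labels)


def write_mesh_gifti(mesh: SurfaceMesh, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gii = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(gii, path)
    return path


def read_mesh_gifti(path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing surface: {path}")
    gii = nib.load(path)
    coords = gii.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = gii.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int))


def write_surface_map_gifti(values: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gii = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                 intent="NIFTI_INTENT_NONE"),
    ])
    nib.save(gii, path)
    return path


def read_surface_map_gifti(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"missing surface map: {path}")
    return np.asarray(nib.load(path).darrays[0].data, dtype=float)


def write_confounds_tsv(motion: MotionParams, tissue: pd.DataFrame, path) -> Path:
    df = pd.DataFrame(motion.params, columns=list(MOTION_COLUMNS))
    for c in TISSUE_COLUMNS:
        df[c] = np.asarray(tissue[c], dtype=float)
    return write_table(df, path)


def read_confounds_tsv(path) -> tuple[MotionParams, pd.DataFrame]:
    df = read_table(path)
    missing = [c for c in (*MOTION_COLUMNS, *TISSUE_COLUMNS) if c not in df.columns]
    if missing:
        raise InputOutputError(f"confound file {path} lacks columns {missing}")
    motion = MotionParams(df[list(MOTION_COLUMNS)].to_numpy(float))
    return motion, df[list(TISSUE_COLUMNS)].copy()


def load_subject_dir(subject_dir) -> tuple[BoldRun, VolumeGrid, MotionParams, pd.DataFrame]:
    """Read one subject directory (bold.nii + confounds.tsv)."""
    subject_dir = Path(subject_dir)
    run, grid = read_bold_nifti(subject_dir / "bold.nii")
    motion, tissue = read_confounds_tsv(subject_dir / "confounds.tsv")
    return run, grid, motion, tissue
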