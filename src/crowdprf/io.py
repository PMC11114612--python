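"""Containers on disk: voxel-by-time matrices, aperture movies, tables.

Matrices travel as compressed ``.npz`` tensors with a JSON sidecar carrying
the metadata the pipeline needs (TR, raster geometry, run type); tables as
TSV.  4D NIfTI import/export (via nibabel) is available for interoperating
with standard neuroimaging layouts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import ApertureMovie, FieldRaster


def save_matrix(path, data: np.ndarray, meta: dict | None = None) -> None:
    """Write a (voxels x TRs) matrix as .npz plus a .json sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=np.asarray(data))
    path.with_suffix(".json").write_text(json.dumps(meta or {}, indent=2))


def load_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data, meta


def save_movie(path, movie: ApertureMovie) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), frames=movie.frames)
    meta = {
        "frame_duration": movie.frame_duration,
        "tr": movie.tr,
        "paradigm": movie.paradigm,
        "half_width": movie.raster.half_width,
        "n_pixels": movie.raster.n_pixels,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_movie(path) -> ApertureMovie:
    path = Path(path)
    frames = np.load(path.with_suffix(".npz"))["frames"]
    meta = json.loads(path.with_suffix(".json").read_text())
    raster = FieldRaster(meta["half_width"], meta["n_pixels"])
    return ApertureMovie(
        frames, meta["frame_duration"], meta["tr"], raster, meta["paradigm"]
    )


def save_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def matrix_to_nifti(data: np.ndarray, tr: float):
    """Pack a (voxels x TRs) matrix into a 4D NIfTI image (voxels along x)."""
    import nibabel as nib

    arr = np.asarray(data)[:, None, None, :]
    img = nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = tr
    return img


def nifti_to_matrix(img) -> np.ndarray:
    """Flatten a 4D NIfTI image back to (voxels x TRs)."""
    arr = np.asarray(img.dataobj)
    return arr.reshape(-1, arr.shape[-1])
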