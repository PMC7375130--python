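"""Readers and writers for the pipeline's on-disk formats.

Voxel maps travel either as 4-D NIfTI volumes against a 3-D brain mask
(one volume per subject) or as an HDF5 matrix container with a JSON
sidecar recording subject order and the voxel mask; parcellations as
integer NIfTI or two-column CSV; subject tables as CSV/TSV; fitted models
and results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import NetworkParcellation

__all__ = [
    "synthetic_mask",
    "write_maps_nifti",
    "read_maps_nifti",
    "save_matrix",
    "load_matrix",
    "write_parcellation_csv",
    "read_parcellation_csv",
    "write_parcellation_nifti",
    "read_subject_table",
    "write_subject_table",
    "write_json",
]

_VOXEL_MM = 2.0


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    """Smallest near-cubic grid holding n_voxels."""
    side = int(np.ceil(n_voxels ** (1 / 3)))
    nx = side
    ny = side
    nz = int(np.ceil(n_voxels / (nx * ny)))
    return nx, ny, nz


def synthetic_mask(n_voxels: int) -> nib.Nifti1Image:
    """Binary mask laying the 1-D voxel ordering onto a compact 3-D grid."""
    shape = _grid_shape(n_voxels)
    flat = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    flat[:n_voxels] = 1
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    return nib.Nifti1Image(flat.reshape(shape), affine)


def write_maps_nifti(values: np.ndarray, path, mask: nib.Nifti1Image | None = None):
    """Write an n x m map matrix as a 4-D NIfTI (one volume per subject)."""
    values = np.asarray(values, dtype=np.float32)
    n, m = values.shape
    if mask is None:
        mask = synthetic_mask(m)
    mdata = np.asarray(mask.dataobj).astype(bool)
    if mdata.sum() != m:
        raise ValueError("mask voxel count does not match the matrix")
    vol = np.zeros(mdata.shape + (n,), dtype=np.float32)
    vol[mdata, :] = values.T
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))
    return mask


def read_maps_nifti(path, mask_path) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    data = np.asarray(img.dataobj)
    return data[mask, :].T.astype(float)


def save_matrix(path, values: np.ndarray, subject_ids=None, meta: dict | None = None):
    """HDF5 matrix container plus a JSON sidecar (subject order, metadata)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.asarray(values, dtype=float),
                         compression="gzip")
    sidecar = {"shape": list(np.asarray(values).shape),
               "subject_ids": list(subject_ids) if subject_ids is not None else None}
    sidecar.update(meta or {})
    write_json(path.with_suffix(path.suffix + ".json"), sidecar)


def load_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return values, meta


def write_parcellation_csv(parcellation: NetworkParcellation, path):
    df = pd.DataFrame({
        "voxel": np.arange(len(parcellation.labels)),
        "network": parcellation.labels,
        "name": [parcellation.names[v] for v in parcellation.labels],
    })
    df.to_csv(path, index=False)


def read_parcellation_csv(path) -> NetworkParcellation:
    df = pd.read_csv(path)
    names = (df.drop_duplicates("network").set_index("network")["name"]
             .to_dict())
    return NetworkParcellation(labels=df["network"].to_numpy(),
                               names={int(k): str(v) for k, v in names.items()})


def write_parcellation_nifti(parcellation: NetworkParcellation, path):
    mask = synthetic_mask(len(parcellation.labels))
    mdata = np.asarray(mask.dataobj).astype(bool)
    vol = np.zeros(mdata.shape, dtype=np.int16)
    vol[mdata] = parcellation.labels
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_subject_table(table: pd.DataFrame, path):
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
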