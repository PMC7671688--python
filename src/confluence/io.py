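"""Reading and writing standard neuroimaging formats.

Surfaces go to GIFTI (.surf.gii) with per-vertex fields as .func.gii /
.label.gii, or to ASCII PLY; volumes to NIfTI-1 with a RAS affine; tables
to TSV. A confluence model serializes as a directory of those files plus a
plain-text key=value manifest.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .surfaces import ConfluenceModel

__all__ = [
    "save_surface_gifti", "load_surface_gifti",
    "save_scalar_gifti", "load_scalar_gifti",
    "save_surface_ply",
    "save_volume_nifti", "load_volume_nifti",
    "save_confluence_model", "load_confluence_model",
    "write_manifest", "read_manifest",
]


def save_surface_gifti(mesh: SurfaceMesh, path: str) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, path)


def load_surface_gifti(path: str) -> SurfaceMesh:
    img = nib.load(path)
    verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(np.asarray(verts, float), np.asarray(tris, np.int64))


def save_scalar_gifti(values: np.ndarray, path: str, label: bool = False) -> None:
    values = np.asarray(values)
    if label:
        arr = nib.gifti.GiftiDataArray(values.astype(np.int32),
                                       intent="NIFTI_INTENT_LABEL")
    else:
        arr = nib.gifti.GiftiDataArray(values.astype(np.float32),
                                       intent="NIFTI_INTENT_NONE")
    nib.save(nib.gifti.GiftiImage(darrays=[arr]), path)


def load_scalar_gifti(path: str) -> np.ndarray:
    img = nib.load(path)
    return np.asarray(img.darrays[0].data)


def save_surface_ply(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def save_volume_nifti(volume: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)


def load_volume_nifti(path: str):
    img = nib.load(path)
    return np.asarray(img.get_fdata()), img.affine


def write_manifest(entries: dict, path: str) -> None:
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def read_manifest(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                key, value = line.split("=", 1)
                out[key] = value
    return out


def save_confluence_model(model: ConfluenceModel, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    save_surface_gifti(model.inner, os.path.join(directory, "inner.surf.gii"))
    save_surface_gifti(model.outer, os.path.join(directory, "outer.surf.gii"))
    if model.axis_mm is not None:
        save_scalar_gifti(model.axis_mm, os.path.join(directory, "axis.func.gii"))
    save_scalar_gifti(model.ap_mm, os.path.join(directory, "ap.func.gii"))
    if model.subregion is not None:
        save_scalar_gifti(model.subregion,
                          os.path.join(directory, "subregion.label.gii"),
                          label=True)
    save_scalar_gifti(model.origin.astype(np.int32),
                      os.path.join(directory, "origin.label.gii"), label=True)
    pd.DataFrame({"bridgehead": model.bridgeheads}).to_csv(
        os.path.join(directory, "bridgeheads.tsv"), sep="\t", index=False)
    write_manifest({"n_vertices": model.n_vertices,
                    "n_bridgeheads": len(model.bridgeheads)},
                   os.path.join(directory, "manifest.txt"))


def load_confluence_model(directory: str) -> ConfluenceModel:
    inner = load_surface_gifti(os.path.join(directory, "inner.surf.gii"))
    outer = load_surface_gifti(os.path.join(directory, "outer.surf.gii"))
    bridgeheads = pd.read_csv(os.path.join(directory, "bridgeheads.tsv"),
                              sep="\t")["bridgehead"].to_numpy(np.int64)
    origin = load_scalar_gifti(
        os.path.join(directory, "origin.label.gii")).astype(np.int8)
    axis_path = os.path.join(directory, "axis.func.gii")
    axis = load_scalar_gifti(axis_path).astype(float) \
        if os.path.exists(axis_path) else None
    sub_path = os.path.join(directory, "subregion.label.gii")
    subregion = load_scalar_gifti(sub_path).astype(np.int32) \
        if os.path.exists(sub_path) else None
    inner.scalars["ap"] = load_scalar_gifti(
        os.path.join(directory, "ap.func.gii")).astype(float)
    model = ConfluenceModel(inner=inner, outer=outer, bridgeheads=bridgeheads,
                            origin=origin, axis_mm=axis, subregion=subregion)
    return model
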