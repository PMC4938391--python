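"""File I/O: GIFTI interchange and the internal HDF5 array container.

GIFTI (.surf.gii / .func.gii / .label.gii) is the interchange surface for
standard neuroimaging tools; the single-file HDF5 container holds named
datasets (``mesh/vertices``, ``mesh/triangles``, ``field/data``,
``labels``) with metadata attributes and is the format the toolkit itself
round-trips byte-identically (HDF5 object timestamps are disabled).

All vertex indices are 0-based.  Fields and label maps record the SHA-1
checksum of the mesh they were computed on; readers that are handed a mesh
verify it.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from tnlm.filtering import TimeSeriesField
from tnlm.mesh import SurfaceMesh
from tnlm.parcellation import Parcellation

__all__ = [
    "read_surface",
    "write_surface",
    "read_field",
    "write_field",
    "read_labels",
    "write_labels",
]

_H5_KW = dict(track_times=False)  # deterministic, byte-stable files


def _is_gifti(path: Path) -> bool:
    return path.name.endswith(".gii")


# -- surfaces ---------------------------------------------------------------

def read_surface(path) -> SurfaceMesh:
    """Read a triangulated surface from GIFTI (.surf.gii) or the container."""
    path = Path(path)
    if _is_gifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
        if not coords or not tris:
            raise ValueError(f"{path}: missing pointset/triangle arrays")
        return SurfaceMesh(
            vertices=coords[0].data.astype(np.float64),
            triangles=tris[0].data.astype(np.int64),
        )
    with h5py.File(path, "r") as f:
        return SurfaceMesh(
            vertices=f["mesh/vertices"][()],
            triangles=f["mesh/triangles"][()],
        )


def write_surface(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if _is_gifti(path):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32),
                    intent="NIFTI_INTENT_POINTSET",
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32),
                    intent="NIFTI_INTENT_TRIANGLE",
                ),
            ]
        )
        nib.save(img, str(path))
        return
    with h5py.File(path, "w", track_order=False) as f:
        f.create_dataset("mesh/vertices", data=mesh.vertices, **_H5_KW)
        f.create_dataset("mesh/triangles", data=mesh.triangles, **_H5_KW)
        f.attrs["index_base"] = 0


# -- time-series fields -----------------------------------------------------

def read_field(path, mesh: SurfaceMesh | None = None) -> TimeSeriesField:
    """Read a per-vertex time series (GIFTI functional or container).

    If a mesh is given, its vertex count (and, for container files, its
    recorded checksum) must match the field.
    """
    path = Path(path)
    if _is_gifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.column_stack([d.data for d in img.darrays]).astype(np.float64)
        fld = TimeSeriesField(data=data)
    else:
        with h5py.File(path, "r") as f:
            ds = f["field/data"]
            fld = TimeSeriesField(
                data=ds[()],
                standardized=bool(ds.attrs.get("standardized", False)),
                tr=(
                    float(ds.attrs["tr"]) if "tr" in ds.attrs else None
                ),
                mesh_checksum=ds.attrs.get("mesh_checksum", None),
                zero_variance=(
                    f["field/zero_variance"][()]
                    if "field/zero_variance" in f
                    else None
                ),
            )
    if mesh is not None:
        if fld.n_vertices != mesh.n_vertices:
            raise ValueError(
                f"field has {fld.n_vertices} vertices but mesh has "
                f"{mesh.n_vertices}"
            )
        if fld.mesh_checksum and fld.mesh_checksum != mesh.checksum():
            raise ValueError("field was computed on a different mesh (checksum)")
    return fld


def write_field(fld: TimeSeriesField, path) -> None:
    path = Path(path)
    if _is_gifti(path):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    np.ascontiguousarray(fld.data[:, t], dtype=np.float32),
                    intent="NIFTI_INTENT_NONE",
                )
                for t in range(fld.T)
            ]
        )
        nib.save(img, str(path))
        return
    with h5py.File(path, "w", track_order=False) as f:
        ds = f.create_dataset("field/data", data=fld.data, **_H5_KW)
        ds.attrs["standardized"] = fld.standardized
        if fld.tr is not None:
            ds.attrs["tr"] = fld.tr
        if fld.mesh_checksum is not None:
            ds.attrs["mesh_checksum"] = fld.mesh_checksum
        if fld.zero_variance is not None:
            f.create_dataset(
                "field/zero_variance", data=fld.zero_variance, **_H5_KW
            )
        f.attrs["index_base"] = 0


# -- label maps -------------------------------------------------------------

def read_labels(path) -> Parcellation:
    """Read a parcellation from GIFTI label, TSV, or the container."""
    path = Path(path)
    if _is_gifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    elif path.suffix == ".tsv":
        import pandas as pd

        tab = pd.read_csv(path, sep="\t")
        tab = tab.sort_values("vertex_index")
        if not np.array_equal(
            tab["vertex_index"].to_numpy(), np.arange(len(tab))
        ):
            raise ValueError(f"{path}: vertex_index must be 0..n-1")
        labels = tab["label"].to_numpy(dtype=np.int64)
    else:
        with h5py.File(path, "r") as f:
            labels = f["labels"][()]
    return Parcellation(labels=labels, K=int(labels.max()) + 1)


def write_labels(parc: Parcellation, path) -> None:
    path = Path(path)
    labels = parc.labels
    if _is_gifti(path):
        import nibabel as nib

        darray = nib.gifti.GiftiDataArray(
            labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
        table = nib.gifti.GiftiLabelTable()
        rng = np.random.default_rng(0)  # stable arbitrary colors
        for k in np.unique(labels):
            r, g, b = rng.uniform(0.2, 1.0, 3)
            lab = nib.gifti.GiftiLabel(
                key=int(k), red=r, green=g, blue=b, alpha=1.0
            )
            lab.label = f"parcel_{int(k)}"
            table.labels.append(lab)
        img = nib.gifti.GiftiImage(darrays=[darray], labeltable=table)
        nib.save(img, str(path))
        return
    if path.suffix == ".tsv":
        import pandas as pd

        pd.DataFrame(
            {"vertex_index": np.arange(labels.size), "label": labels}
        ).to_csv(path, sep="\t", index=False)
        return
    with h5py.File(path, "w", track_order=False) as f:
        ds = f.create_dataset("labels", data=labels, **_H5_KW)
        ds.attrs["K"] = parc.K
        f.attrs["index_base"] = 0
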