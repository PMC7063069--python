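"""File formats: MetaImage/NIfTI volumes, JSON beams/plans/contours,
CSV fluence maps.

SimpleITK carries the image I/O.  Arrays in this package are indexed
``[ix, iy, iz]`` with world position ``origin + index * spacing``; ITK
images store the same lattice with the array axes reversed, so every
read/write transposes between the two layouts.  DVFs are 3-component
vector images in mm; masks are unsigned 8-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .bev import DVF2D, PlaneGrid
from .dvf import DVF3D, ROIMask, Volume3D
from .fluence import FluenceGrid
from .geometry import BeamGeometry, Grid3D
from .sequencing import AperturePlan
from .contours import ContourSet

__all__ = [
    "write_volume", "read_volume",
    "write_mask", "read_mask",
    "write_dvf", "read_dvf",
    "write_dvf2d", "read_dvf2d",
    "write_fluence", "read_fluence",
    "write_beams", "read_beams",
    "write_plan", "read_plan",
    "write_contours", "read_contours",
]


def _grid_to_image(grid: Grid3D, array_xyz: np.ndarray, vector: bool = False):
    if vector:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(array_xyz, (2, 1, 0, 3))),
            isVector=True,
        )
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(array_xyz.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def _image_to_grid(img) -> Grid3D:
    return Grid3D(
        shape=tuple(int(n) for n in img.GetSize()),
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )


def write_volume(vol: Volume3D, path) -> None:
    sitk.WriteImage(_grid_to_image(vol.grid, vol.values), str(path))


def read_volume(path) -> Volume3D:
    img = sitk.ReadImage(str(path))
    return Volume3D(grid=_image_to_grid(img),
                    values=sitk.GetArrayFromImage(img).T.astype(float))


def write_mask(mask: ROIMask, path) -> None:
    sitk.WriteImage(_grid_to_image(mask.grid, mask.mask.astype(np.uint8)), str(path))


def read_mask(path, name: str = None) -> ROIMask:
    img = sitk.ReadImage(str(path))
    return ROIMask(grid=_image_to_grid(img),
                   mask=sitk.GetArrayFromImage(img).T.astype(bool),
                   name=name or Path(path).stem.split(".")[0])


def write_dvf(dvf: DVF3D, path) -> None:
    sitk.WriteImage(_grid_to_image(dvf.grid, dvf.vectors, vector=True), str(path))


def read_dvf(path) -> DVF3D:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    return DVF3D(grid=_image_to_grid(img),
                 vectors=np.transpose(arr, (2, 1, 0, 3)).astype(float))


# -- 2-D deformation fields --------------------------------------------------

def write_dvf2d(d: DVF2D, path_stem) -> None:
    """Write a plane field as <stem>.mha (2-component vector image),
    <stem>_coverage.mha and a <stem>.json geometry sidecar."""
    stem = str(path_stem)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(d.vectors, (1, 0, 2))), isVector=True)
    img.SetSpacing(tuple(float(s) for s in d.plane.spacing))
    img.SetOrigin(tuple(float(o) for o in d.plane.origin))
    sitk.WriteImage(img, stem + ".mha")
    cov = sitk.GetImageFromArray(np.ascontiguousarray(d.coverage.T.astype(np.int32)))
    cov.SetSpacing(tuple(float(s) for s in d.plane.spacing))
    cov.SetOrigin(tuple(float(o) for o in d.plane.origin))
    sitk.WriteImage(cov, stem + "_coverage.mha")
    with open(stem + ".json", "w") as fh:
        json.dump({
            "beam_id": d.beam_id,
            "shape": list(d.plane.shape),
            "spacing_mm": list(d.plane.spacing),
            "origin_mm": list(d.plane.origin),
        }, fh, indent=2)


def read_dvf2d(path_stem) -> DVF2D:
    stem = str(path_stem)
    with open(stem + ".json") as fh:
        meta = json.load(fh)
    plane = PlaneGrid(tuple(meta["shape"]), tuple(meta["spacing_mm"]),
                      tuple(meta["origin_mm"]))
    vec = np.transpose(sitk.GetArrayFromImage(sitk.ReadImage(stem + ".mha")),
                       (1, 0, 2)).astype(float)
    cov = sitk.GetArrayFromImage(sitk.ReadImage(stem + "_coverage.mha")).T
    return DVF2D(plane=plane, vectors=vec, coverage=cov.astype(int),
                 beam_id=meta.get("beam_id", "beam"))


# -- fluence maps ------------------------------------------------------------

def write_fluence(f: FluenceGrid, path_stem) -> None:
    """CSV matrix (rows = x index) plus a JSON geometry sidecar."""
    stem = str(path_stem)
    np.savetxt(stem + ".csv", f.intensity, delimiter=",")
    with open(stem + ".json", "w") as fh:
        json.dump({
            "beam_id": f.beam_id,
            "shape": list(f.plane.shape),
            "spacing_mm": list(f.plane.spacing),
            "origin_mm": list(f.plane.origin),
        }, fh, indent=2)


def read_fluence(path_stem) -> FluenceGrid:
    stem = str(path_stem)
    with open(stem + ".json") as fh:
        meta = json.load(fh)
    plane = PlaneGrid(tuple(meta["shape"]), tuple(meta["spacing_mm"]),
                      tuple(meta["origin_mm"]))
    arr = np.loadtxt(stem + ".csv", delimiter=",").reshape(plane.shape)
    return FluenceGrid(plane=plane, intensity=arr, beam_id=meta.get("beam_id", "beam"))


# -- beams, plans, contours --------------------------------------------------

def write_beams(beams, path) -> None:
    with open(path, "w") as fh:
        json.dump({"beams": [b.to_dict() for b in beams]}, fh, indent=2)


def read_beams(path):
    with open(path) as fh:
        doc = json.load(fh)
    return [BeamGeometry.from_dict(d) for d in doc["beams"]]


def write_plan(plan: AperturePlan, path) -> None:
    with open(path, "w") as fh:
        json.dump(plan.to_dict(), fh, indent=2)


def read_plan(path) -> AperturePlan:
    with open(path) as fh:
        return AperturePlan.from_dict(json.load(fh))


def write_contours(c: ContourSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "structure_name": c.structure_name,
            "slice_axis": c.slice_axis,
            "slices": {str(iz): [p.tolist() for p in polys]
                       for iz, polys in c.slices.items()},
        }, fh)


def read_contours(path) -> ContourSet:
    with open(path) as fh:
        doc = json.load(fh)
    return ContourSet(
        structure_name=doc["structure_name"],
        slices={int(iz): [np.asarray(p) for p in polys]
                for iz, polys in doc["slices"].items()},
        slice_axis=doc.get("slice_axis", "z"),
    )
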