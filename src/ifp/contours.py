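"""Planar contours <-> voxel masks, and structure propagation through a DVF.

The automatic delineation chain fills the planning contours slice by slice
into a voxel mask, maps the mask through the deformation field (backward,
nearest-neighbour — binary masks admit no gray-level thresholding), and
re-extracts closed planar polygons from the deformed mask with per-slice
marching squares at the 0.5 iso-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path
from skimage import measure

from .dvf import DVF3D, ROIMask, invert_dvf
from .geometry import Grid3D

__all__ = ["ContourSet", "fill_contours", "propagate_mask", "extract_contours"]

log = logging.getLogger(__name__)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class ContourSet:
    """Closed planar polygons of one structure, grouped by slice index.

    ``slices`` maps a slice index (along ``slice_axis``, currently ``z``)
    to a list of ``(n, 2)`` vertex arrays in in-slice world mm ``(x, y)``.
    The polygon edge from the last vertex back to the first is implicit; a
    duplicated closing vertex is accepted and dropped.  Nested polygons are
    holes under the even-odd rule.
    """

    structure_name: str
    slices: dict
    slice_axis: str = "z"

    def __post_init__(self):
        if self.slice_axis != "z":
            raise ValueError("only z-sliced contours are supported")
        clean = {}
        for iz, polys in self.slices.items():
            out = []
            for p, poly in enumerate(polys):
                a = np.asarray(poly, dtype=float)
                if a.ndim != 2 or a.shape[1] != 2:
                    raise ValueError(
                        f"slice {iz} polygon {p}: vertices must be (n, 2)")
                if len(a) > 1 and np.allclose(a[0], a[-1]):
                    a = a[:-1]
                if len(a) < 3:
                    raise ValueError(
                        f"slice {iz} polygon {p}: open polygon "
                        f"(fewer than 3 distinct vertices)")
                if _polygon_area(a) <= 0:
                    raise ValueError(f"slice {iz} polygon {p}: zero area")
                out.append(a)
            clean[int(iz)] = out
        object.__setattr__(self, "slices", clean)


def fill_contours(c: ContourSet, grid: Grid3D) -> ROIMask:
    """Rasterize contours into a voxel mask (even-odd rule, holes supported).

    A voxel is inside when its center is inside an odd number of the
    slice's polygons.
    """
    nx, ny, nz = grid.shape
    mask = np.zeros(grid.shape, dtype=bool)
    xs = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    for iz, polys in c.slices.items():
        if not (0 <= iz < nz):
            raise ValueError(f"slice index {iz} outside grid (nz={nz})")
        inside = np.zeros(len(pts), dtype=bool)
        for poly in polys:
            inside ^= Path(poly).contains_points(pts)
        mask[:, :, iz] = inside.reshape(nx, ny)
    return ROIMask(grid=grid, mask=mask, name=c.structure_name)


def propagate_mask(m: ROIMask, dvf: DVF3D, iterations: int = 20,
                   tol: float = 0.01, interp: str = "linear") -> ROIMask:
    """Map a planning-anatomy mask onto the daily anatomy.

    The (planning -> daily) field is inverted; a daily voxel at ``x`` is
    true when the planning mask, sampled at the preimage ``x + v_inv(x)``,
    is true.  The default samples the binary indicator trilinearly and
    thresholds at 0.5, which localises the propagated surface to sub-voxel
    accuracy and is fully deterministic (>= resolves the tie); nearest-
    neighbour sampling (``interp='nearest'``) is available but carries a
    half-voxel classification band.  A whole-voxel translation is an exact
    index shift under either rule.
    """
    if m.grid != dvf.grid:
        raise ValueError("mask and DVF must share a grid")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interp {interp!r}")
    inv = invert_dvf(dvf, iterations=iterations, tol=tol)
    src = m.grid.voxel_centers().reshape(-1, 3) + inv.vectors.reshape(-1, 3)
    fidx = m.grid.world_to_index(src)
    shape = np.asarray(m.grid.shape)
    ok = np.all((fidx >= -0.5) & (fidx <= shape - 0.5), axis=1)
    out = np.zeros(len(src), dtype=bool)
    if interp == "nearest":
        idx = np.round(fidx).astype(int)
        idx_ok = np.clip(idx[ok], 0, shape - 1)
        out[ok] = m.mask[idx_ok[:, 0], idx_ok[:, 1], idx_ok[:, 2]]
    else:
        from scipy.ndimage import map_coordinates
        coords = [np.clip(fidx[ok, a], 0, shape[a] - 1) for a in range(3)]
        vals = map_coordinates(m.mask.astype(float), coords, order=1,
                               mode="nearest")
        out[ok] = vals >= 0.5
    return ROIMask(grid=m.grid, mask=out.reshape(m.grid.shape), name=m.name)


def extract_contours(m: ROIMask) -> ContourSet:
    """Per-slice marching squares at iso-level 0.5 on the binary mask.

    Polygons are closed by construction (each slice is padded with a false
    border before contouring, so every contour is a loop).  Filling the
    result recovers the mask except for at most a one-voxel boundary band.
    An empty mask gives an empty contour set.
    """
    slices = {}
    dx, dy = m.grid.spacing[0], m.grid.spacing[1]
    ox, oy = m.grid.origin[0], m.grid.origin[1]
    for iz in range(m.grid.shape[2]):
        sl = m.mask[:, :, iz]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        polys = []
        for cont in measure.find_contours(padded, 0.5):
            # drop the duplicated closing vertex; convert index -> mm
            v = cont[:-1] if np.allclose(cont[0], cont[-1]) else cont
            poly = np.empty_like(v)
            poly[:, 0] = ox + (v[:, 0] - 1.0) * dx
            poly[:, 1] = oy + (v[:, 1] - 1.0) * dy
            if len(poly) >= 3 and _polygon_area(poly) > 0:
                polys.append(poly)
        if polys:
            slices[iz] = polys
    return ContourSet(structure_name=m.name, slices=slices)
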