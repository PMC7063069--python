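"""Reduce a 3-D deformation field to a 2-D field on a beam's isocenter plane.

Each fluence-plane pixel defines a divergent ray from the source.  The ray
is traversed through the voxel grid; the 3-D displacement of every ROI
voxel it crosses is projected endpoint-wise onto the isocenter plane, and
the pixel's 2-D vector is the unweighted mean of those projections (an
optional chord-length-weighted mean is available for sensitivity checks).
Pixels whose rays miss the ROI carry the zero vector by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt
from scipy.sparse.linalg import spsolve

from .dvf import DVF3D, ROIMask
from .geometry import BeamGeometry, Grid3D, Ray, pixel_ray, project_vector, world_to_beam

__all__ = [
    "PlaneGrid",
    "DVF2D",
    "trace_ray_voxels",
    "project_dvf_to_bev",
    "fill_uncovered",
]

log = logging.getLogger(__name__)

#: intersection lengths below this (mm) count as grazing contacts, not crossings
GRAZE_TOL = 1e-9


@dataclass(frozen=True)
class PlaneGrid:
    """Pixel lattice on the isocenter plane, in beam-frame (x, y) mm.

    ``origin`` is the beam-frame position of the center of pixel (0, 0).
    """

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 2 or len(spacing) != 2 or len(origin) != 2:
            raise ValueError("PlaneGrid fields must have 2 components")
        if any(n < 1 for n in shape) or any(s <= 0 for s in spacing):
            raise ValueError("PlaneGrid needs shape >= 1 and spacing > 0")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def pixel_area(self) -> float:
        return self.spacing[0] * self.spacing[1]

    def pixel_centers(self) -> np.ndarray:
        """Beam-frame (x, y) centers, shape ``(*shape, 2)``."""
        ix, iy = np.indices(self.shape, dtype=float)
        return np.stack(
            [self.origin[0] + ix * self.spacing[0],
             self.origin[1] + iy * self.spacing[1]], axis=-1
        )


@dataclass(frozen=True)
class DVF2D:
    """Per-pixel 2-D displacement field (mm) on the isocenter plane.

    ``coverage`` counts, per pixel, the ROI voxels crossed by the pixel's
    ray; pixels with zero coverage carry the zero vector.
    """

    plane: PlaneGrid
    vectors: np.ndarray
    coverage: np.ndarray
    beam_id: str = "beam"

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        c = np.asarray(self.coverage, dtype=int)
        if v.shape != self.plane.shape + (2,):
            raise ValueError("vectors shape mismatch with plane")
        if c.shape != self.plane.shape:
            raise ValueError("coverage shape mismatch with plane")
        if np.any(c < 0):
            raise ValueError("coverage must be >= 0")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "coverage", c)


def _ray_box_t(source: np.ndarray, direction: np.ndarray, lo: np.ndarray,
               hi: np.ndarray):
    """Entry/exit parameters of a ray with an axis-aligned box (slab method).

    Returns ``(t0, t1)`` or ``None`` when the ray misses the box.  ``t`` is
    mm along the (unit) direction, clipped to the forward half-line.
    """
    t0, t1 = 0.0, np.inf
    for a in range(3):
        d = direction[a]
        if abs(d) < 1e-12:
            if source[a] < lo[a] or source[a] > hi[a]:
                return None
            continue
        ta = (lo[a] - source[a]) / d
        tb = (hi[a] - source[a]) / d
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
    if t1 - t0 <= GRAZE_TOL:
        return None
    return t0, t1


def trace_ray_voxels(ray: Ray, grid: Grid3D):
    """Voxels a ray crosses, with chord lengths, in order along the ray.

    Parametric (Siddon-type) traversal: the entry/exit parameters of the
    grid's bounding box are merged with every voxel-boundary crossing; each
    resulting sub-interval lies in exactly one voxel, identified by its
    midpoint.  Grazing contacts shorter than ``GRAZE_TOL`` are dropped, so
    the summed lengths equal the bounding-box chord length to float
    precision.  A ray that misses the box yields an empty list.
    """
    src = np.asarray(ray.source)
    d = np.asarray(ray.direction)
    lo, hi = grid.bbox_min, grid.bbox_max
    hit = _ray_box_t(src, d, lo, hi)
    if hit is None:
        return []
    t0, t1 = hit
    ts = [np.array([t0, t1])]
    for a in range(3):
        if abs(d[a]) < 1e-12:
            continue
        # voxel boundary planes: lo[a] + k * spacing, k = 0..shape[a]
        k_a = (src[a] + t0 * d[a] - lo[a]) / grid.spacing[a]
        k_b = (src[a] + t1 * d[a] - lo[a]) / grid.spacing[a]
        k_lo, k_hi = sorted((k_a, k_b))
        ks = np.arange(np.ceil(k_lo), np.floor(k_hi) + 1.0)
        ts.append((lo[a] + ks * grid.spacing[a] - src[a]) / d[a])
    t = np.unique(np.concatenate(ts))
    t = t[(t >= t0 - GRAZE_TOL) & (t <= t1 + GRAZE_TOL)]
    t[0], t[-1] = t0, t1
    lengths = np.diff(t)
    mids = src + 0.5 * (t[:-1] + t[1:])[:, None] * d
    idx = np.floor((mids - lo) / np.asarray(grid.spacing)).astype(int)
    np.clip(idx, 0, np.asarray(grid.shape) - 1, out=idx)
    keep = lengths > GRAZE_TOL
    return [
        (tuple(i), float(l)) for i, l in zip(idx[keep], lengths[keep])
    ]


def project_dvf_to_bev(
    dvf: DVF3D,
    roi: ROIMask,
    beam: BeamGeometry,
    plane: PlaneGrid,
    length_weighted: bool = False,
) -> DVF2D:
    """Project a 3-D deformation field into a beam's 2-D field on the plane.

    For every plane pixel, the pixel's divergent ray is traversed through
    the grid; for each ROI voxel crossed, the voxel's displacement is
    projected endpoint-wise (start = voxel center, end = center + vector,
    both taken to the beam frame) and the pixel vector is the mean of the
    projections — unweighted by default, as the per-ray average divides by
    the plain count ``n``; ``length_weighted=True`` weights each voxel by
    its chord length instead.

    Raises on an empty ROI, or if any ROI voxel endpoint reaches the source.
    """
    if dvf.grid != roi.grid:
        raise ValueError("DVF and ROI must share a grid")
    if not roi.mask.any():
        raise ValueError(f"ROI {roi.name!r} is empty")

    grid = dvf.grid
    mask = roi.mask
    # bounding box of the ROI (world) for cheap ray prefiltering
    ii = np.nonzero(mask)
    lo = grid.index_to_world([a.min() for a in ii]) - 0.5 * np.asarray(grid.spacing)
    hi = grid.index_to_world([a.max() for a in ii]) + 0.5 * np.asarray(grid.spacing)

    vectors = np.zeros(plane.shape + (2,))
    coverage = np.zeros(plane.shape, dtype=int)
    centers = plane.pixel_centers()
    for ip in range(plane.shape[0]):
        for jp in range(plane.shape[1]):
            ray = pixel_ray(centers[ip, jp], beam.sad, beam)
            if _ray_box_t(np.asarray(ray.source), np.asarray(ray.direction), lo, hi) is None:
                continue
            crossed = trace_ray_voxels(ray, grid)
            if not crossed:
                continue
            idx = np.array([c[0] for c in crossed])
            lens = np.array([c[1] for c in crossed])
            keep = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
            if not keep.any():
                continue
            idx, lens = idx[keep], lens[keep]
            starts_w = grid.index_to_world(idx)
            vecs = dvf.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
            start_b = world_to_beam(starts_w, beam)
            end_b = world_to_beam(starts_w + vecs, beam)
            proj = project_vector(start_b, end_b, beam.sad)
            if length_weighted:
                w = lens / lens.sum()
                vectors[ip, jp] = (proj * w[:, None]).sum(axis=0)
            else:
                vectors[ip, jp] = proj.mean(axis=0)
            coverage[ip, jp] = len(idx)
    return DVF2D(plane=plane, vectors=vectors, coverage=coverage,
                 beam_id=beam.beam_id)


def fill_uncovered(dvf2d: DVF2D, mode: str = "zero") -> DVF2D:
    """Fill pixels whose rays missed the ROI.

    Modes: ``zero`` leaves them at (0, 0) — the default, so fluence outside
    the ROI shadow is delivered as planned; ``nearest`` copies the nearest
    covered pixel's vector (Euclidean distance in mm); ``smooth`` solves a
    Laplace interpolation with covered pixels as Dirichlet boundary.
    Covered pixels are unchanged in every mode.
    """
    if mode == "zero":
        return dvf2d
    covered = dvf2d.coverage > 0
    if not covered.any():
        raise ValueError("cannot fill: no covered pixel")
    if covered.all():
        return dvf2d
    if mode == "nearest":
        _, (inds_x, inds_y) = distance_transform_edt(
            ~covered, sampling=dvf2d.plane.spacing, return_indices=True
        )
        vec = dvf2d.vectors[inds_x, inds_y]
    elif mode == "smooth":
        vec = dvf2d.vectors.copy()
        for c in range(2):
            vec[..., c] = _laplace_fill(vec[..., c], covered)
    else:
        raise ValueError(f"unknown fill mode {mode!r}")
    vec[covered] = dvf2d.vectors[covered]
    return DVF2D(plane=dvf2d.plane, vectors=vec, coverage=dvf2d.coverage,
                 beam_id=dvf2d.beam_id)


def _laplace_fill(values: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Solve the 5-point Laplace equation on unknown pixels (Dirichlet at
    known pixels, natural/Neumann at the grid border)."""
    nx, ny = values.shape
    unknown = ~known
    n_unk = int(unknown.sum())
    num = -np.ones(values.shape, dtype=int)
    num[unknown] = np.arange(n_unk)
    rows, cols, data = [], [], []
    rhs = np.zeros(n_unk)
    ux, uy = np.nonzero(unknown)
    for k, (i, j) in enumerate(zip(ux, uy)):
        neigh = [(i + di, j + dj) for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                 if 0 <= i + di < nx and 0 <= j + dj < ny]
        rows.append(k); cols.append(k); data.append(float(len(neigh)))
        for (a, b) in neigh:
            if known[a, b]:
                rhs[k] += values[a, b]
            else:
                rows.append(k); cols.append(num[a, b]); data.append(-1.0)
    A = sparse.csr_matrix((data, (rows, cols)), shape=(n_unk, n_unk))
    sol = spsolve(A, rhs)
    out = values.copy()
    out[unknown] = sol
    return out
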