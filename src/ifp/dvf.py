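"""3-D deformation vector fields: data model, analytic families, warping.

Direction convention: a DVF maps the *planning* anatomy onto the *daily*
anatomy — the stored vector at planning position ``x`` is the displacement
to the corresponding daily position, ``x + v(x)``.  Consumers that need the
opposite direction (backward mapping for warps, organ propagation) invert
the field explicitly with :func:`invert_dvf`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import Grid3D

__all__ = [
    "Volume3D",
    "ROIMask",
    "DVF3D",
    "make_dvf",
    "sample_dvf",
    "warp_volume",
    "invert_dvf",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Volume3D:
    """A scalar volume (relative electron density, or dose) on a Grid3D."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ROIMask:
    """A per-voxel boolean structure mask."""

    grid: Grid3D
    mask: np.ndarray
    name: str = "roi"

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != self.grid.shape:
            raise ValueError(f"mask shape {m.shape} != grid shape {self.grid.shape}")
        object.__setattr__(self, "mask", m)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * float(np.prod(self.grid.spacing))


@dataclass(frozen=True)
class DVF3D:
    """Per-voxel 3-D displacement field (mm) on a regular grid."""

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vectors shape {v.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("DVF vectors must be finite")
        object.__setattr__(self, "vectors", v)

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.vectors, axis=-1).max())


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def make_dvf(kind: str, params: dict, grid: Grid3D) -> DVF3D:
    """Construct an analytic deformation field sampled at voxel centers.

    Families
    --------
    ``zero``
        No deformation.
    ``translation``
        Constant field; ``params['translation']`` is the 3-vector (mm).
    ``scaling``
        ``v(x) = (f - 1) * (x - c)`` for ``params['factor']`` = f and
        ``params['center']`` = c: isotropic scaling about c.
    ``gaussian_bump``
        ``v(x) = amplitude * exp(-|x - c|^2 / (2 sigma^2))`` with 3-vector
        ``amplitude``, center ``c`` and scalar ``sigma`` (mm).
    ``windowed_translation`` / ``windowed_scaling``
        The corresponding affine field multiplied by a radial smoothstep
        window about ``center``: 1 inside ``r_inner``, easing to 0 at
        ``r_outer``.  These model a localized organ deformation that leaves
        distant anatomy (body outline, cord) untouched.

    All families are deterministic functions of their parameters.
    """
    centers = grid.voxel_centers()

    def _p(name):
        if name not in params:
            raise ValueError(f"make_dvf kind={kind!r} requires param {name!r}")
        v = np.asarray(params[name], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"param {name!r} must be finite")
        return v

    if kind == "zero":
        vec = np.zeros(grid.shape + (3,))
    elif kind == "translation":
        vec = np.broadcast_to(_p("translation"), grid.shape + (3,)).copy()
    elif kind == "scaling":
        c, f = _p("center"), float(_p("factor"))
        vec = (f - 1.0) * (centers - c)
    elif kind == "gaussian_bump":
        c, amp, sigma = _p("center"), _p("amplitude"), float(_p("sigma"))
        r2 = np.sum((centers - c) ** 2, axis=-1)
        vec = amp * np.exp(-r2 / (2.0 * sigma**2))[..., None]
    elif kind in ("windowed_translation", "windowed_scaling"):
        c = _p("center")
        r_in, r_out = float(_p("r_inner")), float(_p("r_outer"))
        if not 0 <= r_in < r_out:
            raise ValueError("need 0 <= r_inner < r_outer")
        r = np.linalg.norm(centers - c, axis=-1)
        w = _smoothstep((r_out - r) / (r_out - r_in))
        if kind == "windowed_translation":
            affine = np.broadcast_to(_p("translation"), grid.shape + (3,))
        else:
            affine = (float(_p("factor")) - 1.0) * (centers - c)
        vec = w[..., None] * affine
    else:
        raise ValueError(f"unknown DVF kind {kind!r}")
    return DVF3D(grid=grid, vectors=vec)


def sample_dvf(dvf: DVF3D, points) -> np.ndarray:
    """Trilinearly interpolate the field at arbitrary world points.

    Points outside the grid's physical bounding box return the zero vector
    (rays and warps routinely touch the border); the count of such points
    is logged once per call.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    inside = dvf.grid.contains(pts)
    n_out = int((~inside).sum())
    if n_out:
        log.debug("sample_dvf: %d/%d points outside grid, returning zero", n_out, len(pts))
    idx = dvf.grid.world_to_index(pts)
    coords = [np.clip(idx[:, a], 0, dvf.grid.shape[a] - 1) for a in range(3)]
    out = np.zeros_like(pts)
    for c in range(3):
        out[:, c] = map_coordinates(
            dvf.vectors[..., c], coords, order=1, mode="nearest"
        )
    out[~inside] = 0.0
    return out[0] if single else out.reshape(np.asarray(points).shape)


def invert_dvf(dvf: DVF3D, iterations: int = 20, tol: float = 0.01) -> DVF3D:
    """Invert a displacement field by fixed-point iteration.

    Iterates ``v_inv(x) <- -v(x + v_inv(x))`` at every voxel center until the
    largest update falls below ``tol`` (mm) or ``iterations`` is reached.
    Suitable for the smooth, small-deformation fields in scope; the residual
    of the composition ``|v(x + v_inv(x)) + v_inv(x)|`` is logged, with a
    warning (not an error) if it exceeds ``10 * tol``.
    """
    centers = dvf.grid.voxel_centers().reshape(-1, 3)
    u = -dvf.vectors.reshape(-1, 3).copy()
    for _ in range(int(iterations)):
        u_new = -sample_dvf(dvf, centers + u)
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break
    residual = np.linalg.norm(sample_dvf(dvf, centers + u) + u, axis=-1).max()
    if residual > 10 * tol:
        log.warning("invert_dvf: composition residual %.3g mm exceeds %.3g mm",
                    residual, 10 * tol)
    else:
        log.debug("invert_dvf: composition residual %.3g mm", residual)
    return DVF3D(grid=dvf.grid, vectors=u.reshape(dvf.grid.shape + (3,)))


def warp_volume(vol: Volume3D, dvf: DVF3D, iterations: int = 20,
                tol: float = 0.01) -> Volume3D:
    """Deform a volume with a (planning -> daily) field by backward mapping.

    The output value at daily position ``x`` is the input sampled (trilinear)
    at the preimage ``x + v_inv(x)``, with ``v_inv`` from :func:`invert_dvf`.
    For a pure translation this reduces to an exact shifted copy up to
    interpolation at non-integer offsets.
    """
    if vol.grid != dvf.grid:
        raise ValueError("volume and DVF must share a grid (v1 restriction)")
    inv = invert_dvf(dvf, iterations=iterations, tol=tol)
    centers = vol.grid.voxel_centers().reshape(-1, 3)
    src = centers + inv.vectors.reshape(-1, 3)
    idx = vol.grid.world_to_index(src)
    coords = [np.clip(idx[:, a], 0, vol.grid.shape[a] - 1) for a in range(3)]
    out = map_coordinates(vol.values, coords, order=1, mode="nearest")
    return Volume3D(grid=vol.grid, values=out.reshape(vol.grid.shape))
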