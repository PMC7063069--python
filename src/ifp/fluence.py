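"""2-D ray-intensity distributions and their deformation along a 2-D field.

The fluence map ``I(x, y)`` lives on the isocenter plane of one beam.
Adapting a plan to a deformed anatomy moves each ray's intensity with the
deformation: the value at ``(x, y)`` re-appears at ``(x', y') = (x, y) + r``.
``push`` realises this as a conservative forward bilinear splat; ``pull``
samples the input at ``(x, y) - r`` (the small-deformation approximation of
the inverse map), which transports values, cannot leave holes, and gives
the displaced aperture a clean sub-pixel penumbra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .bev import DVF2D, PlaneGrid

__all__ = ["FluenceGrid", "warp_fluence", "fluence_stats"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluenceGrid:
    """Non-negative relative fluence on a plane grid."""

    plane: PlaneGrid
    intensity: np.ndarray
    beam_id: str = "beam"

    def __post_init__(self):
        a = np.asarray(self.intensity, dtype=float)
        if a.shape != self.plane.shape:
            raise ValueError(f"intensity shape {a.shape} != plane shape {self.plane.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("fluence must be finite")
        if np.any(a < 0):
            raise ValueError("fluence must be non-negative")
        object.__setattr__(self, "intensity", a)

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


def warp_fluence(f: FluenceGrid, d: DVF2D, mode: str = "push",
                 conserve_total: bool = False) -> FluenceGrid:
    """Deform a fluence map along a 2-D deformation field.

    Parameters
    ----------
    mode : {'push', 'pull'}
        ``push`` (default) splats each pixel's intensity to
        ``center + vector`` with bilinear weights; the splat conserves the
        intensity sum (up to what leaves the plane) and a uniform
        whole-pixel shift reproduces an exact index shift, but an expansive
        field spreads — dilutes — the pattern.  ``pull`` samples the input
        at ``center - vector`` by bilinear interpolation, transporting
        intensity *values* instead of mass, which is what an adapted
        aperture needs (each ray keeps its intensity at its displaced
        position); the adaptation pipeline therefore warps with ``pull``.
    conserve_total : bool
        If true, rescale the output so its intensity sum equals the input
        sum exactly (an MU-renormalisation decision, off by default).

    Intensity transported beyond the plane is dropped; the dropped fraction
    is logged.  Output is clamped at zero as a guard (neither mode can
    produce negative values from non-negative input).
    """
    if f.plane != d.plane:
        raise ValueError("fluence and deformation field must share a plane")
    if not np.all(np.isfinite(d.vectors)):
        raise ValueError("deformation vectors must be finite")
    nx, ny = f.plane.shape
    sp = np.asarray(f.plane.spacing)

    if mode == "push":
        ix, iy = np.indices((nx, ny), dtype=float)
        dest_x = ix + d.vectors[..., 0] / sp[0]
        dest_y = iy + d.vectors[..., 1] / sp[1]
        x0 = np.floor(dest_x).astype(int)
        y0 = np.floor(dest_y).astype(int)
        fx = dest_x - x0
        fy = dest_y - y0
        out = np.zeros((nx, ny))
        vals = f.intensity
        kept = 0.0
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            for dy, wy in ((0, 1.0 - fy), (1, fy)):
                xi = x0 + dx
                yi = y0 + dy
                w = wx * wy
                ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny) & (w > 0)
                np.add.at(out, (xi[ok], yi[ok]), (w * vals)[ok])
                kept += (w * vals)[ok].sum()
        total = vals.sum()
        if total > 0 and total - kept > 1e-12 * total:
            log.debug("warp_fluence push: fraction %.3g of intensity left the plane",
                      1.0 - kept / total)
    elif mode == "pull":
        ix, iy = np.indices((nx, ny), dtype=float)
        src_x = ix - d.vectors[..., 0] / sp[0]
        src_y = iy - d.vectors[..., 1] / sp[1]
        out = map_coordinates(f.intensity, [src_x, src_y], order=1,
                              mode="constant", cval=0.0)
    else:
        raise ValueError(f"unknown warp mode {mode!r}")

    if conserve_total:
        s = out.sum()
        if s > 0:
            out *= f.intensity.sum() / s
    np.clip(out, 0.0, None, out=out)
    return FluenceGrid(plane=f.plane, intensity=out, beam_id=f.beam_id)


def fluence_stats(f: FluenceGrid, open_threshold_rel: float = 0.01) -> dict:
    """Summary statistics: total (intensity-area product, mm^2-weighted),
    max, intensity-weighted centroid (mm, beam frame; ``None`` when the map
    is all zero) and open field area (pixels above ``open_threshold_rel`` of
    the maximum)."""
    I = f.intensity
    total = float(I.sum() * f.plane.pixel_area)
    mx = float(I.max()) if I.size else 0.0
    if I.sum() > 0:
        centers = f.plane.pixel_centers()
        centroid = tuple((centers * I[..., None]).sum(axis=(0, 1)) / I.sum())
    else:
        centroid = None
        log.info("fluence_stats: all-zero fluence, centroid undefined")
    open_area = float((I > open_threshold_rel * mx).sum() * f.plane.pixel_area) if mx > 0 else 0.0
    return {"total": total, "max": mx, "centroid": centroid, "open_area": open_area}
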