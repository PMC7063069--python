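"""Beam geometry and the divergent-beam projection onto the isocenter plane.

Coordinate conventions (used package-wide)
------------------------------------------
* World coordinates are patient coordinates in mm.  The gantry rotates
  about the world ``z`` axis (the patient's superior-inferior axis).
* Gantry angles follow IEC-61217: at gantry 0 deg the source sits on the
  ``+y`` side of the isocenter and the beam travels toward ``-y``
  ("beam pointing downward" with the patient supine on a couch whose
  vertical is ``y``).  The angle increases so that at 90 deg the source is
  on the ``+x`` side.
* The beam frame has its origin at the isocenter.  ``+z`` points from the
  isocenter toward the source, so the source is at ``(0, 0, SAD)`` and a
  point with beam-frame ``z > 0`` is on the source side of the isocenter
  plane (magnified by the divergent projection).  ``x``/``y`` span the
  field; the frame is right handed.
* Lengths are mm and angles are degrees at every interface; radians exist
  only inside trigonometric calls.
* Voxel grids are axis-aligned in world space, 0-based, with ``origin``
  the world coordinate of the *center* of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "GeometryError",
    "Grid3D",
    "BeamGeometry",
    "Ray",
    "world_to_beam",
    "beam_to_world",
    "project_point",
    "project_vector",
    "pixel_ray",
]


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated (e.g. a point at or
    behind the radiation source where the divergent projection is undefined)."""


def _as_vec3(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


@dataclass(frozen=True)
class Grid3D:
    """A regular, axis-aligned voxel lattice in world coordinates.

    ``origin`` is the world position (mm) of the center of voxel (0, 0, 0);
    the physical bounding box extends half a voxel beyond the first and last
    centers on every axis.
    """

    shape: tuple
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("Grid3D fields must have 3 components")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- derived geometry -------------------------------------------------
    @property
    def bbox_min(self) -> np.ndarray:
        """Lower corner of the physical bounding box (voxel boundaries)."""
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    @property
    def bbox_max(self) -> np.ndarray:
        return (
            np.asarray(self.origin)
            + (np.asarray(self.shape) - 0.5) * np.asarray(self.spacing)
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        centers = np.stack(
            [self.origin[a] + idx[a] * self.spacing[a] for a in range(3)], axis=-1
        )
        return centers

    def index_to_world(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, points) -> np.ndarray:
        """Fractional voxel indices of world points (no bounds check)."""
        points = _as_vec3(points, "points")
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains(self, points) -> np.ndarray:
        """True where points fall inside the physical bounding box."""
        points = _as_vec3(points, "points")
        lo, hi = self.bbox_min, self.bbox_max
        return np.all((points >= lo) & (points <= hi), axis=-1)


@dataclass(frozen=True)
class BeamGeometry:
    """Source/isocenter geometry of one beam in IEC-61217 gantry coordinates.

    Parameters
    ----------
    gantry_angle : float
        Gantry angle in degrees, in ``[0, 360)``.
    sad : float
        Source-axis distance in mm (> 0).
    isocenter : array-like of 3 floats
        World coordinates of the isocenter, mm.
    collimator_angle : float
        Must be 0 in this version; the field exists for interface stability.
    beam_id : str
        Free-text label.
    """

    gantry_angle: float
    sad: float
    isocenter: tuple
    collimator_angle: float = 0.0
    beam_id: str = "beam"

    def __post_init__(self):
        if not np.isfinite(self.sad) or self.sad <= 0:
            raise ValueError(f"SAD must be > 0, got {self.sad}")
        if not (0.0 <= float(self.gantry_angle) % 360.0 < 360.0):
            raise ValueError(f"bad gantry angle {self.gantry_angle}")
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)
        object.__setattr__(self, "sad", float(self.sad))
        iso = tuple(float(c) for c in np.asarray(self.isocenter, dtype=float))
        if len(iso) != 3:
            raise ValueError("isocenter must have 3 components")
        object.__setattr__(self, "isocenter", iso)
        if float(self.collimator_angle) != 0.0:
            raise ValueError("collimator rotation is not supported (must be 0)")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are the beam-frame axes in world coordinates.

        ``p_beam = rotation @ (p_world - isocenter)``.
        """
        t = np.deg2rad(self.gantry_angle)
        zb = np.array([np.sin(t), np.cos(t), 0.0])   # isocenter -> source
        xb = np.array([-np.cos(t), np.sin(t), 0.0])
        yb = np.array([0.0, 0.0, 1.0])
        return np.stack([xb, yb, zb])

    @property
    def source_position(self) -> np.ndarray:
        """World coordinates of the beam source."""
        return np.asarray(self.isocenter) + self.sad * self.rotation[2]

    def to_dict(self) -> dict:
        return {
            "beam_id": self.beam_id,
            "gantry_angle_deg": self.gantry_angle,
            "collimator_angle_deg": self.collimator_angle,
            "SAD_mm": self.sad,
            "isocenter_mm": list(self.isocenter),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamGeometry":
        return cls(
            gantry_angle=d["gantry_angle_deg"],
            sad=d["SAD_mm"],
            isocenter=d["isocenter_mm"],
            collimator_angle=d.get("collimator_angle_deg", 0.0),
            beam_id=d.get("beam_id", "beam"),
        )


@dataclass(frozen=True)
class Ray:
    """A ray from the beam source through one fluence-plane pixel.

    ``source`` and unit ``direction`` are world coordinates (mm);
    ``pixel_index`` records which plane pixel the ray belongs to.
    """

    source: tuple
    direction: tuple
    pixel_index: tuple = None

    def __post_init__(self):
        src = tuple(float(c) for c in np.asarray(self.source, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"ray direction must be unit length, |d| = {n}")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "direction", tuple(float(c) for c in d))
        if self.pixel_index is not None:
            object.__setattr__(
                self, "pixel_index", tuple(int(i) for i in self.pixel_index)
            )

    def point_at(self, t) -> np.ndarray:
        """World point at parameter ``t`` (mm along the ray)."""
        t = np.asarray(t, dtype=float)
        return np.asarray(self.source) + t[..., None] * np.asarray(self.direction)


# ---------------------------------------------------------------------------
# operations


def world_to_beam(point, beam: BeamGeometry) -> np.ndarray:
    """Express world point(s) in the beam's gantry frame (origin = isocenter,
    +z toward the source).  Accepts shape ``(..., 3)``."""
    p = _as_vec3(point, "point")
    return (p - np.asarray(beam.isocenter)) @ beam.rotation.T


def beam_to_world(point, beam: BeamGeometry) -> np.ndarray:
    """Inverse of :func:`world_to_beam`."""
    p = _as_vec3(point, "point")
    return p @ beam.rotation + np.asarray(beam.isocenter)


def project_point(p, sad: float) -> np.ndarray:
    """Divergent projection of beam-frame point(s) onto the isocenter plane.

    A point ``(x, y, z)`` (beam frame, ``z`` toward the source) maps to
    ``(x * SAD / (SAD - z), y * SAD / (SAD - z), 0)``: the intersection of
    the source->point ray with the plane ``z = 0``.  Points with ``z = 0``
    are fixed; points on the source side (``0 < z < SAD``) are magnified.

    Raises
    ------
    GeometryError
        If any point has ``z >= SAD`` (at or behind the source).
    """
    p = _as_vec3(p, "point")
    z = p[..., 2]
    if np.any(z >= sad):
        bad = np.asarray(z)[np.asarray(z) >= sad]
        raise GeometryError(
            f"projection undefined for z >= SAD={sad}: offending z={bad.flat[0]:.6g}"
        )
    m = sad / (sad - z)
    out = np.zeros_like(p)
    out[..., 0] = p[..., 0] * m
    out[..., 1] = p[..., 1] * m
    return out


def project_vector(start, end, sad: float) -> np.ndarray:
    """Project a displacement (both endpoints in the beam frame) onto the
    isocenter plane and return the in-plane difference ``end' - start'``.

    This is the projected deformation vector: each endpoint is carried along
    its own source ray to the plane, so a displacement at depth ``z`` is
    magnified by ``SAD / (SAD - z)``.
    """
    s = project_point(start, sad)
    e = project_point(end, sad)
    return (e - s)[..., :2]


def pixel_ray(pixel_center, sad: float, beam: BeamGeometry) -> Ray:
    """The ray from the beam source through a point on the isocenter plane.

    ``pixel_center`` is the 2-vector (mm) of the plane point in the beam
    frame; the returned :class:`Ray` is expressed in world coordinates.
    """
    px = np.asarray(pixel_center, dtype=float)
    if px.shape != (2,):
        raise ValueError("pixel_center must be a 2-vector")
    src_b = np.array([0.0, 0.0, sad])
    tgt_b = np.array([px[0], px[1], 0.0])
    src_w = beam_to_world(src_b, beam)
    tgt_w = beam_to_world(tgt_b, beam)
    d = tgt_w - src_w
    d /= np.linalg.norm(d)
    return Ray(source=src_w, direction=d)
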