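"""Step-and-shoot MLC leaf sequencing of a fluence map, and its inverse.

The sequencer quantizes the map to a uniform number of intensity levels and
decomposes it with the classical unidirectional sweep: per leaf row, the
multi-unit exposure window of each pixel is scheduled so both leaves move
monotonically left to right, which reproduces the quantized profile exactly
and delivers the minimal total MU for a sweep (the sum of positive
gradients, maximised over rows).  Leaf rows run along the plane's first
axis (leaves travel in x), stacked along y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bev import PlaneGrid
from .fluence import FluenceGrid

__all__ = [
    "Segment",
    "AperturePlan",
    "fit_jaws",
    "sequence_fluence",
    "reconstruct_fluence",
    "quantize_fluence",
]

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """One static MLC aperture: per-leaf-pair left/right positions (mm at
    isocenter) and a non-negative MU-equivalent weight."""

    left: np.ndarray
    right: np.ndarray
    weight: float

    def __post_init__(self):
        l = np.asarray(self.left, dtype=float)
        r = np.asarray(self.right, dtype=float)
        if l.shape != r.shape:
            raise ValueError("left/right leaf banks must have equal length")
        if np.any(l > r + _EPS):
            raise ValueError("left leaf beyond right leaf")
        if self.weight < 0:
            raise ValueError("segment weight must be >= 0")
        object.__setattr__(self, "left", l)
        object.__setattr__(self, "right", r)
        object.__setattr__(self, "weight", float(self.weight))


@dataclass(frozen=True)
class AperturePlan:
    """Jaws plus a weighted sequence of MLC segments realising a fluence map.

    ``jaws`` is ``(x1, x2, y1, y2)`` mm at the isocenter; ``leaf_y0`` is the
    lower edge (mm) of leaf pair 0, so pair ``i`` spans
    ``[leaf_y0 + i * leaf_width, leaf_y0 + (i + 1) * leaf_width)``.
    ``plane`` records the fluence grid the plan was sequenced on.
    """

    beam_id: str
    jaws: tuple
    leaf_width: float
    leaf_y0: float
    segments: tuple
    plane: PlaneGrid = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        x1, x2, y1, y2 = (float(v) for v in self.jaws)
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate jaws {self.jaws}")
        if not self.segments:
            raise ValueError("plan needs at least one segment")
        object.__setattr__(self, "jaws", (x1, x2, y1, y2))
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "leaf_width", float(self.leaf_width))
        object.__setattr__(self, "leaf_y0", float(self.leaf_y0))

    @property
    def total_mu(self) -> float:
        return float(sum(s.weight for s in self.segments))

    def to_dict(self) -> dict:
        return {
            "beam_id": self.beam_id,
            "jaws_mm": list(self.jaws),
            "leaf_width_mm": self.leaf_width,
            "leaf_y0_mm": self.leaf_y0,
            "segments": [
                {"left_positions_mm": s.left.tolist(),
                 "right_positions_mm": s.right.tolist(),
                 "weight": s.weight}
                for s in self.segments
            ],
            "plane": None if self.plane is None else {
                "shape": list(self.plane.shape),
                "spacing_mm": list(self.plane.spacing),
                "origin_mm": list(self.plane.origin),
            },
            "flags": dict(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AperturePlan":
        plane = None
        if d.get("plane"):
            p = d["plane"]
            plane = PlaneGrid(tuple(p["shape"]), tuple(p["spacing_mm"]),
                              tuple(p["origin_mm"]))
        return cls(
            beam_id=d["beam_id"],
            jaws=tuple(d["jaws_mm"]),
            leaf_width=d["leaf_width_mm"],
            leaf_y0=d["leaf_y0_mm"],
            segments=tuple(
                Segment(np.array(s["left_positions_mm"]),
                        np.array(s["right_positions_mm"]), s["weight"])
                for s in d["segments"]
            ),
            plane=plane,
            flags=d.get("flags", {}),
        )


def fit_jaws(f: FluenceGrid, margin: float = 0.0,
             open_threshold_rel: float = 0.01) -> tuple:
    """Tightest jaw rectangle containing every open pixel, expanded by
    ``margin`` mm and snapped outward to pixel boundaries."""
    I = f.intensity
    mx = I.max()
    if mx <= 0:
        raise ValueError("cannot fit jaws to an all-zero fluence")
    open_px = I > open_threshold_rel * mx
    xs, ys = np.nonzero(open_px)
    ox, oy = f.plane.origin
    dx, dy = f.plane.spacing
    x1 = ox + xs.min() * dx - dx / 2 - margin
    x2 = ox + xs.max() * dx + dx / 2 + margin
    y1 = oy + ys.min() * dy - dy / 2 - margin
    y2 = oy + ys.max() * dy + dy / 2 + margin
    return (x1, x2, y1, y2)


def quantize_fluence(f: FluenceGrid, levels: int) -> np.ndarray:
    """Round the map onto ``levels`` uniform intensity levels (level width
    ``max / levels``); returns the quantized map in original units."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    mx = f.intensity.max()
    if mx <= 0:
        raise ValueError("cannot quantize an all-zero fluence")
    step = mx / levels
    return np.round(f.intensity / step) * step


def _sweep_schedule(q: np.ndarray):
    """Exposure windows [s_j, e_j) (in quantization units) for one row under
    a unidirectional sweep; both leaf trajectories are monotone and the
    exposed set at any instant is a single interval."""
    s = np.zeros(len(q), dtype=int)
    for j in range(1, len(q)):
        s[j] = s[j - 1] + max(0, q[j - 1] - q[j])
    e = s + q
    return s, e


def sequence_fluence(f: FluenceGrid, leaf_width: float = None,
                     levels: int = 10) -> AperturePlan:
    """Decompose a fluence map into step-and-shoot MLC segments.

    The map is quantized to ``levels`` uniform levels; rows are grouped into
    leaf pairs of width ``leaf_width`` (default: one fluence row; must be an
    integer multiple of the row spacing), each pair's profile being the
    maximum over its rows; the synchronized unidirectional sweep then emits
    one segment per MU unit, merging consecutive identical apertures.
    Reconstruction of the result reproduces the quantized map exactly
    (leaf pairs wider than one row reproduce the row-maximum profile).
    """
    dx, dy = f.plane.spacing
    if leaf_width is None:
        leaf_width = dy
    ratio = leaf_width / dy
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ValueError(
            f"leaf_width {leaf_width} must be an integer multiple of the row spacing {dy}"
        )
    mx = f.intensity.max()
    if mx <= 0:
        raise ValueError("cannot sequence an all-zero fluence")
    step = mx / levels
    q = np.round(f.intensity / step).astype(int)  # [nx, ny] in level units

    nx, ny = q.shape
    n_pairs = int(np.ceil(ny / k))
    profiles = np.zeros((n_pairs, nx), dtype=int)
    for p in range(n_pairs):
        profiles[p] = q[:, p * k:(p + 1) * k].max(axis=1)

    jaws = fit_jaws(f, margin=0.0)
    x1 = jaws[0]
    ox = f.plane.origin[0]
    sched = [_sweep_schedule(profiles[p]) for p in range(n_pairs)]
    total_units = max((int(e.max()) if len(e) else 0) for _, e in sched)

    raw = []
    for t in range(total_units):
        left = np.full(n_pairs, x1)
        right = np.full(n_pairs, x1)
        for p, (s, e) in enumerate(sched):
            open_j = np.nonzero((s <= t) & (t < e))[0]
            if len(open_j):
                left[p] = ox + open_j[0] * dx - dx / 2
                right[p] = ox + open_j[-1] * dx + dx / 2
        raw.append((left, right))
    segments = []
    for left, right in raw:
        if segments and np.array_equal(segments[-1].left, left) \
                and np.array_equal(segments[-1].right, right):
            segments[-1] = Segment(left, right, segments[-1].weight + step)
        else:
            segments.append(Segment(left, right, step))

    flags = {}
    if total_units > levels:
        flags["segments_exceed_levels"] = True  # multimodal rows
    plan = AperturePlan(
        beam_id=f.beam_id, jaws=jaws, leaf_width=leaf_width,
        leaf_y0=f.plane.origin[1] - dy / 2, segments=tuple(segments),
        plane=f.plane, flags=flags,
    )
    log.debug("sequenced %s: %d segments, total MU %.4g", f.beam_id,
              len(segments), plan.total_mu)
    return plan


def reconstruct_fluence(plan: AperturePlan, plane: PlaneGrid) -> FluenceGrid:
    """Sum of ``weight x open-aperture indicator`` over segments, evaluated
    at pixel centers (a pixel is open when its center lies strictly between
    the leaves and inside the jaws)."""
    centers = plane.pixel_centers()
    x = centers[..., 0]
    y = centers[..., 1]
    x1, x2, y1, y2 = plan.jaws
    in_jaws = (x > x1 + _EPS) & (x < x2 - _EPS) & (y > y1 + _EPS) & (y < y2 - _EPS)
    pair = np.floor((y - plan.leaf_y0) / plan.leaf_width).astype(int)
    n_pairs = len(plan.segments[0].left)
    valid = (pair >= 0) & (pair < n_pairs)
    pair_c = np.clip(pair, 0, n_pairs - 1)
    out = np.zeros(plane.shape)
    for seg in plan.segments:
        open_px = valid & in_jaws \
            & (x > seg.left[pair_c] + _EPS) & (x < seg.right[pair_c] - _EPS)
        out[open_px] += seg.weight
    return FluenceGrid(plane=plane, intensity=out, beam_id=plan.beam_id)
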