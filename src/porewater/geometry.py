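"""Channel geometry: per-frame polyhedron, enveloping cylinder, cell grid.

The channel interior is defined per frame as the convex hull of the centres
of mass of a configurable set of "corner" residues lining the channel — the
convex hull is the unique volume-maximal polyhedron on fixed vertices.  For
spatially resolved statistics the channel is enveloped by a cylinder anchored
on a median structure and discretised into slices along the axis, concentric
rings, and angular segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .frames import FrameSeries

__all__ = [
    "DegenerateGeometryError",
    "PolyhedronFrame",
    "ChannelCylinder",
    "CellIndex",
    "OUTSIDE",
    "build_polyhedron",
    "polyhedron_from_points",
    "point_in_polyhedron",
    "points_in_polyhedron",
    "find_median_frame",
    "build_cylinder",
    "assign_cell",
    "assign_cells",
]


class DegenerateGeometryError(ValueError):
    """Raised when corner points cannot span a 3D polyhedron."""


#: Sentinel returned by :func:`assign_cell` for points outside the cylinder.
OUTSIDE = "outside"


class CellIndex(NamedTuple):
    """1-based (slice, ring, segment) address of a cylinder cell."""

    slice: int
    ring: int
    segment: int


@dataclass
class PolyhedronFrame:
    """Convex polyhedron spanned by corner-residue centres of mass.

    ``volume`` is in nm³ (1 nm³ = 1000 Å³); vertices/facets are in Å.
    """

    vertex_points: np.ndarray  # (n_corners, 3) input corner points, Å
    facets: np.ndarray  # (n_facets, 3) vertex indices of triangulated hull
    volume: float  # nm³
    equations: np.ndarray = field(repr=False)  # (n_facets, 4) outward half-spaces
    corner_labels: tuple = ()

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorised inside-or-on test for ``(..., 3)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts @ self.equations[:, :3].T + self.equations[:, 3]
        return (d <= tol).all(axis=-1)


def polyhedron_from_points(
    points: np.ndarray, labels: Sequence | None = None
) -> PolyhedronFrame:
    """Convex hull of corner points, with volume reported in nm³.

    Raises :class:`DegenerateGeometryError` for fewer than four points or a
    (near-)coplanar set, naming the offending corners.
    """
    pts = np.asarray(points, dtype=float)
    labels = tuple(labels) if labels is not None else tuple(range(len(pts)))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("corner points must have shape (n, 3)")
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"need at least 4 corner points to span a polyhedron, got {len(pts)} "
            f"(corners: {labels})"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"corner points are degenerate (coplanar or collinear); corners: {labels}"
        ) from exc
    return PolyhedronFrame(
        vertex_points=pts,
        facets=hull.simplices.copy(),
        volume=hull.volume / 1000.0,
        equations=hull.equations.copy(),
        corner_labels=labels,
    )


def build_polyhedron(
    frames: FrameSeries, frame: int, corner_residues: Sequence[int]
) -> PolyhedronFrame:
    """Channel polyhedron of one frame from corner-residue centres of mass."""
    corners = np.array([frames.residue_com(r, frame) for r in corner_residues])
    return polyhedron_from_points(corners, labels=corner_residues)


def point_in_polyhedron(
    point: np.ndarray, poly: PolyhedronFrame, tol: float = 1e-9
) -> bool:
    """True iff the point satisfies every facet half-space (boundary counts)."""
    return bool(poly.contains(np.asarray(point))[0])


def points_in_polyhedron(
    points: np.ndarray, poly: PolyhedronFrame, tol: float = 1e-9
) -> np.ndarray:
    return poly.contains(points, tol=tol)


def find_median_frame(
    frames: FrameSeries, window: tuple[int, int] | None = None
) -> int:
    """Index of the frame closest (RMSD, no refitting) to the mean structure.

    ``window`` is a half-open frame range ``(start, stop)``; the returned
    index is absolute.  Ties break to the lowest index.
    """
    start, stop = window if window is not None else (0, frames.n_frames)
    sub = frames.coords[start:stop]
    if sub.shape[0] == 0:
        raise ValueError(f"empty frame window {window}")
    mean = sub.mean(axis=0)
    rmsd = np.sqrt(((sub - mean) ** 2).sum(axis=(1, 2)) / frames.n_atoms)
    return start + int(np.argmin(rmsd))  # argmin takes first minimum: lowest index


@dataclass
class ChannelCylinder:
    """Axis-aligned analysis cylinder with a slice/ring/segment partition.

    The axis runs from ``axis_base`` (channel entrance, negative heights) to
    ``axis_top`` (positive heights); the height origin is the axis midpoint.
    Slices cover the central ``n_slices * slice_thickness`` of the axis.
    """

    axis_base: np.ndarray
    axis_top: np.ndarray
    radius: float = 9.5
    n_slices: int = 15
    slice_thickness: float = 2.0
    ring_bounds: tuple[float, ...] = (1.0, 3.5, 5.0, 9.5)
    segment_width: float = 30.0

    def __post_init__(self) -> None:
        self.axis_base = np.asarray(self.axis_base, dtype=float)
        self.axis_top = np.asarray(self.axis_top, dtype=float)
        axis = self.axis_top - self.axis_base
        length = float(np.linalg.norm(axis))
        if length <= 0:
            raise ValueError("cylinder axis has zero length")
        if self.n_slices * self.slice_thickness > length + 1e-9:
            raise ValueError(
                f"slice coverage {self.n_slices * self.slice_thickness} Å exceeds "
                f"axis length {length:.3f} Å"
            )
        bounds = tuple(float(b) for b in self.ring_bounds)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("ring bounds must be strictly increasing")
        if abs(bounds[-1] - self.radius) > 1e-9:
            raise ValueError("last ring bound must equal the cylinder radius")
        if abs(360.0 / self.segment_width - round(360.0 / self.segment_width)) > 1e-9:
            raise ValueError("segment width must divide 360 degrees")
        self.ring_bounds = bounds
        self._unit = axis / length
        self._centre = 0.5 * (self.axis_base + self.axis_top)
        # Deterministic in-plane basis for azimuth/segment assignment.
        ref = np.eye(3)[int(np.argmin(np.abs(self._unit)))]
        e1 = ref - np.dot(ref, self._unit) * self._unit
        self._e1 = e1 / np.linalg.norm(e1)
        self._e2 = np.cross(self._unit, self._e1)

    @property
    def axis_unit(self) -> np.ndarray:
        return self._unit

    @property
    def centre(self) -> np.ndarray:
        return self._centre

    @property
    def half_height(self) -> float:
        """Half of the sliced height (slices span ``[-half_height, half_height]``)."""
        return 0.5 * self.n_slices * self.slice_thickness

    @property
    def n_rings(self) -> int:
        return len(self.ring_bounds)

    @property
    def n_segments(self) -> int:
        return int(round(360.0 / self.segment_width))

    @property
    def slice_centres(self) -> np.ndarray:
        """Signed height of each slice centre, Å."""
        h = self.half_height
        return -h + self.slice_thickness * (np.arange(self.n_slices) + 0.5)

    # -- coordinate helpers ---------------------------------------------------

    def heights(self, points: np.ndarray) -> np.ndarray:
        """Signed axial height(s) of point(s) relative to the axis midpoint."""
        return (np.asarray(points, dtype=float) - self._centre) @ self._unit

    def cylindrical(self, points: np.ndarray):
        """(height, radial distance, azimuth in [0, 360)) for ``(..., 3)`` points."""
        rel = np.asarray(points, dtype=float) - self._centre
        h = rel @ self._unit
        x = rel @ self._e1
        y = rel @ self._e2
        r = np.hypot(x, y)
        az = np.degrees(np.arctan2(y, x)) % 360.0
        return h, r, az


def build_cylinder(
    frames: FrameSeries,
    median_frame: int,
    bottom_residues: Sequence[int],
    top_residues: Sequence[int],
    *,
    radius: float = 9.5,
    n_slices: int = 15,
    slice_thickness: float = 2.0,
    ring_bounds: tuple[float, ...] = (1.0, 3.5, 5.0, 9.5),
    segment_width: float = 30.0,
    elongation: float = 0.10,
    ca_name: str = "CA",
) -> ChannelCylinder:
    """Cylinder from Cα centres of mass of the lowermost/uppermost residues.

    The bottom→top axis is elongated by ``elongation`` (split symmetrically,
    5% beyond each end by default) to cover the channel mouth regions, then
    capped so the sliced height never exceeds ``n_slices * slice_thickness``.
    """

    def ca_com(residues: Sequence[int]) -> np.ndarray:
        pts = []
        for r in residues:
            idx = np.flatnonzero((frames.resids == r) & (frames.names == ca_name))
            if idx.size == 0:
                raise KeyError(f"residue {r} has no {ca_name!r} atom")
            pts.append(frames.coords[median_frame, idx, :].mean(axis=0))
        return np.mean(pts, axis=0)

    bottom = ca_com(bottom_residues)
    top = ca_com(top_residues)
    axis = top - bottom
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("zero-length cylinder axis (bottom and top coincide)")
    unit = axis / length
    half_elong = 0.5 * elongation * length
    base = bottom - half_elong * unit
    tip = top + half_elong * unit
    coverage = n_slices * slice_thickness
    total = length * (1.0 + elongation)
    if abs(total - coverage) / coverage > 1e-12:
        # cap (or pad) symmetrically about the midpoint so the axis carries
        # exactly the sliced height n_slices × slice_thickness
        centre = 0.5 * (base + tip)
        base = centre - 0.5 * coverage * unit
        tip = centre + 0.5 * coverage * unit
    return ChannelCylinder(
        axis_base=base,
        axis_top=tip,
        radius=radius,
        n_slices=n_slices,
        slice_thickness=slice_thickness,
        ring_bounds=ring_bounds,
        segment_width=segment_width,
    )


def assign_cells(points: np.ndarray, cyl: ChannelCylinder):
    """Vectorised cell assignment.

    Returns ``(slices, rings, segments, inside)`` arrays; entries of the
    first three are 0 where ``inside`` is False.  Slice intervals are
    half-open ``[low, high)`` with the topmost closed; ring bounds are
    inclusive on the upper edge; segments are ``[0°, w)`` etc.; radial
    distance exactly 0 falls in segment 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h, r, az = cyl.cylindrical(pts)
    H = cyl.half_height
    inside = (h >= -H) & (h <= H) & (r <= cyl.radius)
    s = np.floor((h + H) / cyl.slice_thickness).astype(int) + 1
    s = np.where(h >= H, cyl.n_slices, s)  # topmost slice closed
    ring = np.searchsorted(np.asarray(cyl.ring_bounds), r, side="left") + 1
    seg = np.floor(az / cyl.segment_width).astype(int) + 1
    seg = np.where(seg > cyl.n_segments, 1, seg)  # az == 360 wraps
    z = np.zeros_like(s)
    return (
        np.where(inside, s, z),
        np.where(inside, ring, z),
        np.where(inside, seg, z),
        inside,
    )


def assign_cell(point: np.ndarray, cyl: ChannelCylinder):
    """Cell of a single point, or the sentinel :data:`OUTSIDE`."""
    s, ring, seg, inside = assign_cells(np.asarray(point)[None, :], cyl)
    if not inside[0]:
        return OUTSIDE
    return CellIndex(int(s[0]), int(ring[0]), int(seg[0]))
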