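"""Water counting and localisation inside the channel polyhedron and cylinder.

All replica-level statistics follow one convention: quantities are averaged
per replica first, then across replicas, and the standard error of the
replica means (std/√R, ddof=1) is reported.  With a single replica the
standard error is reported as 0 together with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import FrameSeries
from .geometry import ChannelCylinder, PolyhedronFrame, assign_cells

__all__ = [
    "HydrationSummary",
    "OccupancyProfile",
    "track_channel_waters",
    "waters_in_polyhedron_per_frame",
    "waters_in_cylinder_per_frame",
    "hydration_summary",
    "occupancy_profile",
    "cumulative_profile",
    "occupancy_projection",
    "replica_mean_se",
]


def replica_mean_se(values: Sequence[float]) -> tuple[float, float, bool]:
    """Mean of replica values, standard error of that mean, single-replica flag."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 1:
        return float(vals[0]), 0.0, True
    return (
        float(vals.mean()),
        float(vals.std(ddof=1) / np.sqrt(vals.size)),
        False,
    )


@dataclass
class HydrationSummary:
    """Mean channel occupancy and polyhedron volume, replica-averaged."""

    mean_waters_polyhedron: float
    mean_waters_cylinder: float
    mean_volume: float  # nm³
    se_waters_polyhedron: float
    se_waters_cylinder: float
    se_volume: float
    replica_waters_polyhedron: tuple[float, ...]
    replica_waters_cylinder: tuple[float, ...]
    replica_volumes: tuple[float, ...]
    single_replica: bool = False


@dataclass
class OccupancyProfile:
    """Mean water count per cylinder slice, plus residue marker heights."""

    slice_means: np.ndarray  # (n_slices,)
    slice_centres: np.ndarray  # (n_slices,) signed Å
    marker_heights: dict  # residue id -> mean projected height (Å)
    cell_means: np.ndarray | None = None  # (n_slices, n_rings, n_segments)

    @property
    def total(self) -> float:
        """Mean number of waters inside the cylinder."""
        return float(self.slice_means.sum())


def track_channel_waters(
    frames: FrameSeries, polys: Sequence[PolyhedronFrame]
) -> set[int]:
    """Water ids whose oxygen lies inside the channel polyhedron in ≥1 frame.

    This ever-visited set gates which waters enter the cylinder-based
    analyses; it is not itself an occupancy measure.
    """
    if len(polys) != frames.n_frames:
        raise ValueError("need one polyhedron per frame")
    visited = np.zeros(len(frames.water_ids), dtype=bool)
    for t, poly in enumerate(polys):
        visited |= poly.contains(frames.water_oxygens(t))
    return {int(w) for w in frames.water_ids[visited]}


def waters_in_polyhedron_per_frame(
    frames: FrameSeries, polys: Sequence[PolyhedronFrame]
) -> np.ndarray:
    """Instantaneous water count inside the per-frame polyhedron."""
    return np.array(
        [int(poly.contains(frames.water_oxygens(t)).sum()) for t, poly in enumerate(polys)]
    )


def waters_in_cylinder_per_frame(
    frames: FrameSeries, cyl: ChannelCylinder, water_subset: set[int] | None = None
) -> np.ndarray:
    """Instantaneous water count inside the cylinder, optionally restricted."""
    ox = frames.water_oxygens()
    if water_subset is not None:
        keep = np.array([int(w) in water_subset for w in frames.water_ids])
        ox = ox[:, keep, :]
    counts = np.empty(frames.n_frames, dtype=int)
    for t in range(frames.n_frames):
        _, _, _, inside = assign_cells(ox[t], cyl)
        counts[t] = int(inside.sum())
    return counts


def hydration_summary(
    replicas: Sequence[FrameSeries],
    polys_per_replica: Sequence[Sequence[PolyhedronFrame]],
    cyl: ChannelCylinder,
) -> HydrationSummary:
    """Replica-averaged channel water counts and polyhedron volume.

    Counts are instantaneous per-frame occupancies averaged over frames
    within each replica, then over replicas.
    """
    if len(replicas) < 1:
        raise ValueError("need at least one replica")
    rep_poly, rep_cyl, rep_vol = [], [], []
    for frames, polys in zip(replicas, polys_per_replica):
        rep_poly.append(waters_in_polyhedron_per_frame(frames, polys).mean())
        rep_cyl.append(waters_in_cylinder_per_frame(frames, cyl).mean())
        rep_vol.append(float(np.mean([p.volume for p in polys])))
    mp, sp, single = replica_mean_se(rep_poly)
    mc, sc, _ = replica_mean_se(rep_cyl)
    mv, sv, _ = replica_mean_se(rep_vol)
    return HydrationSummary(
        mean_waters_polyhedron=mp,
        mean_waters_cylinder=mc,
        mean_volume=mv,
        se_waters_polyhedron=sp,
        se_waters_cylinder=sc,
        se_volume=sv,
        replica_waters_polyhedron=tuple(rep_poly),
        replica_waters_cylinder=tuple(rep_cyl),
        replica_volumes=tuple(rep_vol),
        single_replica=single,
    )


def occupancy_profile(
    frames: FrameSeries,
    cyl: ChannelCylinder,
    marker_residues: Sequence[int] = (),
    per_cell: bool = False,
) -> OccupancyProfile:
    """Mean per-frame water count per slice (and optionally per cell).

    Marker residues are reported as the mean over frames of their
    centre-of-mass height projected onto the cylinder axis, for annotating
    profile plots.
    """
    ox = frames.water_oxygens()
    slice_counts = np.zeros((frames.n_frames, cyl.n_slices))
    cell_counts = (
        np.zeros((cyl.n_slices, cyl.n_rings, cyl.n_segments)) if per_cell else None
    )
    for t in range(frames.n_frames):
        s, ring, seg, inside = assign_cells(ox[t], cyl)
        s_in = s[inside]
        slice_counts[t] = np.bincount(s_in - 1, minlength=cyl.n_slices)
        if per_cell:
            np.add.at(cell_counts, (s_in - 1, ring[inside] - 1, seg[inside] - 1), 1.0)
    markers = {
        int(r): float(cyl.heights(frames.residue_com_series(r)).mean())
        for r in marker_residues
    }
    return OccupancyProfile(
        slice_means=slice_counts.mean(axis=0),
        slice_centres=cyl.slice_centres,
        marker_heights=markers,
        cell_means=None if cell_counts is None else cell_counts / frames.n_frames,
    )


def cumulative_profile(profile: OccupancyProfile) -> np.ndarray:
    """Mean water count accumulated from the bottom slice upward."""
    return np.cumsum(profile.slice_means)


def occupancy_projection(
    frames: FrameSeries,
    cyl: ChannelCylinder,
    n_height_bins: int = 60,
    n_plane_bins: int = 38,
    azimuth: float = 0.0,
):
    """2D water occupancy histogram in cylinder coordinates, per frame.

    Water oxygens inside the cylinder are binned on (height, signed in-plane
    coordinate along the direction given by ``azimuth`` in degrees) and the
    counts divided by the frame count, so the histogram total equals the
    mean in-cylinder water count.

    Returns ``(hist, height_edges, plane_edges, marker_positions)`` where
    ``marker_positions`` must be requested via :func:`occupancy_profile`.
    """
    ox = frames.water_oxygens()
    a = np.radians(azimuth)
    direction = np.cos(a) * cyl._e1 + np.sin(a) * cyl._e2
    H, R = cyl.half_height, cyl.radius
    height_edges = np.linspace(-H, H, n_height_bins + 1)
    plane_edges = np.linspace(-R, R, n_plane_bins + 1)
    hist = np.zeros((n_height_bins, n_plane_bins))
    for t in range(frames.n_frames):
        pts = ox[t]
        _, _, _, inside = assign_cells(pts, cyl)
        rel = pts[inside] - cyl.centre
        h = rel @ cyl.axis_unit
        p = rel @ direction
        hh, _, _ = np.histogram2d(h, p, bins=(height_edges, plane_edges))
        hist += hh
    return hist / frames.n_frames, height_edges, plane_edges
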