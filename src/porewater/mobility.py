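"""Slice-resolved water diffusion from single-lag mean squared displacement.

For each slice *s* of the analysis cylinder the diffusion coefficient is

    D_s = MSD_s / (6 τ),   MSD_s = (1/N_s) Σ |x_w(t) − x_w(t−τ)|²,

where the sum runs over every (water, frame-pair) observation whose water
was inside the cylinder at the start frame, the squared displacement is
credited to the slice occupied at the start frame, and N_s counts the
observations.  Every consecutive frame pair serves as a time origin.
Slices empty in more than 95% of frames are reported as D_s = 0 with an
"insufficient data" flag.  Replica averages are weighted by N_s and their
spread is the N_s-weighted standard deviation of the replica values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import FrameSeries
from .geometry import ChannelCylinder, assign_cells

__all__ = [
    "SliceMSD",
    "DiffusionProfile",
    "slice_msd",
    "slice_occupancy_fraction",
    "diffusion_profile",
    "decompose_msd",
]


@dataclass
class SliceMSD:
    """Per-slice accumulated squared displacements for one replica."""

    sq_sums: np.ndarray  # (n_slices,) Σ|Δx|² per start slice, Ų
    components: np.ndarray  # (n_slices, 3) axial/radial/angular partial sums
    ns: np.ndarray  # (n_slices,) observation counts
    lag: float  # ps


@dataclass
class DiffusionProfile:
    """Slice-resolved diffusion coefficients with replica weighting."""

    ds: np.ndarray  # (n_slices,) replica-weighted Ds, Ų/ps
    spread: np.ndarray  # (n_slices,) Ns-weighted std of replica Ds
    ns: np.ndarray  # (n_slices,) total observations
    components: np.ndarray  # (n_slices, 3) weighted directional MSD fractions of Ds
    insufficient: np.ndarray  # (n_slices,) bool flag (95%-empty rule)
    slice_centres: np.ndarray
    replica_ds: np.ndarray  # (n_replicas, n_slices)


def decompose_msd(
    start: np.ndarray, end: np.ndarray, cyl: ChannelCylinder
) -> tuple[float, float, float]:
    """Split a squared displacement into axial, radial and angular parts.

    The displacement is resolved in the orthonormal frame anchored at the
    start point: the cylinder axis, the radial unit vector, and the residual
    (angular) direction; the three squared components sum to |Δx|² exactly.
    A start point on the axis has no defined radial direction; its in-plane
    motion is then wholly angular.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    disp = end - start
    u = cyl.axis_unit
    axial = float(np.dot(disp, u)) ** 2
    rel = start - cyl.centre
    perp = rel - np.dot(rel, u) * u
    norm = np.linalg.norm(perp)
    radial = float(np.dot(disp, perp / norm)) ** 2 if norm > 1e-12 else 0.0
    total = float(np.dot(disp, disp))
    return axial, radial, total - axial - radial


def slice_msd(frames: FrameSeries, cyl: ChannelCylinder, lag: float | None = None) -> SliceMSD:
    """Accumulate per-slice squared displacements at a single lag.

    ``lag`` (ps) must be an integer multiple of the frame spacing; it
    defaults to one frame.  Waters outside the cylinder at the start frame
    of a pair contribute nothing, even if inside at the end frame.
    """
    dt = frames.dt
    lag = dt if lag is None else float(lag)
    k = lag / dt
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(f"lag {lag} ps is not a positive multiple of dt = {dt} ps")
    k = int(round(k))
    ox = frames.water_oxygens()  # (n_frames, n_w, 3)
    n_slices = cyl.n_slices
    sq_sums = np.zeros(n_slices)
    comps = np.zeros((n_slices, 3))
    ns = np.zeros(n_slices, dtype=int)
    u = cyl.axis_unit
    for t0 in range(frames.n_frames - k):
        p0 = ox[t0]
        s, _, _, inside = assign_cells(p0, cyl)
        if not inside.any():
            continue
        p0 = p0[inside]
        disp = ox[t0 + k][inside] - p0
        sl = s[inside] - 1
        total = (disp**2).sum(axis=1)
        axial = (disp @ u) ** 2
        rel = p0 - cyl.centre
        perp = rel - np.outer(rel @ u, u)
        norm = np.linalg.norm(perp, axis=1)
        rhat = np.where(norm[:, None] > 1e-12, perp / np.maximum(norm, 1e-300)[:, None], 0.0)
        radial = (disp * rhat).sum(axis=1) ** 2
        np.add.at(sq_sums, sl, total)
        np.add.at(comps, sl, np.column_stack([axial, radial, total - axial - radial]))
        np.add.at(ns, sl, 1)
    return SliceMSD(sq_sums=sq_sums, components=comps, ns=ns, lag=lag)


def slice_occupancy_fraction(frames: FrameSeries, cyl: ChannelCylinder) -> np.ndarray:
    """Fraction of frames in which each slice holds at least one water."""
    ox = frames.water_oxygens()
    occupied = np.zeros((frames.n_frames, cyl.n_slices), dtype=bool)
    for t in range(frames.n_frames):
        s, _, _, inside = assign_cells(ox[t], cyl)
        occupied[t, s[inside] - 1] = True
    return occupied.mean(axis=0)


def diffusion_profile(
    msds: Sequence[SliceMSD],
    occupancies: Sequence[np.ndarray],
    cyl: ChannelCylinder,
    min_occupancy: float = 0.05,
) -> DiffusionProfile:
    """Combine per-replica MSD sums into a weighted diffusion profile.

    The 95%-empty rule is applied per replica: a replica's slice occupied in
    fewer than ``min_occupancy`` of its frames contributes Ds = 0 with zero
    weight.  Replica values are averaged with weights N_s.
    """
    if len(msds) != len(occupancies):
        raise ValueError("need one occupancy vector per replica")
    lag = msds[0].lag
    if lag <= 0:
        raise ValueError("lag must be positive")
    n_slices = cyl.n_slices
    n_rep = len(msds)
    rep_ds = np.zeros((n_rep, n_slices))
    rep_comp = np.zeros((n_rep, n_slices, 3))
    weights = np.zeros((n_rep, n_slices))
    sufficient = np.zeros((n_rep, n_slices), dtype=bool)
    for i, (m, occ) in enumerate(zip(msds, occupancies)):
        if abs(m.lag - lag) > 1e-9:
            raise ValueError("replicas must use the same lag")
        ok = (np.asarray(occ) >= min_occupancy) & (m.ns > 0)
        sufficient[i] = ok
        with np.errstate(invalid="ignore", divide="ignore"):
            ds = np.where(ok, m.sq_sums / np.maximum(m.ns, 1) / (6.0 * lag), 0.0)
            comp = np.where(
                ok[:, None], m.components / np.maximum(m.ns, 1)[:, None] / (6.0 * lag), 0.0
            )
        rep_ds[i] = ds
        rep_comp[i] = comp
        weights[i] = np.where(ok, m.ns, 0)
    wsum = weights.sum(axis=0)
    any_ok = wsum > 0
    w = np.where(any_ok, wsum, 1.0)
    ds_mean = (weights * rep_ds).sum(axis=0) / w
    comp_mean = (weights[:, :, None] * rep_comp).sum(axis=0) / w[:, None]
    var = (weights * (rep_ds - ds_mean) ** 2).sum(axis=0) / w
    return DiffusionProfile(
        ds=np.where(any_ok, ds_mean, 0.0),
        spread=np.where(any_ok, np.sqrt(var), 0.0),
        ns=np.array([m.ns for m in msds]).sum(axis=0),
        components=comp_mean,
        insufficient=~any_ok,
        slice_centres=cyl.slice_centres,
        replica_ds=rep_ds,
    )
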