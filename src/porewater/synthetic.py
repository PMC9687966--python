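"""Synthetic channel trajectories with known ground truth.

The generator emulates, at the analysis level, what a solvated channel MD
run hands to the pipeline: a static channel-shaped scaffold of pseudo
corner residues, water molecules performing confined Brownian motion, an
optional hydronium-like particle at a fixed height, and donor–acceptor
pairs whose bonded/unbonded geometry follows a two-state Markov process
with prescribed dwell times.  Every statistical property the analysis
modules estimate (hull volume, occupancy, diffusion coefficient, bond
survival) therefore has a known generating value.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from the spec, so a given spec reproduces bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSeries

__all__ = [
    "SyntheticChannelSpec",
    "generate_scaffold",
    "simulate",
    "simulate_waters",
    "simulate_hbond_events",
    "markov_h",
    "reflect_into_cylinder",
]

# Rigid water hydrogen offsets relative to the oxygen (Å); orientation is
# arbitrary but fixed — the analyses read only the oxygen position, and the
# bond-event generator controls its own geometry explicitly.
_WATER_H1 = np.array([0.9572, 0.0, 0.0])
_WATER_H2 = np.array([-0.2399, 0.9266, 0.0])
_H3O_H = (
    np.array([0.98, 0.0, 0.0]),
    np.array([-0.49, 0.85, 0.0]),
    np.array([-0.49, -0.85, 0.0]),
)

# Residue id blocks of the generated system.
_CORNER_BASE = 1
_MARKER_BASE = 101
_HYDRONIUM_ID = 200
_DONOR_BASE = 301
_PARTNER_BASE = 401
_WATER_BASE = 1001


@dataclass
class SyntheticChannelSpec:
    """Parameters of a synthetic channel system.

    The scaffold is a box (default) or triangular prism of length
    ``channel_length`` along z whose caps carry single-atom corner
    pseudo-residues; waters diffuse with coefficient ``diffusion`` inside a
    reflecting cylinder of radius ``confinement_radius`` spanning the
    channel.  ``hbond_pairs`` lists (bonded dwell, unbonded dwell) mean
    times in ps for serine-like donor / water pairs toggling between a
    bonded geometry (2.8 Å, collinear) and an unbonded one (5 Å).
    """

    channel_length: float = 30.0  # Å along z
    box_half_width: float = 5.0  # Å; corners at ±half_width
    shape: str = "box"  # "box" or "prism"
    confinement_radius: float = 8.5  # Å
    n_waters: int = 20
    diffusion: float = 0.2  # Ų/ps
    dt: float = 2.0  # ps
    n_frames: int = 500
    hydronium_height: float | None = None  # Å, signed height from channel midpoint
    marker_heights: tuple[float, ...] = ()  # signed heights from channel midpoint
    hbond_pairs: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diffusion < 0 or self.dt <= 0 or self.n_frames < 1:
            raise ValueError("need diffusion ≥ 0, dt > 0, n_frames ≥ 1")
        if any(d <= 0 for pair in self.hbond_pairs for d in pair):
            raise ValueError("Markov dwell times must be positive")
        if self.shape not in ("box", "prism"):
            raise ValueError(f"unknown scaffold shape {self.shape!r}")

    # -- derived geometry -----------------------------------------------------

    @property
    def z_mid(self) -> float:
        return 0.5 * self.channel_length

    def corner_xy(self) -> np.ndarray:
        w = self.box_half_width
        if self.shape == "box":
            return np.array([(-w, -w), (w, -w), (w, w), (-w, w)])
        return np.array([(-w, -w), (w, -w), (-w, w)])

    @property
    def corner_ids(self) -> tuple[int, ...]:
        n = len(self.corner_xy())
        return tuple(range(_CORNER_BASE, _CORNER_BASE + 2 * n))

    @property
    def bottom_ids(self) -> tuple[int, ...]:
        n = len(self.corner_xy())
        return self.corner_ids[:n]

    @property
    def top_ids(self) -> tuple[int, ...]:
        n = len(self.corner_xy())
        return self.corner_ids[n:]

    @property
    def marker_ids(self) -> tuple[int, ...]:
        return tuple(range(_MARKER_BASE, _MARKER_BASE + len(self.marker_heights)))

    @property
    def hydronium_id(self) -> int | None:
        return _HYDRONIUM_ID if self.hydronium_height is not None else None

    @property
    def donor_ids(self) -> tuple[int, ...]:
        return tuple(range(_DONOR_BASE, _DONOR_BASE + len(self.hbond_pairs)))

    @property
    def partner_ids(self) -> tuple[int, ...]:
        return tuple(range(_PARTNER_BASE, _PARTNER_BASE + len(self.hbond_pairs)))

    @property
    def water_ids(self) -> tuple[int, ...]:
        return tuple(range(_WATER_BASE, _WATER_BASE + self.n_waters))

    def analytic_volume_nm3(self) -> float:
        """Exact hull volume of the scaffold corners, nm³."""
        w = 2 * self.box_half_width
        area = w * w if self.shape == "box" else 0.5 * w * w
        return area * self.channel_length / 1000.0


def _scaffold_atoms(spec: SyntheticChannelSpec):
    """Static atoms: corners, markers, hydronium, bond-event residues."""
    names, resids, resnames, chains, pos = [], [], [], [], []

    def add(name, rid, rname, xyz):
        names.append(name)
        resids.append(rid)
        resnames.append(rname)
        chains.append("S")
        pos.append(np.asarray(xyz, dtype=float))

    xy = spec.corner_xy()
    for k, rid in enumerate(spec.corner_ids):
        z = 0.0 if k < len(xy) else spec.channel_length
        x, y = xy[k % len(xy)]
        add("CA", rid, "COR", (x, y, z))
    for h, rid in zip(spec.marker_heights, spec.marker_ids):
        add("CA", rid, "MRK", (0.0, 0.0, spec.z_mid + h))
    if spec.hydronium_height is not None:
        o = np.array([0.0, 0.0, spec.z_mid + spec.hydronium_height])
        add("O", _HYDRONIUM_ID, "H3O", o)
        for i, off in enumerate(_H3O_H, start=1):
            add(f"H{i}", _HYDRONIUM_ID, "H3O", o + off)
    # Bond-event pairs: serine-like hydroxyl donors at 5 Å vertical spacing,
    # each facing its own partner water along +x; spacing keeps pairs from
    # cross-bonding (all cross distances exceed the 3.5 Å cutoff).
    for i, (did, pid) in enumerate(zip(spec.donor_ids, spec.partner_ids)):
        og = np.array([-4.0, 0.0, 5.0 + 5.0 * i])
        add("OG", did, "SER", og)
        add("HG", did, "SER", og + [1.0, 0.0, 0.0])
        ow = og + [5.0, 0.0, 0.0]  # unbonded placement; events overwrite x
        add("O", pid, "WAT", ow)
        add("H1", pid, "WAT", ow + _WATER_H1)
        add("H2", pid, "WAT", ow + _WATER_H2)
    return names, resids, resnames, chains, np.array(pos)


def generate_scaffold(spec: SyntheticChannelSpec) -> FrameSeries:
    """Single static frame of the scaffold (no diffusing waters)."""
    names, resids, resnames, chains, pos = _scaffold_atoms(spec)
    partner_waters = list(spec.partner_ids)
    return FrameSeries(
        times=np.array([0.0]),
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=pos[None, :, :],
        water_ids=np.array(partner_waters, dtype=int),
        hydronium_id=spec.hydronium_id,
    )


def reflect_into_cylinder(
    pts: np.ndarray, radius: float, z_lo: float, z_hi: float
) -> np.ndarray:
    """Mirror-reflect points back inside a finite cylinder (in place)."""
    z = pts[:, 2]
    for _ in range(64):
        over = z > z_hi
        under = z < z_lo
        if not (over.any() or under.any()):
            break
        z[over] = 2 * z_hi - z[over]
        z[under] = 2 * z_lo - z[under]
    r = np.hypot(pts[:, 0], pts[:, 1])
    for _ in range(64):
        out = r > radius
        if not out.any():
            break
        scale = (2 * radius - r[out]) / r[out]
        # fold the radial coordinate back across the wall, keeping azimuth;
        # a negative scale (huge step) flips through the axis, which is fine
        pts[out, 0] *= scale
        pts[out, 1] *= scale
        r = np.hypot(pts[:, 0], pts[:, 1])
    return pts


def simulate_waters(spec: SyntheticChannelSpec) -> FrameSeries:
    """Brownian waters in a reflecting cylinder, plus the static scaffold.

    Each water takes independent Gaussian steps of variance 2·D·dt per axis
    and is mirror-reflected at the confinement surface, so the occupancy is
    stationary and no water ever leaves the cylinder.
    """
    rng = np.random.default_rng(spec.seed)
    names, resids, resnames, chains, static = _scaffold_atoms(spec)
    n_static = len(names)
    for wid in spec.water_ids:
        names += ["O", "H1", "H2"]
        resids += [wid] * 3
        resnames += ["WAT"] * 3
        chains += ["W"] * 3

    nw = spec.n_waters
    z_lo, z_hi = 0.0, spec.channel_length
    # uniform initial positions inside the confinement cylinder
    r = spec.confinement_radius * np.sqrt(rng.uniform(size=nw))
    phi = rng.uniform(0, 2 * np.pi, size=nw)
    o = np.column_stack(
        [r * np.cos(phi), r * np.sin(phi), rng.uniform(z_lo, z_hi, size=nw)]
    )
    sigma = np.sqrt(2.0 * spec.diffusion * spec.dt)
    coords = np.empty((spec.n_frames, n_static + 3 * nw, 3))
    for t in range(spec.n_frames):
        if t > 0 and sigma > 0:
            o = o + rng.normal(0.0, sigma, size=(nw, 3))
            o = reflect_into_cylinder(o, spec.confinement_radius, z_lo, z_hi)
        coords[t, :n_static] = static
        w = coords[t, n_static:].reshape(nw, 3, 3)
        w[:, 0] = o
        w[:, 1] = o + _WATER_H1
        w[:, 2] = o + _WATER_H2
    all_waters = list(spec.partner_ids) + list(spec.water_ids)
    return FrameSeries(
        times=np.arange(spec.n_frames) * spec.dt,
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        coords=coords,
        water_ids=np.array(all_waters, dtype=int),
        hydronium_id=spec.hydronium_id,
    )


def simulate(spec: SyntheticChannelSpec) -> FrameSeries:
    """Full synthetic trajectory: diffusing waters plus any bond events."""
    if spec.hbond_pairs:
        frames, _ = simulate_hbond_events(spec)
        return frames
    return simulate_waters(spec)


def markov_h(
    n_frames: int,
    bonded_dwell: float,
    unbonded_dwell: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state Markov bonded/unbonded sequence with geometric dwells.

    Dwell lengths (in frames) are geometric with means ``dwell/dt``; the
    initial state is drawn from the stationary distribution.  Dwell means
    should be well above dt for the discrete chain to approximate the
    intended exponential kinetics.
    """
    p_off = min(1.0, dt / bonded_dwell)  # leave-bonded probability per frame
    p_on = min(1.0, dt / unbonded_dwell)
    # continuous-time limits: a dwell shorter than a frame means the state
    # is never observed at the frame resolution
    if p_on >= 1.0 and p_off < 1.0:
        return np.ones(n_frames, dtype=bool)
    if p_off >= 1.0 and p_on < 1.0:
        return np.zeros(n_frames, dtype=bool)
    h = np.empty(n_frames, dtype=bool)
    state = rng.uniform() < bonded_dwell / (bonded_dwell + unbonded_dwell)
    u = rng.uniform(size=n_frames)
    for t in range(n_frames):
        h[t] = state
        if state:
            state = u[t] >= p_off
        else:
            state = u[t] < p_on
    return h


def simulate_hbond_events(
    spec: SyntheticChannelSpec, inject_h: dict[int, np.ndarray] | None = None
) -> tuple[FrameSeries, dict[int, np.ndarray]]:
    """Trajectory whose donor/water pairs toggle bond geometry by a Markov chain.

    For each (bonded_dwell, unbonded_dwell) pair in the spec, the partner
    water oxygen sits collinear with the donor O–H at 2.8 Å while bonded
    and at 5.0 Å while unbonded.  Returns the frames and the ground-truth
    per-donor bonded state h(t).  ``inject_h`` bypasses the Markov chain
    with caller-supplied state sequences (keyed by donor residue id).
    """
    if not spec.hbond_pairs:
        raise ValueError("spec defines no hbond_pairs")
    rng = np.random.default_rng(spec.seed)
    base = simulate_waters(spec)
    coords = base.coords
    truth: dict[int, np.ndarray] = {}
    for (did, pid), (d_on, d_off) in zip(
        zip(spec.donor_ids, spec.partner_ids), spec.hbond_pairs
    ):
        if inject_h is not None and did in inject_h:
            h = np.asarray(inject_h[did], dtype=bool)
            if h.size != spec.n_frames:
                raise ValueError("injected h(t) length must equal n_frames")
        else:
            h = markov_h(spec.n_frames, d_on, d_off, spec.dt, rng)
        og = coords[0, base.atom_index(did, "OG")]
        x = np.where(h, 2.8, 5.0)
        io = base.atom_index(pid, "O")
        for j, off in enumerate((np.zeros(3), _WATER_H1, _WATER_H2)):
            coords[:, io + j, 0] = og[0] + x + off[0]
            coords[:, io + j, 1] = og[1] + off[1]
            coords[:, io + j, 2] = og[2] + off[2]
        truth[did] = h
    return base, truth
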