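"""Topology/trajectory reading and writing via MDAnalysis.

Readers accept a PDB topology plus DCD or XTC coordinate files and produce
the package's :class:`~porewater.frames.FrameSeries`; writers round-trip a
FrameSeries back to those formats (used by the synthetic generator so the
full file path is exercised).  Residues are re-indexed to globally unique
ids on load; the original (chain, residue number) labels are preserved in
the series.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import MDAnalysis as mda
import numpy as np

from .frames import FrameSeries

__all__ = ["load_trajectory", "write_frames", "detect_water_ids"]

_WATER_RESNAMES = {"WAT", "HOH", "TIP3", "TIP3P", "SOL", "SPC", "SPCE", "T3P"}
_HYDRONIUM_RESNAMES = {"H3O", "HYD", "H3O+"}


def detect_water_ids(resids: np.ndarray, resnames: np.ndarray) -> np.ndarray:
    """Residue ids whose residue name is a common water model name."""
    ids = []
    seen = set()
    for rid, rn in zip(resids, resnames):
        if rid not in seen and str(rn).upper() in _WATER_RESNAMES:
            ids.append(int(rid))
        seen.add(rid)
    return np.array(sorted(set(ids)), dtype=int)


def load_trajectory(
    topology: str | Path,
    coordinates: str | Path | Sequence[str | Path] | None = None,
    stride: int = 1,
    dt: float | None = None,
) -> FrameSeries:
    """Read a PDB topology (+ DCD/XTC coordinates) into a FrameSeries.

    ``dt`` (ps) overrides the trajectory metadata; with ``stride`` > 1 the
    effective spacing is ``stride`` times the file spacing.  Waters are
    detected by residue name; a hydronium-like residue, if present, is
    flagged.  A topology/trajectory atom-count mismatch surfaces as an
    explicit error.
    """
    topology = str(topology)
    if coordinates is None:
        u = mda.Universe(topology)
    else:
        if isinstance(coordinates, (str, Path)):
            coordinates = [coordinates]
        try:
            u = mda.Universe(topology, [str(c) for c in coordinates])
        except ValueError as exc:
            raise ValueError(
                f"topology {topology!r} and coordinate files disagree: {exc}"
            ) from exc
    atoms = u.atoms
    # keep file resids when globally unique; otherwise re-index (resids can
    # repeat across chains in PDB files)
    per_res = u.residues.resids
    if len(np.unique(per_res)) == len(per_res):
        unique_ids = atoms.resids.astype(int)
    else:
        unique_ids = atoms.resindices + 1
    names = atoms.names.astype(str)
    resnames = atoms.resnames.astype(str)
    try:
        chains = atoms.chainIDs.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        chains = atoms.segids.astype(str)

    n_frames = len(u.trajectory[::stride])
    coords = np.empty((n_frames, len(atoms), 3))
    times = np.empty(n_frames)
    for i, ts in enumerate(u.trajectory[::stride]):
        coords[i] = atoms.positions
        times[i] = ts.time
    if n_frames > 1:
        steps = np.diff(times)
        if dt is not None:
            times = np.arange(n_frames) * dt * 1.0
        elif not np.all(steps > 0) or not np.allclose(steps, steps[0], rtol=1e-4):
            raise ValueError("trajectory frame times are not uniformly increasing")
    elif dt is not None:
        times = np.array([0.0])

    water_ids = detect_water_ids(unique_ids, resnames)
    hydronium = None
    for rid, rn in zip(unique_ids, resnames):
        if str(rn).upper() in _HYDRONIUM_RESNAMES:
            hydronium = int(rid)
            break
    return FrameSeries(
        times=times,
        names=names,
        resids=unique_ids,
        resnames=resnames,
        chains=chains,
        coords=coords,
        water_ids=water_ids,
        hydronium_id=hydronium,
    )


def write_frames(
    frames: FrameSeries,
    topology: str | Path | None,
    trajectory: str | Path | None = None,
) -> None:
    """Write a FrameSeries as PDB topology and/or DCD/XTC trajectory.

    Either path may be omitted.  The trajectory format follows the file
    extension; frame times go into the trajectory metadata where the
    format supports it.
    """
    n_res = len(np.unique(frames.resids))
    u = mda.Universe.empty(
        n_atoms=frames.n_atoms,
        n_residues=n_res,
        atom_resindex=np.unique(frames.resids, return_inverse=True)[1],
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", frames.names.astype(str))
    first = np.array(
        [np.flatnonzero(frames.resids == r)[0] for r in np.unique(frames.resids)]
    )
    u.add_TopologyAttr("resids", np.unique(frames.resids))
    u.add_TopologyAttr("resnames", frames.resnames[first].astype(str))
    u.add_TopologyAttr("chainIDs", [c[:1] for c in frames.chains.astype(str)])
    u.atoms.positions = frames.coords[0]
    if topology is not None:
        u.atoms.write(str(topology))
    if trajectory is not None:
        dt = frames.dt if frames.n_frames > 1 else 1.0
        with mda.Writer(str(trajectory), frames.n_atoms, dt=dt) as w:
            for t in range(frames.n_frames):
                u.atoms.positions = frames.coords[t]
                u.trajectory.ts.time = frames.times[t]
                u.trajectory.ts.frame = t
                w.write(u.atoms)
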