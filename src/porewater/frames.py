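"""Core in-memory trajectory container.

A :class:`FrameSeries` holds labelled atom coordinates for an ordered set of
equally spaced snapshots.  All analysis modules consume this container; the
:mod:`porewater.io` module converts to and from on-disk topology/trajectory
formats, and :mod:`porewater.synthetic` generates them directly.

Coordinates are in Å, times in ps throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["FrameSeries", "atom_masses", "element_of"]

# Standard atomic masses (u).  Two-letter symbols are matched before
# single-letter ones when guessing the element from an atom name.
_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,  # calcium ion; the atom name "CA" in a residue is carbon
    "FE": 55.845,
    "ZN": 65.38,
    "CU": 63.546,
}

_ION_RESNAMES = {"CLA", "CL", "SOD", "NA", "POT", "K", "MG", "CAL", "ZN", "CU", "FE"}


def element_of(name: str, resname: str = "") -> str:
    """Guess the element from an atom name (PDB-style conventions).

    Within ordinary residues a leading C/N/O/S/H/P letter names the element
    ("CA" is an α-carbon); only in ion residues is the full name taken as a
    two-letter symbol.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if resname.upper() in _ION_RESNAMES and stripped in _MASSES:
        return stripped
    return stripped[0]


def atom_masses(names, resnames) -> np.ndarray:
    """Standard atomic masses (u) for arrays of atom/residue names."""
    out = np.empty(len(names))
    for i, (n, rn) in enumerate(zip(names, resnames)):
        el = element_of(str(n), str(rn))
        try:
            out[i] = _MASSES[el]
        except KeyError:
            raise ValueError(f"no standard mass for element {el!r} (atom {n!r})")
    return out


@dataclass
class FrameSeries:
    """Ordered snapshots of labelled atom coordinates with uniform spacing.

    Parameters
    ----------
    times:
        Frame times in ps, shape ``(n_frames,)``; spacing must be uniform.
    names, resids, resnames, chains:
        Per-atom labels, each shape ``(n_atoms,)``.  ``resids`` must be
        unique per residue across the whole system (readers re-index).
    coords:
        Coordinates in Å, shape ``(n_frames, n_atoms, 3)``.
    water_ids:
        Residue ids flagged as water; each must resolve to exactly one
        oxygen atom, whose position stands for the molecule.
    hydronium_id:
        Optional residue id of a hydronium-like particle.
    """

    times: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    water_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    hydronium_id: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.names = np.asarray(self.names)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames)
        self.chains = np.asarray(self.chains)
        self.coords = np.asarray(self.coords, dtype=float)
        self.water_ids = np.asarray(self.water_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if len(self.times) != self.n_frames:
            raise ValueError("times and coords disagree on frame count")
        if self.n_frames > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9) or steps[0] <= 0:
                raise ValueError("frame times must be uniformly spaced with dt > 0")
        for wid in self.water_ids:
            sel = (self.resids == wid) & np.char.startswith(
                self.names.astype(str), "O"
            )
            if sel.sum() != 1:
                raise ValueError(
                    f"water residue {wid} must have exactly one oxygen atom"
                )

    # -- basic shape / timing -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps."""
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame series")
        return float(self.times[1] - self.times[0])

    # -- lookups --------------------------------------------------------------

    def atom_indices(self, resid: int) -> np.ndarray:
        idx = np.flatnonzero(self.resids == resid)
        if idx.size == 0:
            raise KeyError(f"no atoms with residue id {resid}")
        return idx

    def atom_index(self, resid: int, name: str) -> int:
        idx = np.flatnonzero((self.resids == resid) & (self.names == name))
        if idx.size != 1:
            raise KeyError(f"expected one atom {name!r} in residue {resid}, found {idx.size}")
        return int(idx[0])

    def resname_of(self, resid: int) -> str:
        return str(self.resnames[self.atom_indices(resid)[0]])

    @cached_property
    def water_oxygen_indices(self) -> np.ndarray:
        """Atom index of the oxygen of every water, in ``water_ids`` order."""
        isO = np.char.startswith(self.names.astype(str), "O")
        out = np.empty(len(self.water_ids), dtype=int)
        for i, wid in enumerate(self.water_ids):
            out[i] = np.flatnonzero((self.resids == wid) & isO)[0]
        return out

    def water_oxygens(self, frame: int | None = None) -> np.ndarray:
        """Water oxygen coordinates: one frame ``(n_w, 3)`` or all ``(n_frames, n_w, 3)``."""
        ox = self.water_oxygen_indices
        if frame is None:
            return self.coords[:, ox, :]
        return self.coords[frame, ox, :]

    def masses(self) -> np.ndarray:
        return atom_masses(self.names, self.resnames)

    def residue_com(self, resid: int, frame: int) -> np.ndarray:
        """Centre of mass of a residue in one frame (standard atomic masses)."""
        idx = self.atom_indices(resid)
        m = atom_masses(self.names[idx], self.resnames[idx])
        return (self.coords[frame, idx, :] * m[:, None]).sum(axis=0) / m.sum()

    def residue_com_series(self, resid: int) -> np.ndarray:
        """Centre of mass of a residue in every frame, shape ``(n_frames, 3)``."""
        idx = self.atom_indices(resid)
        m = atom_masses(self.names[idx], self.resnames[idx])
        return (self.coords[:, idx, :] * m[None, :, None]).sum(axis=1) / m.sum()

    def slice_frames(self, start: int = 0, stop: int | None = None, step: int = 1) -> "FrameSeries":
        """A new series restricted to ``frames[start:stop:step]``."""
        return FrameSeries(
            times=self.times[start:stop:step],
            names=self.names,
            resids=self.resids,
            resnames=self.resnames,
            chains=self.chains,
            coords=self.coords[start:stop:step],
            water_ids=self.water_ids,
            hydronium_id=self.hydronium_id,
        )
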