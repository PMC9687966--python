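"""Side-chain conformational statistics: χ dihedrals, distances, up/down.

Dihedrals follow the IUPAC sign convention, reported in (−180°, 180°].
Distance conventions mirror common channel-width practice: Cα–Cα for
backbone width measures and the polar side-chain atom for residue–residue
measures (hydroxyl O for Ser/Thr/Tyr, Nζ for Lys, Cε1 for His — the carbon
bridging the two ring nitrogens — and Cδ for Glu, bridging the two
carboxylate oxygens).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import FrameSeries
from .hydration import replica_mean_se

__all__ = [
    "CHI_ATOMS",
    "POLAR_ATOM",
    "DihedralSeries",
    "DistanceSeries",
    "dihedral",
    "dihedral_series",
    "chi_distributions",
    "residue_distances",
    "classify_up_down",
]

# χ1..χ4 atom quadruples per residue type (standard rotamer definitions).
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "HSD": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "HSE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "GLU": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "GLH": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "LYS": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ),
    "LYN": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ),
}

# Polar side-chain atom used for residue–residue distance measures.
POLAR_ATOM: dict[str, str] = {
    "SER": "OG",
    "THR": "OG1",
    "TYR": "OH",
    "LYS": "NZ",
    "LYN": "NZ",
    "HIS": "CE1",
    "HSD": "CE1",
    "HSE": "CE1",
    "GLU": "CD",
    "GLH": "CD",
}


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-12:
        raise ValueError("degenerate dihedral: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: collinear points")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def _dihedral_array(a, b, c, d) -> np.ndarray:
    """Vectorised torsion of (n, 3) point arrays, degrees in (−180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    ang = np.degrees(np.arctan2((m * n2).sum(-1), (n1 * n2).sum(-1)))
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


@dataclass
class DihedralSeries:
    """Per-frame χ angle of one residue with its normalised histogram."""

    residue: int
    chi: int  # 1-based χ index
    angles: np.ndarray  # degrees in (−180, 180], one per frame
    bin_edges: np.ndarray
    density: np.ndarray  # histogram density (integrates to 1 over degrees)


def dihedral_series(
    frames: FrameSeries, resid: int, quad: tuple[str, str, str, str]
) -> np.ndarray:
    idx = [frames.atom_index(resid, n) for n in quad]
    c = frames.coords[:, idx, :]
    return _dihedral_array(c[:, 0], c[:, 1], c[:, 2], c[:, 3])


def chi_distributions(
    replicas: Sequence[FrameSeries],
    resid: int,
    bin_width: float = 5.0,
    chi_atoms: dict | None = None,
) -> list[DihedralSeries]:
    """χ1..χ4 distributions (where defined) of one residue, pooled histogram.

    The per-frame angle series concatenates the replicas; the histogram is
    replica-averaged (equal-length replicas make this the pooled density).
    Missing atoms raise a KeyError naming the atom.
    """
    table = CHI_ATOMS if chi_atoms is None else chi_atoms
    resname = replicas[0].resname_of(resid).upper()
    if resname not in table:
        raise KeyError(f"no χ atom definitions for residue type {resname!r}")
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    out = []
    for k, quad in enumerate(table[resname], start=1):
        per_rep = [dihedral_series(fr, resid, quad) for fr in replicas]
        dens = np.mean(
            [np.histogram(a, bins=edges, density=True)[0] for a in per_rep], axis=0
        )
        out.append(
            DihedralSeries(
                residue=int(resid),
                chi=k,
                angles=np.concatenate(per_rep),
                bin_edges=edges,
                density=dens,
            )
        )
    return out


@dataclass
class DistanceSeries:
    """Per-frame distance between two residues under a stated atom convention."""

    res_a: int
    res_b: int
    atom_a: str
    atom_b: str
    distances: np.ndarray  # Å, concatenated over replicas
    mean: float
    se: float
    replica_means: tuple[float, ...]


def _convention_atom(frames: FrameSeries, resid: int, atom: str | None) -> str:
    if atom is not None:
        return atom
    resname = frames.resname_of(resid).upper()
    if resname not in POLAR_ATOM:
        raise KeyError(
            f"no polar-atom convention for residue type {resname!r}; specify the atom"
        )
    return POLAR_ATOM[resname]


def residue_distances(
    replicas: Sequence[FrameSeries],
    res_a: int,
    res_b: int,
    atom_a: str | None = None,
    atom_b: str | None = None,
) -> DistanceSeries:
    """Per-frame distance between two residues, replica mean ± SE.

    Atoms default to the polar side-chain convention; pass ``"CA"`` for the
    backbone channel-width measures.
    """
    atom_a = _convention_atom(replicas[0], res_a, atom_a)
    atom_b = _convention_atom(replicas[0], res_b, atom_b)
    per_rep = []
    for fr in replicas:
        ia = fr.atom_index(res_a, atom_a)
        ib = fr.atom_index(res_b, atom_b)
        per_rep.append(np.linalg.norm(fr.coords[:, ia, :] - fr.coords[:, ib, :], axis=1))
    mean, se, _ = replica_mean_se([d.mean() for d in per_rep])
    return DistanceSeries(
        res_a=int(res_a),
        res_b=int(res_b),
        atom_a=atom_a,
        atom_b=atom_b,
        distances=np.concatenate(per_rep),
        mean=mean,
        se=se,
        replica_means=tuple(float(d.mean()) for d in per_rep),
    )


def classify_up_down(
    distances: np.ndarray, threshold: float = 11.5
) -> tuple[np.ndarray, dict[str, float]]:
    """Label frames "up" (≤ threshold, side chain toward the reference) or "down".

    Returns per-frame labels and the occupancy fractions of each state.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(distances, dtype=float)
    labels = np.where(d <= threshold, "up", "down")
    up = float((labels == "up").mean())
    return labels, {"up": up, "down": 1.0 - up}
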