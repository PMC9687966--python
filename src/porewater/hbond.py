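"""Geometric hydrogen-bond detection, per-residue counts and lifetimes.

A hydrogen bond exists when the donor–acceptor distance is at most 3.5 Å
and the donor–hydrogen⋯acceptor angle deviates from linear by at most 35°
(both boundaries inclusive).  Lifetimes are continuous any-water survival
times: for a residue bonded to *some* water at a time origin t₀, the
autocorrelation

    C(τ) = ⟨ Σ h(t₀) h(t₀+τ) / Σ h(t₀)² ⟩

counts the fraction of bonded origins that stay bonded to some water
(identity may change) at every frame through t₀+τ.  C(τ) is fitted with a
bi-exponential A·exp(−t/τ₁) + B·exp(−t/τ₂), A + B = 1, and the reported
lifetime is the weighted sum A·τ₁ + B·τ₂.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .frames import FrameSeries
from .hydration import replica_mean_se

__all__ = [
    "HBondCriterion",
    "HBond",
    "SurvivalCurve",
    "BiexpFit",
    "ChemistryError",
    "DonorAcceptorTable",
    "DEFAULT_CHEMISTRY",
    "resolve_donors_acceptors",
    "detect_hbonds",
    "residue_water_bond_counts",
    "mean_hbond_counts",
    "any_water_bond_series",
    "survival_curve",
    "fit_biexponential",
    "lifetime_summary",
]


class ChemistryError(ValueError):
    """Raised when donor/acceptor atoms cannot be resolved from the topology."""


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric bond criterion (distances in Å, angles in degrees)."""

    max_donor_acceptor_distance: float = 3.5
    max_deviation_from_linear: float = 35.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0 or self.max_deviation_from_linear <= 0:
            raise ValueError("criterion thresholds must be positive")


class HBond(NamedTuple):
    donor: int  # atom index of donor heavy atom
    hydrogen: int  # atom index of the shared hydrogen
    acceptor: int  # atom index of acceptor heavy atom
    frame: int


# Donor entries map a heavy-atom name to the names of its polar hydrogens;
# acceptor entries list heavy atoms with accessible lone pairs.  Waters and
# hydronium act as both donor and acceptor.  The table covers the hydroxyl,
# carboxyl(ate), amine/ammonium, imidazole, water and hydronium chemistry
# used in channel work; it is configurable for anything else.
DEFAULT_CHEMISTRY: dict[str, dict] = {
    "WAT": {"donors": {"O": ("H1", "H2")}, "acceptors": ("O",)},
    "HOH": {"donors": {"O": ("H1", "H2")}, "acceptors": ("O",)},
    "TIP3": {"donors": {"OH2": ("H1", "H2")}, "acceptors": ("OH2",)},
    "SOL": {"donors": {"OW": ("HW1", "HW2")}, "acceptors": ("OW",)},
    "H3O": {"donors": {"O": ("H1", "H2", "H3")}, "acceptors": ("O",)},
    "SER": {"donors": {"OG": ("HG", "HG1")}, "acceptors": ("OG",)},
    "THR": {"donors": {"OG1": ("HG1",)}, "acceptors": ("OG1",)},
    "TYR": {"donors": {"OH": ("HH",)}, "acceptors": ("OH",)},
    "LYS": {"donors": {"NZ": ("HZ1", "HZ2", "HZ3")}, "acceptors": ("NZ",)},
    "LYN": {"donors": {"NZ": ("HZ1", "HZ2", "HZ3")}, "acceptors": ("NZ",)},
    "GLU": {"donors": {}, "acceptors": ("OE1", "OE2")},
    "GLH": {"donors": {"OE2": ("HE2",)}, "acceptors": ("OE1", "OE2")},
    "ASP": {"donors": {}, "acceptors": ("OD1", "OD2")},
    "ASH": {"donors": {"OD2": ("HD2",)}, "acceptors": ("OD1", "OD2")},
    "HIS": {"donors": {"ND1": ("HD1",), "NE2": ("HE2",)}, "acceptors": ("ND1", "NE2")},
    "HSD": {"donors": {"ND1": ("HD1",)}, "acceptors": ("NE2",)},
    "HSE": {"donors": {"NE2": ("HE2",)}, "acceptors": ("ND1",)},
    "HSP": {"donors": {"ND1": ("HD1",), "NE2": ("HE2",)}, "acceptors": ()},
    "ASN": {"donors": {"ND2": ("HD21", "HD22")}, "acceptors": ("OD1",)},
    "GLN": {"donors": {"NE2": ("HE21", "HE22")}, "acceptors": ("OE1",)},
}


@dataclass
class DonorAcceptorTable:
    """Resolved donor (heavy, hydrogen) atom-index pairs and acceptor indices."""

    donors: np.ndarray  # (n_d, 2) columns: heavy index, hydrogen index
    acceptors: np.ndarray  # (n_a,)
    resids: np.ndarray = field(repr=False, default=None)  # per-atom residue ids


def resolve_donors_acceptors(
    frames: FrameSeries,
    residue_ids: Sequence[int] | None = None,
    chemistry: dict | None = None,
) -> DonorAcceptorTable:
    """Resolve donor/acceptor atoms for the given residues from the topology.

    Donor hydrogens are matched by name within the residue; a donor heavy
    atom whose listed hydrogens are all absent raises :class:`ChemistryError`.
    Residues whose name is not in the chemistry table contribute nothing.
    """
    chem = DEFAULT_CHEMISTRY if chemistry is None else chemistry
    if residue_ids is None:
        residue_ids = np.unique(frames.resids)
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    names = frames.names.astype(str)
    for rid in residue_ids:
        idx = np.flatnonzero(frames.resids == rid)
        if idx.size == 0:
            raise KeyError(f"residue {rid} not in topology")
        resname = str(frames.resnames[idx[0]]).upper()
        entry = chem.get(resname)
        if entry is None:
            continue
        local = {names[i]: int(i) for i in idx}
        for heavy, hyds in entry["donors"].items():
            if heavy not in local:
                continue
            found = [local[h] for h in hyds if h in local]
            if not found:
                raise ChemistryError(
                    f"donor {heavy} of residue {rid} ({resname}) has none of its "
                    f"hydrogens {hyds} in the topology"
                )
            donors.extend((local[heavy], h) for h in found)
        acceptors.extend(local[a] for a in entry["acceptors"] if a in local)
    return DonorAcceptorTable(
        donors=np.array(donors, dtype=int).reshape(-1, 2),
        acceptors=np.array(acceptors, dtype=int),
        resids=frames.resids,
    )


def detect_hbonds(
    frames: FrameSeries,
    frame: int,
    table: DonorAcceptorTable,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[HBond]:
    """All hydrogen bonds in one frame under the geometric criterion.

    Intra-residue pairs are excluded.  Detection is deterministic and
    independent of atom ordering; bonds are returned sorted by
    (donor, hydrogen, acceptor).
    """
    if table.donors.size == 0 or table.acceptors.size == 0:
        return []
    pos = frames.coords[frame]
    d_heavy = table.donors[:, 0]
    d_hyd = table.donors[:, 1]
    acc = table.acceptors
    dvec = pos[acc][None, :, :] - pos[d_heavy][:, None, :]  # (n_d, n_a, 3)
    dist = np.linalg.norm(dvec, axis=2)
    same_res = frames.resids[d_heavy][:, None] == frames.resids[acc][None, :]
    cand = (dist <= table_cutoff(criterion)) & ~same_res & (d_heavy[:, None] != acc[None, :])
    bonds: list[HBond] = []
    di, ai = np.nonzero(cand)
    if di.size:
        h = pos[d_hyd[di]]
        v1 = pos[d_heavy[di]] - h  # H→D
        v2 = pos[acc[ai]] - h  # H→A
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = (180.0 - ang) <= criterion.max_deviation_from_linear + 1e-9
        for j in np.flatnonzero(ok):
            bonds.append(
                HBond(int(d_heavy[di[j]]), int(d_hyd[di[j]]), int(acc[ai[j]]), frame)
            )
    bonds.sort(key=lambda b: (b.donor, b.hydrogen, b.acceptor))
    return bonds


def table_cutoff(criterion: HBondCriterion) -> float:
    # small tolerance keeps the boundary (d == cutoff) inclusive under rounding
    return criterion.max_donor_acceptor_distance + 1e-9


def _water_atom_mask(frames: FrameSeries) -> np.ndarray:
    """Per-atom mask of water (and hydronium) residues."""
    ids = set(int(w) for w in frames.water_ids)
    if frames.hydronium_id is not None:
        ids.add(int(frames.hydronium_id))
    return np.isin(frames.resids, list(ids))


def residue_water_bond_counts(
    frames: FrameSeries,
    residue: int,
    table: DonorAcceptorTable,
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """Per-frame number of hydrogen bonds between one residue and any water.

    Bonds are counted, not distinct water partners; a water bonded twice to
    the residue contributes two.
    """
    water = _water_atom_mask(frames)
    counts = np.zeros(frames.n_frames, dtype=int)
    for t in range(frames.n_frames):
        for b in detect_hbonds(frames, t, table, criterion):
            rd, ra = frames.resids[b.donor], frames.resids[b.acceptor]
            if (rd == residue and water[b.acceptor]) or (
                ra == residue and water[b.donor]
            ):
                counts[t] += 1
    return counts


def mean_hbond_counts(
    replicas: Sequence[FrameSeries],
    residues: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
    chemistry: dict | None = None,
) -> dict[int, tuple[float, float]]:
    """Replica-averaged residue–water bond counts: residue → (mean, SE)."""
    out: dict[int, tuple[float, float]] = {}
    tables = [resolve_donors_acceptors(fr, chemistry=chemistry) for fr in replicas]
    for res in residues:
        means = [
            residue_water_bond_counts(fr, res, tb, criterion).mean()
            for fr, tb in zip(replicas, tables)
        ]
        m, se, _ = replica_mean_se(means)
        out[int(res)] = (m, se)
    return out


@dataclass
class SurvivalCurve:
    """Continuous any-water bond survival C(τ) sampled at uniform lags."""

    lags: np.ndarray  # ps, starting at 0
    values: np.ndarray  # C(τ)
    n_origins: int  # bonded time origins used
    defined: bool = True


def any_water_bond_series(
    frames: FrameSeries,
    residue: int,
    table: DonorAcceptorTable,
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """h(t): 1 iff the residue has ≥1 bond to any water in frame t."""
    counts = residue_water_bond_counts(frames, residue, table, criterion)
    return counts > 0


def survival_curve(
    h: np.ndarray,
    dt: float,
    max_lag: float = 100.0,
    origin_spacing: float = 120.0,
) -> SurvivalCurve:
    """Survival autocorrelation of a binary bonded series.

    Time origins are spaced ``origin_spacing`` ps apart (must exceed
    ``max_lag`` so the per-origin windows do not overlap).  An origin with
    h(t₀)=1 survives lag τ iff h=1 at every frame in [t₀, t₀+τ]; C(τ) is
    the surviving fraction of bonded origins.  With no bonded origin the
    curve is undefined and flagged.
    """
    if origin_spacing <= max_lag:
        raise ValueError("origin spacing must exceed the maximal lag (non-overlap)")
    h = np.asarray(h, dtype=bool)
    n = h.size
    k_max = int(np.floor(max_lag / dt + 1e-9))
    lags = np.arange(k_max + 1) * dt
    stride = max(1, int(round(origin_spacing / dt)))
    origins = np.arange(0, n, stride)
    origins = origins[h[origins]]
    if origins.size == 0:
        return SurvivalCurve(lags=lags, values=np.full(k_max + 1, np.nan), n_origins=0, defined=False)
    # run[i] = number of consecutive bonded frames starting at i
    run = np.zeros(n + 1, dtype=int)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if h[i] else 0
    surv = run[origins]  # each ≥ 1
    values = np.array([(surv >= k + 1).mean() for k in range(k_max + 1)])
    return SurvivalCurve(lags=lags, values=values, n_origins=int(origins.size))


@dataclass
class BiexpFit:
    """Bi-exponential fit of a survival curve; τ₁ ≤ τ₂ by convention."""

    A: float
    B: float
    tau1: float  # ps
    tau2: float  # ps
    residual: float  # sum of squared fit residuals
    valid: bool = True

    @property
    def weighted_lifetime(self) -> float:
        """A·τ₁ + B·τ₂ in ps."""
        return self.A * self.tau1 + self.B * self.tau2


def fit_biexponential(curve: SurvivalCurve) -> BiexpFit:
    """Constrained least-squares bi-exponential fit of C(τ).

    A + B = 1 with A ∈ [0, 1] and τ₁, τ₂ > 0 are enforced through the
    parametrisation; a small multi-start grid over (A, τ₁, τ₂) guards
    against local minima (the best residual wins).
    """
    if not curve.defined:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.inf, valid=False)
    mask = np.isfinite(curve.values)
    t = curve.lags[mask]
    c = curve.values[mask]
    if t.size < 5:
        raise ValueError("need at least 5 lag points to fit a bi-exponential")

    def model(p):
        a, t1, t2 = p
        return a * np.exp(-t / t1) + (1 - a) * np.exp(-t / t2)

    best = None
    for a0 in (0.3, 0.7):
        for t1_0 in (2.0, 10.0):
            for t2_0 in (50.0, 200.0):
                try:
                    res = least_squares(
                        lambda p: model(p) - c,
                        x0=[a0, t1_0, t2_0],
                        bounds=([0.0, 1e-6, 1e-6], [1.0, 1e6, 1e6]),
                        xtol=1e-14,
                        ftol=1e-14,
                        gtol=1e-14,
                    )
                except Exception:
                    continue
                cost = float(np.sum(res.fun**2))
                if best is None or cost < best[0]:
                    best = (cost, res)
    if best is None:
        return BiexpFit(np.nan, np.nan, np.nan, np.nan, np.inf, valid=False)
    cost, res = best
    a, t1, t2 = res.x
    if t1 > t2:  # order the time constants, swapping the weights with them
        a, t1, t2 = 1 - a, t2, t1
    return BiexpFit(A=float(a), B=float(1 - a), tau1=float(t1), tau2=float(t2),
                    residual=cost, valid=bool(res.success))


def lifetime_summary(fits: Sequence[BiexpFit]) -> dict:
    """Replica-averaged weighted lifetime with the reporting rule applied.

    Lifetimes whose standard error across replicas exceeds the mean are
    reported as not determined (``"N/A"``), as are all-invalid fits.
    """
    valid = [f for f in fits if f.valid and np.isfinite(f.weighted_lifetime)]
    if not valid:
        return {"lifetime": None, "se": None, "reported": "N/A", "n_replicas": 0}
    m, se, single = replica_mean_se([f.weighted_lifetime for f in valid])
    reported = "N/A" if (not single and se > m) else f"{m:.1f}"
    return {
        "lifetime": m,
        "se": se,
        "reported": reported,
        "n_replicas": len(valid),
    }
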