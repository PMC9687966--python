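"""Replica orchestration: run every analysis stage and write tidy outputs.

The protocol mirrors standard multi-replica practice: each replica is
analysed separately (its own median structure and cylinder), statistics are
averaged across replicas, and the standard error of the replica means is
reported.  Outputs are plain CSV/JSON tables ready for plotting.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import conformation, hbond, hydration, mobility, network
from .config import RunConfig
from .frames import FrameSeries
from .geometry import build_cylinder, build_polyhedron, find_median_frame
from .io import load_trajectory
from .synthetic import SyntheticChannelSpec, simulate

log = logging.getLogger("porewater")

__all__ = ["run_pipeline", "load_replicas"]

ALL_STAGES = ("hydration", "mobility", "hbonds", "network", "conformers")


def load_replicas(config: RunConfig) -> list[FrameSeries]:
    """Load (or generate) all replicas and discard the equilibration lead-in."""
    replicas: list[FrameSeries] = []
    if config.synthetic:
        for i in range(config.n_replicas):
            spec = SyntheticChannelSpec(
                **{**config.synthetic, "seed": int(config.seed) + i}
            )
            replicas.append(simulate(spec))
    else:
        for paths in config.replicas:
            replicas.append(
                load_trajectory(config.topology, paths, stride=config.stride, dt=config.dt)
            )
    out = []
    for fr in replicas:
        skip = int(round(config.discard_fraction * fr.n_frames))
        out.append(fr.slice_frames(skip) if skip else fr)
    return out


def _corner_ids(config: RunConfig, spec: SyntheticChannelSpec | None):
    if config.corner_residues:
        return config.corner_residues, config.bottom_residues, config.top_residues
    if spec is None:
        raise ValueError("corner_residues must be configured for file-based input")
    return list(spec.corner_ids), list(spec.bottom_ids), list(spec.top_ids)


def run_pipeline(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested stages and write their tables under the output dir.

    Returns a dict of in-memory results keyed by stage.  Deterministic for a
    given config and seed; every output file is a pure function of them.
    """
    t_start = time.time()
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = (
        SyntheticChannelSpec(**{**config.synthetic, "seed": int(config.seed)})
        if config.synthetic
        else None
    )
    replicas = load_replicas(config)
    log.info("loaded %d replicas (%s frames)", len(replicas), [r.n_frames for r in replicas])
    corner_ids, bottom_ids, top_ids = _corner_ids(config, spec)
    marker_ids = config.marker_residues or (list(spec.marker_ids) if spec else [])
    analysis_ids = config.analysis_residues or (list(spec.donor_ids) if spec else [])

    # Per-replica geometry: median structure over the configured window, then
    # the cylinder anchored on it; the polyhedron is rebuilt every frame.
    cylinders, polys_per_rep, medians = [], [], []
    for fr in replicas:
        if config.median_window_ps is not None:
            n = min(fr.n_frames, max(1, int(round(config.median_window_ps / fr.dt))))
        else:
            n = fr.n_frames
        med = find_median_frame(fr, (0, n))
        medians.append(med)
        cylinders.append(
            build_cylinder(fr, med, bottom_ids, top_ids, **config.cylinder)
        )
        polys_per_rep.append(
            [build_polyhedron(fr, t, corner_ids) for t in range(fr.n_frames)]
        )
    cyl = cylinders[0]
    criterion = hbond.HBondCriterion(
        max_donor_acceptor_distance=config.hbond.get("max_distance", 3.5),
        max_deviation_from_linear=config.hbond.get("max_angle_deviation", 35.0),
    )
    results: dict = {"medians": medians, "cylinders": cylinders}

    if "hydration" in stages:
        t0 = time.time()
        summary = hydration.hydration_summary(replicas, polys_per_rep, cyl)
        profiles = [
            hydration.occupancy_profile(fr, cy, marker_ids)
            for fr, cy in zip(replicas, cylinders)
        ]
        slice_means = np.mean([p.slice_means for p in profiles], axis=0)
        slice_se = (
            np.std([p.slice_means for p in profiles], axis=0, ddof=1)
            / np.sqrt(len(profiles))
            if len(profiles) > 1
            else np.zeros_like(slice_means)
        )
        cum = np.cumsum(slice_means)
        pd.DataFrame(
            {
                "slice": np.arange(1, cyl.n_slices + 1),
                "height": cyl.slice_centres,
                "mean_waters": slice_means,
                "se": slice_se,
                "cumulative": cum,
            }
        ).to_csv(outdir / "occupancy_profile.csv", index=False)
        markers = {
            str(r): float(np.mean([p.marker_heights[r] for p in profiles]))
            for r in marker_ids
        }
        with open(outdir / "hydration_summary.json", "w") as fh:
            json.dump(
                {
                    "mean_waters_polyhedron": summary.mean_waters_polyhedron,
                    "se_waters_polyhedron": summary.se_waters_polyhedron,
                    "mean_waters_cylinder": summary.mean_waters_cylinder,
                    "se_waters_cylinder": summary.se_waters_cylinder,
                    "mean_volume_nm3": summary.mean_volume,
                    "se_volume_nm3": summary.se_volume,
                    "single_replica": summary.single_replica,
                    "marker_heights": markers,
                },
                fh,
                indent=2,
            )
        hist, hedges, pedges = hydration.occupancy_projection(replicas[0], cyl)
        pd.DataFrame(
            hist,
            index=pd.Index(0.5 * (hedges[:-1] + hedges[1:]), name="height"),
            columns=0.5 * (pedges[:-1] + pedges[1:]),
        ).to_csv(outdir / "occupancy_projection.csv")
        results["hydration"] = {"summary": summary, "profiles": profiles}
        log.info("hydration stage done in %.2f s", time.time() - t0)

    if "mobility" in stages:
        t0 = time.time()
        lag = config.lag
        msds = [
            mobility.slice_msd(fr, cy, lag) for fr, cy in zip(replicas, cylinders)
        ]
        occs = [
            mobility.slice_occupancy_fraction(fr, cy)
            for fr, cy in zip(replicas, cylinders)
        ]
        prof = mobility.diffusion_profile(msds, occs, cyl)
        pd.DataFrame(
            {
                "slice": np.arange(1, cyl.n_slices + 1),
                "height": prof.slice_centres,
                "Ds": prof.ds,
                "spread": prof.spread,
                "Ns": prof.ns,
                "insufficient_data": prof.insufficient,
                "msd_axial": prof.components[:, 0],
                "msd_radial": prof.components[:, 1],
                "msd_angular": prof.components[:, 2],
            }
        ).to_csv(outdir / "diffusion_profile.csv", index=False)
        results["mobility"] = prof
        log.info("mobility stage done in %.2f s", time.time() - t0)

    tables = None
    if {"hbonds", "network"} & set(stages):
        tables = [hbond.resolve_donors_acceptors(fr) for fr in replicas]

    if "hbonds" in stages:
        t0 = time.time()
        counts = hbond.mean_hbond_counts(replicas, analysis_ids, criterion)
        pd.DataFrame(
            [
                {"residue": r, "mean_bonds": m, "se": se}
                for r, (m, se) in counts.items()
            ]
        ).to_csv(outdir / "hbond_counts.csv", index=False)
        max_lag = config.lifetime.get("max_lag", 100.0)
        spacing = config.lifetime.get("origin_spacing", 120.0)
        lifetimes = {}
        for res in analysis_ids:
            fits, curves = [], []
            for fr, tb in zip(replicas, tables):
                h = hbond.any_water_bond_series(fr, res, tb, criterion)
                curve = hbond.survival_curve(h, fr.dt, max_lag, spacing)
                curves.append(curve)
                if curve.defined:
                    fits.append(hbond.fit_biexponential(curve))
            pd.DataFrame(
                {
                    "lag": curves[0].lags,
                    **{
                        f"C_rep{i + 1}": c.values for i, c in enumerate(curves)
                    },
                }
            ).to_csv(outdir / f"survival_res{res}.csv", index=False)
            summary = hbond.lifetime_summary(fits)
            summary["fits"] = [
                {
                    "A": f.A,
                    "B": f.B,
                    "tau1": f.tau1,
                    "tau2": f.tau2,
                    "weighted_lifetime": f.weighted_lifetime,
                    "valid": f.valid,
                }
                for f in fits
            ]
            lifetimes[str(res)] = summary
        with open(outdir / "lifetimes.json", "w") as fh:
            json.dump(lifetimes, fh, indent=2)
        results["hbonds"] = {"counts": counts, "lifetimes": lifetimes}
        log.info("hbond stage done in %.2f s", time.time() - t0)

    if "network" in stages:
        t0 = time.time()
        net = network.connection_probabilities(
            replicas, analysis_ids, criterion, tables=tables
        )
        rows = []
        for i, a in enumerate(net.residues):
            for j, b in enumerate(net.residues):
                if i < j:
                    rows.append(
                        {
                            "res_a": a,
                            "res_b": b,
                            "probability": net.probability[i, j],
                            "se": net.se[i, j],
                        }
                    )
        pd.DataFrame(rows, columns=["res_a", "res_b", "probability", "se"]).to_csv(
            outdir / "connections.csv", index=False
        )
        results["network"] = net
        log.info("network stage done in %.2f s", time.time() - t0)

    if "conformers" in stages:
        t0 = time.time()
        rows = []
        for pair in config.residue_pairs:
            a, b = int(pair[0]), int(pair[1])
            atoms = (pair[2], pair[3]) if len(pair) > 3 else (None, None)
            d = conformation.residue_distances(replicas, a, b, *atoms)
            rows.append(
                {
                    "res_a": a,
                    "res_b": b,
                    "atom_a": d.atom_a,
                    "atom_b": d.atom_b,
                    "mean": d.mean,
                    "se": d.se,
                }
            )
        if rows:
            pd.DataFrame(rows).to_csv(outdir / "distances.csv", index=False)
        dihedrals = {}
        for res in analysis_ids:
            resname = replicas[0].resname_of(res).upper()
            if resname not in conformation.CHI_ATOMS:
                continue
            try:
                series = conformation.chi_distributions(replicas, res)
            except KeyError as exc:
                log.warning("skipping χ angles of residue %s: %s", res, exc)
                continue
            for s in series:
                centres = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
                pd.DataFrame({"angle": centres, "density": s.density}).to_csv(
                    outdir / f"dihedral_res{res}_chi{s.chi}.csv", index=False
                )
            dihedrals[res] = series
        if config.updown:
            ud = config.updown
            d = conformation.residue_distances(
                replicas,
                int(ud["residue"]),
                int(ud["reference"]),
                *(ud.get("atoms", (None, None))),
            )
            labels, fractions = conformation.classify_up_down(
                d.distances, float(ud.get("threshold", 11.5))
            )
            pd.DataFrame([fractions]).to_csv(outdir / "updown.csv", index=False)
        results["conformers"] = {"distances": rows, "dihedrals": dihedrals}
        log.info("conformation stage done in %.2f s", time.time() - t0)

    log.info("pipeline finished in %.2f s", time.time() - t_start)
    return results
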