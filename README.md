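# porewater

Channel hydration, water mobility, hydrogen-bond lifetime and water-wire
connectivity analysis for molecular-dynamics trajectories of membrane
proteins — built for proton-uptake channels such as the K-channel of
cytochrome *c* oxidase, but generic over any residue-lined pore.

Given a topology and one or more trajectory replicas (or a synthetic
trajectory from the built-in generator), the package computes:

- **Channel geometry** — the per-frame channel interior as the convex hull
  ("volume-maximal polyhedron") of the centres of mass of configurable
  corner residues; an enveloping analysis cylinder (default radius 9.5 Å)
  anchored on the median structure, discretised into 15 axial slices of
  2 Å, concentric rings at radii 1.0/3.5/5.0/9.5 Å, and 30° segments.
- **Hydration** — instantaneous water counts in polyhedron and cylinder,
  per-slice occupancy profiles, cumulative profiles, and 2D occupancy
  projections, replica-averaged with standard errors.
- **Water mobility** — slice-resolved diffusion coefficients from the
  single-lag mean squared displacement,

  $$D_s = \frac{1}{N_s}\sum_{w,t}\frac{\lVert x_{w,s}(t) - x_{w,s}(t-\tau)\rVert^2}{6\tau},$$

  with displacements credited to the start slice, a 95 %-empty rule, and
  $N_s$-weighted replica averaging, plus an axial/radial/angular
  decomposition of the MSD.
- **Hydrogen bonds** — geometric detection (donor–acceptor ≤ 3.5 Å,
  D–H⋯A deviation from linear ≤ 35°), per-residue bond counts, and
  *any-water* continuous survival lifetimes from the autocorrelation
  $C(\tau) = \langle \sum h(t_0)h(t_0{+}\tau)/\sum h(t_0)^2\rangle$
  fitted with $C(t) = A e^{-t/\tau_1} + B e^{-t/\tau_2}$, $A+B=1$,
  reporting the weighted lifetime $\tau = A\tau_1 + B\tau_2$.
- **Connectivity networks** — per-frame graphs over residues and waters
  with hydrogen bonds as edges; shortest-path (Dijkstra, unit weights)
  existence between residue pairs, counted over frames into
  water-mediated connection probabilities.
- **Side-chain conformations** — χ1–χ4 dihedral distributions, residue
  distance series under polar-atom or Cα conventions, and up/down state
  classification against a distance threshold.

All multi-replica statistics follow one convention: average within each
replica, then across replicas, reporting the standard error of the replica
means.

## Worked example

Three synthetic replicas of a 30 Å channel holding 30 Brownian waters
(D = 0.2 Ų/ps, dt = 2 ps), analysed exactly like a real trajectory:

```python
from porewater import build_cylinder, build_polyhedron
from porewater.synthetic import SyntheticChannelSpec, simulate_waters
from porewater.hydration import hydration_summary
from porewater.mobility import slice_msd, slice_occupancy_fraction, diffusion_profile

spec = SyntheticChannelSpec(n_waters=30, n_frames=2000, diffusion=0.2, seed=1)
replicas = [simulate_waters(SyntheticChannelSpec(n_waters=30, n_frames=2000,
                                                 diffusion=0.2, seed=s))
            for s in (1, 2, 3)]
cylinders = [build_cylinder(fr, 0, spec.bottom_ids, spec.top_ids) for fr in replicas]
polys = [[build_polyhedron(fr, t, spec.corner_ids) for t in range(fr.n_frames)]
         for fr in replicas]

summary = hydration_summary(replicas, polys, cylinders[0])
print(f"waters in polyhedron: {summary.mean_waters_polyhedron:.1f} ± {summary.se_waters_polyhedron:.1f}")
print(f"waters in cylinder:   {summary.mean_waters_cylinder:.1f} ± {summary.se_waters_cylinder:.1f}")
print(f"polyhedron volume:    {summary.mean_volume:.2f} nm³")

msds = [slice_msd(fr, cy) for fr, cy in zip(replicas, cylinders)]
occs = [slice_occupancy_fraction(fr, cy) for fr, cy in zip(replicas, cylinders)]
prof = diffusion_profile(msds, occs, cylinders[0])
print(f"D_s at height +0 Å:  {prof.ds[7]:.3f} ± {prof.spread[7]:.3f} Å²/ps  (Ns = {prof.ns[7]})")
```

prints

```
waters in polyhedron: 13.3 ± 0.1
waters in cylinder:   30.0 ± 0.0
polyhedron volume:    3.00 nm³
D_s at height +0 Å:  0.192 ± 0.002 Å²/ps  (Ns = 12206)
```

The box scaffold's hull is exactly 3 nm³; all 30 confined waters stay in
the cylinder while on average 13.3 occupy the hull (≈ the hull/cylinder
volume ratio); the mid-channel diffusion coefficient recovers the
generating 0.2 Ų/ps up to the small reflecting-wall bias of the confined
walk.

## Command line

```bash
porewater run-all   --config run.yaml            # every stage
porewater mobility  --config run.yaml --out out/  # one stage
porewater simulate  --config run.yaml             # write synthetic PDB + DCD
```

The YAML config names the topology and per-replica trajectory files (PDB +
DCD/XTC) or a `synthetic:` section for the generator, the corner/marker/
analysis residue selections, cylinder and H-bond parameters, the
equilibration discard (default: leading 20 % of each replica), and the
seed.  Outputs are tidy CSV/JSON tables (occupancy and diffusion profiles,
bond counts, survival curves, lifetime fits, connection edge lists,
dihedral histograms, distance summaries).

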