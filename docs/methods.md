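# Methods

This note records the models and estimators the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions frozen by the test suite.

## Channel geometry

The channel interior of a frame is the convex hull of the centres of mass
(standard atomic masses over all residue atoms) of a configurable set of
corner residues lining the pore.  The convex hull is the unique
volume-maximal polyhedron on fixed vertices, which makes the construction
well defined without any cavity-detection heuristics.  Hull volumes are
reported in nm³ (Å³/1000).  Fewer than four corner centres, or a
(near-)coplanar set, raises a degenerate-geometry error naming the
offending residues.  Point-inclusion tests use the hull's facet
half-spaces with the boundary counting as inside (tolerance 1e-9 Å by
default; tests that compare against the independent tetrahedral
decomposition oracle use a matched tolerance on both sides).

The analysis cylinder is anchored on a *median structure*: the frame with
the lowest RMSD (no refitting) to the coordinate-wise mean structure over
a configurable window, ties broken to the lowest index.  Its axis runs
from the Cα centre of mass of the lowermost residues to that of the
uppermost, elongated by 10 % (5 % beyond each end) to cover the channel
mouths, then capped — or padded, for short axes — symmetrically about the
midpoint so the axis always carries exactly `n_slices × slice_thickness`
of sliced height (defaults 15 × 2 Å = 30 Å).  Heights are signed, with
origin at the axis midpoint and positive toward the top (reaction-centre)
end, so residues near the channel entrance get negative heights.

Cells are (slice, ring, segment) triples: slices are half-open `[low,
high)` intervals with the topmost closed; rings use radii
(1.0, 3.5, 5.0, 9.5 Å] inclusive on the upper edge — four rings, since
only four intervals are well defined, configurable for other
discretisations; segments are 30° sectors `[0°, 30°)` etc. measured in a
deterministic in-plane basis (the basis vector is the axis-orthogonalised
Cartesian axis least aligned with the cylinder axis, so results are
reproducible across runs).  A radial distance of exactly 0 falls in
segment 1 by convention.  Points beyond the radius or the sliced height
map to the sentinel `OUTSIDE`.  These boundary conventions are frozen by
tests.

## Hydration

A water is a residue whose single oxygen atom stands for the molecule.
The *ever-visited set* — waters whose oxygen enters the polyhedron in at
least one frame — gates which waters the channel analyses consider; the
reported "waters in polyhedron/cylinder" are instantaneous per-frame
occupancies averaged over frames, not the size of that set, because an
average occupancy is what a hydration level means.  Slice profiles are
mean per-frame counts per slice (not probabilities), so they sum exactly
to the mean in-cylinder count; cumulative profiles are prefix sums from
the channel entrance upward.  The 2D projection bins in-cylinder oxygens
on (height, signed in-plane coordinate along a configurable azimuth,
default 0°) and divides by the frame count, preserving the same total.

## Water mobility

Diffusion coefficients are single-lag MSD estimates per slice:
`D_s = (Σ|Δx|²/N_s)/(6τ)` with τ defaulting to one frame spacing (2 ps).
Every consecutive frame pair is a time origin (overlapping origins
maximise statistics; the estimator is a mean, so overlap biases nothing).
Displacements are credited to the slice occupied at the *start* frame;
waters outside the cylinder at the start contribute nothing even if they
end inside.  A slice empty in more than 95 % of a replica's frames is
reported as D_s = 0 with an insufficient-data flag; the rule is applied
per replica before averaging.  Replica values are combined with weights
N_s and the quoted spread is the N_s-weighted standard deviation of the
replica values.  The MSD decomposes into axial (projection on the axis),
radial (projection on the radial unit vector at the start point) and
angular (residual) squared components, which sum to the total exactly; a
start point on the axis has no radial direction and its in-plane motion
counts as angular.

With D ≈ 0.2 Ų/ps and 2 Å slices at dt = 2 ps the per-frame probability
of crossing more than one slice is small (the RMS axial step is
√(2·0.2·2) ≈ 0.9 Å), which keeps the start-slice attribution meaningful.

## Hydrogen bonds and lifetimes

A bond exists when the donor–acceptor distance is ≤ 3.5 Å *and* the
D–H⋯A angle (measured at the hydrogen) deviates from linear by ≤ 35°,
both boundaries inclusive.  Donor/acceptor atoms come from a small
built-in chemistry table (hydroxyl, carboxyl/carboxylate, amine/ammonium,
imidazole tautomers, amide, water, hydronium), configurable; a donor whose
listed hydrogens are absent from the topology is a configuration error.
Intra-residue pairs are excluded.  Bond counts are counts of bonds, not of
distinct water partners: a water donating twice to the same residue
contributes two.

Lifetimes are *continuous, any-water* survival times: h(t) = 1 iff the
residue has at least one bond to any water (identity free to change) in
frame t.  Time origins are spaced 120 ps apart — strictly more than the
100 ps maximal lag, so per-origin windows never overlap — and an origin
with h(t₀) = 1 survives lag τ iff h = 1 at every frame of [t₀, t₀+τ].
Since h is binary the autocorrelation denominator Σh(t₀)² is simply the
number of bonded origins.  C(τ) is fitted with
A·exp(−t/τ₁) + B·exp(−t/τ₂) under A + B = 1, A ∈ [0,1], τ₁,τ₂ > 0,
via bounded least squares with a multi-start grid over
τ₁ ∈ {2, 10} ps, τ₂ ∈ {50, 200} ps, A ∈ {0.3, 0.7} (best residual wins);
the time constants are ordered τ₁ ≤ τ₂ by swapping weights.  The reported
lifetime is A·τ₁ + B·τ₂, replica-averaged; a lifetime whose standard
error across replicas exceeds its mean is reported as N/A, as are
all-failed fits.  A consequence worth recording: for three non-negative
replica values SE ≤ mean identically (equality only when two values are
zero), so in practice the N/A rule fires through failed or degenerate
fits rather than through scatter.

## Connectivity networks

Each frame's bonds induce a simple undirected graph over residues, waters
and the hydronium; parallel bonds collapse to one edge.  Two residues are
connected when a shortest-path search (Dijkstra with unit edge weights,
which reduces to reachability and is tested against an independent BFS
oracle) finds any path; a direct residue–residue bond is a path of length
one.  Connection probabilities are fractions of connected frames,
computed per replica and then averaged with the standard error of the
replica means; the matrix is symmetric with diagonal 1 by convention.

## Conformations

Dihedrals follow the IUPAC sign convention, reported in (−180°, 180°]
with −180° mapped to +180°; χ1–χ4 atom quadruples for Ser, Thr, Tyr,
His (all tautomer names), Glu and Lys (plus protonation variants) are
built in, and nonstandard residues — including cross-linked ones — use
the standard definitions of their parent type.  Histograms default to 5°
bins and are normalised to integrate to 1 over degrees.  Residue–residue
distances default to the polar side-chain atom convention (hydroxyl O for
Ser/Thr/Tyr, Nζ for Lys, Cε1 for His, Cδ for Glu — the atoms bridging the
titratable protons), with Cα available for backbone channel-width
measures.  The up/down classifier labels a frame "up" when the distance
to the reference residue is at most the threshold (default 11.5 Å, the
midpoint between the observed ~8–11 Å "up" and ~12.4–13.2 Å "down"
distance bands for a lysine–tyrosine pair; thresholds are configurable
because no universal cutoff exists).

## Synthetic ground truth

The generator emulates the statistical structure the estimators assume,
not the physics that produces it:

- a static box (default 10 × 10 × 30 Å, hull exactly 3 nm³) or prism
  scaffold of single-atom corner pseudo-residues, with optional marker
  residues at prescribed heights and an optional fixed hydronium;
- waters as independent Gaussian walks (variance 2·D·dt per axis,
  defaults D = 0.2 Ų/ps, dt = 2 ps — channel-water scale) mirror-reflected
  at a confinement cylinder (default radius 8.5 Å, inside the 9.5 Å
  analysis radius so no generated water ever exits the analysis volume);
  reflecting rather than absorbing/periodic boundaries keep the occupancy
  stationary, which makes hydration and diffusion expectations exact;
- donor–water pairs that toggle between a bonded geometry (2.8 Å,
  collinear) and an unbonded one (5 Å) under a two-state Markov chain
  with geometric dwell lengths of prescribed means; pairs are spaced 5 Å
  apart so they cannot cross-bond; an injection hook substitutes
  caller-supplied h(t) sequences when a test wants to bypass geometry.

All randomness flows through one seeded generator: identical specs give
bit-identical trajectories.  What the generator does *not* emulate —
water–water correlations, rotational dynamics, realistic bond-vector
geometry fluctuations, anisotropic or position-dependent diffusion,
protein flexibility — bounds what passing tests prove: they validate the
estimators against known statistical ground truth, not the biology of any
particular channel.

Two discretisation effects are worth knowing when reading recovery tests.
A geometric dwell of mean m frames has continuous survival (1 − 1/m)^k,
so a 20 ps dwell at dt = 2 ps yields a fitted weighted lifetime of
−dt/ln(0.9) ≈ 19.0 ps, not 20.0 — an inherent ~5 % discretisation offset,
inside the 15 % recovery band the tests assert.  Likewise reflecting
walls slightly depress single-lag MSD estimates (~4 % for D = 0.2 Ų/ps
in the 8.5 Å default cylinder); recovery tests that target the generating
D itself therefore use a wide confinement where the wall effect is
negligible.

## Problem sizes and numerics

Recovery analyses use 50 waters × 10⁴ frames for diffusion (≈ 5 × 10⁵
observations), 10⁵ frames for Markov lifetime recovery, and 500-frame,
20-water channels for end-to-end runs — sizes at which the estimators'
sampling error is comfortably inside the asserted tolerances while a full
suite run stays fast.  Least-squares fits run with xtol/ftol/gtol 1e-14;
hull computations delegate to Qhull; angle computations clip cosines into
[−1, 1] before arccos.  Boundary cases (bond distance exactly 3.5 Å,
deviation exactly 35°, slice tops, ring edges, r = 0, −180° dihedrals)
are resolved as stated above and pinned by tests.

## Known limitations

- Single-lag diffusion only; no Einstein–Helfand long-lag fits or
  velocity autocorrelation estimators.
- Continuous (not intermittent) bond survival; no Luzar–Chandler
  reactive-flux kinetics; no per-partner lifetimes (aggregation over
  water identity is deliberate).
- No per-frame trajectory re-fitting/alignment: the analysis assumes the
  channel does not drift appreciably relative to the median structure.
- The chemistry table covers common polar side chains and water species;
  exotic residues need explicit table entries.
- Connection probabilities use path existence only; no path-length or
  flow statistics.
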