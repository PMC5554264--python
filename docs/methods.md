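# Methods

This note records the scientific and numerical choices behind
`cardiolattice`, in the order the pipeline runs: tissue growth,
morphometrics, gap-junction labelling, wave propagation, and the
measurement protocols. It also states what the virtual experiments do and
do not establish about real cardiac cultures.

## Tissue-growth model

Cells live on a square lattice of 2.5 µm subcells (the standard
cellular-Potts resolution for eukaryotic cells); each cell is the set of
subcells carrying its index, kept 4-connected at all times. The energy has
four state terms:

* **Adhesion** `J(τi,τj)` per heterotypic neighbour pair. The adhesion
  neighbourhood (and the copy-source choice) is the 8-neighbour Moore
  stencil, the common convention; cell connectivity uses the 4-neighbour
  stencil. Out-of-lattice sites count as medium (closed boundary).
* **Area elasticity** `λ(v − Vᵗ)²` per cell, with `v` in subcells.
* **Protrusion potential** `G/ρ` per focal-adhesion site, distance `ρ`
  measured from the cell's (continuously maintained) centre of mass. On a
  nanofibre subcell the projection argument replaces `ρ` by
  `ρ·|cos α|`, `α` the angle between the fibre axis and the direction from
  the centre of mass; alignment is axial, so the cosine enters in absolute
  value, and is clamped below at 0.1 so the projected force never diverges
  nor pulls backwards. `ρ` itself is floored at half a subcell.
  The potential acts as a *field* sourced at the quasi-static centre of
  mass: only a moved attachment site does work in it (no back-reaction on
  the centre of mass enters ΔH). With exact back-reaction the published
  parameters freeze the dynamics — interior adhesions at small ρ carry
  `G/ρ²` gradients that veto every move at T = 1 — so the field reading
  is the only one under which the model moves at all.
* **Stiff nucleus**: a copy that converts a subcell within 7 µm of the
  invaded cell's centre of mass (medium or another cell pushing into the
  nucleus region) pays `P_N = 2 P_detach` of that cell. Like the
  detachment penalties this is a per-event cost, not stored energy: a
  state-energy reading with centre-of-mass back-reaction makes the term
  fire continuously for cells thinner than the nucleus diameter (fibre-
  aligned spindles) and freezes the tissue.

Two transition penalties enter ΔH without being state energy: `P_detach`
when a copy overwrites an existing focal adhesion (the adhesion is lost),
and `P_unleash` when a fibre-anchored adhesion site attempts to copy onto
a non-fibre subcell (fibre→fibre and substrate→fibre moves are free).

**Focal-adhesion bookkeeping.** Cells start with no adhesions. Whenever an
accepted copy expands a cell whose adhesion count is below its quota
`N_protr`, the newly gained subcell becomes an adhesion. An adhesion
moves in two ways: an accepted expansion whose source subcell is an
adhesion carries the adhesion to the new tip, and a same-index copy
attempt whose source is an adhesion hops the site to the target subcell
of its own cell (the protrusion-tip migration channel; such hops pay
`P_unleash` when leaving a fibre and `P_detach` when landing on — and
destroying — another attachment). Adhesion destruction (by overwrite or
by hop collision) is non-conservative: the stored `G/ρ` potential is not
released, only `P_detach` is charged. Without the hop channel the
initial elastic inflation buries every adhesion in the cell interior and
no preset elongates; with reclaimable destruction energy the published
on-fibre parameters (`G/ρ > 8 P_detach` at the membrane) would make
adhesions self-destruct.

**Forbidden moves.** A copy is rejected outright — before any energy
evaluation — if it would (i) remove a cell's last subcell, (ii) break the
cell's 4-connectivity, or (iii) extend the cell farther than `L_MAX` from
its centre of mass. The connectivity test first applies the local
Moore-ring arc criterion (sufficient); only inconclusive cases run a flood
fill bounded by the cell's bounding box, which keeps the check O(cell)
rather than O(lattice).

**Dynamics.** One Monte-Carlo step (MCS) performs rows×cols copy attempts
(uniform target, uniform Moore-neighbour source), each accepted with
`min(1, e^{−ΔH/T})`. ΔH is evaluated incrementally but exactly: adhesive
terms are recounted locally, elastic terms in closed form, the nucleus and detachment penalties added per event, and the
protrusion field work added for moved attachment sites;
the incremental value equals the from-scratch recomputation of the same
quantities to 1e-9 (property-tested over >= 1e4 accepted moves). Every
attempt consumes exactly three uniform draws, plus one for the Metropolis
test when ΔH > 0 — the whole trajectory is reproducible from the seed.

**Units.** The published parameter table mixes length-bearing units that
do not close dimensionally against the lattice Hamiltonian. The
convention adopted here (chosen once, at preset load): `J` and `T` are
dimensionless energies with areas in subcells; `G`, `P_detach`,
`P_unleash` are multiplied by `ENERGY_LENGTH_SCALE` = 2000; `λ` is
multiplied by `ELASTIC_AREA_SCALE` = 4; lengths (`L_MAX`, nucleus
radius) convert µm → subcells and target areas µm² → subcells. The two
factors are not recoverable from the printed units, so they were
calibrated once against the published cell-shape statistics — the same
data the original Monte-Carlo parameter fit targeted — plus the
requirement that monolayers reach confluence: the protrusion scale was
scanned over {400…4000} on the isolated-cell presets, the elastic scale
over {1, 4, 6.25, 39} (too soft and confluent monolayers never close
their interstitial gaps against the large cell–cell adhesion energies;
too stiff and isolated fibroblasts lose their concavity). At (2000, 4)
the three headline shape statistics sit well inside one experimental SD
and monolayers reach ~90% substrate coverage.

**Seeding.** The sample is divided into the preset's grid of areas; each
area receives one square seed of side `√(Vᵗ/10)` at a uniform-random
admissible offset. Types are a seeded random permutation matching the
requested fibroblast fraction with largest-remainder rounding. Nanofibres
are parallel one-subcell rows at a default pitch of 4 subcells (10 µm) —
the published experiments fixed a single (unstated) fibre density; this
default puts several fibres under every cell. L-shaped domains are a mask
of two orthogonal arms; growth and waves are confined to it.

## Morphometrics

Computed per cell on its binary mask: area (subcells × 6.25 µm²); convex
coverage = area / hull area with the hull taken over subcell *corner*
points so convex raster shapes score exactly 1; caliper elongation = long
over short side of the minimum-area bounding rectangle of the hull
(rotating-calipers extremes — an axis-aligned square scores 1, not √2);
protrusion count = endpoints of the morphological skeleton after removing
the part within 7 µm of the centroid, computed at 1.0 µm (nearest-
neighbour upsampling) and at the native 2.5 µm ("convexes", where the
coarser raster averages some protrusions out). Endpoints are skeleton
pixels with exactly one 8-connected skeleton neighbour; endpoints sitting
on the central cut are excluded (they are artefacts of the removal, not
tips). The per-type summary is mean ± SD; `shape_fitness` is the summed
squared z-distance to a reference report — the objective a parameter
search would minimise.

## Gap-junction labels and conductances

A secondary Potts-like model distributes binary "more-GJ" labels over each
cell's subcells with the cell map frozen. Labels start as a two-subcell
ring around each focal adhesion (clipped to the cell) — the "surrounding
of the attachment sites" — and evolve by label swaps between neighbouring
subcells of the same cell (conserving each cell's label count) under

`H = Σ pairs + Σ_more-GJ G/ρ(i, cm)`,

where a more-GJ/more-GJ pair within one cell costs `J_B = 10` (labels
disperse along the border), the same pair across a cell–cell contact is
free (an end-to-end connection), and a more-GJ label facing another cell's
less-GJ subcell costs `J_H = 2` (labels prefer to pair up across
contacts); `G = 25`. One hundred MCS at `T = 1` is enough for the label
field to settle (it is frozen-in well before that on test meshes).

Faces then receive: `D_in` within a cardiomyocyte; `D_end` across CM–CM
border faces where a more-GJ subcell exists on both sides of the border
within a two-subcell patch radius — paired labels mark a gap-junction
plaque whose conducting patch spans a few subcells of the shared
membrane, not a single 2.5 µm lattice face (with the strict per-face
rule, junctions of one or two faces cannot charge a ~90-subcell
downstream cell past threshold and the conduction graph fragments);
`D_side` across other CM–CM faces; and 0 for any face touching medium, a
fibroblast, or a CM–FB contact — fibroblasts are unexcited obstacles in
this study. `D_in = 1 cm²/s` (the highest coefficient used); the
headline studies use `D_end = 0.01·D_in` (isotropic) / `0.02·D_in`
(anisotropic) and `D_side = 0`.

## Monodomain solver

`∂V/∂t = ∇(D∇V) − (I_ion + I_stim)/C_m` with per-face `D`. The
alternating-direction implicit scheme advances two half-steps per step:
diffusion implicit along one axis (independent tridiagonal systems per
row/column, solved exactly by the Thomas algorithm) and explicit along the
other, axes swapped in the second half-step. Reaction rates are evaluated
once per full step from the step-n state and added in both half-steps;
gates advance once per full step (forward Euler). The scheme is
unconditionally stable for the diffusion part — the operating point
h = 2.5 µm, dt = 1 ms, D = 1 cm²/s (diffusion number ≈ 8000) runs 300
steps without divergence, where an explicit method would need ~ns steps.
At such diffusion numbers the scheme is not monotone (transient over- and
undershoots), so the surrogate's kinetics are evaluated on a clipped copy
of V to keep the recovery equation away from its `1/(µ₂+V)` pole.

**Ionic surrogate.** The default reaction is a two-variable
Aliev-Panfilov-type activator–inhibitor (k = 8, a = 0.10, ε₀ = 0.002,
µ₁ = 0.2, µ₂ = 0.3), V dimensionless in [0, 1], activation threshold at
50% amplitude. Its time scale (2.5 ms per dimensionless unit) was chosen
so that on sub-millimetre meshes the depolarisation length
`√(D_eff·τ_up)` stays well below the domain and excitation crosses
gap-junction faces with a comfortable safety factor; with the literature
mapping of ~13 ms the front is wider than the 0.8 mm tissue and no
travelling wave fits. Any model implementing the `IonicModel` contract
(resting state, rates, threshold) can replace it; the published detailed
neonatal-rat ventricular model would slot in here.

The default integration step for the surrogate is dt = 0.1 ms; the 1 ms
step is retained as a stability test case. Activation time per pixel is
the first upward threshold crossing, linearly interpolated in time.

## Measurement protocols

Velocities are read from activation maps. On cellular meshes with
`D_side = 0`, conduction is percolation-like and single-pixel line
sampling is dominated by junction detours, so the estimators pool:
`conduction_velocity` fits time against distance over a ±band of parallel
lines; `axis_velocity` pools the two opposite angular wedges of an axis
around a point stimulus in a single fit. Activation maps are first
smoothed with a 50 µm normalised-convolution Gaussian (NaN-aware); this
mirrors the optical-mapping processing chain, where arrival times are read
from Gaussian-blurred fluorescence movies (250/300 µm kernels at the
published 5 mm scale; 50 µm keeps the same kernel-to-domain proportion at
0.8 mm). `optical_smoothing` applies the full-size kernels to voltage
frames for rendering.

* **Isotropy study**: no-fibre monolayer preset, 0.8 × 0.8 mm, 30%
  fibroblasts, central point stimulus (40 µm electrode footprint),
  orthogonal axis-velocity ratio, averaged over seeds.
* **Anisotropy study**: on-fibre monolayer preset at 35% fibroblasts on an
  L-shaped domain (arms 0.4 mm wide, fibres parallel to the horizontal
  arm), stimulus at the junction of the arm middle lines; each arm's
  speed is the leading wavefront arrival time fitted against distance
  (earliest activation across the arm cross-section per station), and
  the ratio longitudinal/transversal is the functional anisotropy. The
  L geometry avoids wavefront-curvature bias, as in the original
  protocol. Couplings: `D_end = 0.02·D_in`, `D_side = D_end/2` — with
  `D_side` exactly zero the transversal front stalls within ~0.1 mm at
  this reduced arm width (row-to-row end-end links are too sparse to
  percolate), while the original parameter study spans nonzero
  side-to-side couplings. Samples without measurable propagation are
  excluded from the ratio statistic, as in the experimental protocol.

## What the synthetic tissue does and does not capture

The generator reproduces: polygonal spreading shapes anchored at a
discrete number of adhesion sites, the coverage gap between cardiomyocytes
and fibroblasts, fibre-guided elongation, confluent monolayer packing with
a fibroblast fraction, and junction-limited, zig-zag conduction. It does
not include cell division or death, migration-driven sorting, per-cell
parameter variability (every CM shares one parameter set, so simulated
shape variances are narrower than measured ones), three-dimensionality, or
a biophysically detailed ionic model. Passing acceptance therefore shows
that the growth rules and coupling rules jointly reproduce the *measured
shape statistics* and the *measured anisotropy range* — not that the
surrogate's action potential matches real neonatal-rat electrophysiology.

## Problem sizes and realisation noise

All wave studies run on 320 × 320 lattices (0.8 × 0.8 mm, the native
monolayer-preset sample size), three seeds each; morphometrics run one
full preset sample (400 × 400, 50–119 cells for the isolated presets).
At this scale a single seed's velocity ratio carries ~10% realisation
noise from the random contact network (the original optical-mapping
fields were several millimetres), which is why ratios are reported as
means over seeds. Growth determinism is bit-exact per seed; solver
results are deterministic given the mesh.

## Known limitations

* The unit convention for the published parameter table is a
  reconstruction (see above); the table's printed units are internally
  inconsistent, and the ×400 reading was fixed from commensurability.
* The label-model quota ("ring" size) around adhesions is not specified in
  the source material; one subcell is the default and it is configurable.
* `P_detach` applies to any destroyed adhesion; with this bookkeeping the
  destroyed adhesion always belongs to the invaded cell.
* Activation-map-based velocities are biased low in regions reached by
  detours; the smoothing + pooling estimators reduce but cannot eliminate
  this at 0.8 mm scale.
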