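# Methods

## Problem and model

`crowdcrush` simulates what happens to a densely packed *standing* crowd
when the space it occupies shrinks — the mechanism behind crush-asphyxia
disasters, where virtually all deaths are caused by chest compression
rather than trampling. The model is deliberately minimal: a rectangular
enclosure with three fixed walls and one movable "piston" wall, filled with
a hexagonally packed crowd that has nowhere to escape, and a
quasi-static compression protocol in which the piston advances in steps and
the crowd settles to mechanical equilibrium before each measurement.

Each agent is an ellipse in plan view (semi-axes 0.25 m × 0.125 m — half a
0.5 m shoulder width and half a 0.25 m chest depth), mass 50 kg, with a
random initial orientation. The dynamics are two-dimensional: we do not
model vertical motion, falling, or climbing over others. Torso
compressibility is represented instead by *finite contact stiffness*:
agents are not hard bodies, and under piston load their footprints
interpenetrate. This is essential — rigid non-overlapping ellipses of this
size cannot exceed ≈ 9.2 bodies/m² in the plane, while compressed real
crowds (and this model) register far higher local densities because chests
compress.

## Forces

* **Personal-space repulsion.** For agent *i* with neighbour set
  N_i = { j : |p_i − p_j| < D },

      F_r(i) = Σ_{j∈N_i} (p_i − p_j) · C · w_ij,   w_ij = max(0, 1 − d_ij/D).

  The weight *decreases* with distance, so the force is strongest for close
  neighbours and fades continuously to zero at the cutoff D. (A weight that
  *grows* with distance would make "repulsion" strongest between the most
  separated pair, which contradicts its purpose; we adopt the decreasing
  form.) Note the un-normalised difference vector: the magnitude is
  C·d·(1 − d/D), zero both at contact and at the cutoff. At crowd-packing
  distances this force shapes the loose initial arrangement; once the
  piston load dominates it is negligible compared to contacts.

* **Contacts.** Each elliptical footprint is approximated by three circles
  of radius b = semi_minor whose centers sit at −(a−b), 0, +(a−b) along the
  body's major axis (exact for the 2:1 aspect ratio used here in the sense
  that the circles reproduce the ellipse's width everywhere to within a few
  per cent, and there is no closed form for ellipse–ellipse distance).
  Every overlapping circle pair receives a penalty force
  k·δ + c·(closing speed) along the center line, applied at the
  mid-overlap point (equal and opposite by construction, torque-consistent).
  The dashpot term is clamped so the total normal force is never adhesive.

* **Walls.** The same penalty law (stiffness k_w) against the three fixed
  planes and the moving piston plane, evaluated per contact circle.

## Integration and quasi-statics

Semi-implicit Euler with dt = 10⁻³ s. After the force update, each linear
velocity is multiplied by (1 − linear_damping·dt)(1 − γ) and each angular
velocity by (1 − angular_damping·dt)(1 − γ), with per-body damping 0 (linear)
and 0.05 (angular) and a global dissipation γ = 0.05 per step. The global
factor overdamps the system (velocity memory ≈ 20 steps), which is what
makes displacement-controlled compression quasi-static: the crowd is always
within a hair of force balance. Equilibrium is declared when total kinetic
energy stays below `relax_tolerance` = 10⁻³ J for 25 consecutive steps (the
consecutive-step window exists because a freshly packed crowd starts at
exactly zero kinetic energy while still carrying unbalanced forces).

Piston modes:

* **displacement-controlled** (default, used for all reported protocols):
  the piston plane advances at 0.1 m/s to the target displacement, then the
  crowd relaxes.
* **pressure-controlled**: the piston is a damped 1-DOF body of 500 kg
  loaded with 4450 N per metre of wall length (the classic estimate of
  dangerous crowd pressure) and settles where the crowd's penalty reaction
  balances the load (verified to 0.01% on a single-row configuration).

Default constants: C = 200 N, D = 0.6 m, k = k_w = 10⁵ N/m,
c = 10³ N·s/m. k is sized so an agent bearing its share of the 4450 N/m
line load penetrates a few centimetres — the intended "chest compression"
scale. With dt·sqrt(k/m) ≈ 0.045 the penalty springs are integrated well
inside the stability limit.

Determinism: all randomness (initial orientations; the seeded fallback
direction for exactly coincident contact circles) derives from the scenario
seed. The spatial-hash neighbour search (cell size max(D, 2a)) sorts each
agent's candidate list so that force accumulation order is identical to the
all-pairs loop; trajectories are bit-identical between the two paths and
across reruns.

## Scenarios

Three presets share a 10.27 m wall, 20 agents per row, and a near-identical
starting density of 7.0–7.4 people/m²:

| preset   | N   | enclosure        | piston schedule (m)               |
|----------|-----|------------------|-----------------------------------|
| crowd200 | 200 | 10.27 m × 2.76 m | 0.5, 1.0, 1.5, 2.0                |
| crowd300 | 300 | 10.27 m × 4.01 m | 0.5, 1.0, 1.5, 2.0, 2.5           |
| crowd400 | 400 | 10.27 m × 5.28 m | 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5 |

The hexagonal lattice uses intra-row spacing (L − 2·margin)/20 = 0.5 m with
an outer margin of 0.135 m — chosen so a 20-wide row plus the half-spacing
offset of alternate rows exactly spans the 10.27 m wall with the agents'
circumscribed circles touching within rows — and row pitch W/n_rows.
Random orientations can make diagonal neighbours overlap slightly; the
pre-compression relaxation phase resolves this before any measurement.

## Local crowd density

The estimator rasterizes every footprint at 100 px/m (pixel-center test
against the rotated ellipse) and scans the bounding box of the union of
footprints with 1 m × 1 m cells anchored at its (min X, min Y) corner,
left→right then bottom→top; trailing partial cells are evaluated as full
1 m² windows with no area renormalisation. A cell's density is
ρ_s = Σ_agents (pixels in cell)/N_a, with N_a the pixel count of a
reference agent at the same resolution (computed once, centered on a pixel
center — the least-biased single pose, within 0.2% of πab·res²). An
agent's *experienced* density is the ρ_s of the cell containing its center
(a footprint-weighted mean over overlapped cells is available behind the
`experienced="footprint"` flag).

In the default independent-occlusion mode every agent's pixels are counted
even where footprints overlap, so the field integrates to the population
(within raster error ≪ 2%) no matter how compressed the crowd is. Painter
mode assigns each pixel to the topmost (highest-id) agent, reproducing what
an opaque top-view image can measure; it is retained because it makes the
occlusion ceiling (~10.2 people/m²) demonstrable, not because it is useful
for risk assessment.

Colour scale for heatmaps: white = 0, then (0,4] blue, (4,8] green,
(8,12] yellow, (12,16] orange, (16,∞) red (the integer band edges of the
conventional 1–4/5–8/… scale read as contiguous half-open real intervals;
values above 20 clamp to red).

## A geometric ceiling on window densities

One property of the estimator deserves emphasis because it dominates the
deep-compression results. The scan window is 1 m tall, but at large piston
displacements the occupied strip is *shorter* than the window (e.g. the
200-agent scenario at d = 2.0 m leaves a 0.76 m strip). Because
independent-mode counting conserves the population, a column of windows can
never report more than the crowd's *linear* density along the wall
(≈ N/L ≈ 19.5 agents per metre for 200 agents on a 10.27 m wall),
regardless of how high the true areal density inside the strip becomes
(25.6 people/m² in that configuration). The same dilution affects the
trailing partial window row whenever the strip height is not an integer.
Consequently:

* the closed-form check “mean experienced density = N/(L·(W−d))” holds only
  while the occupied strip is at least as tall as the window and nearly an
  integer number of window rows; at deep compression the measured mean falls
  below the closed form by the strip/window area ratio, and the
  corresponding test is expected to fail there — the discrepancy is a
  property of the 1 m² scanning definition, not of the dynamics (the *areal*
  density inside the strip does match the closed form);
* exceedance fractions above thresholds near or above N/L (20 people/m² for
  the 200- and 400-agent scenarios) saturate well below 100% at deep
  compression in this model, whereas measurements taken from a rendered
  top view with a perspective camera or with three-dimensional stacking of
  bodies can report substantially higher apparent densities. The package
  reports what the conserving 2-D estimator actually measures;
* exceedance-vs-displacement curves are not guaranteed monotone: each time
  the shrinking strip height crosses an integer number of window rows, the
  trailing partial row is freshly diluted and the agents in it can drop
  back below a threshold even though the true areal density rose.

## Statistics

Per converged displacement: experienced-density histogram (bin width
1 people/m², a value the published figures do not state), the fraction of
agents whose experienced density *strictly* exceeds a threshold (10, 15 and
20 people/m² by default), and the area-reduction coordinate d/W. Series are
exported as tidy CSV and plotted as exceedance-vs-area-reduction curves.

## Problem sizes and runtime

All published-scale runs use the full populations (200–400 agents) and the
full schedules; a complete preset schedule takes tens of seconds to a few
minutes on one CPU core with the numba-compiled kernel (first call adds
~1 min of JIT compilation). Unit and property tests use 1–25 agents and
run in seconds.

## Known limitations

* Strictly 2-D: no falling, trampling, or vertical stacking — precisely the
  behaviours that dominate some real crushes.
* Penalty contacts with a single scalar stiffness summarise torso
  mechanics; no anatomy, no injury model beyond density exposure.
* The 3-circle footprint slightly fattens the ellipse near the 45° flanks.
* Pressure-controlled mode treats the piston as rigid and frictionless.
* The density estimator's window dilution at deep compression (above) is
  inherent to the 1 m² scanning definition.
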