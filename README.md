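# crowdcrush

Physics-based simulation of **static crowd compression** and the local
crowd densities that signal crush-asphyxia risk.

Nearly all deaths in crowd crushes are caused by compressive asphyxia —
people squeezed until they cannot breathe — not by trampling. `crowdcrush`
models the canonical worst case: a standing crowd packed hexagonally inside
a rectangular enclosure whose three walls are fixed while the fourth acts
as a piston, advancing into the crowd and shrinking the occupied area. It
is aimed at crowd-safety researchers and venue designers who want to relate
*area loss* to the *local density each person experiences*.

## Model in brief

* Agents are plan-view ellipses (0.5 m × 0.25 m, 50 kg) with random
  orientations, packed hexagonally at ~7.2 people/m².
* Quasi-static damped rigid-body dynamics: personal-space repulsion
  F_r = Σ_j (p_i − p_j)·C·w_ij with w_ij = max(0, 1 − d_ij/D); penalty
  contacts (3-circle footprint approximation, finite stiffness k standing
  in for torso compressibility); penalty walls; semi-implicit Euler with
  strong velocity dissipation. The piston is displacement-controlled, or
  pressure-controlled with the classic 4450 N/m dangerous-crowd line load.
* Local crowd density ρ_s (people/m²) is measured by rasterizing every
  footprint (100 px/m) and scanning 1 m × 1 m cells from the crowd's
  bottom-left corner: ρ_s = Σ_agents (agent pixels in cell)/N_a. Overlapping
  footprints are all counted ("independent" mode), so the field integrates
  to the population; an opaque-top-view "painter" mode is included for
  comparison. An agent's *experienced* density is the ρ_s of the cell
  containing its center.

Three presets reproduce the study scenarios: `crowd200`
(10.27 m × 2.76 m, piston schedule 0.5–2.0 m), `crowd300` (× 4.01 m,
0.5–2.5 m) and `crowd400` (× 5.28 m, 0.5–3.5 m), all 20 agents per row.

See `docs/methods.md` for the full model description, parameter rationale,
and known limitations — including the geometric ceiling that the 1 m²
scanning window imposes on measured densities once the compressed strip
becomes shorter than the window.

## Worked example

```sh
crowdcrush --scenario crowd200 --seed 0 --out runs/crowd200
```

runs the 200-agent protocol end to end and prints one line per converged
piston displacement (output from this exact command):

```
d=0.50 m  area_reduction= 18.1%  mean_density=  7.10  >10:   0.0%  >15:   0.0%  >20:   0.0%
d=1.00 m  area_reduction= 36.2%  mean_density=  9.39  >10:   5.0%  >15:   0.0%  >20:   0.0%
d=1.50 m  area_reduction= 54.3%  mean_density= 10.10  >10:  61.0%  >15:   0.0%  >20:   0.0%
d=2.00 m  area_reduction= 72.5%  mean_density= 16.12  >10:  94.5%  >15:  94.5%  >20:   0.0%
```

Reading: after the piston advances 2 m (72.5% of the initial area gone),
the mean experienced density is ~16 people/m² and 94.5% of the crowd sits
in cells above both the 10 and 15 people/m² marks — far beyond the
threshold where injuries are expected. The output directory contains the initial
layout, per-displacement agent states, density grids as CSV and
colour-coded PNG heatmaps (white/blue/green/yellow/orange/red for
0/≤4/≤8/≤12/≤16/>16 people/m²), per-displacement histograms, the tidy
series table `series.csv`, an exceedance-curve plot, and `manifest.json`
with everything needed to reproduce the run.

Custom scenarios are YAML files with `ScenarioSpec` keys (plus optional
`physics:`/`raster:` override sections); `--mode pressure` lets the piston
settle under its line load instead of following a displacement schedule.

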