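# g4dyn

Geometric analysis of G-quadruplex dynamics in molecular-dynamics
trajectories, with a focus on loop-base behaviour: when does a loop adenine
or thymine sit stacked on the adjacent G-quartet, how planar do the quartets
stay, and how persistent are the hydrogen bonds that hold loop conformations
together.

The package is aimed at structural-bioinformatics users who have a solvated
(and pre-imaged, solvent-stripped) multi-model PDB trajectory of a
quadruplex — e.g. the human-telomeric anti-parallel or hybrid folds — and
want reproducible per-frame geometric observables rather than visual
inspection.

## The geometry

Every observed base is fitted to a standard planar reference base by rigid
least squares over its ring heavy atoms (9 for purines, 6 for pyrimidines),
giving a base triad: center *O*ᵢ and unit normal *Z*ᵢ. Two normals are merged
by a half-angle (Rodrigues) rotation of *Z*₁ about *Z*₁ × *Z*₂ — the geodesic
bisector — and a G-quartet normal *Z*_q is built by bisecting pairwise:
(*Z*₁,*Z*₂) → *Z*_a, (*Z*₃,*Z*₄) → *Z*_b, (*Z*_a,*Z*_b) → *Z*_q, with the
quartet center *O*_q the mean of the four base centers. From two groups
(base, pair or quartet) the package derives:

- **angle** φ = arccos |*Z*₁·*Z*₂| (acute convention), and
- **stacking distance** d_z = |(*O*₂ − *O*₁)·*Z*₁₂|, the center displacement
  projected on the combined axis,
- a **stacking verdict**: stacked iff 3 Å ≤ d_z ≤ 4 Å and φ ≤ 30°
  (configurable; a documented loose preset 2.5–4.5 Å / 35° exists),
- **quartet planarity** RMSD_Z = √( Σᵢⱼ z²ᵢⱼ / Σᵢ Nᵢ ), the RMS of ring-atom
  displacements along *Z*_q measured from *O*_q, recomputed every frame,
- **hydrogen-bond occupancy and lifetime** (donor–acceptor ≤ 3.5 Å,
  D–H···A within 30° of linear; lifetimes from contiguous bonded runs times
  the frame spacing),
- **pairwise RMSD matrices**, RMSD to a reference (fit on one selection,
  measure another), and **backbone torsion rotamers** (g+/t/g− wells).

A synthetic generator (`g4dyn.synthetic_data`) builds ideal stacked quartet
layers plus loop bases at exactly specified poses, evolves them with rigid
per-base noise and an optional two-state Markov stacking switch, and returns
the ground truth — so every analysis stage is tested against known answers.

## Worked example

```python
from g4dyn import Selection, geometry_series, planarity_distribution
from g4dyn.synthetic_data import (LoopBaseSpec, MarkovSwitch, Pose,
                                  SyntheticSpec, simulate_trajectory)

spec = SyntheticSpec(
    n_layers=3, noise_t=0.15, noise_r=3.0, n_frames=2000, seed=42,
    loop_bases=(LoopBaseSpec("A", Pose(d_z=3.4, tilt=15.0, offset=1.0),
                             attach_layer=3),),
    markov=MarkovSwitch(p_leave=0.05, p_enter=0.15,
                        alt_pose=Pose(d_z=6.5, tilt=40.0, offset=2.0)))
traj, truth = simulate_trajectory(spec)

s = geometry_series(traj, Selection([13]), Selection([9, 10, 11, 12]))
print(f"d_z   = {s.mean_d_z:.2f} +/- {s.sd_d_z:.2f} A")
print(f"angle = {s.mean_angle:.1f} +/- {s.sd_angle:.1f} deg")
print(f"stacked fraction = {s.stacked_fraction:.2f} "
      f"(stationary truth {truth.stationary_stacked:.2f})")

hist = planarity_distribution(traj, Selection([1, 2, 3, 4]), n_bins=40)
print(f"layer-1 RMSD_Z: peak {hist.mode:.3f} A, width {hist.sd:.3f} A")
```

prints

```
d_z   = 4.21 +/- 1.37 A
angle = 22.0 +/- 11.4 deg
stacked fraction = 0.73 (stationary truth 0.75)
layer-1 RMSD_Z: peak 0.191 A, width 0.071 A
```

The adenine (residue 13) spends 73% of frames stacked on the top quartet
(residues 9–12) — within sampling error of the 75% stationary probability of
the configured switch; the mean distance/angle mix the stacked pose
(3.4 Å, 15°) with excursions to the unstacked one. The quartet planarity
distribution peaks at 0.19 Å with a 0.07 Å width, reflecting the injected
0.15 Å rigid-body noise.

The same analyses are available from the shell:

```sh
g4dyn synth --layers 3 --frames 200 --noise-t 0.1 --seed 7 --out run/
g4dyn stack     --traj run/synthetic.pdb --sel1 9-12 --sel2 5-8 --out run/
g4dyn planarity --traj run/synthetic.pdb --quartet 1-4 --out run/
```

Each command echoes its resolved configuration to `config.yaml` in the
output directory and writes TSV series/summaries.

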