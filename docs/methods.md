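# Methods

## Base reference frames

Each nucleobase is represented by an orthonormal triad obtained by rigid
least-squares superposition of a standard planar base onto the observed ring
heavy atoms (purines: N1 C2 N3 C4 C5 C6 N7 C8 N9; pyrimidines: N1 C2 N3 C4
C5 C6). Exocyclic substituents are excluded because they bias the fitted
plane. The standard coordinates follow the published standard reference
frame for nucleic-acid bases, translated so the ring centroid is the origin
and with sub-millidegree out-of-plane residuals zeroed, making the reference
exactly planar; the triad origin is therefore the ring centroid and the Z
axis the exact plane normal of the reference.

The superposition uses a closed-form solver
(`scipy.spatial.transform.Rotation.align_vectors`) that enforces a proper
rotation (det +1), so near-planar inputs can never produce a reflected
frame; an independent SVD-Kabsch oracle in the test suite cross-checks the
residual RMSD. Collinear inputs, for which the plane normal is undefined,
are rejected. The fit is unweighted. Because only ring atoms enter, the
syn/anti glycosidic state does not affect the frame.

## Group frames by half-angle association

Two unit normals are combined by rotating the first by half the inter-axis
angle about their cross product (Rodrigues rotation). This is the geodesic
bisector: it makes equal angles with both inputs, and for non-antiparallel
unit vectors it equals the normalized vector sum — the property the test
oracles exploit. A quartet normal is built hierarchically: members are split
into two pairs (sequence order by default, diagonal pairing available),
each pair is bisected, and the two results are bisected again. The group
center is the arithmetic mean of member centers.

Fitted normals of anti-parallel quadruplexes point to both sides of the
quartet plane, so member normals are first flipped into the hemisphere of
the first member. After flipping, any member whose |cos| against the first
is below 0.1 (within ~6° of perpendicular) is rejected as not a stacked
group. Exactly parallel inputs return the first normal unchanged (the
continuous limit); exactly anti-parallel inputs cannot survive the flip and
are an error.

Which member of a pair is rotated is immaterial (the bisector is symmetric
to machine precision), and for members within 10° of one another the two
pairing schemes agree to well under 1°, which the property tests pin down.

## Inter-group geometry and stacking

For groups (O₁, Z₁) and (O₂, Z₂): angle = arccos |Z₁·Z₂| (acute convention —
plane orientations are not physically signed, and stacking angles of
interest are all under ~45°); combined axis Z₁₂ = bisector after hemisphere
flip; d_z = |(O₂ − O₁)·Z₁₂|. The "distance" reported for stacking is this
Z-projection, not the Euclidean center distance, since it is the rise-like
quantity that stays near 3.3–3.4 Å for genuinely stacked bases regardless of
in-plane slide.

Stacking criterion: 3.0 Å ≤ d_z ≤ 4.0 Å and angle ≤ 30.0°, bounds inclusive.
Real loop bases can sit slightly closer than 3 Å while still visually
stacked, so a documented loose preset (2.5–4.5 Å, 35°) is provided; outputs
always record which criterion was active. Trajectory summaries are plain
per-frame means and standard deviations with no autocorrelation correction,
and the stacked fraction is the fraction of all frames classified stacked —
no frames are dropped.

## Quartet planarity (RMSD_Z)

Ring-atom coordinates are taken relative to the quartet center, projected on
the quartet normal, and pooled: RMSD_Z = sqrt(Σᵢ Σⱼ z²ᵢⱼ / Σᵢ Nᵢ) over the
36 guanine ring atoms. The frame is recomputed in every trajectory frame,
making the statistic exactly invariant under rigid motion. An alternative
normalization (mean of the four per-base RMSDs) is available as
`normalization="per_base"`; pooled is the default because a single RMS of
the quartet's out-of-plane displacements is the natural reading of a
quartet-level statistic, and the two differ only in how they weight a
strongly displaced single base. The trajectory-level distribution is a
probability-normalized histogram; its peak bin locates the typical
distortion and its standard deviation measures the fluctuation.

## Hydrogen bonds

A contact is bonded when the donor–acceptor heavy-atom distance is ≤ 3.5 Å
and the D–H···A angle is within 30° of linear (donor-centered convention,
matching common MD analysis tools for a 30° cutoff; the cutoffs are
configurable). With several donor hydrogens, any one passing the angle test
suffices; hydrogens are auto-detected as same-residue atoms named H… within
1.3 Å of the donor, or can be named explicitly. Rosters without hydrogens
degrade to a distance-only test and the result carries a flag.

Occupancy is the bonded fraction of frames in the (optionally windowed)
trajectory. Lifetime is the mean length of contiguous bonded runs times the
frame spacing (default 5 ps, a common trajectory writing interval); by
default a single broken frame ends a run (`max_gap=0`), since no gap
tolerance is obviously more defensible than another; bridged gaps, when
enabled, affect lifetimes only, never occupancy.

## RMSD machinery and torsions

Pairwise matrices superpose every frame pair on the fit selection (rigid
least squares) and measure RMSD over the calculation selection; fitting on
the rigid G-stem while measuring loop atoms isolates loop motion. Per-pair
superposed RMSD is not a metric; the matrices are descriptive displays of
state structure. Strided matrices are exact sub-matrices of the full one.

Torsions use the standard backbone definitions (α = O3′(i−1)–P–O5′–C5′ …
ζ = C3′–O3′–P(i+1)–O5′(i+1); χ via N9/C4 for purines, N1/C2 for
pyrimidines), IUPAC sign, wrapped to [0, 360), with rotamer wells g+ =
[0, 120), t = [120, 240), g− = [240, 360) — 120°-wide bins centered on the
canonical 60/180/300° staggered minima.

## Synthetic trajectories and what they do (not) show

The generator builds exact standard-base copies: quartet layers at rise
3.3 Å, inter-layer twist 30°, center-to-base radius 5.4 Å (typical
quadruplex stem geometry; all overridable), and loop bases at poses
(d_z, tilt, in-plane offset) relative to a chosen layer. Placement solves
the analyzer's own geometry: the loop center is displaced along the bisector
of the layer and base normals, so the analysis recovers the nominal pose to
machine precision on noiseless frames — a closure property that ties
generator and analyzer together and is asserted in the tests.

Dynamics are (i) a two-state Markov switch on one loop base (stationary
stacked probability p_enter/(p_leave+p_enter), initial state drawn from the
stationary law) and (ii) independent per-frame rigid-body noise per base:
rotation-vector components N(0, σ_r) applied about the base center and
translations N(0, σ_t) per axis. Rigid noise keeps fit RMSD at zero so the
observables measure pure pose dynamics; per-atom Gaussian noise exists as a
fitter stress-test option. One seeded generator drives everything, and the
multi-model PDB writer is fixed-format, so output is byte-reproducible.

What the generator does **not** emulate: frame-to-frame autocorrelation
(real MD displacements are strongly correlated; the independent-noise SE
formulas in the tests would be optimistic on real data), backbone
connectivity and sterics (loop bases float freely; only a minimal α-torsion
scaffold exists for torsion tests), solvent/ions, and force-field
energetics. Passing tests therefore demonstrate the correctness of the
geometry pipeline, not the realism of any particular trajectory.

## Numerical choices

- Orthonormality and det +1 of rotation matrices hold to 1e-9; bisector
  symmetry to 1e-9; fit residuals of exact copies are below 1e-6 Å (the
  closed-form solver's numerical floor).
- The bisector quartet normal weights the four bases equally, while an SVD
  plane fit of all 36 atoms weights atoms; the two agree within 2° only in
  the near-planar regime (per-base rocks of a few degrees, sub-0.1 Å center
  jitter), which is the regime of intact quartets — the agreement bound is
  checked at per-base perturbations up to 2.5° and 0.05 Å.
- Histogram of a zero-variance series would degenerate; the range is padded
  by 1e-6 Å so all mass falls in one bin.
- Angle bin boundaries (120°, 240°) belong to the upper well; dihedrals are
  computed with atan2 and wrapped, so values sitting exactly on a boundary
  are subject to floating-point rounding like any angular quantity.

## Problem sizes

Statistical tests use 2000-frame trajectories for mean-recovery and
planarity-monotonicity checks and 5000 frames for Markov-stationarity and
noise-honesty checks; rotation-core properties use 1000 random draws and the
quartet-vs-SVD comparison 200 quartets. These sizes put 3-standard-error
bands at roughly ±0.02–0.04 on recovered fractions and means, tight enough
to catch systematic errors while keeping the whole suite fast.
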