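# Methods notes

## Coordinate and angle conventions

All geometry uses the image convention: x rightward, y downward, origin at
the top-left of the after photograph; because y grows downward, the
`atan2(dy, dx)` angle is the clockwise angle from horizontal as seen on the
image. Orientations of undirected features (walls, tangents, bisectors) are
reduced mod 180° to [0°, 180°); the divergence between two orientations is
the smaller of the two angles between them, in [0°, 90°]. Pixel landmarks
are converted to world millimetres through a single scalar calibration
(default 9 px/mm, matching a rig that images a 333 mm frame across ~3000
px); conversion is refused for points already in world units.

## Registration

The before photograph is registered onto the after photograph by the plane
projective map determined by four landmark correspondences. Four points in
general position determine the 8 degrees of freedom exactly, so the map is
obtained by a direct 8×8 linear solve, not least squares: the residual at
the defining landmarks is machine precision, and no robust estimation is
warranted for a 4-point problem. Configurations with a (nearly) collinear
or duplicated triple are rejected; a condition number above 1e8 is logged
as a warning. Measurements are taken on landmark coordinates in the after
frame (stimuli marked on the before image are mapped forward); image pixels
are never resampled for measurement, though a warp utility exists for
visual inspection.

## The four metrics

**Rim overlap.** A pit is gauged by a circle of diameter 4.0 mm around its
marked centre. The human operator's judgement "the wall coincides with the
rim here" is formalized as: a gauge-circle point overlaps a wall when it
lies within `tol_mm` of the wall segment (default 0.35 mm ≈ half a natural
wall thickness; configurable). The overlapping set is computed analytically
as the intersection of the circle with each wall's capsule-shaped proximity
band — four half-plane arc cuts for the rectangle plus two circle–circle
arcs for the end caps — merged across walls into disjoint arcs. A dense
0.1°-sampling oracle is used in tests, never in the implementation.

**Tangent divergence.** For a pit pair the predicted wall orientation is
the common tangent, perpendicular to the centre–centre line. The measured
wall is the one nearest the pair midpoint (segment distance). A measurement
is excluded when the *infinite line* through the marked wall does not cross
the open segment between the pit centres; the infinite line is used because
marked walls may be offset along their own axis. Note a consequence
verified by simulation: under a fully random wall field this exclusion
preferentially removes walls perpendicular to the tangent (divergence near
90°), so the surviving control mean falls from 45° to roughly 36°. The raw
(pre-exclusion) control divergence is the uniform-null quantity with mean
45°.

**Bisection divergence.** The predicted orientation at a V apex is the
internal-angle bisector (the normalized sum of the two unit arm vectors),
reduced mod 180°. The measured wall is the one whose nearer endpoint
("corner") is closest to the apex, matching how walls are marked by their
endpoints; ties break deterministically by annotation order and are logged.

**Proximity ratio.** P = d₁/(d₁+d₂) with d₁ ≤ d₂ the apex-to-corner
distances of the two nearest distinct walls. P is 0.5 exactly when the two
corners are equidistant and approaches 0 as the nearest corner reaches the
apex; d₁ = 0 is accepted as the boundary P = 0 with a warning.

## Virtual controls

Controls are drawn from seeded generators so a control population is
reproducible from its seed, which is recorded in output tables. A virtual
pit is uniform in the 10.0 mm disc around its real pit (radial density ∝ r),
rejection-sampled against the tab bounds; a virtual pair has uniform
midpoint and orientation with separation uniform on [5.0, 6.0] mm; a
virtual V has uniform apex and bisector orientation with splay uniform on
[90°, 152.2°]. Virtual-V arm length (default 6 mm) only affects marking,
not the metric. Placement bounds are the after-frame landmark extent inset
by 4 mm — the same keep-out real stimuli respect — so real and virtual
stimuli sample the same region of the wall field.

## Statistics

The rim-overlap comparison uses an unpaired two-tailed t test; Welch is the
default (the pooled Student variant is available by flag) since equal
variances between real and control overlap populations are not guaranteed.
Divergence and proximity comparisons use the two-sided rank-sum
(Mann–Whitney) test — exact for small tie-free samples, normal
approximation with tie correction otherwise — reporting the U of the first
group (all-real-below-all-control gives U = 0). The hybrid experiment
compares the two divergences of the *same* wall, so the default test is the
paired Wilcoxon signed-rank (an unpaired option exists). The orientation
ratio is a least-squares slope through the origin of built vs predicted
orientation after unwrapping each pair to the 180°-representation that
minimizes its angular difference; it is 1 when built walls track the guide
one-for-one. No multiple-testing correction is applied; each experiment
asks one pre-specified question.

## Synthetic comb generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale: 25 × 40 mm tabs; 6 stimuli per tab for pits and pairs, 4
for Vs and hybrids, laid on a jittered grid whose nearest-neighbour
spacings land in 10–15 mm (a hard-core rejection sampler cannot pack 6
points at ≥10 mm on a tab this small; rows are what the physical pressing
produces anyway); pair separation U[5, 6] mm; splay U[90°, 152.2°]; a
distractor lattice of hexagon edges at 5.2 mm pitch (worker-cell scale)
with per-tab random phase and rotation and 3° edge jitter; and a mild
random projective before/after perturbation (corner displacements ≤ 5 px at
9 px/mm) standing in for a fixed photographic jig.

Each stimulus receives one response wall. In **biased** mode its
orientation is the predicted guide plus noise ε ~ N(0, σ) folded to
(−90°, 90°] (default σ = 5°, the scale of the empirical spreads such
construction experiments report), its midpoint tracks the predicted
location with a Gaussian offset (sd 0.5 mm), and the lattice keeps a 4 mm
clearance around each stimulus — the built cell displaces background comb.
A single pit's response is instead a chain of rim-hugging chords covering a
contact arc ~N(140°, 40°) clipped to [30°, 360°], emulating deposition
spreading along the rim. In **null** mode construction ignores the stimuli
entirely: response walls take uniform position over the tab and uniform
orientation, and no clearance is carved. Decoupling position as well as
orientation is deliberate: a null that pins the response wall to the
stimulus location would still correlate the wall field with the stimuli and
would bias the rim-overlap and proximity metrics, making a type-I-error
check meaningless for them.

The hybrid generator builds a V, places the pit pair so its common tangent
passes through the apex misaligned from the bisection by 30° (the two
guides must disagree for the preference question to be answerable), and
lets each response wall follow the tangent with probability
`tangent_follow_frac` (default 1; the acceptance run uses 2/3).

**What the generator does not emulate:** comb growth dynamics and any
behavioural model of the builders; curved or merged walls (all walls are
straight segments); wall thickness and height; photographic noise, lighting
or lens distortion (the before/after map is an exact homography, so
registration error contributes nothing at desk scale); and operator
marking error. Passing tests therefore show that the measurement and
inference chain is correct and calibrated on data with the assumed
statistical structure — not that real photographs are free of marking or
registration artefacts.

## Bias recovery

`recover_bias` runs the full pipeline and estimates the angular-noise sd as
σ̂ = √(mean d²) over the surviving real divergences d — the RMS of a
half-normal sample estimates the underlying normal's sd. With 4 mm of
lattice clearance the response wall is essentially always the selected
nearest wall, so contamination from distractors is negligible at σ ≤ 15°.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their statistical
assertions sharp while keeping a desk-scale run: type-I calibration uses
3–4 tabs per replicate (16–18 measurements per group) over 500 replicates
per experiment type, judged against the 99% binomial band around 0.05;
effect recovery uses the study's own sample sizes (11 tabs ≈ 66 pairs, 20
tabs ≈ 80 Vs) over 100 replicates; preference detection uses 81 hybrids
over 50 replicates against the exact binomial interval. Arc arithmetic
merges intervals with a 1e-12° tolerance; homography solves refuse
configurations with collinear triples rather than attempting
regularization; degenerate Vs (splay 0° or 180°) and zero-length walls are
rejected at construction.

## Known limitations

* The rank-sum U convention in the literature varies; printed W values from
  other software may not be comparable without knowing its convention.
* The exclusion rule's selection effect (control mean ≈ 36° rather than
  45°) means post-exclusion control divergences are not uniform; comparisons
  remain valid because real and control records pass through the same rule.
* The annotation schema stores one polyline per wall and leaves the
  marking convention (midline vs edge) to the annotator.
* Degrees of freedom reported for the t test are those of the chosen
  variant (pooled: n₁+n₂−2; Welch: Welch–Satterthwaite); no variant
  reproduces every df convention other software may print.
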