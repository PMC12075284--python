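# Methods

## Scope and data model

The package operates downstream of image registration: every input volume
is assumed rigidly pre-aligned on a common grid.  Grids follow a fixed
RAS-like convention (axis 0 = left→right, 1 = posterior→anterior,
2 = inferior→superior, 0-based indices); files stored in other orientations
are reoriented on read by axis permutation/flip only.  The physical
coordinate of voxel `(i, j, k)` is `origin + (i, j, k) * spacing`.
Resampling preserves the half-open physical extent
(`ceil(n * spacing / new_spacing)` output voxels) and samples the input at
output voxel positions by linear or nearest-neighbour interpolation;
nearest is mandatory for label and mask volumes.

## Synthetic cohorts

The phantom generator emulates the study design the pipeline targets:
three age groups × two sexes of pre-aligned subjects.  Anatomy is a nest
of ellipsoids on a 64³ grid at 2.5 mm spacing by default (brain radii
54×65×48 mm, about 650 mL — a deliberately compact head that keeps the
default test and acceptance runs fast; all sizes are spec parameters).
Hemisphere-split fine labels (12 tissue labels + ventricles) stand in for
a many-label anatomical segmentation and are merged downstream to the six
canonical regions (cerebrum WM, cortical GM, deep GM, cerebellum WM/GM,
brainstem).  The configured group effects are: male brains 3% larger in
linear scale (~9% by volume); the older group 3% smaller in linear scale
with double the ventricle volume; and 8% lower shear modulus in the older
group (1% in mid-age).  These magnitudes sit in the range reported for
healthy aging (stiffness decline of roughly 7–10% in older adults,
ventricular enlargement with atrophy) and define the conditions under
which the trend checks run.  Per-subject variation is multiplicative
Gaussian jitter on the ellipsoid radii (`jitter_sd`, default 0); subject
seeds derive deterministically from the master seed via `SeedSequence`.

The brainstem is a cylinder descending to slice `sas_thickness_vox + 1`
above the inferior grid face (slice 2 at the default 1-voxel SAS), which
guarantees that the dural floor and a skull voxel exist below it inside
the grid, so the foramen construction in the FE builder is always
exercised.

Moduli are generated by evaluating each region's Prony material at the
requested frequencies and applying multiplicative Gaussian noise
`(1 + N(0, sd))`; the multiplicative form keeps `G' > 0` at small noise
and matches the relative-error character of elastography maps.
Displacement fields are spatially linear (rigid rotation about the grid
centre, simple shear `u_x = gamma * y`, or their sum) with amplitude
ramping linearly over frames, so the deformation gradient — and hence the
Green–Lagrange strain — is known exactly everywhere.  Head kinematics are
half-sine angular-velocity pulses: `omega(t) = omega_peak sin(pi t / T)`,
with `alpha_peak = omega_peak * pi / T` and net angle
`omega_peak * 2T / pi`.

What the phantom does *not* model: cortical folding, realistic membrane
geometry, MR acquisition physics, elastography inversion artifacts, or
subject-specific loading variability.  Passing tests therefore demonstrate
that the operators implement their stated mathematics and interlock
correctly — not that the pipeline's outputs match any particular clinical
population.

## Templates

Group averaging is voxelwise mean and sample standard deviation (n−1
denominator; SD defined as 0 for a single contribution) with a per-voxel
contribution count; masked voxels simply do not contribute.  The variance
is computed two-pass to avoid cancellation.  Edge sharpening is
`out = in − alpha * L(in)` with the 6-neighbour discrete Laplacian and
replicate borders.

The falx and tentorium templates are built as the union of per-subject
masks thinned along one axis (left–right for the falx, inferior–superior
for the tentorium): any 1-D run of foreground longer than the bound
(default 2 voxels) keeps a centred block starting at offset
`floor((L − max) / 2)` — a lower-index-biased centred pair for odd runs.
Any centred choice satisfies the published ≤2-voxel bound; the tie-break
is fixed for reproducibility.

Brain volume (BV) counts tissue labels only; ventricle volume (VV) is
separate, and `nVV = VV / BV × 100`.  Whether ventricular CSF belongs in
BV is a convention choice; the label-set arguments make it explicit and
overridable.

## Property maps and group masks

Stiffness and damping are computed per subject from that subject's moduli
and then averaged (averaging derived maps, not moduli).  The printed form
of the stiffness relation in the source literature mixes a complex
quantity into a real denominator; this package uses the standard
elastography definition `mu = 2|G*|^2/(G' + |G*|)`, which reduces to
`mu = G'` for a purely elastic material.  The majority-vote mask keeps a
voxel iff its contribution count is at least half the number of subjects
(removal is strict `count < n/2`).  Distribution summaries use
linear-interpolation percentiles between order statistics (the numpy
default) and empirical CDFs.

## Prony parameterization

Frequency-domain forward model at `w = 2 pi f`:

    G'(w)  = G_inf + sum_i G0 g_i (w tau_i)^2 / (1 + (w tau_i)^2)
    G''(w) =         sum_i G0 g_i (w tau_i)   / (1 + (w tau_i)^2)

with `G_inf = G0 (1 − sum g_i)` by construction, so parameterizing in
`(G0, g_i)` or `(G_inf, g_i)` is interchangeable.

Ex vivo scaling: a single positive scalar minimises the relative squared
error between the log-frequency-interpolated ex vivo curve and the
in-band (30–70 Hz) in vivo samples, jointly over G' and G''; the
minimiser is closed-form (`c = sum r / sum r^2` for ratios `r = e/v`).
The shipped ex vivo curve is a **synthetic placeholder** generated from a
plausible two-term brain-tissue material; substitute a measured master
curve for real use.

Fitting minimises relative residuals on stacked G'/G'' (relative error
keeps the smaller loss modulus from being swamped by the storage
modulus; where a data `G''` is zero the residual is normalised by `G'`
instead, which drives fitted loss toward zero in the elastic limit).
Constraints are enforced by construction: `G0` and `tau_i` in log space,
fractions via stick-breaking variables `s_i ∈ [0,1)` so `g_i ≥ 0` and
`sum g_i ≤ 1` always hold.  A deterministic multi-start over
time-constant initialisations at {1, 10, 100} ms (all size-n
combinations) makes fits reproducible without a seed.  Term counts
1..`n_terms_max` (≤3) are tried, capped by the feasibility rule
`n_samples ≥ 2n + 1`, and an extra term is kept only when it improves the
residual norm by more than 1%.

## Deformation metrics

Displacement gradients use central differences in physical units
(one-sided at borders; border voxels are excluded from accuracy
assertions by a 2-voxel erosion in tests).  "Lagrangian strain" is
implemented as the finite Green–Lagrange tensor, which is exactly zero
under rigid motion; the infinitesimal tensor is available as an option
and serves as the objectivity discriminator in tests (a 10° rotation
produces ~5×10⁻³ spurious strain in small-strain mode).  MPS takes the
largest (most positive) eigenvalue of the symmetric 3×3 tensor per frame
and the maximum over the time history; MRD is the per-voxel maximum
displacement magnitude.  Volume fractions use the strict inequality
`MPS > theta`.  Group averaging operates on the scalar peak maps only —
never on tensors, whose orientation does not survive nonlinear warping.

## FE model construction

Starting from the merged six-region labels, ventricle, dura and
falx+tentorium masks:

1. SAS = inside dura, outside brain/ventricles/membranes;
2. skull = one-voxel 6-connected dilation shell outside the dura
   (6-connectivity keeps the shell watertight for face-adjacency checks);
3. separation repair relabels any skull voxel face-adjacent to brain as
   SAS and re-closes the shell one voxel outward, iterating to a fixed
   point — pushing the skull outward preserves the brain volume the
   pipeline reports;
4. falx columns extend along +z through SAS until the skull (columns
   blocked by tissue are left unextended and logged);
5. below the lowest brainstem slice, inside that slice's axial footprint,
   SAS becomes brainstem and skull becomes foramen, keeping the cord path
   unenclosed.  Because this can create brain voxels beside the lateral
   skull ring at the floor, the separation repair runs once more, so the
   zero-adjacency postcondition holds unconditionally.

Each occupied voxel becomes one 8-node constant-stress hexahedron; node
ids are assigned row-major (x fastest) over the `(nx+1)(ny+1)(nz+1)`
corner lattice so every shared face shares nodes exactly, and the
right-handed corner ordering makes each element volume equal the voxel
volume.  Ventricles and SAS are soft viscoelastic *solids* with shared
nodes (no fluid–structure interaction), matching the voxel-model
approach; the SAS card is `rho = 1.04 g/cm³`, `K = 2.19 GPa`,
`G0 = 0.5 kPa`, `g1 = 0.8`, `tau1 = 12.5 ms` (implying
`G_inf = 100 Pa`).  Membrane, ventricle, foramen and skull cards are
plausible placeholders (flagged in `DEFAULT_FIXED_MATERIALS`) meant to be
overridden from the user's configuration.

The keyword deck uses the g–mm–ms unit system (stress in MPa): density
×10⁻³ from g/cm³, moduli ×10⁻⁶ from Pa, time constants ×10³ from s,
angular velocity ×10⁻³ from rad/s.  Shear relaxation is written as an
exponential series with a zero-decay long-term term plus one `(G0 g_i,
1/tau_i)` pair per Prony term.  Nodes print as I8 ids with E16.9
coordinates, elements as I8 fields; the companion reader recovers nodes,
connectivity and part assignment bit-exactly, and export refuses
kinematics shorter than the termination time (default 160 ms).

## Group statistics

The two-way ANOVA (age × sex, with interaction) uses Type II sums of
squares, appropriate for unbalanced cohorts, computed by nested
least-squares model comparison on treatment-coded design matrices; a
zero residual variance is flagged degenerate rather than reported as a
finite F.  The one-way ANOVA runs Tukey HSD pairwise comparisons only
when the overall test is significant at `alpha` (default 0.05), mirroring
the conditional reporting convention for cohort deformation metrics.
Both the SS type and the post-hoc method are conventions the source
procedure leaves open; they are fixed here and cross-checked against
statsmodels in the tests.

## Numerical choices and limitations

* Percentiles: linear interpolation between order statistics throughout.
* Majority vote: inclusive at exactly half.
* Eigenvalues via `numpy.linalg.eigvalsh`; verified against
  characteristic-polynomial root finding to 1e-10 on random tensors.
* The ANOVA null calibrations run 10,000 seeded replicates in the test
  suite and 5,000 in the acceptance script.
* Registration, segmentation of real images, elastography inversion,
  tag-line tracking and explicit dynamics solving are all out of scope;
  the package consumes their outputs and produces solver input.
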