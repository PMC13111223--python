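# Methods

## Physical model

Transcranial direct-current stimulation operates at frequencies where the
quasi-static approximation holds: capacitive and inductive effects are
negligible and the electric potential φ in the head obeys

    ∇ · (σ ∇φ) = 0

with σ the (possibly tensor-valued) tissue conductivity. The electric
field follows as **EF = −∇φ**. Two conductivity models of the same montage
are compared throughout:

- **NoDTI** — every tissue takes a scalar conductivity from the
  low-frequency tissue table (S/m): skin 0.148, fat 0.078, CSF 1.879,
  grey matter 0.419, white matter 0.348, cancellous bone 0.08, cortical
  bone 0.0063, electrode sponge 1.4, copper 5.9×10⁷.
- **DTI** — white-matter voxels instead carry a symmetric 3×3 conductivity
  tensor derived from the local diffusion tensor; all other tissues stay
  isotropic. The core modelling assumption is that the diffusion tensor's
  major eigenvector is parallel to the local fiber bundle, so the
  conductivity tensor shares the diffusion tensor's eigenvectors.

Electrodes are rectangular copper pads over a conductive sponge, held at
fixed potentials (±1 V); by linearity of the Laplace problem the solved
field is rescaled a posteriori so the anode injects a target current
(default 0.75 mA, the fixed-dose convention).

## Diffusion-to-conductivity mapping

The effective-medium conversion keeps eigenvectors and maps eigenvalues.
Two standard realizations are provided because the calibration constant is
not uniquely fixed by the effective-medium idea itself:

- `scaled_linear`: σᵥ = k·dᵥ with one global k chosen so the field-mean
  diffusivity maps to the reference white-matter conductivity
  (0.348 S/m). Conductivity FA equals diffusion FA voxel-wise.
- `volume_normalized` (default): per-voxel k such that the geometric mean
  of the three conductivity eigenvalues equals 0.348 S/m at every voxel.
  This pins the local bulk conductivity to the isotropic table value, so
  the NoDTI and DTI models are directly comparable in bulk; it is the
  default for that reason.

Tensors whose eigenvalue spread is below 1e-12 (relative) are mapped to
exact isotropy to avoid amplifying eigendecomposition noise.

## Discretization and solver

The domain is a uniform voxel grid. The solver uses **node-based trilinear
hexahedral finite elements** with one conductivity tensor per voxel and
full 2×2×2 Gauss quadrature. This choice (rather than a two-point finite
volume scheme) represents off-diagonal tensor coupling naturally. Air
voxels are excluded from the system, which realizes the zero-normal-flux
boundary on every conductor–air interface. Dirichlet potentials are
imposed on all nodes of the electrode copper voxels; the sponge is solved
as an ordinary conductor. Fixing copper only (not copper+sponge) treats
the copper as the equipotential terminal, which at σ_Cu = 5.9×10⁷ S/m it
effectively is.

The reduced symmetric positive-definite system is solved by conjugate
gradients with a Jacobi (diagonal) preconditioner, relative residual
tolerance 1e-8, at most 10⁴ iterations. The tolerance is far below the
precision of any reported metric. On the desk-scale phantoms used here
(up to ~70³ voxels) CG converges in well under a hundred iterations.

**Electrode currents** are computed from the discrete reaction forces: the
stiffness matrix applied to the converged potential, summed over an
electrode's fixed nodes. In the FEM this equals the face-integrated normal
current σ∇φ·n̂ through any surface separating the electrode from the
tissue, and it is exactly conservative — the anode and cathode currents
cancel to the solver tolerance by construction, which a re-discretized
face quadrature would not guarantee.

**Field evaluation.** The node potential is averaged to voxel centers and
EF = −∇φ is taken by central differences where both axis neighbours are
inside the conductive mask, one-sided at mask boundaries. Copper voxels
are excluded from the differencing mask: the plate is equipotential and
differencing across it would smear the field in the adjacent tissue
layer. Units: potentials in volts, spacing in mm, fields reported in V/m.

**Electrode voxelization.** Pads conform to the phantom surface column by
column: an air voxel joins the sponge (copper) if its distance to the
tissue surface along the electrode normal lies in (0, t_sponge]
((t_sponge, t_sponge + t_copper]). The copper sheet is voxelized at least
one layer thick even when it is thinner than the spacing, so the
Dirichlet plate always exists. A sponge thickness of zero is allowed and
puts the plate directly on the tissue — the configuration of the analytic
slab oracles.

## Field metrics

All metrics operate on block-averaged fields: non-overlapping 2 mm cubic
blocks aligned to the grid origin, each replaced by the component-wise
mean vector of its masked voxels (vector, not magnitude, averaging — so
antiparallel vectors cancel). Block averaging suppresses staircase
artifacts at voxelized tissue interfaces.

- **MaxEF**: 99th percentile of |EF| over the ROI's white matter. The
  percentile uses linear interpolation between closest ranks (the value
  at rank 1 + (n−1)q/100); the convention is fixed for reproducibility.
- **MaxDiff**: 99th percentile of the voxel-wise |,|EF_a| − |EF_b|,|.
- **RE**: Σ(|EF_noDTI| − |EF_DTI|)² / Σ|EF_DTI|², the default reported
  form; the square-root (normalized-RMS) variant common elsewhere in the
  literature is available as `variant="root"` and recorded in output
  metadata.
- **MaxAlpha**: 99th percentile of the voxel-wise angle between the two
  fields' vectors, computed only where both magnitudes reach a floor
  (default 1e-6 V/m; arccos is ill-conditioned near zero), cosine clamped
  to [−1, 1].
- **V50/V70/V80**: percentage of grey+white brain voxels whose |EF|
  *strictly* exceeds 50/70/80 % of the ROI's MaxEF. The threshold comes
  from the ROI's white-matter peak; the counting volume is the whole
  brain mask. V80 is anchored to MaxEF like the others, by symmetry. The
  strict inequality is a fixed boundary convention.

Scalar metrics are pure functions of the (paired) voxel multiset; RE and
MaxAlpha are invariant to a common positive rescaling of both fields, so
they do not depend on the injected-current scaling.

## Connectomes

Streamline endpoints map to the parcel containing them, else to the
nearest parcel whose voxel center lies within a 2 mm search radius
(configurable), else stay unassigned; a streamline counts only when both
endpoints are assigned, and self-connections are excluded. With
inverse-volume weighting each contribution is divided by the arithmetic
mean of the two parcel volumes (the common connectome-construction
semantics; division by the sum is available as a switch and the choice is
recorded per run). Matrices are symmetric with zero diagonal; the
optional 0–1 normalization divides by the maximum entry and is treated as
display-only — it is per-subject and would erase cross-subject
differences in the strongest edge, so the analysis pipeline keeps it off.

The **adjusted inter-subject variability** of parcel i is
Var(i) = 1 − mean over unordered subject pairs of the Pearson correlation
between the subjects' connectivity rows for i (self-entry removed), ×100.
Identical cohorts give 0 %, independent profiles 100 %, anticorrelated
ones up to 200 %. The self-entry is removed before correlating because a
structural zero shared by all subjects would inflate agreement.

Parcel ranking sums each candidate parcel's connections to the seed set
and sorts descending, ties broken by ascending parcel id; matrix
reduction sums parcel-level entries into named disjoint ROI groups with
the diagonal reset to zero.

## Correlation analysis

Pearson r with the two-sided p from t = r√((n−2)/(1−r²)) on n−2 degrees
of freedom; significance at α = 0.05 without multiplicity adjustment
(only a handful of edges are tested); a Bonferroni column is emitted
alongside. A seeded permutation p (default 10⁴ shuffles) is
available for small-n robustness. In a full pipeline run a zero-variance
column (e.g. when the DTI model exactly equals the NoDTI model) is
recorded as r = NaN rather than aborting the run.

## Synthetic data: what it emulates, what it does not

The generators stand in for everything the real study measured:

- **Slab and layered-sphere phantoms** emulate the layered head (skin,
  bone, CSF, grey, white) at desk scale. Voxel membership is by
  voxel-center point test with no partial-volume labels, which keeps the
  analytic volume and field oracles exact.
- **Fiber tensor fields** are piecewise-constant bundles with a chosen
  direction and eigenvalues — controllable anisotropy with exactly known
  ground truth, not realistic fiber geometry.
- **Toy tractograms** realize a requested inter-parcel count matrix
  exactly, with endpoints strictly inside their parcels; interior points
  are smooth arcs with no anatomical meaning.
- **Cohorts** share one phantom geometry; only tensors and tractograms
  vary across subjects, which isolates the connectivity→field effect the
  correlation stage targets. Per subject, the designated P2–P1 edge count
  w is drawn as round(N(150, 30²)) and the white-matter anisotropy
  parameter is t = coupling·(w−150)/30 + noise_sd·z, giving population
  correlation coupling/√(coupling² + noise_sd²) between w and t
  (`coupling_for_target_r` inverts this; 0.45 is the design point used in
  the demonstrations). The longitudinal/transverse diffusivity ratio is
  1 + 2·exp(0.3·t) at fixed mean diffusivity 0.7×10⁻³ mm²/s — smooth,
  monotone, always prolate. The remaining edges carry independent integer
  jitter (sd 3) around fixed baselines so connectivity profiles have
  nonzero variance.
- The cohort phantom is a 32 mm slab with desk-scale pads (8×8 mm anode,
  12×12 mm cathode, 2 mm sponge) so the field stays focal inside the
  32 mm cross-section; the paper-scale 30×30/50×50 mm pads with 5 mm
  sponge are the package defaults for head-scale phantoms
  (`anode_spec` / `cathode_spec`).

In this geometry, increasing anisotropy along the inter-ROI axis
*focalizes* the anisotropic-model field (V50 of the contralateral ROI
decreases monotonically). A cohort that should emulate a *positive*
spread–connectivity correlation therefore uses a negative edge-to-
anisotropy coupling, as in `examples/cohort_correlation.py`.

Passing tests on these phantoms validate the numerics and the metric
definitions; they say nothing about cortical folding, tissue segmentation
accuracy, tractography biases or any other property of real MRI-derived
models, all of which are out of scope.

RNG: every generator is a pure function of its arguments and a seed;
per-subject streams derive from the master seed by fixed offsets, so
truncating a cohort preserves its early subjects bit-exactly.

## Verification summary

- Uniform slab at ±1 V across 20 mm: |EF| = 100 V/m to machine precision
  (the trilinear element is exact for linear fields).
- Two-layer series slab: potential divider fraction
  (1/σ₁)/((1/σ₁)+(1/σ₂)) reproduced to 1e-14.
- Uniform anisotropic slab scaled to fixed current: |EF| = I/(A·σ_nn);
  rotating fibers from along- to across-current multiplies the field by
  exactly σ_l/σ_t (relative error ~1e-7).
- Grid convergence on a five-shell sphere (12 mm outer radius, spacings
  2/1 mm against a 0.5 mm reference): empirical L2 order ≈ 2.
- Every field metric matches a naive per-voxel loop to 1e-10; the
  connectome raw-count matrix reproduces the generating counts exactly.
- Pearson type-I error calibrated at 0.05 (10⁴ null replicates, n = 30);
  cohorts at population r = 0.45 recover the mean sample r within ±0.05
  over 200 replicates.

Problem sizes were chosen at desk scale (20–70 voxels per axis, cohorts
of 3–30) as the smallest instances on which every oracle is sharp.

## Known limitations

- Uniform grids only; no graded or adaptive meshing, so head-scale runs
  at sub-millimeter resolution are out of reach by design.
- Electrode pads assume a locally flattenable surface; strongly curved
  surfaces at coarse spacing produce ragged sponge columns.
- No frequency dependence, no capacitive effects, no skull anisotropy,
  no neuron-level response modelling.
- The gradient at tissue interfaces is one-sided/central on the voxel
  grid; the normal-component discontinuity of EF at conductivity jumps is
  smeared over one voxel layer (mitigated, as in practice, by resolution
  and block averaging).
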