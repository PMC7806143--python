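# Methods

This note documents the models implemented in `pedsar`, the tunable
parameters and their defaults, the numerical choices, and what the synthetic
data can and cannot show. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic phantom

The generator (`pedsar.phantom`) rasterizes an ordered list of geometric
shells — ellipsoids, (elliptic) cylinders, tubes, boxes — by voxel-center
sampling: a voxel belongs to a primitive iff its center lies inside. Later
shells paint over earlier ones, so nested anatomy is listed outside-in;
shells given the same explicit `priority` must be disjoint and an overlap is
an error naming the pair. Output is deterministic for a fixed `rng_seed`
(the seed only matters when the optional boundary-roughness `jitter_mm` is
enabled; the default phantom has none).

The default child phantom stands ~86 cm tall at 2 mm spacing and weighs
~12.5 kg with the packaged densities, with a 4-shell head
(skin/skull/CSF/grey matter over a white-matter core, brain ≈ 1.07 L), a
torso of skin/fat/muscle containing two lungs (0.6 L total), a 53 cm³ heart,
and a spine column, on two legs with cortical-bone cores. Those sizes were
chosen once to sit in the anthropometric range published for a two-to-three
year old (height 86 cm, mass ≈ 13 kg, brain ≈ 1.05–1.1 kg, heart ≈ 55 g);
they are geometric stand-ins, not anatomy.

**Implant.** The VNS-like implant is a polyline lead (conductor ⌀1 mm)
wrapped by 0.5 mm insulation, two cuff electrodes (⌀1.4 mm, length 1 mm,
wall 0.3 mm) centered on the lead axis near its end, and a pulse-generator
box in the left chest. Conductor rasterization combines center-in-radius
voxels with a dense supercover walk of the polyline, so the conductor chain
is 26-connected and at least one voxel wide *at any grid spacing*; the
insulation is the distance shell plus a one-voxel wrap, opened at the
electrode contact zones. On grids much coarser than the cuff, each electrode
degenerates to its nearest voxel — coarse grids keep the topology, not the
geometry.

**Label-map cleanup.** `fill_unlabeled` assigns each unlabeled voxel inside
the body mask the modal nonzero label of its 26-neighborhood, iterating until
no fillable voxel remains; ties break toward the smallest tissue ID (a
deterministic convention — the rule used by the original MATLAB-based
cleanup of real segmentations is not published, so this is a documented
choice, and the operation is idempotent). An interior component that never
acquires a labeled neighbor raises, reporting component sizes.
`resample_labels` is nearest-neighbor on voxel centers with the outer
corner of the sampled extent preserved to within one voxel; it can never
introduce a label absent from the input.

## Tissue properties

The packaged table (`pedsar/data/adult_tissue_properties.csv`) holds adult
conductivity and relative permittivity for 44 tissues at 64 and 128 MHz
(values consistent with the Gabriel dispersion parameterization and the
IT'IS database), mass density, 3 T MR properties for the phantom tissues,
and the pediatric scaling ratios. Scaling is element-wise:
σ_child = r_σ σ_adult, ε_child = r_ε ε_adult. Measured ratios: cortical bone
(2.4, 1.99), brain tissues (1.6, 1.33), skin (1.5, 1.29), liver conductivity
1.2; other soft tissues carry the averaged soft-tissue ratio (1.4, 1.22);
fluids (air, bile, blood, CSF, urine) are unscaled. Tissues without their
own published dielectric data resolve through an editable donor map
(`donor_tissues.json`, e.g. meninges → dura). Note the packaged table scales
vitreous humour with the soft-tissue ratios — consistent with the published
29-month-old property table this package reproduces, although age-invariance
of ocular fluids is sometimes assumed elsewhere. Density is treated as
age-invariant; the ~1.7% lean-tissue difference reported for young children
is handled as an uncertainty via `sensitivity_scan`, not as a model input.
Frequencies are restricted to the tabulated {64, 128} MHz — no dispersion
model is evaluated at other frequencies; new rows must be supplied
explicitly.

## Segmentation QC

DSC = 2|X∩Y|/(|X|+|Y|) with two empty masks defined as perfect agreement
(1.0). The "average Hausdorff distance" is the symmetric mean
boundary-to-boundary distance in mm: boundary voxels are mask voxels with at
least one face-adjacent non-mask neighbor; the mean nearest-neighbor
distance from X's boundary to Y's is averaged with the reverse direction
(the classical max-Hausdorff is available as `hausdorff_max`). The average
variant is the default because published inter-operator tables report values
far below the mask extents, which a max metric could not produce. Quality
classes follow the usual convention: DSC > 0.8 acceptable, ≥ 0.9 excellent.
The inter-operator report evaluates 3D masks by default; a coronal
slice-wise 2D mode exists because published tables are sometimes evaluated
per-slice. Morphometry percent differences use the literature value as the
denominator (nearest bound for a range; 0 inside the range), the single
convention that reproduces the brain (1.1%) and CSF (1.2%) reference rows;
a few published rows are internally inconsistent under any one convention
and are not asserted.

## FDTD solver

Maxwell's equations are time-stepped on a uniform Yee lattice in single
precision (the sweep is memory/SIMD bound; wave propagation is robust in
float32 and the phasor extraction accumulates in float64). The time step is
the largest integer-steps-per-cycle value satisfying the 3D CFL limit
`dt ≤ cfl·dx/(c√3)` (default `cfl` 0.99), so each RF cycle is an exact
integer number of steps and the cycle-locked energy monitor and DFT are
phase-consistent.

**Coil model.** The 16-rung high-pass birdcage (⌀290 mm × 290 mm, 64 MHz)
is realized as ideal impressed currents: rung k carries
I·sin(ωt − p·θ_k) with θ_k its *rasterized* angular position (which
preserves quadrature symmetry on coarse grids) and polarization p = +1
driving the co-rotating (B1⁺) mode. Two end rings carry the discrete
cumulative sums of the rung currents (mean-free), closing every junction so
charge is conserved exactly. The rings matter: open-ended rung currents
accumulate oscillating charge at the tips and radiate a spurious
conservative axial E-field several times the inductive field, which leaks
through a staircased load surface and corrupts SAR benchmarks. No capacitor
network or S11 tuning is modeled — at the field level the driven CP mode is
the quantity of interest. An optional cylindrical PEC shield is available
and off by default. Drive amplitude is arbitrary; all reported quantities
are normalized afterwards.

**Boundaries and materials.** 8-cell CPML on all faces (polynomial grading
m = 3, σ_max = 0.8(m+1)/(η₀dx), α graded to 0.05, κ = 1), implemented as
slab-restricted corrections after a branch-free main sweep. Padding between
coil/shield and PML defaults to 40 mm. Material σ and ε are arithmetic means
over the four voxels sharing each Yee edge; an edge touching any PEC voxel
is PEC (E ≡ 0), which keeps stair-stepped metal closed. Implant conductor
and electrode labels are PEC; implant insulation is a lossless ε_r = 3
dielectric.

**Steady state and extraction.** The source ramps with a raised cosine over
3 cycles. Total Σ|E|², sampled at the same phase each cycle, must change by
< 10⁻³ relative between consecutive cycles, with a minimum of 10 cycles and
a divergence guard (three consecutive growing cycles → error). One further
cycle accumulates the single-frequency DFT of all six components
(H sampled at its half-step times); phasors are collocated to cell centers
(E: 4-edge average; B = μ₀H: 2-face average). Convention: field(t) =
Re(F·e^{iωt}), phasor magnitudes are peak values.

**Grids.** Desk scale means a uniform grid: 8 mm for fast scenes
(vacuum/quadrature checks, the child-phantom pipeline; ~40 s per solve on
one core) and 4 mm for the resolved benchmark scenes (~5 min). The
production-style three-tier grid (0.3 mm implant / 1 mm head / 2 mm body)
that sub-millimeter implant studies require is documented here but not
realized; consequences below.

**Verification.** The solver is anchored to a closed form: a homogeneous
conducting sphere (σ = 0.5 S/m, ρ = 1000 kg/m³, R = 60 mm) in the coil
normalized to |B1⁺| = 2 μT at the center. The quasi-static interior solution
E = −½ r × dB/dt gives time-averaged local SAR σω²B²(z² + r²/2)/(4ρ) —
σω²B²r²/(8ρ) in the central plane — and ring-averaged FDTD SAR matches
within 10% at the 4 mm grid (the acceptance script prints the worst-case
error, ~6%). The sphere's ε_r is set to 5 so that σ/(ωε) ≈ 28: the medium
behaves as a good conductor and the gauge-independent eddy-current solution
applies; a strongly polarizable load would add displacement-current effects
the closed form ignores. The vacuum coil yields |B1⁻|/|B1⁺| < 0.05 at the
center (measured ~0.005), and γ·2 μT·3 ms = 1.605 rad ≈ 92°, within 3% of
the nominal 90° excitation.

## RF safety quantities

Pointwise SAR = σ|E_peak|²/(2ρ) (air and implant voxels → 0); regional SAR
is the mass-weighted mean over a region; the head region is tissue above a
configurable axial plane (default: the coil-center plane, appropriate when
the head is centered in the coil — the full-model head-mask definition used
by production solvers is proprietary). 10g averaging grows a centered cube
per voxel until the enclosed *tissue* mass (background and implant excluded)
reaches 10 g, interpolating the outermost shell so the average is over
exactly 10 g — an IEC 62704-1-style simplification whose correctness anchor
is an exhaustive brute-force cube search on small grids (exact agreement in
the tests and acceptance run). Voxels whose largest in-domain cube cannot
reach 10 g are invalid (NaN) and excluded from the maximum. Reported
E-averages are rms (= peak/√2). Normalizations: |B1⁺|(center) → 2 μT (field
factor linear), head SAR → 3.2 W/kg (field factor √(3.2/SAR_head)); both
idempotent. `compare_implant` reports deltas with the without-implant value
as percent denominator. The Tier-3 helper interpolates the *implant-free*
complex E along a lead trajectory and projects it on the local tangent —
the incident tangential E-field that a transfer-function (Tier-3) heating
model consumes; the transfer function itself is out of scope. A safety
margin helper divides exposure limits by 1.5, the factor suggested to cover
inter-subject variability. `sensitivity_scan` perturbs one parameter ±p%
(central difference) and reports |Δoutput|/output/p; the analytic 1/ρ
dependence of SAR on a global density change is the packaged correctness
check.

## MR synthesis

Voxelwise closed-form steady-state magnitude signals:

* IR: S = PD·|1 − 2e^{−TI/T1} + e^{−TR/T1}|·e^{−TE/T2} (default protocol
  TR/TE/TI = 5000/107/200 ms, the inversion-recovery sequence used for CSF
  delineation at 3 T),
* SE: S = PD·sin(α)·(1 − e^{−TR/T1})·e^{−TE/T2},
* MPRAGE-like spoiled GRE: S = PD·sin(α)(1 − E1)/(1 − cos(α)E1)·e^{−TE/T2}.

A relative B1⁺ map optionally scales the effective flip (and inversion
efficiency via cos(πb1) for IR). A closed-form signal model was chosen over
time-stepped Bloch integration because the steady-state expressions are
exact for these idealized sequences and keep synthesis deterministic and
fast; a time-stepped mode is a natural extension hook. Signal nulls at
TI = T1·ln2 for TR ≫ T1 are reproduced to numerical precision. MR
properties use the 3 T columns of the tissue table. The degradation model
is a smooth multiplicative bias field (unit-mean, heavily smoothed Gaussian
noise) followed by Rician noise, seeded. `compare_images` standardizes both
images to zero mean/unit variance before MSE (making all three scores
invariant to affine intensity rescaling), uses Pearson correlation, and the
standard structural-similarity index (scikit-image implementation, 7-voxel
window) — volume-level standardization, since slice-wise conventions vary.

## Pipeline

`pedsar run --config run.yaml` executes stages in dependency order with a
manifest (inputs, outputs, versions, seed, safety summary), JSON-line logs
with timings, and `.failed` markers on stage failure (exit codes: 0 ok,
1 config error, 2 compute error). One global seed fans out to per-stage
seeds by CRC32 hashing (< 2³¹), so stages are independently reproducible
and a rerun with the same config reproduces non-stochastic outputs
bit-identically.

## What passing tests do and do not show

The synthetic phantom emulates the *structure* of a segmented pediatric
model — nested tissues with realistic bulk sizes, masses and dielectric
contrast, an implant with correct topology — and the synthetic "acquired"
image emulates noise and shading of a real scan. It does not emulate real
anatomy (organ shapes, bone detail, vessels), registration error,
inter-operator disagreement, or sub-millimeter implant geometry. Desk-scale
grids (8/4 mm) resolve head-scale field structure and reproduce closed-form
benchmarks, but a 1 mm lead is below their resolution: the implant-induced
local SAR enhancement that production studies quantify at 0.3 mm grids is
*not* resolved here, and the packaged child-phantom numbers are therefore
internal-consistency results, not predictions for any real model. Published
full-model quantities (head SAR ≈ 0.20 W/kg at 2 μT; the 47% 10g-SAR
increase with the implant; 281 V/m maximum 10g |E| at the head-scan limit)
enter the acceptance checks only where they are pure table arithmetic;
matching them numerically requires the released full-body model and a
production-grade multi-resolution solver, and even then the 10g-averaging
and head-mask internals of commercial solvers preclude bit-level agreement.

## Known limitations

* Uniform grid only; no subgridding, no conformal (sub-cell) metal model.
* Ideal current drive: no coil tuning, matching, or losses; the drive is
  the CP mode by construction rather than by circuit resonance.
* κ = 1 CPML absorbs propagating waves well but evanescent near-fields less
  so; the 40 mm pad keeps reactive fields away from the boundary.
* 10g kernel uses cubes grown about the voxel, not the contiguous-region
  constructions of the full standard.
* Tier-3 stops at the incident tangential E-field; no transfer function,
  no temperature-rise modeling.
* The sequence models ignore k-space, motion, flow, and multi-coil receive.
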