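# Methods

## Scope and model

`cspine` analyses sagittal-plane instability of the occipito-atlanto-axial
complex. The skeleton is four rigid bodies — occiput (C0), atlas (C1),
axis (C2) and a fixed C3 base — connected by three revolute sagittal
joints and 22 tension-only spring ligaments (1 apical odontoid, 1 alar,
1 cruciate longitudinal band, 1 anterior longitudinal at C1–C2,
1 posterior longitudinal at C2–C3, 2 ligamenta flava, 2 interspinal,
1 supraspinous, 4 intertransverse, 1 atlantoaxial collateral, 1 occipital
collateral, 6 capsular). Continuum structures (bone deformation, the
C2–C3 disc, the transverse-ligament solid) are outside the rigid-body
scope; the bulk material block (cortical/cancellous bone, cartilage,
disc) is carried as metadata only.

Coordinates are right-handed with +X anterior, +Y left (medio-lateral),
+Z cranial; each vertebra's body frame is aligned with the laboratory
frame in the neutral position (foramen magnum horizontal, zero applied
moment). Flexion is a positive rotation of the upper vertebra about the
lower vertebra's +Y axis. Units are mm, N, MPa, degrees and N·mm
(1 N·m = 1000 N·mm at configuration boundaries).

## Template geometry

No attachment or marker coordinates are published for the specimen this
package emulates, so a synthetic anatomical template
(`data/template_geometry.json`, versioned) supplies plausible positions:
vertebral body centres 20 mm apart, joint centres midway between them,
four screw-mounted markers per vertebra with 60–90 mm cluster spread
(posterior foramen magnum, transverse processes, spinous processes), and
named ligament attachments placed so that posterior structures stretch
in flexion and anterior ones in extension. Ligament mechanics depends
only on length *changes*, so absolute geometry is a free modelling
choice; rest lengths are the neutral-pose attachment distances, making
the neutral state exactly stress-free.

## Ligament mechanics

Each ligament is a straight-line spring: F = k·Δl for Δl > 0, zero in
slack (springs cannot push), and pressure is engineering stress over a
constant effective area, P = F / A_eff. Although the source protocol
describes nonlinear spring units, every published per-condition state
row satisfies the linear law exactly, so linear tension-only is the
default and a per-ligament force–displacement curve hook covers
nonlinear use.

Two cross-sections are carried. The nominal published values
(`cross_section_A`) and the effective areas (`effective_area_A_eff`)
under which the published stress/pressure tables are internally
consistent: alar 10.3 mm² (nominal 3.4), apical odontoid 2.5 mm²
(nominal 2.7), cruciate 6.8 mm² (no nominal value published); flavum
(50.1), anterior longitudinal (6.1) and posterior longitudinal (5.4)
agree with their nominal values to better than 0.1%. Pressure always
uses A_eff, which reproduces the published pressures exactly. Whether a
paired structure's pressure divides force over one or both bands is
absorbed into A_eff.

Rigidities for the six tabulated entities come from the published state
tables (alar 25.32, flavum 11.6, anterior longitudinal 24, posterior
longitudinal 26.34, apical odontoid 28.6, cruciate 38 N/mm; their
provenance is not documented at source). The sixteen remaining springs
use k = E·A/L₀ from the material block and template rest length.

One published table — instability extension — contains two rows that are
not reproducible from their own Δl and k columns: the alar stress cell
(printed 88.035 N vs 3.303 × 25.32 = 83.632 N, 5%) and the
posterior-longitudinal pressure cell (0.76% off the computed stress over
area). The comparison report (`compare_with_reference`) flags both rows
at a 0.5% threshold instead of matching them; all other cells across the
four tables reproduce to ≤ 2e-9 relative.

## Synthetic motion capture

The generator emulates the in vitro protocol: 500-Hz optical capture of
four markers per vertebra plus a fixed base, slow sagittal
flexion/extension to the end ranges of motion, 1200 frames per cycle by
default. Per-joint angles follow a neutral → flexion → neutral →
extension → neutral cycle built from half-period raised-cosine ramps
(zero angular velocity at neutral and end range — a quasi-static drive);
a triangular profile is available. Default end ranges are the study
conditions (deg, C0–C1 / C1–C2): physiological flexion 3.49 / 8.84,
extension 11.16 / 14.20; instability flexion 5.51 / 13.70, extension
12.96 / 17.20. C2–C3 defaults to zero (the base is cast rigid).
Instability is encoded both as the larger prescribed ranges (for
kinematics) and as a stiffness scale < 1 (default 0.5, for the
equilibrium module) since the physical fatigue protocol itself is not
parameterized.

Marker noise is i.i.d. zero-mean Gaussian, default σ = 0.1 mm (typical
optical mocap precision; none is published). Dropout flags frame-markers
missing independently with a configured probability. All randomness
flows through one seeded generator; identical seeds give byte-identical
TRC output. The generator does **not** model soft-tissue artifact,
camera geometry, reconstruction error correlations, or out-of-plane
motion — passing tests therefore demonstrate correctness of the
analysis chain under the stated noise model, not robustness to every
artifact of real captures.

## Registration

Two rigid-fit routes: a constructive triangle match — translate vertex 1
onto vertex 1, rotate about the normal through vertex 1 to superimpose
the 1–2 edge directions, rotate about that common edge to bring vertex 3
into the target plane on the correct side — and a weighted
orthogonal-Procrustes (Kabsch) solution with a reflection guard (negate
the smallest singular direction when det < 0). For congruent noise-free
triangles the two agree to numerical precision and the Procrustes route
serves as the independent oracle. Which three of the four markers form
the triangle is not specified at source; the maximal-area triple is used
(best conditioning), with label order breaking ties. Similar but
non-congruent triangles are fitted rigidly — no scaling — and the
vertex-3 residual is surfaced, since downstream mechanics assumes rigid
bodies. Registration warns above a 1.0 mm RMS residual (the accepted
matching tolerance is not documented at source; 1.0 mm is the default).

## Kinematics

Per-frame vertebra poses are Procrustes fits of the local marker cluster
to the observed markers (batched SVD over fully-visible frames). The
joint angle is the component of the axis-angle vector of
R_rel = R_lowerᵀ R_upper along the lower vertebra's medio-lateral axis —
robust for single-plane motion and matching flexion/extension reporting;
the anterior-posterior translation is the +X component of the upper
origin in the lower frame, reported as displacement from the neutral
first frame. Frames with fewer than three visible markers are flagged,
never interpolated silently. Optional zero-phase Butterworth smoothing
(6 Hz cutoff for 500-Hz data) is off by default and recommended for
noisy captures; quasi-static motion keeps end ranges intact. ROM is the
end-range extremum per direction (whether published angles are extrema
or averages over repeats is not stated; extrema are assumed).

### Instability classification

The radiographic criterion — angulation > 11° or horizontal displacement
> 3.5 mm, strict inequalities — is exposed as a pure predicate. The
pipeline's headline per-joint classification applies the angle branch to
the *flexion* end range: physiological extension of these joints (11.16°,
14.20°) already exceeds the subaxial 11° threshold, which is known not
to transfer to upper cervical extension, so a raw per-direction
application would classify healthy extension as unstable. Per-direction
raw classifications are also reported.

## Equilibrium surrogate

A deliberately desk-scale stand-in for a continuum finite-element run,
validated by closed forms and mechanical properties, with **no claim** of
reproducing continuum-model angles. Three sagittal rotational unknowns;
at each joint the residual is the net Y-moment of everything acting on
the super-body above it: the applied occipital couple (default 1.5 N·m),
the 100-N compressive preload acting through a configurable lever arm
(default 10 mm anterior at C0 — the head's centre of gravity is not
published), spanning-ligament tensions, a unilateral rotational stop per
joint (default 20°, 5·10⁴ N·mm/rad) standing in for bony facet contact,
and Coulomb facet friction (μ = 0.10) regularized with a tanh law and
engaged past the 0.01-mm joint clearance (converted to angle by a 30-mm
facet radius; effective friction moment arm 5 mm).

Numerics: damped Newton with central-difference Jacobian on the stacked
residual (tolerance 10⁻⁶ N·mm), load-factor bisection continuation as
fallback, and a multistart root search for friction-plateau
snap-through; the tension and stop kinks are C¹-regularized over 10⁻³ mm
and 10⁻⁴ rad with energy-consistent antiderivatives, so forces remain
exact gradients of the stored energy and the work–energy audit closes to
numerical precision.

Known behaviours of the surrogate: the published ligament set contains
no anterior structure crossing C2–C3 (the disc carries that load in
reality), so large extension moments drive that joint to its rotational
stop; and under preload alone the atlanto-occipital joint rests near its
flexion stop, because only the cruciate band resists C0–C1 flexion in a
ligament-only model without muscle tone. Flexion moment sweeps are
strictly monotone and path-independent; extension sweeps are monotone in
total rotation but individual joints can relax slightly at a
snap-through step.

## Validation statistics

Ordinary least-squares regression (slope, intercept, R² = 1 − SSres/SStot)
for strain comparison; the published coefficients (y = 1.348x − 0.723,
R² = 0.891) serve only as generator parameters for synthetic strain
pairs, since the underlying strain data are not deposited. Literature
ROM containment is inclusive at the bounds and judged at the printed
precision of each interval (half-ULP tolerance, 0.05° for one-decimal
bounds): a model angle can only be compared against an interval as
finely as the interval is printed — e.g. 8.84° against an interval
printed as 1–8.8 is within at that precision. The agreement test between
model and specimen-trajectory angle sets is a two-sided paired t-test at
α = 0.05 (pairs matched by joint × direction × condition; the source
names its statistics package but not the test; paired-by-design with
small n makes the paired t the natural choice), with Wilcoxon
signed-rank behind a flag. Degenerate inputs: identical pairs give p = 1
by convention; zero-variance nonzero differences give p = 0.

## Problem sizes and reproducibility

Defaults used throughout the examples and the acceptance script: 1200
frames per capture, 200-step moment sweeps, 1000 random transforms for
the registration oracle, 20–100 noisy-capture replicates, 200 synthetic
strain pairs. All stochastic stages consume explicit seeds; every output
file embeds the tool version, seed and configuration hash. TRC files
carry no free-text header, so their metadata lives in the ground-truth
sidecar JSON written alongside.

## Limitations

Rigid vertebrae only — no bone or disc deformation, no continuum stress
fields. Sagittal plane only (axial rotation and lateral bending are not
simulated at source either). Muscles, vessels and nerves are absent, as
in the in vitro preparation. The equilibrium module is a property-
validated surrogate, not a continuum solver. The synthetic generator's
noise model is simple (i.i.d. Gaussian plus independent dropout);
conclusions about real captures are limited accordingly.
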