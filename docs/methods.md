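# Methods

## Physical problem

A cylindrical soft sample (radius 50 mm, thickness 50 mm) is compressed by
a uniform surface pressure of 1000 Pa, ramped linearly over 1/6 s and then
held. During the hold every material element creeps; an ultrasound imaging
system is assumed to observe the axial strain of each 0.5 mm element in the
region beneath the transducer (radius 25 mm, full depth). Inverting each
element's creep curve with the standard-linear-solid (SLS) creep law
produces 2-D maps of the elastic modulus E, the Prony weight g and the
relaxation time τ_R. Because the inversion assumes the element's axial
stress equals the applied pressure — exactly true only in a homogeneous
uniaxial stress state — the accuracy of the maps depends strongly on the
loading pattern and the sample fixation. The package reproduces that
dependence for six loading/boundary configurations and reports, per
configuration and property, the percentage of imaging-region elements
recovered within 10% of the set value.

## Constitutive model and parameter conventions

The material is isotropic and homogeneous with elastic volumetric response
(bulk modulus K) and a one-branch Prony deviatoric response

    G(t) = G0 · [1 − g (1 − e^(−t/τ_R))],  G0 = G_∞ / (1 − g).

The inputs (E, ν) are interpreted as **long-term** elastic constants, so
G_∞ = E/(2(1+ν)) and K = E/(3(1−2ν)). Two consequences anchor the whole
study and motivate this convention:

* in a uniaxial stress state the long-term compliance is exactly 1/E, so
  the fitted E₁ equals the input E identically (the textbook identities
  E = E₁, g = E₂/(E₁+E₂), τ_R = η/E₂ hold);
* relaxation is deviatoric only, so under confined (zero lateral strain)
  compression the governing P-wave-type modulus M(t) = K + 4G(t)/3 relaxes
  by merely ~5% while the shear part relaxes by 80% — which is what makes g
  unrecoverable but τ_R exactly recoverable in the confined configuration.

With the study values (E = 10 kPa, ν = 0.495, g = 0.8, τ_R = 5 s):
K = 333.3 kPa, G_∞ = 3.344 kPa, G0 = 16.72 kPa. The uniaxial creep
compliance is a single exponential with retardation time
τ_R·G0/G_∞ = τ_R/(1−g) = 25 s; the instantaneous uniaxial modulus is
9KG0/(3K+G0) ≈ 49.34 kPa, so even the ideal configuration recovers an
apparent g of 1 − 10/49.34 ≈ 0.797 rather than 0.8 — the 0.34% bias of a
slightly compressible bulk, far inside the 10% band.

## Forward finite-element solver

Axisymmetric quasi-static FE on a structured grid of square 4-node
quadrilaterals (default 100 × 100 at h = 0.5 mm):

* **Element technology.** B-bar/selective reduced integration: the
  volumetric part of the strain-displacement operator, including the hoop
  term u_r/r, is replaced by its element-volume (r-weighted) average before
  2 × 2 Gauss quadrature. This removes volumetric locking at ν = 0.495 and
  is exact for the spatially uniform states that anchor the closed-form
  checks.
* **Time integration.** The deviatoric hereditary integral is advanced with
  the standard recursive exponential internal-variable update, exact for
  strain varying linearly within a step. With a constant step size the
  effective step modulus is constant, so the global matrix is factorised
  once per phase (scipy sparse LU) and reused; ramp and hold are two such
  phases (ramp: 10 steps of 1/60 s; hold: 0.1 s steps).
* **Loading.** The pressure acts as a consistent axisymmetric edge traction
  on the loaded top extent (full radius, or r ≤ R/2 for the half-coverage
  configurations; an arbitrary extent ending inside an element edge is
  integrated exactly). Equilibrium is monitored by the normalised vertical
  reaction balance, ~1e−12 in practice.
* **Kinematics.** Small-strain linear theory, consistent with the linear
  viscoelastic creep law used for inversion, although long-term strains
  reach ~0.1; geometric nonlinearity is a known unknown of the reference
  configuration and a recognised source of percentage-point-level
  differences in the boundary-layer configurations.
* **Sign convention.** All reported strain components are
  compression-positive (negated physical strains).

Single-element solves match the closed-form uniaxial and confined creep
responses to better than 3e−6 relative; on uniform states the solution is
mesh-objective to 1e−10.

## Creep-curve inversion

Each element's hold-phase strain series (t = 0 at the instant the pressure
plateau is reached) is fitted by bounded trust-region nonlinear least
squares over (E₁, E₂, τ_C), seeded by a moment-style guess (plateau
modulus, instantaneous-to-plateau ratio, 63.2% rise time), with unweighted
residuals and σ₀ fixed at the applied pressure. Non-converged or
degenerate fits propagate as infinite error downstream, i.e. they count as
inaccurate.

**Finite-ramp compensation.** For a linear ramp of duration t_r followed by
a hold, Boltzmann superposition turns the step-load exponential amplitude g
into g·κ(τ_C) with κ = (1 − e^(−t_r/τ_C))/(t_r/τ_C) ≤ 1, while leaving the
plateau and the time constant unchanged. Fitting the plain step-load law to
ramp-loaded data therefore biases the back-converted
τ_R = τ_C·(1 − g_fit) upward (+2.7% in the uniaxial state for
t_r = 1/6 s) — a pure artefact of ignoring a known feature of the
excitation. The fitter carries κ(τ_C) explicitly whenever a curve records
its ramp duration, so recovered parameters always refer to the ideal
step-load experiment; for single-exponential states the compensation is
exact. This matters quantitatively: the τ_R accuracy percentage of the
half-load/confined-side configuration sits on a knife edge (a large
fraction of elements hold τ_R errors between 8% and 12%), and the ~2–3%
ramp bias alone moves that percentage by tens of points.

## Accuracy statistic and maps

The error of each element is |fit − set|/set; an element is accurate when
its error is strictly below 0.10 (the wording "less than 10%" is taken
literally, so an element at exactly 10% counts as inaccurate). Percentages
are unweighted element counts over the half-map of the imaging region —
mirroring the map about the symmetry axis doubles numerator and denominator
alike. Horizontal-strain images mirror with a sign flip in the reflected
half so the full image reads as Cartesian lateral strain.

## Study conditions and problem sizes

Defaults reproduce the reference configuration: 100 × 100 mesh of 0.5 mm
elements, 1000 Pa, 1/6 s ramp, ν = 0.495, E = 10 kPa, g = 0.8, τ_R = 5 s,
imaging radius 25 mm (5 000 fitted elements). The hold duration, not fixed
by the protocol beyond "until steady state", is 150 s = 6 retardation
times; the uniaxial creep is then within 0.07% of its plateau, and fitted
parameters change only in the fourth digit for longer holds. (Strict
steady-state in the sense of a <1e−4 relative change over the final 5% of
the hold requires ≈10 retardation times; the solver meets that criterion
with a 250 s hold, as exercised in the tests.) The homogeneous-field
configurations (tests 1 and 3) are mesh-invariant, so desk-scale checks run
them on 10 × 10 or 25 × 25 meshes with identical accuracy rows; the
boundary-layer configurations (tests 2, 4–6) are only quantitatively
meaningful at the full resolution and are run there by the acceptance
machinery.

## Synthetic-data generator

`viscomap.synthetic` draws per-element curves directly from the SLS creep
law with optional multiplicative Gaussian noise ε·(1 + σ_noise·z), seeded
and bit-reproducible. It emulates the *shape* and scale of the FE-derived
curves (strains 0.02–0.1, exponential rise) and supports uniform,
vertical-gradient and checkerboard parameter grids for exercising the map
stages. It does not emulate ultrasound speckle, displacement-estimation
noise, or the boundary-condition-induced model error that the FE solver
exists to produce — so tests passing on synthetic data validate the
inversion machinery, not the imaging method's physics.

## Numerical choices and edge cases

* Fit tolerances: xtol 1e−12, ftol 1e−14, parameter scaling from the seed;
  noiseless self-consistency is recovered to 1e−6 relative.
* Degenerate curves (no strain increase) are flagged, not fitted.
* The initial-guess rise time falls back to half the first sample interval
  when the curve starts above its 63.2% level.
* Zero applied pressure yields identically zero strain histories and a
  zero reaction residual by convention.
* The symmetry axis always carries u_r = 0; the six configurations all
  constrain vertical rigid motion through the bottom support.

## Known limitations

Homogeneous samples only (no inclusions); no contact mechanics between
plate and sample (pressure is an applied traction); no dynamic or inertial
effects; small-strain kinematics at ~10% strain; single-branch Prony
material; no model of the ultrasound measurement chain. The reference
percentages for the boundary-layer configurations were produced by a
different FE code with unstated element type, step sizes and hold duration;
agreement there is expected at the level of a few percentage points, not to
the printed precision.
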