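# viscomap

Simulation and inversion pipeline for **ultrasound compressional
viscoelastography** — an imaging method that presses a plate onto a soft
sample, holds the pressure constant, and fits each image element's creep
curve (strain vs. time) to recover viscoelastic properties. The package
quantifies a central practical question of the method: *how do the loading
pattern and the sample fixation limit the accuracy of the recovered
property maps?*

It is aimed at researchers in tissue biomechanics and elastography who want
a transparent, fully scriptable stand-in for commercial finite-element
studies of this imaging modality.

## The model

The material is an isotropic, homogeneous, near-incompressible linear
viscoelastic solid (Poisson's ratio ν = 0.495). Its deviatoric response
relaxes through a one-branch Prony series with dimensionless relaxation
modulus

    g_R(t) = 1 − g (1 − e^(−t/τ_R)),        0 < g < 1,

applied to the instantaneous shear modulus G₀ = G_∞/(1−g); the volumetric
response is elastic. The imaging method models every element as a
Maxwell-form standard linear solid (spring E₁ in parallel with a
spring E₂ – dashpot η arm), whose creep under a step stress σ₀ is

    ε(t) = σ₀/E₁ · (1 − E₂/(E₁+E₂) · e^(−t/τ_C)),
    τ_C = η (E₁+E₂) / (E₁ E₂).

Fitting this law to each element's hold-phase strain and back-converting via
E = E₁, g = E₂/(E₁+E₂), τ_R = η/E₂ yields the three property maps. The
catch — and the subject of the study — is that the fit assumes each
element's axial stress equals the applied surface pressure σ₀, which is
only true for ideal loading and boundary conditions.

The forward problem (axisymmetric quasi-static FE with B-bar quadrilaterals
and a recursive exponential Prony update) is solved for six configurations:
pressure on the whole top surface or only its inner half (r ≤ R/2), bottom
fixed vertically or in all directions, side free or horizontally confined.
Each configuration's property maps are reduced to an *accuracy percentage*:
the fraction of imaging-region elements (r ≤ 25 mm) whose recovered E, τ_R
or g lies within 10% of the set values (E = 10 kPa, τ_R = 5 s, g = 0.8).

## Worked example

```python
from viscomap import StudyConfig, configure_test, run_simulation_test

config = StudyConfig(h=0.002)           # 25 x 25 mesh profile
for tid in (1, 3):
    r = run_simulation_test(configure_test(tid, config), config)
    print(tid, r.accuracy)
```

prints

```
1 {'E': 100.0, 'tauR': 100.0, 'g': 100.0}
3 {'E': 0.0, 'tauR': 100.0, 'g': 0.0}
```

Test 1 (full-surface pressure, bottom on frictionless rollers) realises a
homogeneous uniaxial stress state, so every element's fit recovers all
three properties within 10% — the method works perfectly. Test 3
(horizontally confined side) forces a zero-lateral-strain state governed by
the P-wave-type modulus M = K + 4G/3 ≈ 338 kPa instead of E = 10 kPa: the
fitted stiffness is ~34× too high and the apparent g collapses to ≈ 0.05,
so E and g fail in 100% of the region — yet τ_R is still recovered exactly,
because the retardation-to-relaxation conversion cancels the modulus
rescaling. Both outcomes follow in closed form from the package's analytic
oracles (`analytic_uniaxial_response`, `analytic_confined_response`).

The same pipeline is scriptable from a shell:

```bash
viscomap run --test 1 --out results/      # maps (CSV + PNG) and report CSV
viscomap synth --n 10 --noise 0.01 --seed 1 --out curves.csv
viscomap fit --curves curves.csv --sigma0 1000
```

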