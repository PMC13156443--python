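# thbr1 — orientation-dependent R1 relaxation in white matter

`thbr1` models the dependence of the apparent longitudinal relaxation rate
R1 = 1/T1 of human white matter on the angle θ between an axon bundle and
the main magnetic field B0, and on the field strength itself.  It is aimed
at quantitative-MRI researchers who have co-registered R1 maps and
diffusion-derived microstructure (principal eigenvector V1, NODDI
orientation dispersion index) and want to analyse — or simulate — angular
R1 profiles at one or several field strengths within a single biophysical
framework.

## The model

Water protons transiently hydrogen-bond to hydrophilic lipid heads of
cellular and myelin membranes.  The long-lived bound pool (index A)
exchanges magnetization with water through dipole–dipole coupling of
strength λ_A over a bond lifetime τ_A, producing diagonal and
cross-relaxation coefficients

    k_A = (3/4) λ_A [ (1/9) g0 L(0) + 2 g1 L(ωτ_A) + g2 L(2ωτ_A) ]
    K_A = (3/4) λ_A [ (1/9) g0 L(0) −      g2 L(2ωτ_A) ],

with the Lorentzian spectral density L(ωτ) = τ/(1+(ωτ)²), ω = γB, and
orientational coefficients

    g0 = (1/8)(1 − 30 cos²θ + 27 cos⁴θ)
    g1 = (1/8)(1 +  2 cos²θ −  3 cos⁴θ)
    g2 = (1/8)(3 +  2 cos²θ +  3 cos⁴θ).

Because τ_A is long (≈70 ns, so ωτ_A ≫ 1), the angular behaviour is
dominated by g0, whose minimum at cos²θ = 5/9 (θ ≈ 41.8°) produces the
broad low-R1 band around 40° seen in vivo.

The bound protons themselves relax through two-dimensional lateral
diffusion within the bilayer, with rate

    r1A(θ, Ω) = (Λ/2) [ sin²θ(5+3cos²θ) V0(Ω) + (16cos²θ+6sin⁴θ) V0(2Ω)
                        + (8−3sin⁴θ) V2(Ω) + (8+24sin²θ+3sin⁴θ) V2(2Ω) ],

where V0(Ω) ≈ 0.048 Ω^−1.10 and V2(Ω) ≈ 0.131 Ω^−1.31 for Ω ∈ [5, 25],
and Ω = (B/B_ref)·Ω0 scales linearly with field.  Exchange couples the two
pools through p_A = K_A / [(1−n_bA) r1A + n_bA k_A − r1w], and the
mono-exponentially fitted ("apparent") rate is the mixture

    R1app = (1 − ζ)(R1I + ΔR1wA) + ζ R1bA,
    ΔR1wA = n_wA (k_A − n_bA p_A K_A),
    R1bA  = (1−n_bA) r1A + n_bA k_A + n_wA n_bA p_A K_A,

with a per-field isotropic rate R1I and a small mixing fraction ζ.

The package provides:

* `thbr1.physics` — the closed-form forward model above, plus derived
  lateral-diffusion quantities (τ_d = Ω0/ω_ref, minimal approach distance
  d, diffusion coefficient D);
* `thbr1.binning` — fiber-to-field angles from V1 and B0, ODI-based voxel
  selection, and 4.5°-wide angle binning of voxel R1 into per-field curves;
* `thbr1.model` — `JointR1Model` / `JointR1Results`: joint Bayesian
  estimation of the shared biophysics (n_bA, n_wA, Λ, Ω0, ζ) across
  fields, with per-field R1I and noise scales, via an affine-invariant
  ensemble sampler;
* `thbr1.simulate` — synthetic angular curves and NIfTI voxel phantoms
  with Watson-dispersed fibers, including a large-axon ("CST-like")
  region reproducing the low-angle R1 dip;
* a `thbr1` command line (`simulate-curves`, `simulate-phantom`, `bin`,
  `fit`, `report`).

## Worked example

```python
import numpy as np
from thbr1 import JointR1Model, default_params, generate_curves
from thbr1.params import PUBLISHED_R1I

truth = default_params()            # published shared parameters,
                                    # calibrated coupling lambdaA ≈ 6.69e7
curves = generate_curves(truth, PUBLISHED_R1I,
                         noise_sd=0.02, n_per_bin=1, seed=42)
res = JointR1Model(curves).fit(seed=0)
print(res.summary())
```

prints

```
Joint angular-R1 fit (THB + lateral diffusion)
===============================================
fields [T]      : 1.5, 3, 7
fitted bins     : 18, 18, 18  (centers >= 13.5 deg)
fixed           : lambdaA=6.694e+07 1/s^2, tauA=7e-08 s, r1w=0 1/s

parameter         post. mean    post. SD
nbA                  0.57439       0.204
nwA                 0.035336      0.0223
Lambda                89.798        51.5
Omega0                16.313        5.93
zeta                0.014815      0.0118
R1I_1.5T              1.5489      0.0144
R1I_3T                1.1455     0.00891
R1I_7T                1.0334      0.0119
...
mean relative fitting error 3 T: 1.08 %
```

The generating truth (n_bA = 0.54, n_wA = 0.035, Λ = 23.1 s⁻¹, Ω0 = 9.1,
ζ = 0.0025; R1I = 1.56/1.14/1.03 s⁻¹) lies within the posterior spread of
every parameter.  The wide Λ and Ω0 marginals are real: at this noise
level the likelihood is nearly flat along a ridge where Λ and Ω0 trade off
through the V0/V2 power laws, so only the joint combination is tightly
determined.  With noiseless input the posterior collapses onto the truth
(fit errors below 1e-4 %).  The three lowest bins (0°, 4.5°, 9°) are
excluded from the likelihood: in vivo they are dominated by large-axon
cortico-spinal tracts whose microstructure depresses R1 below the
orientation model.

The same analysis from the shell:

```sh
thbr1 simulate-curves --seed 1 --out-dir out/curves
thbr1 fit    --config fit.yaml --seed 2 --out-dir out/fit
thbr1 report --fit-json out/fit/fit.json --config fit.yaml --out-dir out/rep
```

where `fit.yaml` lists the curve CSVs under `curves:`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults and
their calibration, the synthetic-data generators, numerical safeguards and
known limitations.
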