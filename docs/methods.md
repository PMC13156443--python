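# Methods

## Model

The forward model treats the apparent longitudinal relaxation rate of a
white-matter voxel as a mixture of three channels:

1. an **isotropic rate** R1I per field strength, collecting water–water
   relaxation and exchange with short-lived bound protons; it carries no
   angular information and is a free nuisance parameter of each dataset;
2. an **indirect anisotropic water term** ΔR1wA = n_wA (k_A − n_bA p_A K_A),
   generated by dipole–dipole magnetization exchange between water protons
   and lipid-bound protons inside transient hydrogen bonds (THBs);
3. a **direct bound-pool term** ζ·R1bA, the relaxation of the long-lived
   bound pool itself leaking into the mono-exponential fit with a small
   mixing fraction ζ.

The THB rates k_A, K_A depend on angle through the orientational
coefficients g0, g1, g2 (quartic polynomials in cosθ) and on field through
Lorentzian spectral densities evaluated at ω and 2ω.  The bound-pool rate
r1A is taken from a lateral-diffusion description of the bilayer: bound
protons diffuse two-dimensionally, and the spectral functions V0, V2 of
the dimensionless frequency Ω = ω·τ_d are approximated by the power laws
V0 ≈ 0.048 Ω^−1.10 and V2 ≈ 0.131 Ω^−1.31, stated valid for Ω ∈ [5, 25].
Outside that band the same power laws are evaluated and a warning is
logged; the package has no alternative expressions.

Assumptions inherited from this construction:

* axial symmetry — every angular quantity is even in cosθ, so angles fold
  into [0°, 90°] and eigenvector sign is irrelevant;
* a single long-lived bound pool with fixed lifetime τ_A; rotational
  contributions (picosecond correlation times) are neglected;
* mono-exponential signal fitting — multi-component T1 decay enters only
  through the ζ-mixture.

Several prefactors in the source equations admit more than one
typographical reading; the adopted readings (3/2, 3/4, 1/9, 1/8, Λ/2) are
centralised in `thbr1.physics.EQ_CONSTANTS`, and the alternative grouping
of the water-anisotropy expression is switchable
(`eq2_grouping="grouped"|"ungrouped"`, default grouped, chosen for symmetry
with the +n_wA n_bA p_A K_A cross term in R1bA).  In K_A the 1/9 weight
binds to the g0·L(0) term only, mirroring k_A; a keyword switches the
alternative.

## Parameters and defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| n_bA | bound protons engaged in water coupling | – | 0.54 |
| n_wA | water protons engaged in bound coupling | – | 0.035 |
| λ_A | THB dipole coupling strength | 1/s² | calibrated (≈6.69e7) |
| τ_A | THB lifetime (long-lived pool) | s | 70e-9 |
| Λ | lateral-diffusion strength | 1/s | 23.1 |
| Ω0 | ω·τ_d at the reference field (3 T) | – | 9.1 |
| ζ | bound-pool mixing fraction | – | 0.0025 |
| r1w | water–water contribution | 1/s | 0 (absorbed in R1I) |
| R1I | isotropic rate per field | 1/s | 1.56 / 1.14 / 1.03 |

Field contexts default to the exact scanner Larmor frequencies
63.661 / 123.174 / 297.208 MHz for 1.5 / 3 / 7 T; arbitrary fields use
γ = 2.675×10⁸ rad s⁻¹ T⁻¹.

**Calibration of λ_A.**  No numeric λ_A is published for this tissue; the
observed angular modulation is a few percent of the mean rate.  The default
is therefore set by `calibrate_lambda`: the smallest-residual λ_A for which
the 3 T peak-to-trough R1app anisotropy equals a target fraction (default
4%) of R1I(3 T).  The solution is capped by a conditioning bound: the
denominator of p_A, (1−n_bA) r1A + n_bA k_A − r1w, is linear in λ_A and
crosses zero at 7 T once λ_A exceeds ≈6.7×10⁷ 1/s² (r1A shrinks with field
while the long-lifetime k_A stays negative around the g0 minimum).  Beyond
the cap the model is singular at 7 T, so the calibration returns the
largest λ_A keeping the denominator at ≥25% of its λ_A = 0 value at every
angle and study field — in practice ≈6.69×10⁷, i.e. ≈1.7% anisotropy at
3 T and ≈5% at 7 T.  The 4% target is unreachable with a well-conditioned
three-field model under the adopted equation readings.

**Derived diffusion quantities.**  τ_d = Ω0/ω_ref with ω_ref = γ·B_ref
(≈11.3 ns for Ω0 = 9.1 at 3 T); (d, D) then solve the strength relation
Λ = (9π/(256 D d⁴))(ħγ²/2)² jointly with τ_d = d²/2D, closed-form through
d⁶ = 9π τ_d (ħγ²/2)²/(128 Λ).  Under this convention Λ = 23.1 1/s yields
d ≈ 34 nm and D ≈ 5×10⁻² mm²/s-scale values that are mutually consistent
by construction but do not reproduce literature bilayer diffusion
coefficients; the convention is documented rather than reconciled, and the
round-trip identity is enforced to 1e-9.

## Angular binning

Voxels are selected by ODI ∈ [0, 0.2] (inclusive bounds; optionally also
FA ≥ threshold), a defined nonzero eigenvector, and finite positive R1.
The fiber-to-field angle is arccos|v̂·b̂| in degrees; the magnet axis
defaults to world z and is configurable.  Bins are centred at 0°, 4.5°, …,
90° (21 bins); a voxel joins its nearest centre, exact ties to the lower
centre.  Per-bin SD uses the n−1 denominator (zero when n ≤ 1).
Registration is assumed done upstream; mismatched grids or affines raise a
geometry error rather than being resampled.

## Joint Bayesian fit

The likelihood is Gaussian on the bin means of every supplied field, with
the shared biophysics (n_bA, n_wA, Λ, Ω0, ζ) common to all fields, one
free R1I per field, and — by default — one free noise SD per field sampled
in log-space (a Jeffreys prior truncated to [1e-6, 1] 1/s); setting
`use_bin_sd=True` instead weights residuals by the curves' SD/√n.  λ_A and
τ_A are fixed (a sensitivity flag `sample_coupling` adds log10 λ_A to the
free vector; its near-degeneracy with n_wA is warned about).  Bin centres
below `angle_min` (default 13.5°, i.e. the 0°/4.5°/9° bins) are excluded
from the likelihood only — predictions at any angle are unchanged for
fixed parameters.  The low-angle exclusion reflects the in vivo
observation that near-parallel tracts (cortico-spinal, large axons) fall
below the orientation model.

Priors are uniform within bounds.  The Ω0 bound (2, 25) is anchored to the
validity band of the V0/V2 power laws: beyond Ω0 ≈ 25 every field's Ω
falls outside [5, 25] and the likelihood would be evaluated where the
spectral approximation is meaningless (an open-ended prior admits a
spurious posterior mode out there, at Ω0 ≈ 43 with ζ inflated and the
indirect channel switched off).

Sampling uses an affine-invariant ensemble (48 walkers, 2000 steps, 800
burn-in by default) with differential-evolution and snooker moves, seeded
end-to-end.  Walkers initialise around a multi-start bounded
least-squares MAP; half of them start spread over the shared-parameter
prior box because at realistic noise the likelihood is almost exactly flat
along a ridge where Λ and Ω0 trade off through the V0/V2 power laws (and
n_bA, ζ adjust in compensation) — an ensemble straddling the ridge lets
the moves traverse it, so posterior spreads measure the ridge rather than
one neighbourhood.  Post-burn-in samples whose log-probability lies more
than 300 units below the maximum are discarded: for a mixed posterior the
spread is O(dimension), while in the near-noiseless limit the posterior is
a needle and walkers still travelling from dispersed starts would
otherwise bias the summaries.  Diagnostics include the acceptance
fraction, an autocorrelation-based effective sample size (fits with ESS
below threshold are flagged, not suppressed), the pruned-sample count, and
a MAP refinement by local optimisation from the posterior mean.

Identifiability: with three fields and 18 bins each, n_wA and the R1I are
sharply determined; Λ and Ω0 individually are not — their marginal SDs
reflect the flat ridge and shrink only when the pair is constrained
externally.  Posterior-SD-vs-noise behaviour is therefore tested with the
ridge pinned.

## Synthetic data

`generate_curves` evaluates the forward model on the bin grid and perturbs
each bin mean with N(0, noise_sd/√n_per_bin); `n_per_bin=1` puts the full
noise SD on the bin value (the sd column is 0 then, per the curve
invariant).  `generate_phantom` builds NIfTI-backed voxel volumes: each
box region draws fiber axes from a Watson distribution (rejection-sampled,
seeded) about its mean direction, ODI is the deterministic NODDI map
(2/π)·arctan(1/κ), FA is a cosmetic monotone map 0.8(1−ODI/0.5) clipped to
[0, 1] (not a physical model), and voxel R1 is the forward model at the
voxel's angle plus Gaussian noise (default SD 0.05 1/s, a plausible
voxel-level scatter; the published bin SDs are not tabulated).  The
default two-region phantom has a main slab of fibers perpendicular to B0
and a "CST-like" slab with mean direction ≈5° off B0 whose bound-water
fraction n_wA is halved **and** whose R1I is scaled by 0.98.  The R1I
reduction is needed because, at the calibrated coupling, the indirect term
ΔR1wA changes sign inside the 0–9° band (k_A < 0 in the long-lifetime
regime), so reducing n_wA alone raises R1 in part of that band; reducing
the isotropic part as well matches the large-axon interpretation (fewer
THB-forming water protons in both channels) and produces the observed
low-angle dip.  The phantom emulates orientation dispersion, the ODI mask
and bin statistics; it does not emulate scanner noise correlations,
partial-volume mixtures, registration error, or any acquisition physics —
tests passing on it validate the pipeline's statistics, not those
real-data effects.

## Numerical choices

* Degrees at every interface, radians internally; all angular functions
  broadcast and are even in cosθ.
* p_A singularity: denominators below 1e-12 of their leading-term
  magnitude raise a diagnostic error naming the angle and field (or mark
  NaN inside the sampler, mapped to −inf posterior).
* Curve CSVs are written with 17 significant digits; numeric round-trips
  are lossless to 1e-12.  Empty bins carry n = 0 and empty mean/sd cells.
* Watson rejection sampling sizes batches by a running acceptance
  estimate, keeping extreme concentrations (κ ~ 1e6) efficient.
* Exit codes in the CLI: 0 success (including empty-mask results, which
  warn), 2 usage/configuration, 3 data/geometry, 4 numerical failure.

## Problem sizes

Default analyses are desk-scale: 21-bin curves at three fields; phantoms
of 24³ voxels; posterior sampling with 48×2000 ensemble steps (seconds per
fit on one core thanks to a fully vectorised likelihood); the recovery
study in the test suite uses 20 seeded replicates.

## Known limitations

* The V0/V2 power laws are extrapolated outside [5, 25] with only a
  logged warning; at 1.5 T the default Ω ≈ 4.6 already sits slightly
  below the band, and the 2Ω evaluations always exceed it at 7 T.
* Λ and Ω0 are reported with honest (large) posterior SDs; single-field
  fits leave the field scaling of Ω0 unconstrained entirely (warned).
* The derived (d, D) convention does not reproduce literature bilayer
  diffusion coefficients (see above).
* The anisotropy calibration cannot reach 4% of R1I at 3 T without making
  the 7 T model singular; the conditioning cap takes precedence.
* The low-angle dip is emulated phenomenologically; the package makes no
  mechanistic claim about large-axon microstructure.
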