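# Methods

## Observable and conventions

The package computes the product α(ω)·n′(ω) of the absorption coefficient
and the real refractive index, reported in cm⁻¹ on a wavenumber grid
ν̄ = ω/(2πc). It is obtained from equilibrium fluctuations of the
collective rotational dipole moment M⃗_D(t) = Σᵢ μ⃗ᵢ(t) of all molecules
in the box, through either of two routes:

* **current route** (preferred): α·n′ = [3Vk_BTcε₀]⁻¹ ∫₀^∞ C_JJ(t)cos(ωt)dt
  with C_JJ = ⟨J⃗_D(0)·J⃗_D(t)⟩ and J⃗_D = dM⃗_D/dt. No ω² amplifier, hence
  no baseline correction.
* **moment route**: the same with Φ_D = ⟨M⃗_D(0)·M⃗_D(t)⟩ and an ω²
  prefactor. It amplifies long-lag noise parabolically and is kept mainly
  as a consistency check (the two routes agree within 2% on smooth, fully
  decayed synthetic correlation functions; this is asserted in the tests).

All transforms use the one-sided (Laplace) convention; a Fourier-transform
implementation would carry an extra factor of two because autocorrelations
are even. The complex permittivity is ε̂(ω) − ε_∞ =
[⟨M_D²⟩ − ω∫Φ_D sin(ωt)dt + iω∫Φ_D cos(ωt)dt]/(3Vk_BTε₀); the relative
sign of the sine term is fixed by integrating −dΦ/dt by parts and is the
unique choice that reduces to the Debye form ε̂ ∝ 1/(1+iωτ) for an
exponential Φ_D (the tests assert both the Debye loss peak at ωτ = 1 and
the consistency identity α·n′ = (ω/c)ε″). ε_∞ is an input with default 1.

Internal units: Å, ps, e, D, K, with 1 e·Å = 4.80321 D; fields are
Gaussian-style e/Å² so that μ[e·Å] = α[ų]·E. The spectral prefactor is
assembled from CODATA constants at import time.

## Dipole assembly

**Permanent.** μ⃗ᵢ = Σ_β q_β r⃗_β (origin-independent only for neutral site
sets; non-neutral sets are rejected) plus, for distributed-multipole
models, the atomic permanent dipoles rotated from their local frames.
Local-frame conventions: oxygen z = bisector toward the hydrogen midpoint,
x in-plane (toward H1); hydrogen z = unit vector toward the oxygen,
x in-plane pointing toward the other hydrogen ("inward"); y completes
right-handed frames. These sign choices are the unique set reassembling
the published AMOEBA14 monomer dipole of 1.71 D — flipping the oxygen
dipole gives ≈1.39 D, flipping the hydrogen x component ≈2.54 D; the test
suite enumerates all four alternatives. Bond lengths not printed alongside
the charge tables (SPC/E 1.0 Å, SWM4-NDP 0.9572 Å, AMOEBA14 0.9565 Å,
IPOL-0.13 ≈1.0 Å, OPC3-pol 0.97888 Å) are shipped as named constants in
the per-model YAML files, taken from the respective model definitions.

Two documented data quirks: the SPC/E dipole is printed both as 2.36 and
2.35 D in the source tables; our constant-conversion value is 2.3517 D
and the package standardizes on 2.35. The OPC3-pol charge set (−0.610 e /
+0.305 e) yields 1.66 D at the OPC3 geometry, well below the 2.05 D quoted
for the full model — that partition mixes permanent and Drude
contributions ambiguously, so the package treats the printed charges as
the permanent set, reports the resulting 1.66 D, and leaves the
permanent/induced split configurable.

Atomic quadrupoles are stored as symmetric tensors in D·Å exactly as
tabulated (|trace| ≤ 1.5·10⁻³ after symmetrization) and rotated as RΘRᵀ;
the `one_third` convention divides the tabulated values by three, the form
simulation engines consume.

**Induced.** Drude models: μ⃗ⁱⁿᵈ = q_D·d⃗ with d⃗ the displacement from the
fixed to the mobile Drude particle. Point-polarizability models and
post-trajectory polarization solve μ = α(E⁰ + Tμ) per frame:

* interaction tensor T(r) = (3r̂r̂ᵀ − I)/r³, optionally Thole-damped
  (exponential damping of the r⁻³/r⁻⁵ terms with u = a·r/(αᵢαⱼ)^{1/6},
  a = 0.39 by default). The bare tensor is the faithful default; Thole
  damping is recommended for dense liquid-like configurations because the
  bare tensor diverges once an αT eigenvalue reaches 1 (polarization
  catastrophe — detected and reported with the offending site pair).
* permanent field sources: intermolecular charges by default; atomic
  point dipoles and traceless point quadrupoles (Buckingham convention,
  φ = (3/2)(n̂·Θ·n̂)/r³) can be switched on per run. Intramolecular
  permanent-field and mutual-induction terms are always excluded — the
  only choice that leaves an isolated rigid molecule field-free.
* solvers: damped fixed point (mixing 0.7, tolerance 10⁻⁶ D, ≤200
  iterations, warm-started across frames) and a direct dense solve of
  (I − αT)μ = αE⁰. Both are exposed; they agree to 10× the tolerance on
  random clusters of up to 12 molecules (oracle test, 100 clusters).
* boundaries: open cluster, or cubic minimum image with a real-space
  cutoff (default 9 Å) and a cosine switch-off (default 1 Å width).
  Ewald-type dipolar lattice sums are out of scope; with a cutoff
  approaching half the box the minimum-image result coincides with the
  open cluster on configurations that fit inside the cutoff (tested).

Post-trajectory polarization of a non-polarizable trajectory places the
polarizability on oxygen only (hydrogens stay unpolarized, standard for
water) and defaults to charges-only field sources; the SPC/E file carries
the elevated α = 1.14 ų used for this purpose.

## Correlation estimation and decompositions

Correlations ⟨A⃗(0)·B⃗(t)⟩ are estimated by FFT with unbiased per-lag
normalization, lags restricted to half the series by default (cross terms
are noisy at long lags). The FFT estimator equals the naive double loop to
10⁻¹⁰ (oracle test). Rotational currents are central differences on the
stored dipole series (trajectories need not carry velocities); the
one-sided endpoints are excluded, and the scheme is recorded on the
correlation object so the spectral transform divides out the filter's
sinc²(ωΔt) transfer function — at Δt = 4 fs this matters at the 7% level
near 650 cm⁻¹ and would otherwise distort relative peak intensities.

Self/cross: C_self sums per-molecule current autocorrelations (molecules
are statistically equivalent, so they are averaged and scaled by N);
C_cross = C_total − C_self, with the O(N²) double sum retained as a test
oracle. Permanent/induced: the total current is correlated against each
channel, C_perm = ⟨J⃗_D(0)·J⃗_D^perm(t)⟩ and likewise for the induced part.
Both closures (self+cross = total, perm+ind = total) are exact linear
identities of the estimator and are asserted to 10⁻⁹ at every lag.

The discrete cosine transform is a direct trapezoidal quadrature over the
retained lag window — no zero padding, no taper by default (a Hann taper
is deliberately not applied; the current route needs no baseline
handling). The value of a current-route spectrum at ν̄ = 0 is set to
exactly zero: the rotational current carries no d.c. conductivity, and the
quadrature residual there is pure estimator noise. Total-channel spectra
from true autocorrelations are positive up to that noise; decomposition
channels (cross, induced) may legitimately be negative.

Smoothing follows the Savitzky–Golay convention (default window 21
points, order 3 — the sources state no values) with optional scaling by
the maximum. The 200 cm⁻¹ feature is classified on the smoothed spectrum:
"yes" for a strict local maximum in 150–300 cm⁻¹, "shoulder" for an
inflection plateau (local minimum of the first derivative) without a
maximum, else "no"; window bounds are configurable.

## Synthetic librator

The generator emulates rigid water molecules reorienting by damped
harmonic libration superposed on orientational diffusion. Per molecule, a
base orientation performs isotropic rotational diffusion — composed small
random rotations whose per-step mean is tuned so the rank-1 orientational
correlation is *exactly* e^{−t/τ_r} at the discrete step — and two small
libration angles about the transverse body axes are stationary Gaussian
processes with covariance σ_k²e^{−γ_k t}cos(ω_k t) per mode, realized
exactly as x₁(t)cos(ωt) + x₂(t)sin(ωt) with exact-discretization
Ornstein–Uhlenbeck factors (no integrator drift at any admissible Δt; an
aliasing guard rejects ω_kΔt > 0.5). The molecular-dipole ACF then has the
exact closed form C₁(t) = e^{−t/τ_r}[S + C(S + C)] with
S = e^{−s}sinh(sρ(t)), C = e^{−s}cosh(sρ(t)), s = Σσ_k², and ρ the
normalized mode-covariance mixture; to leading order in the amplitudes
a_k = 2σ_k² this is e^{−t/τ_r}[a₀ + Σ a_k e^{−γ_k t}cos(ω_k t)]. The
generator returns the exact descriptor, and the empirical collective ACF
matches it within 5 standard errors over seeded independent blocks.

Default study conditions: 8 molecules in an 18 Å box, SPC/E dipoles, two
modes (amplitude 0.10 at 200 cm⁻¹, damping 2.0 ps⁻¹; amplitude 0.16 at
650 cm⁻¹, damping 2.5 ps⁻¹), τ_r = 8 ps, Δt = 4 fs. Molecules are
dynamically independent by design, giving a sharp test of the self/cross
split (cross = 0 in expectation); a correlated variant shares the
diffusing base orientation between molecules (fixed small per-molecule
offsets) to produce genuinely nonzero cross terms. Molecular centers are
static: the librator models reorientational dynamics only, which is what
the rotational-current observable probes.

What the librator does *not* emulate: liquid structure (no radial
distribution or hydrogen-bond statistics), translational motion, coupling
between induction and dynamics, and physical cross-correlation
mechanisms. Passing the recovery tests therefore demonstrates estimator
and transform fidelity — that injected spectral content is recovered at
the right positions and relative intensities — not force-field realism.

## Benchmark problem sizes

The mode-recovery benchmark averages the collective current ACF over 8
independent trajectories of 65536 frames × 8 molecules (≈262 ps each,
4 ps lag window, spectral grid 4.17 cm⁻¹, Savitzky–Golay window 13).
These sizes come from a variance estimate targeting ≈3% statistical error
on the smoothed peak-intensity ratio against its 5% acceptance band. The
analytic reference spectrum is pushed through the *identical* estimator
chain (same lag window, grid, transfer-function correction and
smoothing), so discretization and smoothing biases cancel and the
comparison isolates estimator noise; recovered peak positions agree with
the reference to the grid step and the intensity ratio to ≈1% at the
default seed. The analysis driver uses a 4 × 32768 variant of the same
experiment.

## Known limitations

* No Ewald or reaction-field treatment of dipolar interactions; the
  minimum-image cutoff sum is adequate for the cluster-scale systems the
  package targets, not for production-scale dielectric constants.
* The SWM4 Drude polarizability is stored as the canonical
  α = q_D²/k_D = 0.97825 ų; polarizability scaling acts on α directly
  (the pipeline never consumes the force constant).
* Permittivity estimates require the moment ACF to decay inside the lag
  window; an undecayed tail flags the estimate rather than failing.
* AMOEBA-style anisotropic polarizabilities and charge-flux/charge-transfer
  terms are not modeled.
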