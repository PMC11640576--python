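# Methods

## Physical model

The simulator treats tissue as `N_s` discrete point scatterers at positions
`P_s` with nonnegative cross-section weights `ρ_s`, each radiating as a
dipole driven by the incident field (first-order Born approximation; single
scattering only).  The fibre-coupled detector current per wavenumber is

    I(k) = |α_scat(k) + α_mirr(k)|²
    α_scat(k) = Σ_s ρ_s (Ex(P_s; k))²
    α_mirr(k) = Δ_N Σ_t ρ_mirr (Ex(x_t, y_t, z_mirr; k))²

where `Ex` is the x component of the focused incident field and the mirror
sum runs over a uniform grid on the reference-mirror plane.  The incident
beam is x-polarised; low-NA operation justifies ignoring the longitudinal
component in detection (it is still computed by the reference field
routines).  Depth attenuation can be emulated by making `ρ_s` a function of
depth; detector noise, dispersion and spectrometer roll-off are *not*
modelled.

The focal field of the aplanatic objective is the vectorial Debye–Wolf
diffraction integral with Gaussian pupil apodization
`φ(s; k) = exp(−(kW)² |s|²)`.  After the analytic azimuthal reduction it is
a single integral over the aperture angle `θ ∈ [0, arcsin(NA/η)]` with
`J0/J1/J2` Bessel kernels, which `octsim.dwi_reference` evaluates with
fixed-order Gauss–Legendre quadrature (200 nodes by default; a node-doubling
self-check is available and a grid-of-points cross-validation against an
independent 2-D tensor quadrature of the unreduced pupil integral is part of
the test suite).  The azimuthal reduction leaves the `cos θ` weighting of
the longitudinal row ambiguous; both variants are implemented
(`ez_includes_cos_theta`), the default keeps the common `cos θ` prefactor,
and detection is unaffected either way because only `Ex` enters `α_scat`.

The A-scan is the discrete inverse Fourier transform of the spectrum over
the uniform k grid, evaluated at the round-trip argument `2z`.  Because the
depth-encoding cross term carries `exp(+2iηk(z_s − z_mirr))`, the forward
DFT kernel (`np.fft.fft / N`) is the transform that maps positive optical
path difference to ascending depth bins; the depth pixel is
`π/(η Δk N_fft)`.  By default the self-beat backgrounds `|α_scat|²` and
`|α_mirr|²` are removed before the transform, keeping the real cross term;
`background="complex"` transforms `α_scat · conj(α_mirr)` for one-sided
phase-sensitive processing, and `background="raw"` reproduces the plain
detected intensity.  No window and no zero padding are applied by default
(`window="hann"`, `pad_factor` available).

## Taylor source-grid acceleration

Factoring the rapid axial phase out of the Bessel-reduced integrand,
`Ex = −ifk e^{iηkz} (h0 + cos 2ψ · h2)`, leaves two component integrals
`h_c(ρ, z; k)` whose axial rate is only `ηk(1 − cos θ_max)` — at NA 0.1 two
orders of magnitude below the optical oscillation — and which are analytic
in both coordinates.  Their mixed derivatives

    S(c, m, n, j, l; k) = ∂^{m+n} h_c / ∂ρ^m ∂z^n  at source points (ρ_j, z_l)

are computed by differentiating under the integral sign: each axial order
multiplies the integrand by `iηk(cos θ − 1)`, each radial order by
`ηk sin θ` together with the Bessel-derivative identity
`J_c^{(m)} = 2^{−m} Σ_i (−1)^i C(m, i) J_{c−m+2i}` (negative orders folded
by parity).  The field anywhere in the covered domain follows from the
truncated double Taylor series about the nearest source point (ties to the
lower index).  Defaults: radial order `D_ρ = 20`, axial order `D_z = 8`,
spacings `s_ρ = 28 µm`, `s_z = 190 µm`, cell-centred sources so the maximum
offset is half a spacing per axis.  Factorials are never folded into `S`;
the series is evaluated with factorial-scaled Horner recursions in `n`
inside `m`, which keeps order-20 terms bounded and limits rounding.

Storing `D_z0` extra axial orders turns the same array into a fast
displacement series: `h(ρ, z+δ) ≈ Σ_{n0 ≤ D_z0} δ^{n0}/n0! · ∂^{n0}_z h`,
with each derivative itself Taylor-reconstructed via an index shift into
`S`.  The order rule `D_z0 = ceil(0.15 · M_s)` (maximum axial displacement
`M_s` in µm) keeps the truncation below the package error budget; the
displaced field also re-applies the factored phase at `z + δ`.

## Multi-spectral regression

Every pupil integrand has the parametric form
`d(s) e^{−a(s)²k²} e^{ib(s)k}` with geometry-dependent but k-independent
`a, b`.  Complex coefficient functions `C_j(k)` are fitted so that
`e^{−α²k²} e^{iβk} ≈ Σ_j C_j(k) e^{−α²k_j²} e^{iβk_j}` over
`α ∈ [0, W·NA/η]` (the physical apodization range) and `|β| ≤ B`, where

    B = ρ_max·NA + z_max·NA²/η + η·D/2      (24.5 µm for the reference geometry)

bounds the residual pupil phase over the scan volume and one depth band
(`defocus_half=True` selects the small-angle variant with the halved second
term).  The residual is linear in `C_j(k)`, so the fit is an ordinary
complex least-squares problem solved by SVD (`lstsq`) — one factorization
covers every k because only the right-hand side depends on k — on a training
grid of 32 α × 129 β points, with held-out residuals reported on a doubled
grid.  The fit is deterministic; no optimizer seed exists.  With the default
`L = 35` anchors over the 1170–1408 nm spectrum the held-out residual is at
rounding level (~1e−12).

Substituting the anchor reconstruction into `α_scat` and grouping scatterers
into depth bands of thickness `D = 15 µm` (band centres `(h−½)D`, boundaries
assigned to the lower band, per-scatterer shift `Δ = ẑ_h − z_s`) gives the
band-assembled form over cross-modal coefficients
`α_cross(j1, j2, h) = Σ_{s∈h} ρ_s E_s(k_{j1}) E_s(k_{j2})`, reducing the
per-wavenumber cost to `H·L²` products.  The cross-modal table is stored
with its upper triangle mirrored so the `(j1, j2)` symmetry is exact to the
bit.  When the focus is set by translating the axial coordinate, band
centres are likewise expressed in the focus-relative frame, which is
algebraically identical to the surface-referenced form.

## Defaults and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| NA | 0.1 | – | reference low-NA OCT objective |
| spectrum | 1170–1408 | nm | 1300 nm spectral-domain instrument class |
| η | 1.0 | – | air/immersion-free reference case |
| W | 5.5 | µm | reproduces the ~13 µm FWHM lateral resolution of the instrument the default spectrum models; the focal amplitude is `exp(−η²ρ²/4W²)` so FWHM = `2W√(2 ln 2)/η` |
| f | 10⁴ | µm | linear amplitude scale only; cancels from normalized outputs |
| quadrature nodes | 200 | – | resolves the worst axial oscillation at 1 mm depth with ~1e−9 node-doubling residual |
| ρ_max | 70 | µm | field 70 µm off axis is < 1e−3 of the focal peak |
| D_ρ, D_z, s_ρ, s_z | 20, 8, 28 µm, 190 µm | | recommended operating point; integral error ≪ 3e−4 |
| L, D | 35, 15 µm | | anchor count and band thickness of the regression |
| mirror grid | 129², half-width 4 beam waists | | Riemann-sum truncation < 1e−4; evaluated by grouping equal radii (exact) |
| N_k floor | `2ηz_max(k_max−k_min)/π` | | depth-Nyquist bound, enforced at validation, explicitly overridable |

The phantom density default, 7.8125×10⁻³ µm⁻³, is the reference speckle
condition (312 500 scatterers in 200×200×1000 µm³).

## Accuracy metric

All fidelity statements use the relative integral error
`Err(Fa) = Σ|Fr − Fa|² / Σ|Fr|²` over uniformly sampled arrays (fields,
A-/B-/C-scans); `U = 3×10⁻⁴` is treated as negligible.  Note this is a
squared-norm ratio: `Err = 3e−4` corresponds to ~1.7 % RMS amplitude error.
Mixed-resolution comparisons must be resampled by the caller.

## Synthetic phantoms

`sample_generator` draws i.i.d. uniform scatterer positions in a box at the
reference density (or a requested count), with optional depth-dependent or
region-dependent cross-sections.  Deformations are axial only: uniform
strain maps `z → z(1+ε)` (negative ε = compression, motion toward the
surface), and the elliptic-cylinder inclusion integrates its
piecewise-constant strain field from the surface downward along each
A-line, which makes the displacement continuous across the inclusion
boundary and reduces exactly to the uniform map when the two strains agree.
What this does **not** emulate: lateral/shear deformation (deferred to
external mechanical models), multiple scattering, index heterogeneity,
noise.  Passing tests therefore demonstrate fidelity of the image-formation
chain and of parameter recovery on clean axial-motion data, not performance
on real tissue.

## Demonstration strain estimator

`phase_difference_strain` recovers local axial strain from the depth slope
of the interload phase `φ(z) = arg(A_loaded conj(A_unloaded)) ≈ 2ηk̄ δz(z)`.
It is a deliberately simple stand-in for published elastography pipelines
(no 3-D unwrapping, no cross-B-scan weighting) with three robustness
devices, each needed on speckle:

1. **Matched-filter de-aliasing.**  The interload phase can wrap many times
   across the fit window, so the dominant ramp is found by maximizing the
   coherent sum `|Σ_z q(z) e^{−isz}|` over a frequency grid (721 points to
   the ±π-per-pixel limit), with a parabolic sub-grid refinement clamped to
   half a grid step (the objective can be near-flat when a few bright
   pixels dominate, where the unclamped parabola is meaningless).
2. **Gated scale-warp iteration.**  When the estimated motion across the
   window exceeds a quarter depth pixel, the loaded A-line is re-sampled at
   `z(1+ŝ)` by exact evaluation of its band-limited interpolant and the
   bulk phase is removed before re-estimating the residual ramp (four
   passes).  Sampling comoving with the deformation shifts the
   displacement-induced carrier from the spectral centre `k̄` to the lowest
   wavenumber `k_min` (the DFT bin-phase reference); the removal accounts
   for this, and the residual mismatch ramp appears at `2ηk̄(ε−ŝ)` as
   required for convergent updates.  For sub-pixel motion the fixed-frame
   phase slope is already unbiased and warping is skipped — a pure-scaling
   warp would otherwise bias displacement fields with a depth offset (an
   inclusion under an overburden).
3. **Weighted regression with wrap exclusion.**  The final slope adds an
   `|A_unloaded|²`-weighted linear regression of the residual phase, with
   pixels whose residual jumps exceed π between neighbours flagged as
   wrapped/decorrelated and excluded (the count is reported).

On noiseless discrete-reflector fixtures the estimator recovers −0.5, −3
and −10 millistrain to ~0.1 %; on speckle phantoms single-A-line estimates
scatter by a few percent (occasionally failing entirely on unlucky
realizations, as real phase-difference elastography does), so recovered
values are reported as medians over several A-lines.

## Reduced reference experiments

The rigorous path makes full-scale replication (multi-hour volume scans,
3×10⁵-scatterer phantoms) pointless for verification, so the package's own
reference experiments are scaled down while keeping the stated physics
parameters: the fidelity benchmark uses 500 scatterers in the full
70 µm × 1 mm domain at 256 wavenumbers (aliased identically in both
backends, as the depth-Nyquist floor for 1 mm is 578); speckle statistics
use a 70-A-line strip at the reference density and 192 wavenumbers; strain
recovery uses 3×3 and 9-line scans of 20 000–65 000-scatterer phantoms.
`scripts/acceptance.py` re-runs these from scratch.

## Known limitations

* Single scattering only; no comparison against full-wave solvers.
* Linear x input polarization; other states would need a second set of
  pupil kernels.
* The displacement series covers axial motion only; lateral scatterer
  motion requires re-preparation or the rigorous path.
* The MSR training family assumes the Gaussian-apodized pupil; other
  apodizations require adapting the α range.
* Absolute field amplitude is retained from the raw kernels but all
  published-style comparisons are on normalized images; the focal length
  only scales amplitude.
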