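# Methods

## Kinetic model

The simulator and the analytic reference rest on a three-compartment,
well-mixed description of a FLIP experiment: aggregates `A`, cytoplasm
`C`, nucleus `N`, with first-order exchange `k1` (C→N) and `k_m1` (N→C),
slow release from aggregates `k2` (A→C, no rebinding — released protein
is far more likely to be bleached than recaptured), and an effective
bleach rate `k3` acting on the whole cytoplasmic pool. The well-mixed
(bleach-limited) assumption means diffusion inside a compartment is fast
relative to bleaching, so the dynamics are an ODE, not a PDE, and every
pixel trace is a linear combination of at most three exponentials
`exp(l1 t), exp(l2 t), exp(l3 t)` with

    l1 = -k2,
    l2,3 = [-(k1 + k_m1 + k3) -/+ sqrt((k1 + k_m1 + k3)^2 - 4 k_m1 k3)] / 2.

Since the aggregate pool feeds the others but receives nothing back, its
eigenvalue decouples exactly; this is why the slowest DMD mode of a FLIP
stack with aggregates measures the release rate directly, while the
other two eigenvalues mix all rate constants and are not individually
identifiable from decay data (the classic non-orthogonality of real
exponentials). The direction convention for `k1`/`k_m1` is immaterial
for the symmetric validation set `k1 = k_m1`.

Validation rate set: `k1 = k_m1 = 0.016194`, `k2 = 0.005`,
`k3 = 0.617582` s⁻¹, chosen by inverting the eigenvalue sum/product
relations so that the analytic eigenvalues are
{−0.005, −0.6342, −0.01577} s⁻¹ (4–5 printed decimals). `solve` uses the
3×3 matrix exponential; `trajectory` uses the eigen-decomposition with a
matrix-exponential fallback when the eigenvector basis is
ill-conditioned (near-coincident eigenvalues). Both agree with a
black-box LSODA integration to better than 1e−8 relative error.

## Simulator

`default_scene` builds a 128×128 scene at 0.125 µm/pixel, 1 s/frame,
300 frames: an elliptical cell and nucleus, three circular aggregates of
radii 2, 4, 6 px in the cytoplasm, a 5 px circular bleach ROI (rendered
with cytoplasm intensity — the ROI is part of the cytoplasmic pool, with
no separate intra-ROI kinetics), and optionally a neighbor cell of
constant intensity (no bleaching reaches it). Initial intensities are
`A0 = 200`, `C0 = N0 = 100`, neighbor 150 (arbitrary units): aggregates
brighter than the soluble pool, and cytoplasm/nucleus *not*
pre-equilibrated against the bleach, because bleaching starts at t = 0;
this gives the fast eigencomponent a physically honest, non-negligible
amplitude in the data. These values are free choices of the package; the
quantities the acceptance script reports (eigenvalues, mode
assignments) are insensitive to them.

Sub-pixel aggregate positions are rasterized with an anti-aliased disk
(per-pixel coverage `clip(r − dist + 0.5, 0, 1)`), accurate to ~1% of
the disk area; hard rasterization would make a moving aggregate's total
intensity flicker and contaminate the singular spectrum. Edge pixels are
coverage-weighted blends of aggregate and cytoplasm intensity, which
keeps a static scene exactly rank 3 (+1 with a neighbor cell).

Brownian motion draws per-axis Gaussian steps of std
`sqrt(2 D dt)/pixel_size` via the Box–Muller transform of two uniform
deviates (default `D = 0.004 µm²/s`, matching measured small-aggregate
diffusivities); flow subtracts `v/pixel_size` px/frame along −x
(default `v = 0.00625 µm/frame`, i.e. 5% of a pixel). All randomness
(motion, then noise) is consumed from a single seeded generator, so a
scene renders bit-identically given its seed. A trajectory that would
carry an aggregate across the image boundary is clipped with a warning.

Noise default is Gaussian with sigma = 2% of the initial maximum; at
this level the hard-threshold rank selection reliably retains the three
kinetic components. A Poisson (photon-counting) option is provided with
`photon_scale` counts per intensity unit.

What the simulator does *not* emulate: intra-compartment concentration
gradients during bleach pulses, bleach-pulse photophysics, cell motion
or deformation, autofluorescent background, detector offset/gain
structure, and 3-D sectioning. Tests passing on these synthetic stacks
therefore demonstrate correctness of the decomposition machinery under
the stated kinetic model, not robustness to every artifact of real
microscope data; the slow lateral drift real cells show appears in real
data as non-zero imaginary mode parts, which the analysis surfaces but
the simulator only produces via aggregate motion.

## Decomposition

Exact DMD: `Ã = U_r* X′ V_r Σ_r⁻¹`, eigenvalues from `Ã`, modes
`Φ = X′ V_r Σ_r⁻¹ W`. Projected modes (`Φ = U_r W`) are available by
option and share the eigenvalues; exact modes are the default because
they are the standard choice of mainstream DMD libraries. Amplitudes
solve least squares against the *first* snapshot only (standard
practice; fitting all snapshots is a different estimator). The mean is
not subtracted, so static structure (background, unbleached neighbor
cells) appears as a λ ≈ 1 mode rather than being removed. Modes are
sorted by |ω| ascending; "mode 0" is always the slowest dynamics.

Rank selection uses the Gavish–Donoho optimal hard threshold for
unknown noise level, τ = ω(β)·σ_median with
ω(β) ≈ 0.56β³ − 0.95β² + 1.82β + 1.43. Two numerical guards: at least
one singular value is always kept, and singular values below 1e−10 of
the leading one are treated as numerical zeros (on an exactly low-rank
matrix the "noise bulk" is rounding error and the median rule would
otherwise count garbage).

Rescaling uses the principal complex logarithm, ω = log λ / Δt, so
Im ω ∈ (−π/Δt, π/Δt]; eigenvalues on the negative real axis alias to the
Nyquist frequency and produce a warning. λ = 0 is rejected (it cannot
arise after truncation). An all-zero stack is an error, not a zero
model. Reconstruction takes the real part of Σ φ_j λ_j^n b_j with n = 0
at the first frame, making the discrete and continuous forms agree at
t = n·Δt; prediction evaluates the same expansion past the fitted
window and warns if any |λ| exceeds 1 + 1e−6.

## Mode interpretation

Mode-to-region assignment computes, per mode, the fraction of Σ|Re φ|
mass inside each user-supplied region mask and labels the mode with the
argmax region (ties toward the earlier-listed region, logged). |Re φ|
rather than |φ|² is the default so the sign structure of the maps does
not influence assignment; `metric="abs"` switches to |φ|. A mode is
reported "immobile/stable" when |Re ω| ≤ 1e−4 s⁻¹ and "exchanging"
otherwise; the threshold is a reporting convention, not a biological
claim, and is configurable at the module level. Mode maps are exported
in the stack's native orientation with no flipping.

## Metrics

PSNR uses the clean stack's maximum as the peak (float stacks have no
bit-depth peak) and returns +inf for identical stacks. The pixel-wise
stretched-exponential comparator fits `I(t) = I0 exp(−(t/τ)^h)` by
bounded least squares (h ∈ [0.2, 3]), initialised at I0 = first sample,
τ = interpolated 1/e crossing time, h = 1; non-decaying traces and
failed optimisations are flagged with rss = inf rather than guessed.
Per-pixel fitting skips pixels whose initial intensity is below 2% of
the stack maximum, which keeps background out of rate statistics. Rates
are reported as −1/τ (loss-rate sign convention); the h-corrected mean
time constant τ·Γ(1/h)/h is exposed as a property for users who want
the stretched-aware average.

## Problem sizes and determinism

The package's own validation uses the full 128×128×300 default scene
for the headline checks (rank-3 recovery, neighbor mode, rank
selection) and smaller stacks (24×24, 60–150 frames) for oracle
cross-checks and seed sweeps; ensemble statistics use 1000 Brownian
trajectories and 10–20 noise seeds. Every stochastic test and the
acceptance script draw all randomness from explicit seeds; the
acceptance quantities are deterministic up to the seed only through the
(noise-free) simulations, so repeated runs with different seeds produce
identical output.

## Known limitations

- Decay data cannot uniquely attribute the two mixed eigenvalues to
  individual rate constants; only the aggregate-release rate is
  identifiable per se. The toolkit reports eigenvalues, not rate
  constants, for this reason.
- With noise, the fast mixed eigenvalue is estimated with substantial
  bias (it lives in very few frames); the slow modes are the reliable
  ones.
- No image registration or background subtraction is applied before
  fitting; experimental stacks with large drift should be registered
  upstream, or the drift will surface as imaginary mode structure.
- The simulator's well-mixed assumption means it cannot generate
  diffusion-limited FLIP data; validating against that regime requires
  a reaction–diffusion model, which is out of scope.
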