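# flipdmd

Model-free decomposition of fluorescence-loss-in-photobleaching (FLIP)
time-lapse data by dynamic mode decomposition (DMD), plus the
compartmental FLIP simulator used to validate it.

## The problem

In a FLIP experiment a small region of a cell is bleached repeatedly
while the whole field is imaged; the rate at which fluorescence drains
from each pixel reports on how fast tagged protein exchanges with the
bleached pool. This is the standard assay for telling liquid-like
protein condensates (fast exchange) from solid aggregates (slow or no
exchange), e.g. for polyglutamine-expanded mutant Huntingtin fused to
eGFP. Classical analysis fits a decay model pixel by pixel, which is
slow and requires choosing a model. `flipdmd` instead treats the whole
stack at once and is model-free.

## The method

Frames are flattened into columns of two snapshot matrices shifted by
one frame, X = [x₁ … x_{k−1}] and X′ = [x₂ … x_k], and the best linear
propagator X′ ≈ A X (a finite-dimensional Koopman approximation) is
analysed through a rank-r truncated SVD X ≈ U_r Σ_r V_r*:

    Ã = U_r* X′ V_r Σ_r⁻¹,   Ã W = W Λ,   Φ = X′ V_r Σ_r⁻¹ W

Each spatial mode φ_j evolves as a single complex exponential with
discrete eigenvalue λ_j, rescaled to a physical per-second rate
ω_j = log λ_j / Δt; amplitudes b solve Φ b ≈ x₁ and the stack is
approximated by x(t) = Σ_j φ_j e^{ω_j t} b_j. The truncation rank
defaults to the Gavish–Donoho optimal singular-value hard threshold, so
signal/noise separation needs no tuning parameter — truncation doubles
as denoising. Decay rates of modes localised on aggregates measure the
protein release rate directly.

The bundled simulator renders a cell (nucleus, cytoplasm, circular
aggregates, bleach ROI, optional unbleached neighbor cell) whose
compartment intensities follow the three-compartment kinetic ODE

    dA/dt = −k₂A,  dC/dt = k₂A + k₋₁N − (k₁+k₃)C,  dN/dt = k₁C − k₋₁N

with analytic eigenvalues l₁ = −k₂ and
l₂,₃ = [−(k₁+k₋₁+k₃) ∓ √((k₁+k₋₁+k₃)² − 4k₋₁k₃)]/2, plus optional
Brownian (Box–Muller) or flow motion of an aggregate and
Gaussian/Poisson noise.

## Worked example

```
$ flipdmd simulate --preset basic --frames 300 --dt 1.0 --noise-sigma 0.02 --seed 7 --out stack.tif
wrote stack.tif (300 frames) + ground truth + scene sidecar
$ flipdmd fit stack.tif --rank optimal --out model/
rank 3 model -> model; slowest omega = -0.0050428 1/s
$ head -4 model/eigenvalues.csv
mode_index,re_omega,im_omega,abs_lambda,re_b,im_b
0,-0.00504276699279632,0.0,0.9949699264110862,2581.9384047273693,0.0
1,-0.01577287321310897,0.0,0.9843508671171829,2714.1093173365243,0.0
2,-0.6335095420785308,0.0,0.530725923773065,-15527.35541050576,0.0
$ flipdmd reconstruct model/ --out recon.tif
$ flipdmd evaluate --clean stack_clean.tif --test recon.tif --out eval/
PSNR = 51.19 dB -> eval
$ flipdmd evaluate --clean stack_clean.tif --test stack.tif --out eval_noisy/
PSNR = 33.98 dB -> eval_noisy
```

The hard threshold keeps exactly three modes at 2% noise. Mode 0 is the
aggregate-release mode: its fitted rate −0.00504 s⁻¹ recovers the
simulated release rate k₂ = 0.005 s⁻¹ within 1%; modes 1 and 2 recover
the two nucleo-cytoplasmic eigenvalues (true values −0.01577 and
−0.6342 s⁻¹). The rank-3 reconstruction raises PSNR against the clean
ground truth from 34.0 dB (raw noisy input) to 51.2 dB — the
decomposition denoises the sequence as a side effect. On a noise-free
stack the same fit returns all three rates to 1e−6 s⁻¹.

Other subcommands: `predict` extrapolates frames beyond the acquired
window, `modes` exports 2-D mode maps, per-mode stacks and the
unit-circle eigenvalue table. The same functionality is available as a
library (`flipdmd.fit`, `flipdmd.reconstruct`,
`flipdmd.assign_modes_to_regions`, …).

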