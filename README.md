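# densesim

Simulation of 2D short-axis **cine DENSE** (displacement encoding with
stimulated echoes) cardiovascular MR images with **sub-voxel ground-truth
myocardial strain**, and evaluation of regularized strain analysis against
that ground truth.

## Why

Cine DENSE encodes tissue displacement since end-diastole in the image
phase (u = φ / 2π k_e), making it one of the most accurate CMR strain
methods — but the analysis chain that turns noisy phase images into strain
requires spatial regularization, and the smoothing level k trades noise
suppression against systematic underestimation, especially of radial strain
near the endocardium. In vivo there is no ground truth to quantify that
trade-off. `densesim` provides one: it generates realistic DENSE cines from
synthetic anatomies whose Green–Lagrange strain

E = ½(FᵀF − I),  Err = r̂ᵀE r̂,  Ecc = ĉᵀE ĉ

is known analytically at every pixel and time, so the bias (average signed
error, true − estimated) and variance of any strain pipeline can be
measured exactly. Intended users: developers of DENSE/strain analysis
methods and of learning-based strain models needing supervised ground truth.

## The pipeline

1. **anatomy** — end-diastolic label maps from a parametric annulus or an
   imported binary mask (NIfTI/PNG), plus polar geometry (transmural
   coordinate, radial/circumferential directions).
2. **motion** — closed-form contractile polar deformations: blendable
   transmural radial-strain gradient (constant ↔ incompressible annulus),
   2D twist, systole-weighted timing; analytic displacements and
   ground-truth Green strain.
3. **acquisition** — Bloch-simulation DENSE imaging: stimulated-echo
   encoding (k_e = 0.1 cycles/mm), variable flip angles, intravoxel
   dephasing via N1→N2 Fourier gridding, Hamming excitation window,
   4-interleaf / 2-cycle spiral sampling with ECG jitter and T2* decay,
   SNR-calibrated complex noise, 2-point phase cycling, x/y/0 encoding
   combination.
4. **strain_eval** — phase → displacement, spatiotemporal unwrapping, the
   Laplacian-regularized grid fit `argmin ‖A L − E‖² + λ(k)‖∇²L‖²`,
   Lagrangian tracking, order-10 temporal polynomial, Green strain with the
   same operator as the ground truth.
5. **cohort** — seeded virtual cohorts across SNR strata and the summary
   statistics: pooled pixel ASE ± std by smoothness / stratum / transmural
   tertile, transmural profiles, Bland–Altman of global peak strain.

## Worked example

`examples/04_strain_recovery.py` simulates one annulus case at myocardial
SNR 10 and recovers strain at four smoothness levels:

```
measured ES SNR: 10.7

   k    Err ASE+/-std      Ecc ASE+/-std   (true - estimated, ES)
  0.1   +0.007 +/- 0.045   -0.001 +/- 0.019
  0.3   +0.009 +/- 0.040   -0.001 +/- 0.014
  0.6   +0.013 +/- 0.038   -0.001 +/- 0.009
  0.9   +0.023 +/- 0.053   -0.001 +/- 0.005
```

Reading: each row compares estimated end-systolic pixel strain with the
ground truth (positive Err ASE = underestimated wall thickening). As k
rises the error std shrinks (noise suppressed) while radial strain becomes
increasingly underestimated — concentrated subendocardially, where the true
strain gradient is steepest. Circumferential strain stays nearly unbiased
throughout. The other examples cover anatomy (`01`), ground-truth strain
closed forms (`02`), the acquisition chain (`03`) and a mini cohort (`05`).

A thin CLI wraps the same library:

```bash
dense-sim simulate --seed 1 --out case.h5
dense-sim evaluate --case case.h5 --k 0.9 --out strain.h5
dense-sim cohort --out results/ --seed 0
```

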