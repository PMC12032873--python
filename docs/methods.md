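# Methods

`densesim` simulates 2D short-axis cine DENSE (displacement encoding with
stimulated echoes) cardiovascular-MR acquisitions of synthetic beating
anatomies, with analytically known sub-voxel Green–Lagrange strain, and
evaluates a Laplacian-regularized strain-analysis chain against that ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Anatomy

The end-diastolic (ED) anatomy is a label map (0 background, 1 myocardium,
2 blood pool) on an N1 × N1 raster, default 240 × 240 at 0.8 mm. Pixel
centers sit at `(index + 0.5) · pixel_size` with physical coordinates
relative to the raster center; one convention shared by every module
prevents half-pixel drift between the ground truth and the images.

Two sources are supported: a parametric annulus (pixels labelled by center
radius against the endo-/epicardial diameters) and an imported binary
myocardial mask, which is Gaussian-smoothed (σ = 1 input pixel — the value
is not critical; it just suppresses staircase edges before interpolation),
cubic-spline interpolated to the target raster, thresholded at 0.5, and
optionally dilated up to 6 px (manual contours tend to run thin). The blood
pool of an imported mask is inferred by hole-filling, our convention for
masks that only delineate myocardium.

Polar geometry: the LV center is the centroid of blood + myocardium; the
transmural coordinate is `d_endo / (d_endo + d_epi)` from the two Euclidean
distance transforms (half-pixel corrected so interfaces sit at 0 and 1);
radial/circumferential unit vectors follow the outward ray through each
pixel. For an ideal annulus this agrees with `(r − r_endo)/(r_epi − r_endo)`
to within a pixel.

## Motion model

Myocardial pixels move under a closed-form polar map

    r'(r, t) = r − a(t) f(r),    θ'(r, t) = θ + a(t) · ρ · g(r)

with ρ the peak rotation (2D twist) and g(r) a transmural twist profile
(constant by default, optional linear falloff). The radial profile f is the
exact blend

    r'(r) = (1 − γ) · [linear map, constant radial strain E_err]
          + γ · sqrt(r² − c)     (area-preserving)

anchored at the endocardium by the circumferential amplitude: the
endocardial radius contracts by `sqrt(1 − 2 E_ecc)`, so `peak_ecc_scale`
*is* the magnitude of peak endocardial Ecc. `transmural_err_gradient` γ
interpolates between a transmurally constant radial strain (γ = 0) and the
endocardium-weighted, approximately linear gradient of an incompressible
annulus (γ = 1, where det F ≡ 1 exactly). We chose the closed-form blend
over a quadratic polynomial fit of the same target because the fit leaves
±3% Jacobian ripple on thick walls while the blend is exact in both limit
cases; every controllable property (twist, transmural gradient, timing) is
unchanged.

Temporal activation a(t) rises as `sin(π t / 2 t_ES)` — faster early in
systole than late, as in vivo — reaching 1 at end-systole (default
`es_fraction` 0.35 of the R-R interval) and relaxing along a raised cosine
back to 0 at end-cycle. Diastolic untwisting asymmetry and rapid/slow
filling phases are not modelled. Ground-truth displacements are evaluated
analytically at exact times; nothing is interpolated. The map is monotone
in r for all valid parameters, so the deformation cannot fold; a Jacobian
check still guards the constructor.

Ground-truth strain: the deformation gradient F comes from central
differences of deformed pixel positions on the regular ED raster (one-sided
at wall edges; pixels without usable neighbours are flagged invalid), then
E = (FᵀF − I)/2, projected as Err = r̂ᵀE r̂ and Ecc = ĉᵀE ĉ. On the
incompressible-annulus closed form (r_endo 30 → 24 mm: Ecc = −0.18,
Err = 0.28125 at the endocardium) the operator matches per-pixel closed
forms to < 0.1% at ×4 oversampling, with discretization error falling
monotonically ×1 → ×2 → ×4.

## DENSE acquisition

Each labelled pixel is a spin isochromat with 3T properties (myocardium
T1/T2 = 1200/50 ms; blood 1900/250 ms, M0 ×1.2; background M0 = 0). The
signal model has two terms per isochromat:

* **stimulated echo** — amplitude `½ M0 sin(α_i) Π_{j<i} cos(α_j)
  exp(−t/T1)`, phase `2π k_e (x(t) − x(0))·ê` plus the phase-cycling offset
  (k_e = 0.1 cycles/mm; 10 mm wrap period). Blood is additionally damped by
  `exp(−t/T_washout)` with T_washout = 25 ms — the dark-blood washout is
  stated behaviour, the exponential form and constant are our model.
* **T1-recovery echo** — amplitude `M0 (1 − exp(−t/T1)) sin(α_i)`, phase
  `2π k_e x(t)·ê` (position-, not displacement-encoded), no cycling offset.
  n-point phase cycling (weights `e^{−iθ_p}/n`, offsets 0 and π for the
  2-point default) cancels it exactly in this two-term model.

Variable flip angles follow the standard constant-stimulated-echo backward
recursion `tan α_i = sin α_{i+1} exp(−Δ/T1_myo)` over the merged pulse
train (both interleaves of a cycle, spacing dt/2), ending at 15°.

Isochromats are gridded by direct Fourier evaluation onto an N2 × N2
(default 60) k-space and image — the N2 < N1 truncation is what produces
intravoxel dephasing. The image is multiplied by a radial Hamming
excitation profile with half-maximum diameter 0.6× the FOV (floor 0.08),
approximating the reduced-FOV excitation of the first two pulses.

Spiral sampling uses 4 uniform-density Archimedean interleaves at 90°
increments, each reaching `k_max = Nf/(2 FOV)` with `⌈Nf/8⌉` turns and an
11 ms readout; sample count is 1.2× the Nyquist arc length. The timing law
is `t_lci = t_start + ε_c + dt (l−1)/2 + dt·i` (t_start 15 ms, dt 30 ms,
ε_c ~ U[−5, 5] ms per cardiac cycle), interleaves combining into frames at
`t_start + dt/4 + dt·i`, with optional interpolated frames at
`t_start + 3dt/4 + dt·i` built from the complementary interleaf pairing.
The frame count fills the R-R interval unless set explicitly. Ground-truth
motion is sampled at the *jittered* interleaf times, so inter-interleaf
motion inconsistency artifacts appear exactly as acquired. Each sample is
weighted `exp(−τ/T2*)` (T2* = 40 ms) along the readout. Because the object
is band-limited by the N2 gridding stage, spiral samples outside the N2
spectral support (|kx|, |ky| ≤ N2/2FOV) carry no signal — evaluating the
pixelized image's transform there would alias its periodic replicas —
while receiver noise is still added to every sample. Density
compensation uses the analytic area element `2π k_max |k| / (N_int M)`;
reconstruction is the density-compensated adjoint evaluated directly on the
Nf × Nf grid. All non-uniform Fourier steps are exact separable direct DFT
evaluations (no gridding kernels); a noise-free static phantom
reconstructs with < 1% NRMSE against the Cartesian reference.

An idealized `sampling="cartesian"` path (each frame at its nominal
combined time, Fourier zero-padding to Nf, no readout decay) provides the
artifact-free reference used in validation.

Noise: complex white noise of per-sample std σ is added to the measured
spiral samples of every phase-cycle acquisition. σ is calibrated in two
passes — the noiseless end-systolic x/y magnitudes in the myocardial ROI
(deformed mask eroded by 1 px to drop the partial-volume rim) are perturbed
in a pixel-domain Monte-Carlo (common random numbers) and σ root-found so
the measured SNR (mean/std of magnitude in the ROI) meets the target; an
analytic gain `sqrt(Σ w_j² / n_pc)` maps sample-σ to image noise. Two
caveats, both inherent to the mean/std magnitude definition: (i) large
thick-walled annuli (epicardium near the Hamming half-maximum radius) have
noiseless heterogeneity SNR of only ~8–17, so the highest targets are
unreachable there and σ = 0 is returned with a warning; (ii) measured SNR
departs from strict 1/σ proportionality at low SNR through the Rician
floor — doubling σ reduces SNR by ~×1.8, not ×2.0, exactly as the
pixel-domain Monte-Carlo model predicts. Calibration itself stays within
a few percent of the target whenever the target is reachable.

Final images: magnitude = mean of x/y-encoded magnitudes; phase = x/y
phase minus the 0-encoded phase, wrapped to (−π, π].

## Strain evaluation

Phase converts to wrapped Eulerian displacement `u = phase/(2π k_e)`.
Spatial unwrapping per frame uses the reliability-guided algorithm of
scikit-image inside the analysis mask (the known simulated contour,
deformed per frame — semi-automated contouring is out of scope); the
per-frame global period offset is fixed by temporal congruence of the
masked medians, seeded at the first (lowest-motion) frame.

Per frame, the unwrapped samples are fitted to a regular grid (the image
raster windowed to the anatomy, +2 px margin) by

    argmin_L ‖A L − E‖² + λ(k) ‖∇² L‖²

with A bilinear (one-hot when samples coincide with nodes), ∇² the stacked
second differences in x and y, and `λ = k/(1−k) × mean‖A_i‖²/mean‖∇²_i‖²`.
This relative-row-norm mapping emulates the original gridfit tool's
normalization; the original's exact internal scaling is unpublished, and
this mapping is the principal fidelity caveat when comparing error tables
quantitatively. The normal equations are solved sparsely (factorized per
frame, shared across components); a 1e-8-scaled ridge is added with a
warning if k = 0 leaves nodes unconstrained. On grids ≤ 12 × 12 the sparse
solution matches a dense solve to 1e−8.

Lagrangian trajectories of the ED material points (image-resolution pixels
inside the ED wall) come from fixed-point iteration `x = x₀ + U_f(x)` with
bilinear sampling of the fitted field (≤ 5 iterations, 0.01 px tolerance),
then an order-10 temporal polynomial (shared Vandermonde least squares on
times rescaled to [−1, 1]; order reduced with a warning if frames are
scarce; fitting precedes strain computation). Strain uses the *same*
central-difference operator and polar projection as the ground truth, and
the ground truth is also evaluated on the same material grid, so operator
discretization cancels from the comparison.

End-systole: the ground-truth ES frame (nearest to `es_fraction · R-R`) is
used for pixel-error comparisons (both maps need the same frame); peak
|global Ecc| of an estimated series is available where no ground truth
exists. Global peak strain is spatial-mean-then-extremum (max for Err, min
for Ecc).

## Virtual cohort and statistics

The desk-scale default: 24 annulus-only cases, 8 per ES-SNR stratum
([3.9, 6.1], [8.3, 11.5], [13.9, 17.7]), ground truth 120 × 120 at 1.6 mm
(the same 77–115 mm physical annuli as the full-scale setting, epicardial
diameter U[48, 72] px, endo/epi ratio U[0.5, 0.8]), N2 = 60, Nf = 64,
R-R U[825, 1200] ms, peak rotation U[−0.5, 0.5] rad, transmural gradient
γ U[0.2, 1.0], constant-strain component U[0.20, 0.35], endocardial Ecc
amplitude U[0.12, 0.20] (amplitude ranges chosen to span physiological
peak strains). `CohortConfig.full_scale()` restores the published-scale
design (180 cases, 240 × 240 at 0.8 mm, Nf = 128). Child seeds derive from
the master seed; a cohort is bit-reproducible from (config, seed).

Statistics: pixel signed error (true − estimated, so positive radial ASE
means underestimated thickening) pooled across cases per smoothness,
stratum and transmural tertile, with per-case means reported separately
(whether published tables pool pixels or average cases is unstated; we
report both); second-order transmural profiles by ordinary least squares;
Bland–Altman bias ± 1.96 SD limits on global peak strain.

On the desk-scale cohort the expected regularization trade-off reproduces:
pooled ES radial-strain error std falls monotonically with k (0.091 →
0.047 from k = 0.1 to 0.9 at master seed 0) while endocardial |ASE| rises
(0.015 → 0.074); circumferential strain is nearly unbiased at every k.
Error *magnitudes* sit below the published full-scale study's, as expected:
the Nf = 64 grid differentiates displacement noise over coarser pixels, the
cohort is annulus-only (no XCAT/patient-contour anatomy variability), and
the smoothing-weight normalization is our reconstruction of an unpublished
internal scale.

## What the synthetic data do not emulate

B0 inhomogeneity, coil sensitivities and concomitant gradients (so
simulated noise is spatially whiter than in vivo); background torso
tissues; through-plane and long-axis motion; the right ventricle;
systolic/diastolic twist asymmetry; contouring error (analysis masks are
exact). Passing tests therefore demonstrate correctness of the simulation
and analysis chain and the regularization bias–variance structure — not
absolute in-vivo error levels.

## Problem sizes used in validation

The bundled validation suite runs the 24-case desk-scale cohort plus
single-case checks (Cartesian round trip, SNR calibration with 20 noise
realizations per target); the acceptance script re-runs the cohort at
k ∈ {0.1, 0.3, 0.9}. The full-scale 180-case design is supported but not
exercised by the bundled suites.
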