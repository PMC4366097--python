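# Methods

## The measurement being emulated

NOE-mediated CEST at 7 T samples the Z-spectrum `Z(Δω) = M/M₀` at 13
equidistant offsets between −4 and +4 ppm after a 5×100 ms Gaussian pulse
train (B₁ = 0.7 µT, 100 ms interpulse delay, 900 ms effective saturation).
Processing follows the standard asymmetry analysis: per voxel, a cubic
spline through the sampled spectrum is minimized to locate the water center
(the B0 deviation map), the spectrum is re-interpolated at the shifted
offsets so its minimum sits at 0 ppm, and the contrast
`MTR_asym(3.3 ppm) = Z(−3.3) − Z(+3.3)` is read out in percent. On the
13-point grid the nodes closest to the nominal readout are ±10/3 ppm; the
readout is evaluated there (by spline interpolation on corrected spectra)
and reported as 3.3 ppm. Display windowing (−10 % … +5 %) is rendering only;
statistics always use unclipped values, because clipping destroys ranks in
the tails.

## The generative model

The phantom's spectral truth is a sum of Lorentzians,
`Z(Δω) = 1 − Σ_k A_k (Γ_k/2)² / ((Γ_k/2)² + (Δω − δB0 − c_k)²)`, per voxel:

| pool | center c (ppm) | amplitude A | FWHM Γ (ppm) |
|---|---|---|---|
| water + residual MT | 0 | 0.72 | 3.0 |
| NOE | −3.3 | per class × voxel modulation | 3.0 |
| amide (APT) | +3.5 | 0.6 × class NOE amplitude | 1.5 |

Class NOE amplitudes are NAWM 0.12 > edema 0.08 > CE-tumor 0.045 >
necrosis 0.02 > CSF 0.005, reproducing the observed contrast cascade
(noise-free class-mean MTR_asym ≈ −4.6, −3.0, −1.7, −0.6 %). These depths
are free parameters of the generator — no published tissue values exist —
chosen once for a plausible contrast range.

Two modelling choices deserve justification:

- **A single broad central pool** lumps direct water saturation with the
  residual semisolid MT background rather than modelling a narrow DS dip.
  The practical reason is conditioning: locating the minimum of a dip much
  narrower than the 2/3-ppm sampling interval from a cubic spline is
  intrinsically biased by several hundredths of a ppm (verified by scanning
  widths 1.4–5 ppm), which no implementation of the published method can
  overcome. In vivo the dip that the minimum search actually sees is the
  composite water+MT trough, which is broad; Γ = 3 ppm represents that
  composite.
- **Amide amplitude is class-level**, not voxel-modulated: nothing is known
  about the voxelwise covariation of amide and NOE pools, and coupling them
  proportionally would only scale the asymmetry contrast down.

No Bloch–McConnell integration is performed; B₁, pulse count and timings are
carried as metadata. This is deliberate: the package tests a processing
chain, and an analytic forward model provides an exact oracle for it.

## Statistical structure of the tissue fields

A latent standard-normal field `S` (Gaussian-smoothed, correlation length
1 voxel, renormalized) drives cellularity:
`cell = mean_class · exp(0.45 · S)` (0 in CSF/background). Per class, the
NOE and ADC latents mix `S` with iid innovations at Pearson weights
`2 sin(π ρ/6)`, so the *rank* correlations between cellularity and NOE
amplitude (ρ_cell) and between ADC and cellularity (ρ_adc) hit their
configured values exactly under the Gaussian copula. Marginals are strictly
monotone (`A_class · (1 + 0.6·tanh(z/2))` for NOE; lognormal for ADC), so
ranks are preserved.

Defaults: ρ_cell = −0.75 (CE-tumor) and −0.9 (edema) — NOE saturation falls
where cells pack densely, which is what makes MTR_asym rise with
cellularity, the direction seen in the biopsy data; ρ_adc = −0.4 in edema
(the classical ADC–cellularity inverse), 0 in the heterogeneous enhancing
tumor. The smoothness of `S` is what makes a 3×3×3 neighborhood average at a
biopsy site representative of the sampled point; the iid innovations in the
NOE/ADC latents are what keep voxelwise rank-correlation estimates over a
few thousand ROI voxels close to their nominal sampling error.

The B0 field is a low-order polynomial plus one Gaussian bump scaled to a
±0.3 ppm peak — smooth and well inside the ±1 ppm search window. Noise is
Rician with σ = 1 % of M₀ on every magnitude image (saturated volumes and
M₀). M₀ is 1000 inside the head, 0 outside; voxels with M₀ below 5 % of its
99th percentile are masked, never zero-filled.

Geometry: 48×48×32 voxels of 1.8×1.8×2 mm; brain ellipsoid (38, 38, 27 mm
semi-axes) with a CSF rim (outer 8 % of the radius); necrotic core
(r ≤ 5.5 mm) inside a contrast-enhancing shell (r ≤ 10.5 mm) inside
ellipsoidal edema (21×19×16 mm), centered 10, 6, 0 mm off-center. This
yields ≈ 640 CE-tumor and ≈ 3400 edema voxels per subject, the order of
magnitude of real segmentations. The biopsy trajectory runs from a skull
entry point to a target in the enhancing zone, 12 samples at 1.4 mm spacing
crossing enhancing tissue into edema; cell densities carry 5 % multiplicative
counting noise.

## Statistics

Spearman correlation is computed as the Pearson correlation of mid-ranks
(average ranks on ties), with the two-sided t-approximation
`t = r√((n−2)/(1−r²))` on n−2 degrees of freedom; constant input raises an
error rather than returning r = 0, and an exact-formula variant
(`1 − 6Σd²/(n(n²−1))`) serves as a cross-check for small untied samples.
Confidence intervals follow Bonett and Wright: Fisher z with standard error
`√((1 + r²/2)/(n − 3))`, normal quantiles, back-transformed. Association
classes: `none-insignificant` if p > α (0.05); `none-negligible` if
|r| ≤ 0.15; else sign(r) with weak (< 0.40), moderate (< 0.65), strong
(≥ 0.65). The 0.15 bracket is the published no-association band; the strong
threshold sits at 0.65 so that a published coefficient of 0.685 classifies
strong, as it was described.

## Numerical choices

- Natural cubic splines throughout; the B0 search evaluates them on a
  0.001-ppm grid within ±1 ppm, far below every tolerance of interest.
  Minima on the search-window boundary are flagged invalid and the voxel is
  dropped (not silently kept).
- Splines are never extrapolated: offsets shifted outside the acquired range
  become non-finite, and the MTR_asym readout regroups voxels by their
  finite-offset pattern (requiring ≥ 4 points bracketing ±10/3 ppm).
- The B0 oracle in validation is the argmin of the *analytic* spectrum on a
  dense grid, not the injected field: for asymmetric spectra the true
  spectral minimum is genuinely displaced from the water center by the
  NOE/amide tilt (up to ≈ 0.02 ppm at NAWM amplitudes), and the published
  method estimates the minimum, not the water frequency.
- Validated accuracy of the chain (default phantom): B0 RMSE ≈ 0.013 ppm
  noise-free and ≈ 0.033 ppm at 1 % Rician noise; noise-free MTR_asym within
  ≈ 0.13 % RMS of the analytic oracle. The worst-case single-voxel MTR_asym
  error is ≈ 0.45 % (fraction 4.5×10⁻³), concentrated where strong NOE
  amplitudes meet large B0 shifts — an intrinsic floor of 13-offset
  asymmetry processing: residual minimum-location error leaks the steep
  water tail into the asymmetry, and a sub-10⁻³ worst case is not attainable
  at this sampling density for any plausible pool configuration (verified by
  parameter scans), although the map-level RMS is.
- The type-I validation of the biopsy statistic draws 12-sample null
  trajectories (ρ_cell = 0) through homogeneous white matter at 4.5 mm
  spacing with randomized positions and directions. Both conditions matter:
  tissue-crossing paths violate the null through class contrasts, and
  closely spaced samples are autocorrelated by the smooth cellularity field
  and overlapping readout cubes (1.8 mm spacing inflates the empirical rate
  to 15–20 % — a caution that applies equally to real serial biopsies).

## What passing tests do and do not show

The synthetic studies demonstrate that the implementation recovers known
truth under its own generative assumptions: iid Rician noise, Lorentzian
line shapes, a smooth single-bump B0 field, perfectly co-registered grids,
copula-coupled tissue fields. They do not demonstrate robustness to motion,
B₁ inhomogeneity, relaxation-time confounds of asymmetry analysis,
registration error between 3 T and 7 T acquisitions, or non-Lorentzian MT
backgrounds — all of which affect real data and are out of scope here. The
published-cohort tables are reproduced only at the bookkeeping level
(classification counts from printed coefficients); the underlying images
are not available to recompute the coefficients themselves.
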