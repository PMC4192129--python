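# Methods

## Scope and design

The package reproduces, on synthetic data, the measurement and analysis
chain of a grating-based phase-contrast CT study of paired murine kidneys
(contralateral control vs ischemia-reperfusion injury): Talbot
phase-stepping acquisition, tri-contrast retrieval, filtered
back-projection, compartment segmentation, volumetry and statistics.
Everything downstream of the phantom treats the phantom as an unknown
specimen; ground-truth labels are used only (a) to validate results in
tests, and (b) as the stand-in for one manual segmentation step (below).

## Phantom

**Geometry.** The kidney is a set of nested ellipsoids inside a paraffin
cylinder inscribed in the grid (the embedding block; vacuum outside).
Compartment shells, as fractions of the organ semi-axes: outer stripe of
the outer medulla (OSOM) boundary 0.80, inner stripe (ISOM) 0.66, inner
medulla (IM) 0.48. Only compartment topology and volume *ratios* matter
to the analysis, so no anatomical meshes are used. The IM core is
deliberately larger (≈10% of parenchyma) than in a real mouse kidney
(≈4.5%): the analysis counts histogram peaks with a 5%-prominence
detector, and a 4.5% compartment sits at the edge of detectability; the
enlargement changes no reported ratio.

**Vasculature.** A recursively bifurcating tree (4 generations, root
radius 3.4 voxels, radius decay 0.82, length decay 0.72) is rasterized as
capsules from a hilum point. Segments are detoured around an ellipsoid
1.3× the IM semi-axes — macroscopic renal vessels arc around the medulla
— which also keeps the vessel point-spread halo away from the smallest
compartment. Tubule voids (small ellipsoids, ~90 in the control) are
scattered in cortex/OSOM/ISOM, excluding a 6-voxel zone around vessels.

**Material properties.** Per-voxel values are compartment means times
(1 + Gaussian texture, SD 1% of the mean), clipped at zero. Relative δ
means: paraffin 1.00, cortex = OSOM 1.05, ISOM 1.10, IM 1.15, vessel
lumen 0.90, tubule void 0.95; for the injured kidney all four tissue
compartments collapse to 1.08 (merged histogram). The absolute scales are
δ = relative × 1e-7 and β = relative × 2e-9 — physically plausible for
soft tissue at 19 keV — chosen so that transmission stays near 80% and
the differential phase stays well below the ±π wrap limit (max |Δφ| ≈ 1.2
rad at defaults). ε is nonzero only in tissue: a small parenchymal
baseline (0.05 mm⁻¹) plus an elevated 1-voxel rim around each tubule void
(1.0 mm⁻¹), representing dark-field scattering at tubule-tissue
interfaces; both are reduced after injury.

**Injury calibration.** The I/R phantom rebuilds its control counterpart
(same seed and grid) and then bisects three scalars against voxel-count
targets: the outer-shell scale (tissue retained = `shrink_total`, default
0.46, tolerance 0.5%), the IM scale (`im_retain`, default 0.95, tolerance
1%), and a root-first centerline length budget that prunes the vessel
tree (`vessel_retain`, default 0.18, tolerance 1%). Pruning by length
rather than radius models vascular rarefaction and keeps the per-vessel
partial-volume behavior comparable between conditions, so segmented
vessel ratios track ground truth. Tubule voids are reduced to 25% of the
control count. All randomness derives from the spec seed; repeated calls
are bit-identical.

## Forward model

Parallel beam, unit magnification (synchrotron geometry), detector pixel
= voxel size (7.5 µm). Projections are computed by rotating the volume
about the z axis (linear interpolation, fixed frame) and summing along
one axis; path lengths in mm. The interferometer operates at 19 keV
(λ = 1.23984/E nm), p₁ = 4.78 µm, p₂ = 2.4 µm, at the 11th fractional
Talbot distance d = m·p₁²/(8λ) ≈ 481.5 mm of a π grating. Per pixel and
angle the K = 4 stepping intensities are

    I_k = I₀ · e^(−∫μ dz) · [1 + V₀ · e^(−∫ε dz) · cos(2πk/K + φ)],
    φ   = (2πd/p₂) · ∂ₓ∫δ dz,

with μ = 4πβ/λ and ∂ₓ a central difference (one-sided at the detector
edges). The stepping phase is synthesized in projection space rather than
by Fresnel propagation: the analysis chain only consumes the
stepping-curve phase. The reference scan is ideal and flat; visibility
V₀ = 0.3 and flux I₀ = 5000 counts/pixel/step are free parameters (the
study they emulate reports neither). Optional Poisson noise is seeded.

## Retrieval

A K-point DFT per pixel: a₀ = mean, c = (2/K)Σ I_k e^(−2πik/K), a₁ = |c|,
φ = arg c (set to 0 when a₁ is numerically zero). Contrasts: A =
−ln(a₀ˢ/a₀ʳ), Δφ = wrap(φˢ−φʳ) ∈ (−π, π], DF = −ln[(a₁ˢ/a₀ˢ)/(a₁ʳ/a₀ʳ)].
For noiseless forward data this inverts the forward model to machine
precision (the DFT is exact for a single-harmonic curve). No spatial
phase unwrapping is implemented; phantom contrasts are below the wrap
limit, and pixels with |Δφ| > 0.9π are counted and logged as wrap risk.
Negative dark-field values (possible under noise) are reported as-is and
clipped only at reconstruction input.

## Reconstruction

Slice-wise 2-D filtered back-projection, reconstruction grid = detector
grid, rotation center at the detector center (an offset override exists).
Filters are built as band-limited real-space kernels and applied in the
frequency domain with zero-padding to the next power of two ≥ 2× the
detector width:

* ramp (Ram-Lak): h₀ = 1/(4Δx), h_n = −1/(π²n²Δx) for odd n — the
  band-limited form avoids the cupping that direct |ν| sampling on the
  DFT grid produces;
* Hilbert (for differential-phase data, after converting Δφ to
  g = Δφ·p₂/(2πd) = ∂ₓ∫δ dz): h_n = 1/(π²n) for odd n, the antisymmetric
  kernel with response sgn(ν)/(2πi) = ramp / (2πiν). Its zero DC response
  makes the δ reconstruction insensitive to a constant phase offset up to
  a bounded zero-padding edge artifact (tested).

Back-projection uses linear interpolation with per-angle weight
Δθ (half-turn) or Δθ/2 (full turn, each ray measured twice), so a uniform
disc of value μ₀ reconstructs to μ₀; verified to ≈0.15% on analytic disc
sinograms for both kernels. 360° scans use all angles with ½ weighting
rather than rebinning. No apodization by default; a Hann window flag
exists for noisy runs.

## Segmentation

All operations are deterministic. The automated pipeline works on the
phase (δ) volume:

1. **Organ ROI** — the global histogram is dominated by the paraffin
   peak; the organ is everything above the paraffin/tissue valley,
   morphologically closed (3 iterations, to seal the vessel channel that
   opens at the hilum), hole-filled, largest connected component.
2. **Compartments** — histogram peaks inside the ROI. Three peaks
   (control): class boundaries at midpoints between adjacent peak
   positions — unlike the valley minimum, the midpoint does not drift
   toward the smaller of two unequal peaks, so interface partial-volume
   voxels split evenly. The classes are {cortex+OSOM, ISOM, IM}: cortex
   vs OSOM is not separable by value, by design. One peak (I/R): the
   parenchyma is kept as a single class and flagged `not_separable`; the
   inner medulla is then delineated by a supplied mask
   (`apply_roi_and_manual`, provenance `manual`). In the simulated study
   this mask is the phantom's IM label — the stand-in for the manual
   workstation segmentation such a merged volume requires; on real data
   a hand-drawn mask would be supplied the same way.
3. **Vessels** — voxels below the midpoint of the paraffin and main
   parenchyma peaks, inside the ROI extended by clearly sub-paraffin
   voxels in a 4-voxel band around the organ (the protruding hilum
   root), linked with 26-connectivity; components under 60 voxels are
   dropped (isolated tubule voids are smaller than vessels). This
   *detection* mask maximizes recall but includes the point-spread halo;
   the reported vessel *volume* counts only detected voxels below the
   midpoint of the deep-lumen gray value (10th percentile of detected
   voxels) and the parenchyma peak, which splits surface partial-volume
   voxels evenly and is unbiased to ≈2%. Gray values in a 2-voxel rim
   around the lumen are corrupted by the vessel point spread and are
   reassigned to the nearest clean compartment label (Euclidean distance
   transform).

`region_grow` (6-connected, running-mean criterion, lexicographic
frontier, earlier seed wins contested voxels) is provided as the
region-growing primitive; the phantom pipeline's thresholds suffice
without it.

## Volumetry and statistics

Volume = voxel count × voxel volume (0.0075³ ≈ 4.22·10⁻⁷ mm³). The
"total" row is parenchyma + vessels; "cortex/outer medulla" is parenchyma
minus inner medulla. Report ratios are rounded half-up to two decimals
(full precision kept internally). Histograms (256 bins) span the 1st to
99.9th percentile of parenchymal voxels — the low cut drops the
partial-volume tail toward paraffin; the top cut only rejects outliers,
because a symmetric 99th-percentile cut would truncate the upper flank of
the densest (IM) peak and destroy its prominence. Peaks are local maxima
of the Gaussian-smoothed histogram (σ = 1.5 bins) with prominence ≥ 5% of
the maximum and separation ≥ 3 bins.

Statistical testing draws 10 000 gray values per compartment without
replacement (independent seeded streams per compartment) and reports, per
compartment pair, a paired t-test on index-matched draws and a Welch
two-sample t-test (α = 0.05). The pairing carries no information — the
draws are independent — so the paired test is exactly calibrated under
the null; `paired_null_rejection_rate` verifies a type-I error in
[0.03, 0.07] over 1000 seeded repeats. Because n = 10⁴ makes even
sub-SD mean differences significant, "merged" compartments are asserted
via effect size (mean separations below one within-compartment SD), not
via non-significance. No multiple-testing correction is applied.

## Problem sizes and defaults

The default study configuration (`RunConfig`) is a 64³ phantom pair with
180 projections over 360°, noiseless, K = 4 steps — the package's chosen
desk-scale study conditions; one full run takes ≈15 s on one CPU. The
acquisition-geometry class defaults to the emulated beamline protocol
(501 projections over 360°) when used directly. The algebraic
cross-check of the FBP (regularized least squares on a Radon matrix
assembled from basis-image projections) runs on 32² slices with 48
angles.

## What the phantoms do and do not show

Passing tests demonstrate that the chain — stepping simulation, Fourier
retrieval, Ram-Lak/Hilbert FBP, threshold/ROI segmentation, volumetry and
test statistics — is internally correct and reproduces the study's
quantitative structure (peak counts, volume ratios, compartment
contrasts) under Gaussian-textured, piecewise-homogeneous tissue with an
ideal flat reference. Real data differ in ways the phantom does not
model: Moiré and grating-defect artifacts, reference drift, ring
artifacts, beam hardening (none at a monochromatic synchrotron, but
relevant for tube sources), anatomical microstructure within
compartments, phase wrapping at container interfaces, formalin-fixation
density shifts, and center-of-rotation estimation. The segmentation
thresholds are derived from histogram structure and transfer to real
volumes only insofar as compartments remain unimodal and separable.

## Known limitations

* Wave-optics (Fresnel) propagation is not simulated; dark-field is an
  exponential visibility loss via ε, not a microstructure model.
* The I/R inner-medulla volume requires an external mask (by design, as
  in the emulated workflow); fully automatic I/R sub-compartment
  volumetry is impossible when gray values merge.
* The vessel-lumen volume estimator assumes vessels are the darkest
  extended structure; contrast-agent studies would invert the threshold
  direction.
* Reconstruction assumes an exactly centered rotation axis unless an
  offset is given.
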