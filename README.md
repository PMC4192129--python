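# gbpct — grating-based phase-contrast tomography of renal ischemia-reperfusion injury

`gbpct` is an end-to-end, fully simulated reproduction of a grating-based
X-ray phase-contrast CT study of murine kidneys after unilateral
ischemia-reperfusion (I/R) injury. Because no raw synchrotron projections
of such a study are publicly available, the package ships a synthetic-data
module that generates paired digital kidney phantoms (contralateral
control and I/R) with the statistical structure the analysis relies on,
and then runs the full measurement and analysis chain on them:

1. **Phantom** — nested-ellipsoid kidney (cortex, outer/inner stripe of
   the outer medulla, inner medulla) in a paraffin block, with a
   bifurcating vessel tree and scattered tubule voids; per-voxel
   refractive decrement δ, absorption index β and linear diffusion
   coefficient ε.
2. **Forward model** — parallel-beam projections and a two-grating Talbot
   interferometer phase-stepping acquisition at 19 keV (π-shifting phase
   grating p₁ = 4.78 µm, analyzer p₂ = 2.4 µm, 11th fractional Talbot
   order, 4 phase steps, 7.5 µm pixels):

       I_k = I₀ T [1 + V₀ D cos(2πk/K + φ)],   k = 0 … K−1

   with T = exp(−∫μ dz), D = exp(−∫ε dz) and
   φ = (2πd/p₂) ∂ₓ∫δ dz.
3. **Retrieval** — per-pixel Fourier processing of the stepping curves
   into attenuation A = −ln(a₀ˢ/a₀ʳ), differential phase
   Δφ = wrap(φˢ − φʳ) and dark field
   DF = −ln[(a₁ˢ/a₀ˢ)/(a₁ʳ/a₀ʳ)].
4. **Reconstruction** — filtered back-projection: Ram-Lak kernel for the
   attenuation and dark-field channels, Hilbert kernel
   (sgn(ν)/2πi, the ramp divided by the derivative response) for the
   differential-phase channel, which yields δ directly.
5. **Segmentation** — histogram thresholding between compartment peaks,
   hole-filled organ ROI, seeded region growing, vessel extraction by
   connected components, optional external ROI/manual masks.
6. **Volumetry & statistics** — compartment volumes (voxel count ×
   voxel volume, 0.0075³ mm³ ≈ 4.22·10⁻⁷ mm³), ischemic/contralateral
   ratios, gray-value histograms with peak counting, and paired + Welch
   t-tests on 10 000 sampled gray values per compartment.

The biology the phantoms encode: in the healthy kidney the inner medulla,
inner stripe and cortex are separable by decreasing gray value (three
histogram peaks) while the outer stripe matches the cortex; after I/R the
compartment gray values merge into a single peak, the organ shrinks by
more than half (total volume ratio ≈ 0.46), the inner medulla is nearly
preserved (≈ 0.95) and the vasculature is reduced about five-fold
(≈ 0.18).

## Worked example

```bash
gbpct run --seed 1 --out runs/demo
```

runs the whole study on a 64³ phantom pair (180 projections over 360°,
noiseless) and prints

```
peaks: {'control': 3, 'ir': 1}
ratios: {'total': 0.45, 'inner_medulla': 0.94, 'cortex_outer_medulla': 0.39, 'blood_vessels': 0.19}
```

i.e. the control kidney's phase histogram resolves three compartment
peaks while the injured kidney has collapsed to one; the injured kidney
retains 45% of the total volume (55% shrinkage, dominated by
cortex/outer medulla at 0.39), the inner medulla is nearly preserved
(0.94) and the vessels are reduced to 0.19 of the contralateral volume.
`runs/demo/` then contains the phantoms, contrast sinograms,
reconstructed δ/μ/ε volumes (HDF5 + TIFF), label volumes, a Table-style
`report.csv` (volumes in mm³ per compartment), a machine-readable
`report.json` with histograms and t-tests, and a histogram figure.

Each stage is also exposed on its own (`gbpct phantom`, `simulate`,
`retrieve`, `reconstruct`, `segment`) and as a library:

```python
from gbpct import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=1), persist=False)
result.report.peaks          # {'control': 3, 'ir': 1}
result.table["ratio"]        # compartment volume ratios
```

## Layout

```
src/gbpct/
  phantom.py     paired synthetic kidney phantoms
  forward.py     Talbot interferometer + parallel-beam projector
  retrieval.py   phase-stepping Fourier processing
  recon.py       Ram-Lak / Hilbert filtered back-projection
  segment.py     thresholding, region growing, ROI/manual masks, vessels
  stats.py       volumetry, histograms/peaks, paired & Welch t-tests
  pipeline.py    RunConfig + end-to-end orchestration
  io.py          HDF5/TIFF persistence
  cli.py         command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
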