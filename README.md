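# collagenfft

Automated 2D-FFT / power-spectral-density analysis of AFM images of
fibrillar collagen: D-banding periodicity, local fibril-orientation
anisotropy ("arc vs scatter"), synthetic phantom validation, and
multi-rater agreement statistics.

## The problem

Type I collagen fibrils carry a ~64–67 nm axial repeat of gap/overlap
zones (the **D-banding**) and, in healthy dermis, run locally parallel with
well-defined edges. Connective-tissue disorders such as Ehlers–Danlos
syndrome disorganize this architecture: fibrils become kinked, non-linear
and randomly oriented. Both signatures are directly readable in the
frequency domain of an AFM scan, which makes them amenable to automated,
operator-independent quantification — useful to anyone studying
extracellular-matrix ultrastructure (dermis, tendon, cornea, bone) or
screening disease models at the nanoscale.

## The method

For a calibrated scan `f(x, y)` (typically 5 × 5 µm², 512 × 512 px), the
package computes the discrete Fourier transform and its power spectrum

    F(u,v) = Σₓ Σ_y f(x,y) e^{−i2π(ux/M + vy/N)},      P(u,v) = |F(u,v)|²

and reads collagen structure off `P`:

- **D-banding period.** The banding appears as a first-harmonic peak at
  radius k (in frequency bins) along the fibril axis. The image is rotated
  to bring that peak onto the profile axis and maximize its amplitude; the
  winning bin converts to a period `N·Δx/k` nm (`Δx` = pixel size). A
  peak-significance rule (median + 4·MAD and ≥50× the in-band median) makes
  "no detectable banding" a reproducible outcome on structureless input.
- **Local anisotropy.** The image is segmented into 128-px macro-pixels
  (1.25 µm), each with its own 2D FFT. In each tile the angular
  distribution of first-harmonic energy is classified as one or more
  **discrete points** (perfectly aligned populations), a **bright arc**
  (oriented but spread — the arc aperture equals the fibril angular range),
  or a **scatter** (pathological disorganization; no orientation vector can
  be drawn). The orientation vector through the two symmetric harmonic arcs
  gives the mean fibril direction; circular statistics use the axial
  doubled-angle convention.
- **Phantoms.** A generator renders synthetic fields of D-banded fibrils
  with known orientation groups, period, kinking and noise — the ground
  truth every estimator is validated against.
- **Rater agreement.** Fleiss's kappa (with the Landis–Koch verbal bands)
  scores how consistently human raters classify 2D-FFT images as healthy
  vs pathological.

## Worked example

```bash
# render a healthy-dermis-like phantom (one parallel fibril population,
# 64 nm D-period, 512 px / 5 µm) and analyze it end to end
collagenfft phantom --preset wildtype --out wt.tiff --truth wt_truth.json
collagenfft dband wt.tiff --width-um 5 --out dband.json
```

prints

```json
{"period_nm": 63.72484110169491, "rotation_deg": 155.029416855008,
 "peak_bin": 59, "peak_amplitude": 4.651613792655109e+16, "crop": null}
```

The phantom was generated with fibrils at 25° and a 64 nm period: the
pipeline rotated the image by 155° (= −25° mod 180°, bringing the banding
onto the profile axis), found the first harmonic in bin 59 of the
385-px rotated crop, and reports 63.7 nm — within one frequency bin of the
generative truth. The full pipeline

```bash
collagenfft run wt.tiff --width-um 5 --out-dir results/
```

adds the macro-pixel mosaic (`mosaic.png`, `tiles.csv`): for this phantom
all 16 tiles are classified as oriented (`point_set`) with mean direction
25.0° and orientation dispersion < 0.1°; an `eds_like` phantom instead
yields a majority of `scatter` tiles — the pathological-anisotropy readout.

The same analyses are available as library calls
(`collagenfft.estimate_dband`, `collagenfft.build_mosaic`,
`collagenfft.detect_discrete_points`, `collagenfft.fleiss_kappa`, ...).

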