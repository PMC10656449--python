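# Methods

This note documents the models, conventions, parameter choices and known
limitations of `collagenfft`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

- **Coordinates.** Row 0 is the top of the image; x runs along columns,
  y along rows. Angles are measured counterclockwise from +x in the
  conventional (y-up) mathematical frame and, being fibril orientations,
  live on the axial range [0°, 180°).
- **Frequency space.** Spectra are DC-centered (quadrant-shifted); a
  structure whose intensity is modulated along real-space direction θ puts
  its spectral peaks along the same direction θ. Frequency bin k along a
  ray from DC corresponds to a spatial period of `N·Δx/k` nm, where N is
  the analyzed side length and Δx the pixel size; bin spacing is
  `1/(N·Δx)` nm⁻¹.
- **Intensity units.** AFM deflection/height values are used as-is (no
  normalization): every decision rule in the package is scale-invariant
  (peak *locations*, energy *ratios*, angular statistics), and raw values
  keep energy identities (Parseval) meaningful in tests.
- **Circular statistics.** All orientation averaging uses the doubled-angle
  convention (angles ×2 on the unit circle, resultant halved back), the
  standard treatment for 180°-periodic axial data.

## D-banding estimation

Pipeline: optional user crop → rotation search → Hann window and mean
subtraction → 2D FFT → PSD → 1-D profile along the +x axis → in-band peak.

- **Window and DC handling.** Hann by default; unwindowed crops leak edge
  energy across the spectrum, which can mask the first harmonic. The mean
  of the windowed image is subtracted so DC leakage does not dominate
  low-frequency bins. `window="none"` exists for exact-identity tests.
- **Search band.** Default 40–110 nm, bracketing the 64–67 nm physiological
  range with room for calibration drift; configurable. Bins below k = 2 are
  always excluded (DC/fundamental region). Ties break toward the lower bin
  (longer period) for determinism under symmetric noise.
- **Rotation search.** Coarse 2° grid over [0°, 180°) followed by
  golden-section refinement to 0.25°; the objective is the first-harmonic
  peak amplitude normalized by (M·N)², because the inscribed-square crop
  varies with angle and raw PSD peaks scale with the pixel count squared.
  The objective is smooth near the optimum, so coarse-then-refine is both
  cheap and reliable.
- **Rotation interpolation** is cubic-spline, not bilinear. The banding
  carrier sits near 6–7 px per cycle, where bilinear interpolation
  attenuates enough to corrupt amplitudes and break rotate-and-return
  reproducibility (measured ~4–9% mean absolute round-trip error vs <2%
  with cubic). The rotated image is cropped to the largest centered square
  containing only real data — padding would inject spurious spectral
  structure — with the crop side matched to the source parity so the crop
  center coincides exactly with the rotation center (a half-pixel offset
  de-phases the banding on a there-and-back trip). Multiples of 90° are
  exact array rotations.
- **Peak significance.** An in-band maximum counts as a harmonic only if
  it exceeds median + 4·MAD of the in-band profile *and* 50× the in-band
  median. The MAD rule alone is not selective for exponential-tailed PSD
  noise (white noise passes it roughly half the time once the rotation
  search maximizes over ~100 rotations). The two thresholds sit more than
  an order of magnitude from both populations as measured on the package's
  own fixtures: genuine banding peaks exceed the in-band median by ≥1100×
  even at banding contrast 0.2 under noise of 0.15 of the signal
  amplitude, while rotation-maximized white-noise maxima stay below ~25×.
- **Minimum size.** 128 px on the analyzed (cropped) side; below this the
  spectrum does not resolve enough in-band bins.

## Macro-pixel anisotropy

Each 128-px tile (1.25 µm at the 5 µm / 512 px calibration) gets its own
windowed FFT; analysis reads the annulus of radii covering the period band.

- **First-harmonic radial focusing.** Angular readouts (points, arcs,
  orientation, aperture) are computed on a radial sub-band centered on the
  annulus's dominant radius (half-width `max(2, k*/16)` bins). The 40–110 nm
  band unavoidably also contains the inter-fibril *packing* periodicity
  (~100 nm), which appears perpendicular to the fibril axis at a different
  radius than the D-band harmonic; focusing on the harmonic ring removes it
  without touching the physically meaningful signal.
- **Classification chain** (all thresholds scale-invariant,
  in `AnisotropyConfig`): *empty* if the annulus holds < 1% of total
  spectral energy (DC excluded); *point_set* if discrete points are
  detected and their ±2° windows hold ≥ 50% of annulus energy; *arc* if
  the doubled-angle resultant length R̄ ≥ τ_arc = 0.5; otherwise *scatter*.
  On isotropic 128-px noise, R̄ concentrates near 0.05–0.1 (the resultant
  of ~10³ random phasors), so τ_arc = 0.5 sits far from the null while
  accepting arcs up to roughly ±60° angular spread.
- **Discrete points.** Angular energy histogram at 0.5° resolution,
  circularly smoothed (σ = 1°); local maxima must exceed median + 4·MAD
  *and* 20% of the strongest maximum, then greedy non-maximum suppression
  at 5° separation; sub-bin angles by parabolic interpolation. The relative
  threshold separates genuine populations (measured ≥ 0.70× the strongest
  on equal-size groups) from disorder speckle, which scales like
  1/n_fibrils (measured ≤ 0.09×).
- **Arc aperture.** Smallest contiguous angular window (on the doubled
  circle, halved back) holding 90% of the ring energy; undefined — an
  error — for scatter/empty tiles.
- **Orientation vector.** Power-weighted doubled-angle mean of the ring.
  D-banding modulates intensity *along* the fibril axis, so first-harmonic
  energy lies along the fibril direction in frequency space (fibril-edge
  energy lies perpendicular, and outside the harmonic ring); the vector
  therefore reports the mean fibril long-axis direction.
- **Tiling.** Non-overlapping from the top-left; remainder rows/columns
  smaller than one tile are dropped (padding would contaminate tile
  spectra) and reported.

## Phantom generator

The generator is the package's validation instrument: it emulates the AFM
appearance of dermal collagen with exactly known geometry.

- **Fibril model.** Transverse profile: truncated-Gaussian ridge
  (FWHM = `fibril_width_nm`, default 100 nm; cut at 3.5σ). A compact
  cosine ridge of realistic width was rejected because its spectral
  mainlobe spans the whole 40–110 nm band, letting fibril-edge energy rival
  the D-band harmonic inside the analysis annulus; the Gaussian's spectrum
  is negligible at the harmonic radius. Longitudinal profile: band-limited
  asymmetric square pulse train (duty cycle 0.47, harmonics 1–3; the 4th
  harmonic of 64 nm would alias at the 9.77 nm pixel), fundamental period
  `d_period_nm` (default 64 nm), depth `banding_contrast`. Real collagen
  PSDs contain higher harmonics of the D-band; keeping a few preserves that
  realism while the fundamental dominates.
- **Banding registration.** All fibrils of a group share one banding phase
  (lateral D-band register), emulating the duplicated-fibril construction
  this generator stands in for. With independent phases the coherent
  transverse extent collapses to a single fibril width and the
  first-harmonic "point" smears into ±14° speckle.
- **Placement.** Fibrils are stacked side by side at one spacing
  (= fibril width) with uniform ±half-spacing jitter, which nulls the
  coherent packing peak exactly (E[e^{2πiδ/s}] = sinc(π) = 0) while keeping
  coverage even. Kinked mode chains straight segments
  (`segment_length_nm`, default 400 nm) with turns uniform in
  ±`max_turn_deg`, banding phase continuous along the chain.
- **Compositing and noise.** Per-pixel maximum (fibrils occlude as in AFM
  topography; heights do not add), then additive Gaussian noise as a
  fraction of the unit signal amplitude. Identical spec + seed is
  bit-identical.
- **Presets** fix the study conditions: `wildtype` (one parallel population
  at 25°, 72 fibrils, contrast 0.6, noise 0.08), `uniform_aligned` (one
  population at 0°, noise 0.03), `two_group_20` (populations at 0° and
  20°), `four_group_0_30_45_60`, and `eds_like` (kinked fibrils seeded at
  eight spread angles, D = 63 nm, noise 0.10) mimicking pathologically
  disorganized dermis. Noise levels are moderate imaging noise for contact-
  mode deflection images; fibril counts fill the field of view at realistic
  ~100 nm packing.
- **What the phantoms do not emulate:** tip–sample convolution, scanner
  drift/bow, height-dependent contrast, partial fibril depth in histology,
  and the absolute intensity statistics of real deflection images. Passing
  tests therefore demonstrate correct *geometric and spectral* recovery
  under controlled conditions, not instrument-level realism.

## Rater statistics

Standard Fleiss formulas: `P_i = Σ_j n_ij(n_ij−1)/(n(n−1))` (exactly the
fraction of agreeing rater pairs, verified against explicit pair
enumeration), `P_e = Σ_j P_j²`, `κ = (P_o − P_e)/(1 − P_e)`. Degenerate
tables (all mass in one category, P_e = 1) raise an error. Landis–Koch
bands use half-open intervals with edges at the two-decimal midpoints
(0.205, 0.405, 0.605, 0.805) so the conventional two-decimal endpoints
round into their stated bands; negative values are labeled
"poor (below chance)". Long-format (subject, rater, category) records are
aggregated to counts; every subject must have the same number of raters.

## Problem sizes in the test suite

Full-size (512 px) phantoms are used for the headline end-to-end checks
(D-band recovery, point counting, mosaic). Property sweeps (parameter
recovery over 20 random phantoms, separation fidelity 10–80°, point-count
fidelity over 18 seeds) use 256-px phantoms at the same 9.77 nm pixel size
— the estimators' behavior is set by the pixel calibration and band, not
the field of view, and the smaller field keeps the whole suite under a
minute. Tile-level tests use single 128-px tiles, the same size the mosaic
analyzes.

## Known limitations

- The rotation search assumes one dominant banded population per analyzed
  region; two strong populations with different periods would compete for
  the first-harmonic peak (the macro-pixel analysis, not the whole-image
  D-band estimate, is the tool for mixed fields).
- Arc aperture is reported for the 90% energy window; heavy-tailed angular
  distributions read slightly wide.
- Automatic crop selection is deliberately absent: the crop used for
  D-banding in sparse fields is an operator choice, and automating it would
  add an unvalidated detector.
- Proprietary AFM formats (JPK/Bruker/WSXM) are not parsed; supply TIFF,
  PNG or plain-text matrices plus the scan width.
- No kappa variance or significance testing; only the point estimate and
  its verbal band.
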