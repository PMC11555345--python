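# Methods

## Spectral model

The analysis quantity is Im[χ³](ν), proportional to the spontaneous Raman
spectrum. Protein-dense regions are modelled in the amide I window
(1540–1740 cm⁻¹) as a sum of three Gaussian components with fixed
spectroscopic roles and fixed shape parameters (centre, FWHM):
purine ring 1570/15, α-helix + unsaturated lipid 1650/30, β-sheet 1667/22,
all in cm⁻¹. "Linewidth" is interpreted as FWHM, the standard spectroscopic
convention: G(ν) = A·exp(−4 ln2 (ν−c)²/w²). The fitted per-pixel quantity
g_n is the analytic band area A·w·√(π/4ln2) ("integrated band intensity"),
not the peak amplitude; the two senescence indicators are g₂/(g₁+g₂) and
g₂−g₁.

Two fit modes exist. `fixed_shape` (default) pins centres and widths and
solves the amplitudes by non-negative least squares — a linear problem that
is exact on noiseless data and robust per pixel. `bounded_nonlinear`
refines amplitudes, centres (±3 cm⁻¹ by default) and widths (±20%) by
bounded trust-region least squares; it exists to verify that the fixed
shape parameters are recovered from data rather than assumed, and the two
modes agree to 1e-8 on noiseless input. Non-convergent pixels are masked
downstream, never zero-filled.

## Phase retrieval

Raw multiplex CARS intensity is |χ_NR + Σⱼ Aⱼ/(Ωⱼ−ν−iΓⱼ)|². The maximum
entropy method treats the normalized intensity as the power spectrum of an
autoregressive model: autocorrelation coefficients come from an inverse
DFT, a Hermitian Toeplitz system is solved for the AR coefficients a_k,
and with A(x) = 1 + Σ a_k e^(−2πikx) the retrieved phase is arg A. The
modulus is taken as √(raw intensity), so the retrieval is covariant under
intensity rescaling (phase invariant, modulus ∝ √k). Numerical choices:

* The normalized spectrum is edge-padded by its own length on each side
  before the DFT; the DFT's implicit periodicity otherwise couples the two
  window edges and biases the phase (~0.12 rad → ~0.005 rad with padding).
* Pole count defaults to 0.45 × padded length.
* Normalization defaults to division by the median intensity. A constant
  divisor leaves the AR phase exactly unchanged, whereas dividing by a
  smooth envelope estimated *from the same data* deforms the dispersive
  lineshapes that carry the phase information; envelope division remains
  available (`envelope=True`) for data with a genuine instrumental
  response, and an externally measured nonresonant reference is used
  whenever supplied.
* Error phase: physical resonances contribute non-negative phase
  (Im[χ³] ≥ 0), so the spurious slowly varying component is estimated as
  the smooth lower envelope of the retrieved phase (a stiff arPLS baseline,
  λ = 1e8) and subtracted; a polynomial variant (default order 4, fitted to
  the half of the samples nearest that envelope) is also provided.

Retrieval is only well-posed in the minimum-phase regime. When the
resonant term exceeds the nonresonant background (Σ Aⱼ/Γⱼ > χ_NR), χ³ can
acquire zeros in the upper half-plane and |χ|² no longer determines the
phase — no algorithm recovers it from a single spectrum. Validation
therefore draws random models with Σ Aⱼ/Γⱼ < χ_NR, which is also the
physically typical situation in cells, where the nonresonant background
dominates. Under those conditions the MEM result matches the analytic
Im[χ³] to within ~3% in band area and ~1 cm⁻¹ in peak position, and agrees
with the independent Kramers–Kronig (log-modulus Hilbert) oracle to <1%.

## Baseline correction

Stage 1 subtracts the mean spectrum of the pixels outside the cells from
every pixel. The outside mask defaults to ground-truth labels for
synthetic data; for real data the low class of an Otsu threshold on the
2933 cm⁻¹ CH image is used. Stage 2 is arPLS (λ = 1e5, weight-change
tolerance 1e-6, ≤100 iterations), applied per pixel (configurable off).
The penalized smoother is linear at its free boundaries, so the input is
linearly extrapolated by ~10% of its length on each side before smoothing;
without this, a curved baseline sags at the window edges and the positive
edge residuals trigger runaway down-weighting of the whole interior on
noise-free input. With padding, a pure quadratic baseline is absorbed to
0.18% of its range and a unit test peak on that baseline is recovered to
0.2%.

Water-band removal (optional, default off) fits one broad 1640 cm⁻¹
Gaussian (width bounded 60–120 cm⁻¹) *jointly* with the three amide
components and subtracts only the water term, so amide intensity cannot be
misattributed to water.

## Indicators, quantification, statistics

The ratio map masks pixels with ratio ≤ 1e-19 or zero denominator; masked
pixels are rendered in a reserved colour and excluded from all statistics.
The subtraction map stores raw g₂−g₁; its display scale is the standard
deviation over a 2-pixel morphological ring outside the nucleus mask
("perinuclear"), with diverging limits at ±3 scale units (blue =
β-sheet-rich, red = α-helix-rich) and a unit fallback for flat regions.

Per cell, nuclei are 4-connected nucleus-extent components; areas are
pixel count × (pixel size)². The largest nucleolus (pixel count, ties to
the lowest component label) supplies cross-sectional mean indicators.
Classification: control = mononuclear with nucleus strictly < 118 µm²
(larger mononuclear nuclei are potential polyploids → `large_nucleus`);
≥2 nuclei → `binucleate`. Group comparison runs Shapiro–Wilk per group,
then Bartlett + Dunnett-versus-control (multi-group; Dunnett via the
multivariate-t implementation with a fixed quasi-random seed for
determinism) or a variance-ratio F-test + pooled two-tailed Student's t
(two-group), significance at p < 0.05. The size–ratio relationship is
ordinary least squares of the largest-nucleolus mean ratio on its size in
pixels, with the two-sided slope p-value.

## Synthetic data

The generator emulates: circular cells on a jittered grid (0.5 µm/pixel),
cytoplasm/nucleoplasm/nucleolus labels, control cells mononuclear with
small nuclei, senescent cells binucleate with enlarged β-rich nucleoli;
amide spectra as weight-scaled sums of the unit-area band components plus
a CH band (2933/60 cm⁻¹) whose weight grades background < cytoplasm <
nucleoplasm < nucleolus (for segmentation images) and an optional water
band (1640/90); a slowly varying common quadratic baseline; additive
Gaussian noise with an optional shot-like intensity-scaled term.

Default composition weights (purine, α, β) were fixed once with a
dense-grid (0.01 cm⁻¹) argmax oracle: cytoplasm (0.30, 1.00, 0.25) peaks
at 1653.0 cm⁻¹, the canonical cytoplasmic amide I position; control
nucleolus (0.40, 0.70, 0.30) at 1657.2 cm⁻¹ (below the 1660 amyloid
threshold); senescent nucleolus (0.40, 0.40, 0.60), β fraction 0.60, at
1665.0 cm⁻¹. Absolute amplitudes are arbitrary units; only ratios and
peak positions are meaningful.

In raw-CARS mode each Gaussian component becomes a complex Lorentzian line
with the same centre, Γ = FWHM/2, and amplitude chosen so that the
Im[χ³] area *over the 1540–1740 window* equals the Gaussian truth area —
Lorentzian tails put 5–10% of the total area outside the window, so
total-area matching would bias the ground truth. The default
resonant-to-nonresonant contrast is 40 (in truth-area units) against
χ_NR = 1, keeping resonant Im peaks a moderate fraction of the background.

What the phantoms do **not** emulate: realistic morphology, subcellular
texture within a region (regions are spectrally homogeneous), optical
effects (NA, polarization, coherence), z-structure, spectral calibration
drift, or cosmic-ray spikes. Passing tests therefore demonstrate the
correctness of the algorithmic chain under known composition and noise,
not performance on any particular instrument's data.

## Problem sizes and defaults

The demonstration field is 6 control + 6 senescent cells on 96×96 pixels
with 121 spectral channels (1500–1800 cm⁻¹ at 2.5 cm⁻¹), noise σ = 0.001
(arbitrary units, ≈3% of a typical amide peak amplitude) and baseline
amplitude 0.01; the regression sweep uses 24 mononuclear cells on 160×160
pixels with nucleolus radius 1.8–4.2 px co-varying with β fraction
0.25–0.60 (jitter σ = 0.03). These sizes keep a full run in tens of
seconds on one CPU while leaving group effects far from degenerate.
Identical configuration and seed reproduce every output byte-for-byte.

## Known limitations

* MEM and the KK oracle share the minimum-phase assumption; strongly
  resonant spectra (Σ A/Γ > χ_NR) are outside the validated regime.
* Finite spectral windows bias minimum-phase retrieval slightly; validation
  uses a detector window with ≥200 cm⁻¹ margins around the band of
  interest. Narrow windows increase band-area error to the ~10% level.
* arPLS on noise-free smooth inputs relies on the extrapolation padding for
  stability; extremely short spectra (<~30 samples) get proportionally less
  padding.
* The 118 µm² nucleus rule and the 1660 cm⁻¹ peak threshold are biological
  conventions taken as fixed constants, not estimated from data.
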