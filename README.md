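# carsense

Label-free detection of cellular senescence from multiplex CARS
(coherent anti-Stokes Raman scattering) hyperspectral microscopy images.

Senescent cells accumulate amyloid-like, β-sheet-rich protein aggregates in
their nucleoli. In the Raman-equivalent Im[χ³] spectrum this shifts the
protein amide I band upward: α-helix-dominated material peaks near
1650–1653 cm⁻¹, β-sheet-rich aggregates above 1660 cm⁻¹. `carsense`
implements the full analysis chain that turns raw CARS image cubes into
per-cell senescence indicators:

1. **Phase retrieval** — raw CARS intensity is |χ_NR + Σⱼ Aⱼ/(Ωⱼ − ν − iΓⱼ)|²;
   the maximum entropy method (autoregressive model of the normalized power
   spectrum, Toeplitz system solved for the AR coefficients) recovers the
   phase, a slowly varying error phase is subtracted, and
   Im[χ³] = |χ| sin φ is obtained. A direct Kramers–Kronig (log-modulus
   Hilbert transform) estimate serves as an independent cross-check.
2. **Preprocessing** — reference-peak wavenumber calibration; two-stage
   baseline correction: the mean spectrum outside the cells is subtracted,
   then asymmetrically reweighted penalized least squares (arPLS) removes
   residual slow baselines; optional 1640 cm⁻¹ water-band removal.
3. **Amide I decomposition** — each pixel's 1540–1740 cm⁻¹ band is fitted
   with three Gaussians: (0) purine ring of DNA/RNA (1570 cm⁻¹, FWHM 15),
   (1) protein α-helix + unsaturated-lipid C=C (1650 cm⁻¹, FWHM 30),
   (2) protein β-sheet (1667 cm⁻¹, FWHM 22), giving integrated band
   intensities g₀, g₁, g₂ per pixel (non-negative least squares by default,
   bounded Levenberg–Marquardt-type refinement optionally).
4. **Indicator maps** — the β-sheet occupancy ratio g₂/(g₁+g₂) ∈ [0,1]
   (pixels at or below 10⁻¹⁹ masked) and the signed difference g₂ − g₁,
   display-scaled by the perinuclear standard deviation.
5. **Quantification and statistics** — region segmentation, per-cell
   cross-sectional averages over the largest nucleolus of each nucleus,
   morphological classification (control: mononuclear with nucleus
   < 118 µm²; binucleate; large-nucleus), Shapiro–Wilk +
   Bartlett/Dunnett or F-test/Student's t group comparisons, and ordinary
   least squares of nucleolar β ratio on nucleolus size.

Because real cell measurements are not redistributable, the package ships a
first-class synthetic module (`carsense.synthetic`) that generates labelled
phantom cells (cytoplasm / nucleoplasm / nucleoli at 0.5 µm/pixel) with
known spectral composition, in either the Im[χ³] domain or the raw-CARS
domain, so every stage is testable against exact ground truth.

## Worked example

```python
from carsense.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1), "demo_out")
print(summary["group_means"], summary["comparison"]["location_p"])
```

This simulates a field of 6 control + 6 senescent phantom cells
(96×96 pixels, 1500–1800 cm⁻¹), corrects baselines, fits the amide band per
pixel, and compares the largest-nucleolus mean β ratios. It prints:

```
{'control': 0.2988327443623405, 'senescent': 0.6050184554658834} 3.824261072328362e-20
```

i.e. control nucleoli average a β-sheet occupancy of ≈0.30 (their true
generated composition is 0.30) while senescent nucleoli average ≈0.61
(truth 0.60), and the two-sample Student's t-test separates the groups at
p ≪ 0.05. `demo_out/` receives the records CSV, ratio/subtraction TIFF and
RGB maps, and a JSON summary.

The same chain is scriptable from the shell:

```bash
carsense run --seed 1 --out demo_out            # end-to-end
carsense simulate --mode chi3_domain --out sim  # raw-CARS cube + truth
carsense retrieve --cube sim/raw_cube.npy --out sim/chi3   # MEM retrieval
```

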