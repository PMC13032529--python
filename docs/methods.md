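# Methods

This document records the forward model behind `specflux.synthetic`, the
parameter values it ships with, the numerical conventions used across the
package, and the known limitations. Everything here is implemented in the
source; file references point to the module that owns each choice.

## 1. Experimental design being simulated

The generator reproduces a ¹³C pulse-labelling fermentation study of an
oleaginous, carotenogenic filamentous fungus grown on nitrogen-limited
media with seven glucose/glycerol compositions (g/L of ¹²C glucose /
¹³C glucose / glycerol):

| medium | glc ¹²C | glc ¹³C | glycerol |
| --- | ---: | ---: | ---: |
| `nGlu` | 40 | – | – |
| `iGlu` | – | 40 | – |
| `nGlu1:Gly1` | 20 | – | 20 |
| `iGlu1:Gly1` | – | 20 | 20 |
| `nGlu1:Gly7` | 5 | – | 35 |
| `iGlu1:Gly7` | – | 5 | 35 |
| `Gly` | – | – | 40 |

Samples are harvested at 8, 14, 24, 36, 60 and 120 h, giving
7 × 6 = 42 biological samples. Each sample is measured in three
technical replicates on each bulk modality, so a full bulk dataset holds
42 × 3 = 126 spectra per modality.

Four instrument modalities are modelled (`specflux/axes.py`), each with a
fixed wavenumber grid stored ascending:

| modality | range (cm⁻¹) | spacing (cm⁻¹) |
| --- | --- | --- |
| `FTRaman` | 50–3785 | 1.928 |
| `HTSFTIR` | 400–4000 | 1.928 |
| `FTIRMicro` | 900–3850 | 3.851 |
| `RamanMicro` | 0–2920 | 1.928 |

The Raman microscope grid range is instrument-reported; its spacing is
set equal to the FT instruments' because only the range was specified by
the source design.

## 2. Band model

Every metabolite is a set of marker bands (`specflux/bands.py`). A band
is a unit-area pseudo-Voigt profile (η = 0.7 Lorentzian fraction) with a
technique tag (IR, Raman or both), a ¹²C centre, a full width at half
maximum, a relative amplitude, and — for carbon-containing vibrations —
a ¹³C centre red-shifted by 10–62 cm⁻¹. Key assignments:

- TAG ester C=O: 1745 → 1701 cm⁻¹ (FTIR), 1747 → 1705 cm⁻¹ (Raman),
  plus CH₂/CH₃ stretches (2855 → 2846, 2930 → 2918 cm⁻¹) and the
  1440 cm⁻¹ deformation region.
- Carotenoid C=C and C–C stretches: 1523 → 1490 and 1157 → 1124 cm⁻¹
  (Raman, resonance-enhanced ×8 on the Raman microscope).
- Polyphosphate: 1268, 1084, 886 cm⁻¹ (IR) and 1170, 700 cm⁻¹ (Raman),
  all with `center13 = None` — these vibrations contain no carbon and do
  not shift.
- Protein amide I/II, carbohydrate C–O and water/OH background bands
  complete the matrix.

A sample's spectrum is
`Σ_m w_m [(1 − f13_m)·band(ν; center12) + f13_m·band(ν; center13)]`
summed over that modality's visible bands, multiplied by a per-sample
path-length factor, plus a smooth baseline (low-order polynomial with
random coefficients, amplitude parameterised by `BaselineParams`) and
i.i.d. Gaussian noise. Bands whose ¹²C and ¹³C centres partially overlap
(e.g. the carotenoid 1523/1490 pair at intermediate `f13`) produce a
single apparent peak whose position interpolates between the two — the
`INTERPOLATE_POSITION` behaviour exploited by
`band_metrics.peak_position`.

## 3. Composition kinetics

`composition_trajectory` (`specflux/synthetic.py`) maps
(medium, time) → per-metabolite weights `w_m` and labelling fractions
`f13_m`:

- **Glucose consumption**: linear at 0.33 g/L/h until exhaustion
  (`t_exhaust = glc / rate`; zero-glucose media consume nothing).
- **TAG from glucose**: yield 0.08 × consumed glucose, decaying after
  glucose exhaustion with time constant 70 h (turnover of storage
  lipid). Glucose-derived TAG carries the glucose isotope.
- **TAG from glycerol**: in glycerol-surplus media (glycerol:glucose
  ≥ 4) a second, slower lipogenesis phase starts at 36 h at
  0.005 × glycerol g/L/h; glycerol is always ¹²C, so this phase
  *dilutes* the labelling fraction — the signature behaviour of the
  `iGlu1:Gly7` medium.
- **Polyphosphate**: transient bump `x·e^(1−x)` in scaled time, peaking
  at 120 h on pure glucose, 60 h on mixed media and 24 h on pure
  glycerol (early phosphate storage under fast glycerol uptake).
- **Carotenoid**: bump peaking at 14 h. In labelled-glucose media with
  glycerol surplus the carotenoid ¹³C fraction is drawn uniformly from
  (0.25, 0.85) per sample, modelling mixed precursor pools feeding the
  isoprenoid pathway.
- **Protein/carbohydrate**: slowly varying structural background with
  isotope fractions following the consumed substrate mix.

Representative ground-truth values (seed-independent, from the kinetics
alone): final (120 h) TAG weight `nGlu` 2.957 ≥ `nGlu1:Gly1` 0.594 >
`nGlu1:Gly7` 0.462 > `Gly` 0.0006; in `iGlu1:Gly7` at 60 h the ¹²C TAG
pool (0.120) already exceeds the ¹³C pool (0.100).

## 4. Hyperspectral scenes

`make_scene` draws a branched-hypha mask on an H × W grid with embedded
circular lipid bodies (TAG-rich, 6× enriched) and polyphosphate granules
(6× enriched), composition taken from the same kinetics at the requested
(medium, time). `simulate_hyperspectral_image` renders every pixel
through the bulk forward model with a spatially smooth path-length field
(Gaussian-filtered noise, σ = 8 px) and returns the cube together with
truth maps (`hyphae`, `lipid_body`, `polyp_granule`, per-metabolite
weights). Background pixels contain baseline and noise only.

## 5. Preprocessing

`specflux/preprocess.py` provides composable steps and eight frozen
recipes (`RECIPES`), one per modality/analysis pair, serialisable to a
plain-text form for run logs. Conventions:

- **Savitzky–Golay** derivatives delegate to
  `scipy.signal.savgol_filter(delta=1.0, mode="interp")`; tests verify
  each output point against an explicit per-point polynomial fit.
- **Rubberband baseline** is the lower convex hull (monotone-chain),
  linearly interpolated between hull points; this is exact, not
  iterative.
- **MSC/EMSC** solve the per-spectrum least-squares regression onto the
  reference (plus polynomial terms for EMSC) and return the corrected
  spectrum; the reference defaults to the dataset mean.
- **Truncation** to analysis regions requires at least two surviving
  grid points and records the regions in the recipe text.
- Recipes refuse to run on already-differentiated input
  (`derivative_order > 0`) rather than silently double-differentiating.

## 6. Chemometrics conventions

(`specflux/chemometrics.py`)

- **PCA**: SVD of the mean-centred matrix; component signs are fixed so
  the largest-magnitude loading element is positive, making scores
  reproducible across runs.
- **Consensus PCA (CPCA)**: each block is mean-centred and scaled by its
  Frobenius norm, the blocks are concatenated and decomposed by a single
  SVD; global scores, per-block scores (projections onto the block slice
  of each loading) and per-block explained variances are reported.
  Correlation loadings are Pearson correlations between variables and
  global scores.
- **PLS1**: NIPALS with deflation; predictions come with per-sample
  Q residuals (squared reconstruction error in X after projection).
  `plsr_flag_outliers` uses the 99th percentile of the *training*
  Q residuals as threshold.

## 7. Imaging analysis

(`specflux/imaging.py`)

- **Pixel QC** (`remove_empty_pixels`): the per-pixel metric is the
  integrated |signal| over 1700–1500 cm⁻¹ after subtracting the straight
  line through the interval endpoints (removes baseline, keeps bands).
  The threshold is `max(0.2, median_low + 3 × 1.4826 × MAD_low)` where
  the statistics come from the lowest decile of pixels; the absolute
  floor 0.2 keeps the rule meaningful on images with no true background.
- **Binning** (`bin_image`): non-overlapping 10 × 10-ish blocks via
  `BlockGrid.for_shape`; a 128 × 128 image yields 13 × 13 = 169 blocks;
  blocks with fewer than 5 valid pixels are dropped; block spectra are
  means over valid pixels.
- **Basis analysis**: component spectra come from k-means
  (`scikit-learn`, `n_init=10`) on area-normalised valid pixels;
  per-pixel abundances from `scipy.optimize.nnls` (or a shared `lstsq`
  when negativity is allowed). `absorbance_map` reports the nearest-grid
  intensity at a requested wavenumber.

## 8. Randomness and reproducibility

All stochastic functions take a `seed` (or an existing `Generator`).
Dataset- and image-level simulation spawns independent child streams via
`numpy.random.SeedSequence.spawn`, so per-spectrum noise is independent
of the number of spectra requested and identical seeds give bit-identical
outputs on any platform with the same NumPy version.

## 9. Limitations

- **The band table is a generator default, not a fitted library.** Band
  centres, widths and relative amplitudes are plausible literature-style
  values chosen for qualitative realism; absolute intensities are in
  arbitrary units and should not be compared across modalities.
- **Kinetics are phenomenological.** Linear uptake, fixed yields and the
  `x·e^(1−x)` bump reproduce the qualitative fermentation timeline
  (lipid accumulation and turnover, labelling dilution by glycerol,
  transient polyphosphate and carotenoid pools), not a calibrated
  metabolic model.
- **PLSR Q-residual flags are sensitive to residual structure.** With
  purely i.i.d. noise at ~1900 variables, training Q residuals are
  biased low (degrees of freedom absorbed by the fit) and extremely
  tight, so the 99th-percentile threshold over-flags clean test spectra.
  With realistic per-sample path-length and baseline variability — the
  regime the recipes target — train and test residual distributions
  overlap and the flags behave as intended (see
  `examples/06_plsr_calibration.py`).
- **No scattering physics.** Mie-type distortions, fluorescence
  backgrounds beyond smooth polynomials, detector nonlinearity and
  wavenumber-calibration drift are not modelled; EMSC is included
  because it is standard practice, not because the generator produces
  the artefacts it exists to remove.
- **Isotope fractions are per-metabolite scalars**, not per-atom
  isotopomer distributions; partially labelled molecules are represented
  as a linear mix of fully-¹²C and fully-¹³C band positions, which is a
  good approximation only for well-separated band pairs.
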