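# Methods

## Generative model for fingerprint spectra

An isomer fingerprint is a list of absorption bands (center ν₀ in cm⁻¹,
relative intensity a ≥ 0, full width at half maximum). Bands are rendered
as unit-height Gaussians,

    I(ν) = Σ_bands a · exp(−4 ln2 · (ν − ν₀)² / fwhm²),

and superpose linearly. The default fwhm is 8 cm⁻¹: cryogenic gas-phase
bands are narrow and well resolved, and 8 cm⁻¹ keeps neighboring fixture
bands distinguishable on the 2 cm⁻¹ analysis grid while still producing
realistic overlap. Computed stick spectra enter the same machinery after an
affine frequency correction ν → scale·ν + shift (harmonic scale factors
such as 0.965, or a constant anharmonic offset such as ±20 cm⁻¹; the shift
is signed because published conventions differ).

A mixture scan is simulated as the molar-fraction-weighted sum of the pure
renders plus additive white Gaussian noise with standard deviation
sd = max(clean)/snr, drawn from a seeded generator. Negative intensities
produced by the noise are **kept** in raw synthetic spectra — clipping
happens only at NMF-input construction, keeping the generator honest about
what a baseline-subtracted measurement looks like.

### The four-isomer fixture

`default_library()` emulates four α/β-Gal/Glc phytosphingosine isomers.
All four share two backbone bands (1040 and 1110 cm⁻¹), as stereoisomers of
a common sugar–lipid scaffold would, and each adds two smaller diagnostic
bands; every model keeps at least one band ≥ 6 cm⁻¹ from every band of
every other model, and the 1065 cm⁻¹ band occurs in exactly one model. The
shared backbone gives pairwise cosine similarities of ≈ 0.76–0.83 between
area-normalized fingerprints — congested enough that four-component
unmixing is genuinely harder than binary, which is the regime the studies
probe. Band centers stay more than 3 fwhm inside the 1000–1150 cm⁻¹ window
and all models carry the same intensity multiset, so the integrated
response per isomer is equal by construction (numerically re-equalized to
one part in 10¹² at library build time).

Equal integrated response is the **equal-response assumption**: one mole of
any isomer contributes the same integrated absorbance, so molar fractions
and spectral-area fractions coincide and noise-free unmixing is exact.
Real isomers violate this mildly (absolute band intensities differ);
`quantification_bias_study` reintroduces per-isomer response factors to
measure the resulting systematic over/under-estimation.

What the generator does **not** emulate: rotational or combination-band
structure, baseline drift, wavenumber calibration error, laser-fluence
variation across a scan, and ionization-efficiency differences between
isomers. Passing tests therefore demonstrate the correctness and noise
robustness of the *analysis*, not instrument-level performance on real
extracts.

## Preprocessing conventions

* Grids are start/stop/step triplets with both endpoints included:
  1000–1150 cm⁻¹ at 2 cm⁻¹ gives 76 bins; 952–1150 cm⁻¹ gives 100.
* Binning: bin b centered at c_b collects raw points in the half-open
  window [c_b − step/2, c_b + step/2) — every raw point lands in exactly
  one bin — and takes their arithmetic mean, so bin values stay on the
  intensity scale regardless of raw sampling density. Interior empty bins
  are filled by linear interpolation between non-empty neighbors; edge
  empty bins take the nearest non-empty value.
* "Surface area" normalization uses the trapezoidal rule over the analysis
  window; it is idempotent and scale-invariant. Raw scans are simulated at
  0.5 cm⁻¹ and binned down, which mimics a finer instrument scan step and
  halves the per-bin noise.
* Negative (noise) intensities survive binning and are clipped to zero only
  when the NMF input matrix is built, since IR intensities are inherently
  non-negative.

## Factorization

`MultiplicativeNMF` minimizes

    ½‖X − WH‖²_F + α[ r(‖W‖₁+‖H‖₁) + (1−r)/2 (‖W‖²_F+‖H‖²_F) ],  r = l1_ratio,

by the classical alternating multiplicative updates, with denominators
floored at 10⁻¹² (entries can never become exactly zero mid-run). The
objective is recorded every iteration and is non-increasing to numerical
precision. Defaults: 2000 iterations, tol = 0 (fixed-iteration setup; the
convergence flag is still reported), α = 0, r = 0, seeded random
initialization with entries scaled by √(mean(X)/k).

Regularization note: the α penalty is absolute, so its effect depends on
the scale of X. Area-normalized rows have Frobenius norm ≪ 1, and an α of
order 1 then drives the updates to the all-zero fixed point (the update map
is a contraction whenever ‖X‖²_F < α²); α = 0 is therefore the pipeline
default and the bias study uses α values commensurate with the data scale
(≈ 10⁻³–10⁻⁴).

### Non-uniqueness, initialization modes, and percentages

With congested, overlapping fingerprints the pure spectra are not extreme
rays of the non-negative orthant, so X admits families of near-exact
factorizations whose bases are "sharpened" versions of the true spectra.
Random-init multiplicative updates settle on such alternatives: even on
noise-free four-component data the recovered mixture weights deviate by
2–3 percent points after 2000 iterations (and still ≈ 1.7 after 40 000).
This is the practical face of NMF's non-uniqueness and the principal reason
multicomponent quantification is less exact than binary; it is a property
of the default analysis, deliberately retained.

For applications that need exact reference-consistent recovery, the
pipeline offers a semi-supervised mode, `init="reference"`: the initial
basis is anchored at the pure-reference rows of the input matrix, the
weights are first warm-started against that fixed basis (coefficient-only
updates, up to `warm_start_max_iter` = 20 000 cheap iterations with an
objective-based early stop), and ordinary alternating updates follow. In
this mode noise-free mixtures are recovered essentially exactly (< 0.1
percent points at k = 4).

Percentages: NMF leaves the split of scale between W column i and H row i
free, so before converting weights the package rescales each basis row to
unit trapezoidal area over the analysis window (W columns inversely). The
assigned weights of each mixture row are then normalized to sum to 100.
On clean equal-response data this convention makes the percentages equal
the generating molar percentages; without the rescaling the numbers would
depend on the arbitrary per-component scale of the factorization.

Component↔isomer matching uses the pure-reference rows: each reference
row's weights are row-normalized and the bijection maximizing the total
score is found exhaustively (k ≤ 4 here, k! permutations). A tie within
10⁻⁹ raises an "ambiguous assignment" error; a reference whose top
component holds < 50 % of its weight triggers a "weak reference" warning.

## Studies and their defaults

All studies derive per-stage sub-seeds deterministically from the study
seed (`numpy.random.SeedSequence` spawn keys), so results are reproducible
bit for bit from the manifest.

* **Binary series** — β:α ratios 50:50, 75:25, 90:10, 95:5 (optionally
  99:1), one noisy mixture scan per ratio plus the two clean pure
  references, k = 2, joint factorization; reports recovered percentages,
  absolute errors, and agreement of each binned mixture with the
  weighted-average forward model. Default snr 50 ("synthetic standard"
  regime).
* **Multicomponent retrieval** — all 2ⁿ − n − 1 equimolar subsets of the
  four-isomer library (11 designs) plus the four noisy single-component
  scans, which double as the reference rows: a 15 × 76 matrix, k = 4.
  An isomer is called present above 10 % (configurable; equimolar truths
  are ≥ 25 %, so the threshold sits well between signal and background).
* **Detection limit** — minor fractions {50, 25, 10, 5, 1, 0}%, 20
  replicates each, one mixture + two clean references per replicate.
  A fraction is *detected* when its replicate mean exceeds the 0 %-control
  mean by three control standard deviations — this package's
  operationalization of "reliable detection". The study runs at the s/n
  selected by `calibrate_snr`, which scans a descending s/n grid and picks
  the first (largest) s/n whose binary-series maximum error lands in the
  3–5 percent-point band; the calibration replicate count (10) matches the
  10-seed binary protocol it references. Detection monotonicity (every
  fraction above the smallest detected one is also detected) is checked
  and reported rather than assumed.
* **Extract-style study** — unknowns on the extended 952–1150 cm⁻¹ /
  100-bin window against the four standards, default snr 10 (the
  "biological extract" regime); reports per-unknown percentages and the
  dominant-isomer call. The default surrogates are one pure-β-Glc unknown
  and one 85:15 β-Glc:α-Glc unknown.

## Numerical choices and degenerate inputs

* Duplicate wavenumbers on file read are rejected; unsorted rows are
  sorted. Spectrum files round-trip exactly (17 significant digits).
* All-zero or negative input matrices, k > min(rows, cols), degenerate
  (non-positive-area) rows, fractions not summing to 1 (tolerance 10⁻⁹),
  and non-positive Mason–Schamp inputs raise errors rather than warn.
* Adduct mass deltas are charge-carrier masses (electron removed):
  1.007276 (H⁺), 22.989218 (Na⁺), 106.904548 (¹⁰⁷Ag⁺); monoisotopic masses
  use most-abundant-isotope masses to six decimals. CCS uses K₀ referenced
  to 273.15 K / 760 Torr and CODATA constants via scipy.

## Known limitations

* Quantification assumes equal integrated response across isomers; real
  response differences propagate directly into percentage bias (measured,
  not corrected).
* The number of components k must be supplied; there is no model-order
  selection.
* The detection rule compares a replicate mean against a 3-sd single-level
  control threshold; other operationalizations (e.g. per-measurement
  decision limits) would shift the detection limit.
* No baseline correction or smoothing is applied anywhere; spectra are
  assumed baseline-free apart from zero-mean noise.
* Desk-scale problem sizes: studies use 76–100 bins, ≤ 15-row matrices,
  10–20 replicates, chosen so every study runs in seconds while leaving
  the Monte Carlo conclusions stable across seeds.
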