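# Methods

`nutspec` implements a complete NIR hyperspectral-imaging chemometrics
workflow for screening total fat and fatty-acid composition in intact nut
kernels, together with a synthetic-data generator that reproduces the
statistical structure such studies rest on. This note documents the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic experiments do and do not demonstrate.

## Imaging model and radiometric calibration

A hyperspectral acquisition is a cube of raw sensor counts over
`lines x pixels x bands`, nominally covering 900–1,700 nm at 3.25 nm pitch.
Raw counts are converted to relative reflectance by two-point calibration
against a dark-current frame and a white-reference (PTFE tile) frame,

    R = (raw − dark) / (white − dark),

then transformed to apparent absorbance `A = log10(1/R)` and restricted to
the 950–1,650 nm subrange, outside of which detector noise dominates.
Conventions that published descriptions of this workflow leave open, fixed here:

* **Clipping.** Reflectance is clipped to `[1e-4, 1.5]` before the log so
  dead pixels cannot produce infinities while specular glints above 100 %
  reflectance are retained. Configurable.
* **Frame reduction.** Dark and white frames are reduced to per-pixel-column
  medians across scan lines before use; single-frame references are shot-noise
  limited and the median is robust. Frames that are constant across lines
  short-circuit the median, which also makes the synthetic encoding exactly
  invertible (round-trip error < 1e-10 with noise off).
* **Band subsetting** is inclusive on both endpoints.

Cubes are exchanged in the classic ENVI dialect (text header + flat
little-endian binary; BSQ/BIL/BIP read, BSQ written).

## Pixel segmentation

Kernel/background segmentation uses stepwise linear discriminant analysis on
absorbance spectra of labelled training pixels. Forward selection minimizes
Wilks' Λ: the candidate with the largest partial F enters while
`F ≥ f_enter` (default 3.84), and selected bands whose partial F falls below
`f_remove` (default 2.71) are swept out, up to `max_vars` (30). These are
the classic stepwise defaults (the 5 % and 10 % points of F(1, ∞)); published
descriptions name stepwise LDA but no thresholds. A Fisher discriminant
with equal priors is then fit on the selected bands, thresholded at the
midpoint of the projected class means — training-pixel class balance is
under the user's control, so equal priors are the neutral choice.

Kernel regions are 4-connected components of the classified mask with
`min_area = 50` px (kernels are compact; the filter removes classifier
speckle). Per-kernel spectra are arithmetic means over ROI pixels. Each tray
is imaged twice with a 180° rotation; the two spectra of a kernel are
**averaged** (whether reported workflows averaged or concatenated is
typically unstated; averaging preserves band count and halves acquisition noise, and
the choice is configurable in code). When ground-truth pairing is absent,
kernels are paired across acquisitions by rotating one acquisition's
centroids onto the other and solving the optimal assignment.

One caution: with thousands of training pixels, partial-F thresholds are
easily cleared, so the stepwise selection can retain many near-collinear
bands (the guard is `max_vars`). Classification accuracy is insensitive to
this; band parsimony is not a goal of the segmentation stage.

## Spectral pretreatments

Pretreatments are written exactly as reported in NIR calibration tables:
`"<scatter> d,g,s1,s2"` — SNV, MSC, detrend (degree-2 polynomial in
wavelength), combinations, or `None`, followed by a gap–segment derivative:
running-mean smoothing of width `s1`, derivative of order `d` over a gap of
`g` bands, second smoothing of width `s2`. Numerical conventions:

* The derivative stencil is **central**: `D(i) = s(i+g) − s(i−g)` for d=1
  and `s(i−g) − 2 s(i) + s(i+g)` for d=2 (the proprietary original is not
  published; the central form is symmetric and zero-phase).
* Edge bands without full stencil support are **dropped, never padded**; the
  surviving wavelength grid is returned so band bookkeeping stays explicit.
* Widths of 0 or 1 mean no smoothing; even widths round up with a warning.
* Scatter correction runs **before** the derivative (the combined code
  "SNV+detrend" is printed without an order); a `derivative_first` flag
  exposes the other order.
* The MSC reference is the calibration-set mean at fit time and is stored
  with the model, so prediction replays the identical correction.

## Sample selection (global H / neighbourhood H)

Selection operates in the score space of a mean-centred PCA keeping the
fewest components explaining 99 % of variance. Distances follow the
standardized ("global H") convention:

    H(x) = (1/k) Σ_j (t_j / sd_j)²,     NH(x, z) = (1/k) Σ_j ((t_j − u_j)/sd_j)²

so the training mean of H is exactly (N−1)/N ≈ 1, which is what makes the
customary thresholds meaningful: H > 3 flags spectral outliers, NH < 0.9
defines spectral equivalence. Published workflows state the thresholds but not the
normalization; this convention is the one under which they are standard.
Squared (not root) distances are used; this is fixed and documented rather
than configurable, because the thresholds calibrate to it.

Grouping is greedy max-degree: the unassigned sample with the most
unassigned NH-neighbours seeds a group and absorbs them (ties broken by
lowest index), until all samples are assigned. The algorithm is
deterministic, near-minimal in group count (verified against brute force at
small N), and every member lies within NH < 0.9 of its seed by
construction. Group seeds form the calibration set; the member nearest its
seed forms the validation set; everything else is predicted later
("non-selected"). Input order can influence tie-broken seeds only.

## Modified PLS (MPLS)

Calibrations are single-response PLS1 with the classic "modified" twist:
after each factor is extracted (weight ∝ Xᵀy, scores t = Xw, loadings
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation of X and y), **every spectral residual
column and the chemistry residual are divided by their standard
deviations**, and those scalings are stored so prediction can replay them.
With all scalings forced to one the algorithm reduces exactly to standard
PLS1 (verified against an independent NIPALS implementation to < 1e-8 on
random instances; factor 1 is identical by construction since scaling
starts after the first deflation).

The factor count is chosen by cross-validation: contiguous folds of a seeded
shuffle (default 6 folds — reported workflows divide the calibration set into
subsets without stating how many; 4–6 is the working convention at N ≈ 43),
SECV(f) = RMS of held-out residuals, and the global argmin over 1..F_max
wins (no parsimony rule is stated, so none is applied).
`F_max = min(15, ⌊N/3⌋)` caps the search; reported NIR models of this kind
select 1–7 factors. Chemistry outliers are then removed with the
T statistic, `T = |y − ŷ_cv| / SECV > 2.5` (strict), with model and SECV
refit after each pass, at most two passes, never below 10 samples. Whether
the original software uses SEC or SECV in the denominator is not public;
SECV is used because the residuals being screened are cross-validated.
Models serialize to JSON and reload to bitwise-identical predictions.

## Validation statistics and reporting

SEC = √(SSE/(n−f−1)) on the calibration set; RSQ = 1 − SSE/SST;
SECV = √(mean CV residual²); bias = mean validation residual;
SEP = √(Σ(e−bias)²/(n−1)) — the bias-corrected convention classic in NIR
work. Whether published SEP values are bias-corrected is usually
undecidable from a paper, so the uncorrected RMSEP is always emitted
alongside. The applicability range of a model is Est.Min/Est.Max =
calibration mean ∓ 3 SD, and percent errors are quoted relative to the
midpoint of that range: `100 · err / ((Est.Min + Est.Max)/2)`. These two
conventions jointly reproduce published table cells to their printed
precision (percent cells to ~1e-3, limited by the 3-dp rounding of the
inputs). Percentages are rounded half-even to 3 decimals in emitted tables.

## Composition statistics

The 16 fatty acids (relative % of total fatty acids) have fixed family
memberships: 4 SFA, 8 MUFA, 4 PUFA; family totals are sums of member acids.
Variety summaries report mean, SE = SD/√n (missing for n = 1) and n. Grand
means are **unweighted across varieties** — the convention under which the
published within-family shares (palmitic ≈ 69 % and stearic ≈ 25 % of SFA,
oleic ≈ 90 % of MUFA, linoleic ≈ 81 % and α-linolenic ≈ 19 % of PUFA) and
family grand means (9.40 / 14.43 / 76.16) reproduce exactly; sample-weighted
means would not be verifiable without the per-sample data. Between-variety
comparisons use one-way ANOVA plus Tukey–Kramer pairwise tests (α = 0.05,
unequal n supported). The compact letter display labels the maximal cliques
of the not-significantly-different graph, ordered by descending clique
mean — equivalent to the greedy insert-and-absorb construction but exact by
construction; two groups share a letter iff they are not significantly
different. Identical data across groups yield an undefined F and one shared
letter.

## Synthetic data: what it emulates

No kernel-level dataset is publicly deposited for this workflow, so the
generator stands in for it, and its defaults *are* the study conditions.

**Chemistry panels.** Five varieties with published means and SEs for total
fat and the 16 acids. Each acid is drawn independently as
N(mean, n·SE²) — so the SE of a size-n variety sample targets the published
SE — truncated at zero and renormalized so the 16 acids sum to exactly 100.
Default kernel counts per variety are 31/29/32/35/38 (the 165 kernels that
survived visual inspection in the reference walnut study this emulates). Two known distortions of
this scheme are deliberate and documented rather than corrected:
renormalization induces the compositional negative correlation between
acids and shrinks the realized spread of the dominant acids by ~10–17 %
(closure), and zero-truncation biases trace acids whose SE is large relative
to their mean. Tests therefore verify total-fat SEs against the raw targets
and acid SEs against a delta-method oracle that accounts for truncation and
closure. Within-variety biological correlation between acids beyond closure
is not modelled (no published estimates exist to calibrate it against).

**Spectra.** Beer–Lambert by construction: each component carries an
absorptivity signature (sums of Gaussian bands in the 1,150–1,500 nm
first-overtone window, heights chosen so kernel absorbance spans roughly
0.1–1.2), and a kernel pixel's absorbance is the concentration-weighted sum
of signatures, times per-kernel multiplicative scatter (SD 0.05) and
per-pixel path-length jitter (SD 0.02), plus a per-kernel baseline
(SD 0.02), per-kernel smooth microstructure, and sensor noise (SD 0.005);
reflectance is R = 10^(−A) and raw counts are encoded as
`dark + R·(white − dark)`, making the calibration exactly invertible when
noise is off. The linear composition→spectrum map means PLS-family models
are correctly specified, which is what a parameter-recovery acceptance
surface requires; an optional nonlinearity is out of scope.

The signature library carries the four calibrated analytes (total fat, SFA,
MUFA, PUFA) plus four nuisance constituents — moisture, protein,
carbohydrate, fiber — with distinct narrow bands and kernel-to-kernel
concentration spread. The per-kernel microstructure term (12 smooth
Gaussian-bump dofs confined to 1,490–1,650 nm, SD 0.006 absorbance)
represents surface-texture/scattering variability riding on the steep
long-wavelength water shoulder. Together these two terms give the spectra
the high effective rank real kernel spectra show; with the defaults, the
selection stage reproduces the reported study conditions from 165 synthetic
kernels: ~11–12 PCs explain 99 % of SNV-derivative spectral variance,
roughly 45–60 NH < 0.9 groups emerge, and no H > 3 outliers occur. Keeping
the microstructure away from the 1,150–1,500 nm composition bands is what
lets a ~50-sample calibration still recover total fat with external
R² > 0.95 — placing it across the whole range drives the model error floor
several times above the reference noise, which would say more about the
generator than about the method.

**Reference noise.** Measured chemistry is the true composition plus assay
noise (total fat SD 0.5 % by weight — gravimetric extraction repeatability;
family totals SD 0.15–0.30 relative % — GC integration repeatability). The
parameter-recovery criterion compares the pipeline's external SEP to the
injected total-fat assay SD: across 10 seeded replicates the pooled (RMS)
SEP sits at ~1.4–1.6× the assay SD (individual seeds 1.0–2.2×; a single SEP
estimated from ~15 validation kernels carries ~20 % sampling error, which is
why the pooled value is the quantity asserted).

**Scenes.** Up to 10 kernels per tray on a 256 × 320 frame, rendered as
irregular ellipses (area 300–900 px — enough pixels for stable mean
spectra at desk scale), background a flat, spectrally distinct tray
spectrum, dark/white frames with a smooth lamp curve and mild vignetting.
Each tray renders twice at 180°-rotated positions with fresh noise and
scatter but identical kernel geometry and chemistry; the pairing is
recorded. All randomness flows from one integer seed through independent
substreams (layout / chemistry / per-acquisition noise), so layout can be
held fixed while noise varies — this is also what makes the
noiseless-rerender oracle exact. Noiseless scenes render in double
precision (so calibration inverts the encoding to 1e-10); noisy scenes use
single precision, whose rounding is three orders of magnitude below the
sensor noise floor.

**What passing tests do not show.** The generator is linear, uses Gaussian
bands, independent nuisance constituents and white sensor noise; real NIR
spectra have correlated noise, temperature-driven band shifts, nonlinear
path-length effects and biological covariance the generator omits.
Parameter recovery here demonstrates that the *pipeline* is implemented
correctly and is well-behaved under its own assumptions — it does not
predict the SEP attainable on real kernels, and the published headline
errors are not reproducible without the original (undeposited) dataset.
For the same reason the published discriminating wavelengths and
per-analyte T-outlier counts are qualitative context, not targets.

## Pipeline and problem sizes

`run_pipeline` executes simulate → calibrate → segment → select → train →
validate → report from one config and seed, streaming scene by scene so
full raw cubes are never held together in memory. Per analyte, a sweep over
the standard pretreatment codes keeps the model with the lowest SECV (the
"best result" criterion is typically unstated; lowest SEP is available
as a config switch). Reports mirror the usual table layout (pretreatment,
T outliers, factors, N, Est.Min/SD/Est.Max, SEC/RSQ/SECV/SEP and percent
forms) plus a variety-level prediction summary with Tukey letters.

Default problem sizes are the package's own choices: the test suite runs
trays of 10 kernels on 256 × 320 × 216 scenes, a 20-scene segmentation
battery, and 10-seed × 165-kernel recovery replicates at the spectra level
(the imaging and spectra-level generators are statistically identical for
ROI-mean spectra, which is asserted by test); the acceptance script runs
one full 165-kernel recovery plus a 2-scene imaging check.

## Known limitations

* The stepwise-LDA permutation-null example is calibrated per candidate
  band; testing many bands at F-to-enter 3.84 rejects more than 5 % of
  shuffles in aggregate (multiplicity), which is inherent to stepwise
  selection, not a defect of the implementation.
* NH grouping is greedy; pathological geometries can use one group more
  than the true minimum.
* The ENVI dialect supported is the common core (no BIP writing, no bad-band
  lists, little-endian only).
* MPLS residual scaling follows the published description of the
  modification; the proprietary implementation may differ in details
  (T-statistic denominator, fold construction), so model descriptors —
  not coefficients — are the comparable quantities.
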