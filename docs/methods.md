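# Methods

This note documents the models and estimators implemented in
`leukoftir`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical choices a
maintainer would want to know. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Spectral model and preprocessing

A spectrum is absorbance A(k) on a strictly increasing wavenumber grid
(cm⁻¹). Preprocessing is fixed as **resample → baseline → normalize**,
followed by replicate averaging per subject (and re-normalization, since
a mean of unit vectors is not unit). The order is a convention: baseline
correction before normalization makes the unit-norm scale refer to band
material rather than to drift.

- **Resampling**: linear interpolation onto a uniform analysis grid,
  default 800–3500 cm⁻¹ at 2 cm⁻¹ (the acquisition resolution; the
  displayed analysis range of serum work). Linear interpolation at
  2 cm⁻¹ distorts a ≥12 cm⁻¹-wide band by <0.1% of its height.
- **Baseline**: default *rubberband* — subtraction of the lower convex
  hull of (k, A), computed by a monotone-chain scan. It is
  parameter-free, idempotent, and leaves a non-negative spectrum; these
  are tested properties. A polynomial alternative (least squares through
  automatically selected local minima) is provided for dialect
  comparisons. The hull cannot descend into the floor of densely
  overlapped band clusters, so a small positive residual (~1–3% of the
  amide-I height) survives between bands; its visible consequence is
  that windowed-area ratios on noisy/drifting cohorts sit a few percent
  below their clean-spectrum values (the acceptance JSON reports both).
- **Normalization**: division by the Euclidean norm over the analysis
  grid. Every downstream statistic used for inference (area ratios,
  structure fractions, phase correlations) is separately invariant to
  positive rescaling, so normalization is belt-and-braces against film
  thickness rather than load-bearing.
- **Derivatives**: Savitzky–Golay, window 21 points, polynomial order 7
  (the classical second-derivative settings for amide-I work, reused for
  first derivatives). With `mode="interp"` the filter is exact on
  polynomials of degree ≤ 7 everywhere including edges; the suite
  verifies ≤ 1e-9 on scaled degree-7 polynomials. No extra offset
  correction is applied before differentiation: derivatives annihilate
  constant baselines by construction.

## 2. Synthetic cohort generator

The generator is the package's verification instrument: it emulates a
small serum-FTIR case/control study with every downstream quantity
planted and recorded.

Each noiseless spectrum is a sum of Gaussian bands at the canonical
serum band positions and maxima (two tables, one per group, covering
894–3278 cm⁻¹), except that the amide I band is synthesized from its
eight sub-bands directly: sub-band areas are proportional to the
sample's planted structure fractions times a total amide area of
2.2 A.U.·cm⁻¹ (chosen so the composite maximum ≈ 0.07 A.U., the height
of the amide-I line in the band table). Group compositions:

| fraction | control | disease |
|---|---|---|
| α-helix (1649) | 0.51 | 0.40 |
| β-sheet (1623, 1633, 1694; split 0.45/0.45/0.10) | 0.25 | 0.34 |
| β-turn (1672, 1685; split 0.6/0.4) | 0.175 | 0.23 |
| intermolecular β-sheet (1614) | 0.06 | 0.03 |
| side chain (1607) | 0.005 | 0.00 |

Per-sample fractions jitter around the group composition via normalized
Gamma draws (Dirichlet-like, concentration κ=400, ≈2–3 pp SD). With this
composition the analytic composite maximum of the disease model sits
0.37 cm⁻¹ below the control's — the correct direction for a disease
group richer in β structure, though smaller than the ~4 cm⁻¹ shift seen
clinically and below the 2 cm⁻¹ grid resolution; the direction check is
therefore made on the analytic composite.

Note an important consequence: because per-sample fractions average to
the group composition, the **mean %βs+βt is higher in the synthetic
disease group** (57 vs 42.5). Clinical reports of per-patient averages
show the opposite ordering while their average-spectrum decompositions
show this one; a linear generator cannot produce both at once, and this
package plants the spectral (average-spectrum) composition, which also
reproduces the amide-maximum shift and the ratio directions. The %βs+βt
biomarker therefore discriminates with direction `higher_is_case` on
synthetic cohorts; the ROC machinery takes the direction as an input,
and the pipeline chooses it from the group means.

Other planted structure:

- **CH₃/amide-I ratio**: the ~2965 cm⁻¹ band height is solved by fixed
  point so that the clean-spectrum windowed area ratio (windows
  2945–2985 over 1600–1700, trapezoid, after rubberband) hits ≈1.6
  (control) vs ≈0.54 (disease). The per-sample ground-truth ratio is the
  same functional applied to that sample's clean spectrum (its CH₃ band
  carries a log-normal jitter, SD 0.3, giving realistic within-group
  spread). Defining truth through the ideal noise-free measurement makes
  the recovery test a test of noise/drift/thickness robustness, not of
  integration conventions; the integration and hull primitives have
  their own closed-form oracles.
- **Phase marker**: an odd-symmetric bump g(u) = u·exp(−u²/2),
  u = (k−1046)/4 cm⁻¹, added with per-sample polarity ±0.02 A.U. A
  40 cm⁻¹-FWHM carbohydrate-region pedestal at 1046 cm⁻¹ (height
  0.025 A.U.) keeps the region non-negative under the negative marker
  lobe, and its right-flank slope cancels the neighboring
  1070/1071 cm⁻¹ band's tail ramp, so the window's background
  derivative is locally flat. That flatness is the regime the Lissajous
  method presumes: observed phase figures in this application are clean
  ± lines, which requires the polarity feature, not a common background
  ramp, to dominate the window.
- **Relational phase labels**: the classifier's reference is the
  *control average*, so "covariant" is meaningful only relative to the
  control majority's marker direction. The generator draws marker signs
  (P(covariant) = 0.4 in both groups, matching the observed label
  prevalences), re-draws the control sign vector in the rare event of an
  exact tie (a tied reference carries no marker direction, leaving phase
  undefined), and labels a sample phase 0 iff its sign matches the
  control majority. Recovery of these labels by the full pipeline is
  100% across seeds at the default amplitude (10× noise SD), and
  degrades monotonically as the amplitude shrinks — both tested.
- **Counts**: disease samples obey the clinical rule by construction —
  covariant: WBC log-normal (median 20, log-SD 0.8) truncated to > 9.0,
  blasts = WBC·U(0.3, 0.9); contravariant: WBC U(0.1, 9.0),
  blasts = WBC·U(0, 0.15) capped at 1.0. Controls draw WBC log-normal
  (median 6, log-SD 0.35) with no blasts, independent of phase — the
  rule is deliberately uninformative for controls.
- **Nuisances**: per-replicate quadratic baseline drift (coefficient SD
  0.005 A.U., shifted non-negative), log-normal film thickness (log-SD
  0.1), i.i.d. Gaussian noise (SD 0.002 A.U. ≈ 3% of the amide-I
  maximum), log-normal band-height jitter (SD 0.05). Band widths:
  25 cm⁻¹ FWHM for fingerprint bands, 45 cm⁻¹ for C–H stretches,
  80 cm⁻¹ for the broad N–H/O–H stretch, 18 cm⁻¹ for amide sub-bands.

What the generator does **not** emulate: water-vapor and CO₂ lines, ATR
penetration-depth dispersion, Mie scattering, correlated (pink)
instrument noise, and any real biochemical covariance between the
marker, the protein fractions and the counts beyond the planted rule.
Passing recovery tests therefore shows the estimators are correct and
robust to the modeled nuisances — not that real serum data will separate
this cleanly.

## 3. Amide I deconvolution

Second-derivative minima inside 1600–1700 cm⁻¹ seed the line positions;
dips shallower than 5% of the deepest minimum are suppressed as filter
ringing (the 21-point window spans 40 cm⁻¹ and rings around narrow
lines; the threshold sits an order of magnitude above observed ringing
and below any real line's depth). Seeds only refine the optimizer's
starting point: the feasible box for each center is the canonical
position ±3 cm⁻¹ (clinical shifts are reported at the 1–2 cm⁻¹ level),
because derivative minima of heavily overlapped lines are biased
estimators of the line centers and must not move the constraint set.

The fit itself is bounded nonlinear least squares (scipy `trf`, analytic
Jacobian) of eight Gaussians **plus a jointly fitted linear local
background** over the raw 1600–1700 cm⁻¹ region. Two choices here are
deliberate and were forced by estimator behaviour:

- *Joint linear background instead of pre-subtracting the endpoint
  chord.* Sub-band tails are nonzero at 1600/1700, so the chord removes
  ~10% of genuine band area and biases fractions by several points even
  on noise-free data; fitting the background inside the model leaves the
  noise-free truth exactly representable.
- *One shared line width* (FWHM bounded to [6, 40] cm⁻¹) for all eight
  components. With per-line free widths the area partition of lines
  7–16 cm⁻¹ apart is ill-conditioned: 1%-of-peak noise moved individual
  fractions by tens of points while fitting the data to noise level.
  Sharing the width is the standard stabilization in amide-I curve
  fitting and restores identifiability (noiseless recovery is exact;
  mean absolute fraction error ≈ 2 pp at 1% noise with triplicate
  averaging — both computed by the acceptance script).

Amplitudes initialize from a bounded linear solve (non-negative
amplitudes, free background) at the starting centers; up to 5 jittered
restarts (±1 cm⁻¹ centers, width resampled in [12, 26] cm⁻¹) run when
the residual stays above 1e-5 of the region maximum, and the best
residual wins. Components are labeled by nearest canonical center (two
components claiming one center is a degenerate fit and an error), and
percentages are relative analytic areas (amplitude·σ·√(2π)) with
"other" = side chain + intermolecular β-sheet, so
α + (βs+βt) + other = 100 exactly.

Both cohort summary modes are reported and never merged: the average of
per-subject fractions, and the fractions of the group-average spectrum.
They agree on the linear generator but can diverge on real (nonlinear)
biology, which is precisely why both are kept.

## 4. Lissajous phase classification

The reference is the Savitzky–Golay first derivative of the
control-average spectrum (equal, to 1e-10, to the average of control
derivatives — linearity is a tested invariant). For a sample, the curve
(ref′(k), s′(k)) over the closed window [1042, 1050] cm⁻¹ (5 points at
2 cm⁻¹) is summarized by its Pearson correlation r: phase 0 if r > τ,
π if r < −τ, *ambiguous* otherwise, with τ = 0.2. The correlation sign
is the standard operationalization of 0-vs-π phase for in-phase /
anti-phase signals; the published construction classifies by curve shape
without a formula, so τ exists to keep borderline shapes from being
silently assigned. Classification is invariant to positive scaling and
flips under sign flip (tested). By default controls are classified
against a reference that includes them, matching the published
construction; a leave-one-out reference mode
(`classify_cohort(..., leave_one_out=True)`) is the recommendation for
honest evaluation of control-group claims.

The window scan slides a width-Δ window and scores
|P(phase 0 | disease) − P(phase 0 | control)|. Note that with the
default generator both groups share P(covariant) = 0.4, so the planted
marker is *not* group-informative and the scan correctly scores ~0
there; the scan test plants group-separated prevalences instead. On
default cohorts, moderate scores appear near bands whose height differs
between the group models — a real (and clinically plausible) source of
group separation distinct from the marker.

The count-rule concordance takes observed phases and a WBC/blast table
and reports per-sample agreement with *predicted = 0 iff blasts > 1.0
and WBC > 9.0*. The bundled published example (ten disease subjects with
printed counts and phases) is reproduced 10/10; the bundled control
example shows the rule has no explanatory power for controls, as
published.

## 5. Biomarker evaluation

- **ROC/Youden**: empirical ROC over all threshold midpoints (plus
  sentinels beyond the extremes); the cut-off maximizes J with ties
  broken toward higher specificity, and is reported as the midpoint
  between adjacent observed scores — the convention that yields
  interior values like a published cut-off between two groups' scores.
  AUC comes from scikit-learn and is verified exactly against the
  normalized Mann–Whitney U statistic (scipy) on exhaustive small random
  instances, ties included. `direction=lower_is_case` flips scores
  internally so a low biomarker flags disease.
- **Bootstrap AUC CI**: stratified (within-class) percentile interval,
  default 2000 resamples, seeded; stratification makes one-class
  resamples impossible. Coverage of the closed-form binormal AUC
  (Φ(√2) ≈ 0.921 at 2 SD separation) is verified ≥ 90% over 100 outer
  replications.
- **AdaBoost LOOCV**: 50 depth-1 stumps, learning rate 1.0, on the
  first 5 principal components of first-derivative spectra. PCA is refit
  inside every training fold by default (no leakage); a fit-once mode
  exists for comparison with leakier historical practice. The number of
  components and stump count are conventional defaults, configurable
  and logged in the report.

## 6. Pipeline and determinism

`run_pipeline` composes the stages and writes `features.csv`,
`structure.csv`, `phases.csv`, `roc.json` and `report.json`. The report
embeds the fully resolved configuration (minus the output directory,
which is environmental) and its SHA-256 hash, uses sorted keys and no
timestamps, and is byte-identical across runs at a fixed seed — a tested
acceptance property. All randomness flows from explicit seeds through
`numpy.random.default_rng`.

## 7. Sizes and runtimes

The suite and the acceptance script are sized for a single CPU: recovery
studies use 50 subjects per group (amide) and 20-subject cohorts
(phase), the ratio-test power check uses 40 seeded cohorts, and the
bootstrap coverage study uses 100 replications of 500 resamples. The
full suite runs in ~3 minutes and `scripts/acceptance.py` in ~40 s.

## 8. Known limitations

- The amide-I identifiability fix (shared width) matches the generator's
  equal-width truth; real sub-bands have unequal widths, and fractions
  from real spectra inherit whatever bias that approximation carries.
- The rubberband residual between overlapped bands biases windowed areas
  low by a few percent; ratios are consistent within a processing
  dialect but not across dialects (the published OPUS baseline is not
  public).
- The phase marker is a phenomenological stand-in: the spectral origin
  of the published carbohydrate-region polarity flip is not established,
  and the generator makes no claim about it.
- With 5 points per window the correlation statistic is coarse;
  upsampling inside the window was considered and left out to match the
  acquisition resolution.
- Group models differ in several band heights besides the planted
  markers (their tables come from per-group measurements), so synthetic
  group separation is *not* attributable to any single feature unless a
  test plants it that way explicitly.
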