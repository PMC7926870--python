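# leukoftir

Serum FTIR biomarker analysis for screening pediatric B-cell precursor
acute lymphoblastic leukemia (BCP-ALL).

Diagnosing childhood leukemia requires invasive bone-marrow biopsy, often
under general anesthesia. Mid-infrared spectra of dried blood-serum films
are cheap, fast and label-free, and carry candidate biomarkers that could
triage which children actually need a biopsy. This package implements a
complete, testable pipeline for three such biomarker families on small
serum-FTIR cohorts (disease vs. control), together with a synthetic
cohort generator that plants known values of every quantity the pipeline
estimates — so every stage is verifiable end-to-end without patient data.

## The analyses

Given per-sample absorbance spectra A(k) (wavenumber k in cm⁻¹, 400–4000
at 2 cm⁻¹ resolution) the pipeline applies rubberband (lower convex hull)
baseline correction, unit-Euclidean-norm ("vector") normalization, and
replicate averaging, then computes:

1. **Peak-area ratios** — trapezoidal band areas in fixed windows; the
   headline marker is the CH₃-stretch / amide-I ratio
   A(2965)/A(1645). Ratios cancel film thickness; groups are compared
   with Welch's t or Mann–Whitney tests.
2. **Protein secondary structure** — the amide I band (1600–1700 cm⁻¹,
   C=O stretch) is deconvolved into 8 Gaussian lines at canonical
   positions {1607, 1614, 1623, 1633, 1649, 1672, 1685, 1694} cm⁻¹,
   seeded by Savitzky–Golay second-derivative minima (window 21,
   polynomial order 7) and fitted by bounded least squares. Relative
   line areas give %α-helix, %β-sheet, %β-turn; the biomarker
   %βs+βt is evaluated with a Youden-index ROC cut-off
   (J = sensitivity + specificity − 1) and a stratified-bootstrap AUC
   interval.
3. **Lissajous phase classification** — the novel method. A reference
   first-derivative spectrum RefSpec′(k) is the control-group average;
   plotting (RefSpec′(k), PatSpec′(k)) over a narrow window (default
   1042–1050 cm⁻¹) traces a line of positive slope for in-phase
   ("covariant", phase shift 0) samples and negative slope for
   anti-phase ("contravariant", phase π) samples. The decision statistic
   is the sign of the Pearson correlation, with an ambiguity band
   |r| ≤ 0.2. Phase labels are compared against the clinical rule
   *phase 0 ⇔ WBC > 9.0 and blasts > 1.0 (both 10³/µL)*, and a window
   scan ranks regions by group-discriminative power.
4. **ML baseline** — AdaBoost decision stumps on leading principal
   components of the first-derivative spectra, leave-one-out
   cross-validated with PCA refit inside each fold.

## Worked example

The numbered scripts under `analysis/` run the whole study on a seeded
synthetic cohort (10 + 10 subjects, 3 replicates each):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_peak_ratios.py
python analysis/03_amide_structure.py
python analysis/04_phase_lissajous.py
python analysis/05_ml_baseline.py
```

`02_peak_ratios.py` prints, among the eight band-pair ratios:

```
 2965/1645: median control  1.119 vs BCP-ALL  0.519   Welch p = 9.232e-07 *
```

i.e. the CH₃/amide-I area ratio is roughly halved in the disease group —
the planted group models put it at ≈1.6 vs ≈0.54, and residual-baseline
effects shift both medians down a little. `03_amide_structure.py` prints

```
group means (average of per-subject fits):
         pct_alpha  pct_beta_total  pct_other
bcp_all      37.63           57.49       4.88
control      45.85           45.69       8.46
%βs+βt ROC (higher_is_case): AUC 0.950 [0.820, 1.000], cut-off 53.1, sens 0.90, spec 1.00, acc 0.95
```

matching the planted composition (the disease model shifts ~11 points of
α-helix mass into β structures), and `04_phase_lissajous.py` prints

```
planted phase classes recovered: 100% (min |r| = 0.96)
synthetic disease group count-rule concordance: 100%
published worked example: rule reproduces 10/10 disease labels
```

— the classifier recovers every planted covariant/contravariant label,
and the WBC/blast-count rule reproduces all ten phase labels of the
bundled published disease example exactly.

A one-command variant (synthetic or real manifest in, all outputs and a
deterministic `report.json` out) is available as a CLI:

```sh
leukoftir run --seed 0 --out results/pipeline
leukoftir synth --out mycohort --seed 1      # spectra + manifest + truth
leukoftir lissajous mycohort/manifest.csv --window 1042:1050
```

## Reading real data

Spectra: two-column CSV (`wavenumber_cm-1,absorbance`, either axis
order) or JCAMP-DX (AFFN `XYDATA`/`XYPOINTS`). Cohorts: a manifest CSV
with columns `sample_id,group,file_path,replicate,wbc,blasts` where
`group` ∈ {control, bcp_all, unknown} and the count columns may be blank.
See `leukoftir.core.read_spectrum` / `load_cohort`.

## Layout

```
src/leukoftir/    library: core (I/O), preprocess, synthetic, peaks,
                  amide, lissajous, evaluate, datasets, pipeline, cli
analysis/         numbered study drivers (simulate → ratios → structure
                  → phases → ML), writing results/
scripts/          acceptance.py (headline-quantity reproduction)
tests/            pytest suite incl. end-to-end acceptance properties
docs/methods.md   model and estimator details, defaults, limitations
```
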