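# sirtflow

Analysis toolkit for the quantitative characterisation of a slow NAD⁺-dependent
protein deacetylase (SIRT6) and of the NFκB-driven transcriptional response it
modulates. The package covers five experimental readouts end to end — enzyme
kinetics, nuclear-translocation imaging, FRAP, two-colour expression arrays and
regulatory-network enrichment — and ships seeded synthetic-data generators with
known ground truth for every one of them, so each estimator can be validated
against the truth that produced its input.

## What it computes

**Enzyme kinetics** (`sirtflow.kinetics`). Fluorescent deacetylation assays are
converted to product concentration through a linear calibration, initial
velocities are taken as the slope of the longest early-time window with ≤10%
substrate conversion, and titrations are fit to the Michaelis–Menten equation
v = V·S/(Kₘ+S) by nonlinear least squares. `summarize_kinetics` derives
k_cat = V/E₀ and the specificity constant k_cat/Kₘ. The reference truth preset
is a deliberately slow enzyme: k_cat = 0.001 min⁻¹ (1.67×10⁻⁵ s⁻¹),
Kₘ(peptide) = 14.7 µM, Kₘ(NAD⁺) = 52.4 µM at E₀ = 2 µM.

**Translocation imaging** (`sirtflow.imaging`). Nuclei are segmented from a
DNA-stain channel by fixed or Otsu thresholding, the cytoplasm is sampled as a
dilated perinuclear annulus, and each cell is scored by its
nuclear:cytoplasmic stain ratio. A cell counts as nuclear-positive only when
the ratio strictly exceeds 1.25; annuli that would leave the image are
excluded.

**FRAP** (`sirtflow.frap`). Bleach traces normalised to the pre-bleach mean
are fit to F(t) = F₀ + (F∞−F₀)(1−e^(−t/τ)); half-time of recovery is t½ = τ·ln 2
and the immobile fraction is (1−F∞)/(1−F₀). Groups of half-times are compared
by Welch tests with Benjamini–Hochberg correction across pairs.

**Differential expression** (`sirtflow.diffexpr`). Probe-level log₂ matrices
are tested per contrast with a pooled-variance t statistic (df = n₁+n₂−2),
corrected by Benjamini–Hochberg, and called up/down with a strict fold-change
threshold (|FC| > 1.5) at q ≤ 0.05. Fold changes use the signed convention
(FC = 2^lfc for lfc ≥ 0, −2^(−lfc) otherwise). Response profiles from two
contrasts can be intersected and scored for containment or Jaccard similarity.

**Regulatory enrichment** (`sirtflow.enrichment`). For a query gene set of
size n in a universe of N genes, each transcription-factor regulon of size R
overlapping the query in k genes is scored by

- expected overlap  E = n·R/N,
- ratio  k/E,
- z = (k − E) / √( n·(R/N)·(1−R/N)·(N−n)/(N−1) ),
- p = the hypergeometric tail (upper for z ≥ 0, lower otherwise),

with BH correction across regulators. Pathway-level shifts in a fold-change
vector are scored by PAGE: z = (mean(member) − µ)·√m / σ against the
genome-wide background.

## Worked example

Generate a synthetic deacetylation assay and recover the rate:

```bash
$ sirtflow simulate kinetics --seed 7 --out demo
$ sirtflow rates --in demo/progress_curve.tsv --calib demo/calibration.tsv
{"v_um_per_min": 0.000808, "stderr": 9.8e-08, "r2": 0.99999987, "window": [0, 13]}
```

At S = 10 µM the truth preset predicts v = k_cat·E·S/(Kₘ+S)
= 0.001·2·10/24.7 = 8.097×10⁻⁴ µM/min; the windowed regression recovers it to
0.1%. Score the reference 200-gene NFκB response profile against the bundled
regulon database (N = 22 651 genes):

```bash
$ sirtflow simulate regulons --seed 0 --out demo_reg
$ sirtflow tf --query demo_reg/query.txt --gmt demo_reg/regulons.gmt --universe 22651
    tf  actual    r  expected  ratio         p      z         q
  RelA      47  451     3.982  11.80  1.01e-36  21.87  1.21e-35
 c-Rel      37  330     2.914  12.70  5.06e-30  20.20  3.03e-29
NF-kB1      29  200     1.766  16.42  6.66e-27  20.68  2.67e-26
   SP1      57 2410    21.279   2.68  1.87e-12   8.23  4.87e-12
  RelB      10   41     0.362  27.62  2.03e-12  16.10  4.87e-12
   ...
```

The three NFκB subunits dominate the ranking, while the large SP1 regulon
shows how raw overlap (57 genes) is discounted by its expectation (21.3).

Other entry points: `sirtflow quantify` (per-cell ratios from an image pair),
`sirtflow frapfit` (one trace), `sirtflow contrast` (expression TSV),
`sirtflow page` (pathway scores), `sirtflow mmfit` (titration table), and
`sirtflow run`, which executes all five analysis stages on synthetic presets
and writes `summary.json` plus `report.md` to an output directory —
deterministic for a fixed seed and configuration.

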