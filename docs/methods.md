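# Methods

This note records the models behind each stage, the default parameters and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that matter for reproducing results.

## Enzyme kinetics

### Assay model

A fluorogenic deacetylation assay is modelled as a linear map from product
concentration to signal, signal = slope·[product] + intercept, with the
intercept absorbing constant background fluorescence. The reference
calibration is slope = 1000 FU/µM, intercept = 50 FU. `fit_calibration`
rejects calibrations whose slope is below 10⁻¹² of the signal range, since
the inverse map would be numerically meaningless.

### Rate law

The enzyme follows a two-substrate rate law with the NAD⁺ dependence
expressed as a saturation factor normalised at the assay reference
concentration:

    v = k_cat · E · S_pep/(Kₘ_pep + S_pep) · f(S_nad)
    f(S_nad) = [S_nad/(Kₘ_nad + S_nad)] / [nad_ref/(Kₘ_nad + nad_ref)]

with nad_ref = 500 µM. The normalisation makes k_cat, Kₘ_pep and Kₘ_nad
*apparent* constants, measured at a fixed saturating co-substrate — exactly
the quantities a peptide titration at fixed NAD⁺ (or an NAD⁺ titration at
fixed peptide) estimates. A titration analysed by the package's own route
therefore recovers the truth parameters directly, with no hidden conversion
between intrinsic and apparent constants.

Reference truth preset: k_cat = 0.001 min⁻¹, Kₘ_pep = 14.7 µM,
Kₘ_nad = 52.4 µM, E = 2 µM. At S_pep = 10 µM, S_nad = nad_ref this gives
v = 0.001·2·10/24.7 = 8.097×10⁻⁴ µM/min, the value unit tests pin.

### Progress-curve integration

`gen_progress_curve` integrates the rate law with substrate depletion (both
substrates consumed 1:1 with product) using a fixed-step midpoint (RK2)
scheme, h = 0.05 min. For the slow reference enzyme the curve is nearly
linear over 60 min, so integration error is far below the 2% signal noise
used in simulations; unit tests confirm the initial slope matches the
closed-form rate to 0.5%.

### Initial-rate window

The initial velocity is the slope of an ordinary regression over the longest
prefix of the converted curve in which cumulative substrate conversion stays
at or below 10% (at least 3 points). This is the standard steady-state
criterion: within the window the substrate is effectively undepleted and the
time course linear. The cap is configurable (`max_conversion`).

### Michaelis–Menten fitting

`fit_michaelis_menten` uses `scipy.optimize.curve_fit` with V₀ = max
observed v, Kₘ₀ = the concentration whose rate is nearest V₀/2, positive
bounds, and **tight tolerances (xtol = ftol = gtol = 1e-15)**. The tight
tolerances are required, not cosmetic: rates are O(10⁻³ µM/min) while Kₘ is
O(10 µM), and at default tolerances the optimiser halts early on this badly
scaled problem, biasing Kₘ by several percent even on noiseless data.
Non-convergence is flagged on the result rather than raised, so downstream
summaries can propagate it. k_cat = V/E₀; the specificity constant is
k_cat[s⁻¹]/Kₘ[M].

Titration designs follow the bench protocol: 8 two-fold dilutions from a top
of 160 µM peptide (at reference NAD⁺) or 1 mM NAD⁺ (at 10 µM peptide), with
2% multiplicative noise on rates. The acceptance route for k_cat runs the
full chain — calibration fit, signal-to-product conversion, windowed
regression — on a 60-minute progress curve with Gaussian noise of 2% of the
noiseless signal span.

## Translocation imaging

Synthetic fields model each cell as a uniform disk nucleus (radius 10 px)
with a surrounding cytoplasmic annulus (width 5 px) on a dark background
(512×512, 8-bit). The DNA channel renders nuclei at 200 against background 5;
the stain channel renders cytoplasm at 100 and the nucleus at
true_ratio × 100, plus Gaussian noise (default sd 5). Cells are placed by
rejection sampling with a minimum separation that keeps annuli disjoint and
inside the image; impossible placements raise rather than loop forever.

Analysis: nuclei are segmented by thresholding the DNA channel (fixed 40 by
default — the generator's modes are far apart — or Otsu on request) with
8-connected labelling and a 20 px minimum area. Per cell, the cytoplasm is
sampled as a binary dilation of the nucleus minus all nuclear pixels; cells
whose annulus would leave the image are excluded and logged. The
nuclear:cytoplasmic ratio uses raw (not background-subtracted) means, and
positivity requires ratio strictly greater than 1.25 — 126 vs 100 is
positive, 125 vs 100 is not. Condition summaries report mean ratio ± SEM
(sample sd/√n) and positive counts; two conditions are compared by a Welch
test.

Not emulated: optical blur, uneven illumination, nuclear texture,
non-circular or overlapping cells. The generator is a ground-truth harness
for the measurement code, not a microscope model.

## FRAP

Traces are normalised to the mean of the pre-bleach frames and fit to

    F(t) = F₀ + (F∞ − F₀)(1 − e^(−t/τ))

over the post-bleach frames only (bleach frames excluded; t = 0 at the first
recovery frame). Derived quantities: t½ = τ·ln 2 (an identity of the fit, so
it holds exactly for every converged fit) and immobile fraction
(1 − F∞)/(1 − F₀), clipped to [0, 1] with a flag when clipping occurred.
Fits with F∞ < F₀ (no recovery) are flagged unconverged. Defaults mirror the
acquisition protocol: 0.27 s frame interval, 2 pre-bleach and 2 bleach
frames, ~30 s of recovery. Group comparisons of half-times use pairwise
Welch tests with BH correction.

## Differential expression

Input is a probes × samples matrix of log₂ intensities with columns named
`<condition>_<replicate>`; a guard rejects matrices whose values look
unlogged (max ≥ 30). Per contrast, each probe gets a pooled-variance t test
with df = n₁+n₂−2 (vectorised over probes). Zero-residual-variance probes are
assigned p = 1 when the group means are equal and the smallest positive float
otherwise, and are logged. BH correction uses
`statsmodels.stats.multitest.multipletests`; an independent brute-force
step-up implementation lives in the tests as an oracle. Calls require
|FC| > 1.5 strictly and q ≤ 0.05 (raw-p mode available by flag). The signed
fold-change convention maps lfc = 1 → 2.0 and lfc = −1 → −2.0, so |FC| ≥ 1
always.

The 8-condition generator plants identical up/down blocks in two stimulated
conditions over a shared N(7, 1) probe baseline with N(0, replicate_sd)
replicate noise (default sd 0.25, triplicates). **Effect sizes matter**:
with triplicates the t statistic has only 4 degrees of freedom, so planted
log₂ effects of 1.5 (barely above the call threshold) are recovered only
~60–90% of the time — correct statistical behaviour, not an estimator
defect. Tests that assert *exact* planted-set recovery therefore plant
strong effects (log₂ ±3 to ±4, i.e. 8- to 16-fold, comparable to the most
strongly induced inflammatory genes in this biology), while the generator
default stays at threshold level to exercise the interesting regime.

## Regulatory enrichment

Over-connectivity of a query of n genes against a regulon of R genes in a
universe of N: expected E = n·R/N; ratio k/E; z standardises k by the
hypergeometric standard deviation √(n·(R/N)(1−R/N)(N−n)/(N−1)); the p-value
is the exact hypergeometric tail on the side indicated by z (upper for
z ≥ 0), via `scipy.stats.hypergeom`. Regulons with zero hypergeometric
variance (R = N) are flagged `z_defined=False`. Tables carry BH q-values
across regulators.

The bundled reference database plants 12 regulons with exact (R, k) overlaps
against a 200-gene query in a 22 651-gene universe — RelA (451, 47),
c-Rel (330, 37), NF-kB1 (200, 29), SP1 (2410, 57), RelB (41, 10) and seven
more — chosen so the full table of expected counts, ratios, z-scores and
p-values is reproduced at printed precision from first principles. The
membership draw is seeded but the statistics depend only on (N, n, R, k), so
every seed yields the same table.

PAGE scores a pathway of m measured members by z = (mean(member) − µ)·√m/σ,
with µ and σ (population sd) from the genome-wide fold-change vector and a
two-sided normal p. σ = 0 is an error; members absent from the chip are
dropped from m. Under the null (random member sets) z is standard normal,
which the tests verify by KS.

## Pipeline, seeding and problem sizes

`RunConfig` names the stages, output directory, master seed and per-stage
parameter blocks; `run_all` executes stages in order, each in its own
subdirectory, and writes `summary.json` and `report.md` stamped with the
seed and a SHA-256 config hash. Stage seeds derive from
`np.random.SeedSequence([master_seed, stage_index])` reduced below 2³¹, so
stages are independent, reproducible, and insensitive to which other stages
run. All generators take explicit seeds through `numpy.random.default_rng`.

Problem sizes are the package's own demo-scale choices: 2 000-probe
expression experiments (with 153 up / 45 down planted responders), 100-cell
imaging fields, 24 FRAP traces per group, 8-point titrations, 50-seed
medians for kinetic acceptance. They are large enough for the statistics to
be meaningful and small enough that the whole suite runs in seconds on one
CPU.

## Limitations

- Generators produce idealised data: no image blur, no probe-specific
  variance structure, no batch effects, no photobleaching during FRAP
  acquisition beyond the bleach step itself.
- The kinetics module assumes a linear calibration and a single active
  enzyme species; substrate inhibition and product inhibition are not
  modelled.
- The exponential FRAP model is a one-component approximation; diffusion-
  dominated recoveries would need a different functional form.
- Expression inference is probe-level only; no probe-to-gene summarisation
  or cross-platform normalisation is provided.
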