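# Methods

`cecflux` implements the computation and quality-control pipeline of a
plate-based, BODIPY-cholesterol HDL cholesterol efflux capacity (CEC) assay,
together with the statistics used to compare its two referencing methods.
This note records the model, the parameter choices, the numerical
conventions, and what the synthetic data can and cannot show.

## The assay computation

Each serum is measured in triplicate wells of a 96-well plate of
cAMP-stimulated J774A.1-type macrophages labelled with a fluorescent
cholesterol analogue and incubated with apoB-depleted serum (default 2%) as
acceptor. Per plate the layout must provide: ≥3 *t0 control* wells (lysed at
time zero instead of receiving acceptor), ≥3 *passive* wells (acceptor-free
medium), ≥3 *unstained background* wells, ≥1 *no-cell blank* (for the
resazurin read), four *correction controls* and two *monitoring controls*.

Processing per plate:

1. **Background.** The mean supernatant and lysate fluorescence of the
   unstained wells is subtracted from the matching read of every well.
   Backgrounds are per plate and per read type — reader gain differs
   between plates. A negative net read invalidates the well; it is never
   clamped to zero, which would bias CEC upward.
2. **Referencing.** Two statistics are computed from the net reads:

       CEC_per_well = 100 · FI_sup / (FI_sup + FI_lys)
       CEC_t0       = 100 · FI_sup / FI_t0_control

   where `FI_t0_control` is the mean of the plate's t0 wells (mean, not
   median, to match the CV-based triplicate QC used elsewhere). t0 values
   above 100% are retained but flagged. Both statistics are exactly
   invariant to a common multiplicative gain on all of a plate's reads.
3. **Passive subtraction.** The mean raw CEC of the passive wells (under
   the matching method) is subtracted from every sample well's raw CEC.
   Negative results are retained and flagged. Passive subtraction applied
   per replicate or per sample mean gives identical sample means; both are
   exported.
4. **Resazurin.** The 570/600 nm absorbance ratio minus the no-cell blank
   ratio is a per-well proxy for viable cell number. It is used for
   monitoring and for the seeding-bias regression; `normalize_to_resazurin`
   (CEC divided by the well's relative ratio) is provided only for the
   normalisation comparison — on simulated standard runs it *increases*
   the per-well method's interassay CV, because that method already
   self-references each well's cell content and the normalisation adds
   independent read noise.

## Replicate QC, plate correction, performance metrics

* A sample is **rejected** when the CV of its replicate CECs is strictly
  greater than 15% (the rule is stated as ">15%", so CV = 15.0 is kept), or
  when fewer than 3 valid wells remain. The CV is computed on raw
  (pre-passive) CEC: subtracting passive efflux shifts means toward zero
  and would blow up the CV of perfectly reproducible wells. This is
  switchable (`QCConfig.cv_on_raw`).
* **Intra-assay CV** is the mean replicate CV of retained study samples;
  **interassay CV** is `100·sd/mean` of a monitoring control's per-plate
  CEC across plates. All SDs use the *n−1* denominator. Rates and CVs are
  reported to 2 decimals, relative reductions to whole percent, both
  rounded half-up (the convention under which the published performance
  table's derived cells reproduce exactly).
* **Plate correction.** For each plate, the relative difference
  `(expected−observed)/expected` of the four correction controls is
  averaged; the factor `1 + mean(observed/expected − 1)` divides every CEC
  on the plate. The correction is multiplicative — the additive/
  multiplicative choice is not fixed by the assay description, and the
  multiplicative form preserves positivity and the percent-of-total scale,
  and removes a multiplicative plate effect *exactly* (a property test
  asserts machine-precision recovery). "Expected" values default to the
  control's mean across all plates of the run (two-pass); externally
  supplied reference values are accepted. If a control is rejected the
  factor uses the remaining ≥3 controls with a warning; with <3 the plate
  stays uncorrected and flagged. Interassay CV series use only plates
  where the monitoring control itself survived replicate QC.

## Agreement statistics

* **Bland-Altman**: bias = mean of paired differences, limits of agreement
  = bias ± 2·SD (multiplier exactly 2, not 1.96, matching the convention
  of the assay literature this package follows).
* **Michaelis-Menten saturation fit** `CEC = vmax·A/(km+A)`:
  trust-region-reflective least squares with non-negativity bounds;
  deterministic initialisation (vmax₀ = max CEC, km₀ = acceptor level at
  half-max by linear interpolation); ftol 1e-8 on the relative cost
  change, xtol 1e-12 (so exactly-fitting data terminate on step size),
  ≤500 function evaluations. A km estimate below 1e-4 of the largest
  acceptor level is flagged as a boundary solution (fully saturated data).
  Tests check parameter recovery from noise-free points to ≤1e-6 and
  agreement with an independent 200×200 grid-search oracle.
* **Seeding-bias regression**: ordinary least squares of per-well CEC on
  the z-scored resazurin net ratio with a fixed intercept per serum and
  one common slope. A mixed model would match the field's habit, but with
  ~5 sera in triplicate the random-effect variance is weakly identified;
  the estimand (common slope per 1 SD of the cell proxy) is unchanged. The
  z-scoring SD is taken over all analysed wells, making the slope
  invariant to constant shifts of the ratio. 95% CI from the t
  distribution on the residual df.
* **cAMP contrast**: Welch difference of condition means with a
  Satterthwaite-df CI.

## Synthetic plate generator

The generator emulates the assay's error structure so that every pipeline
stage, and every directional claim about the two methods, is testable
without wet-lab data. Per well:

* cell count ~ mean-one lognormal around 7×10⁴ cells × a deliberate
  seeding multiplier (lognormal rather than normal: positive counts,
  degeneracy-free at 30% CV);
* total label = `stain_per_cell` × cells × lognormal stain noise;
* efflux fraction `f = passive + e_p·shift·camp·(emax/100)·A/(km·c + A)`
  with `c` the cell count relative to standard: the half-saturation point
  scales with relative cell number, so the *acceptor:cell ratio* drives
  the cell-number bias. This functional form is a modelling convenience —
  the link between cell number and efflux is not specified by the assay
  description; it is the simplest form that reproduces the observed
  opposite-sign biases of the two methods without inventing new biology;
* reads: `sup = g_p·f·T·ε + b`, `lys = g_p·(1−f)·T·(1−r)·ε + b`,
  t0 wells `g_p·τ_p·T·(1−r)·ε + b`, with per-plate gain `g_p` (cancels in
  both methods), per-plate active-efflux effect `e_p`, per-plate
  t0-reference factor `τ_p`, lysis residual `r`, per-read lognormal noise
  `ε`, and background `b` added after the gain; unstained wells draw from
  the same background distribution;
* resazurin ratio = blank + 2×10⁻⁵ × live cells (t0 wells count as dead),
  realised as a constant-A600/proportional-A570 grid pair.

Two heavy-tailed handling-error processes give replicate QC something to
reject: a **well disturbance** (4% of wells, lognormal σ-scale 0.35) that
rescales a well's cell layer — it cancels in the per-well statistic but
propagates fully into the t0 statistic, which is the mechanistic reason the
per-well method rejects fewer samples — and a **read disturbance** (1.5%
of single fluorescence reads, scale 0.2) that hits both methods.

One global RNG stream with a documented, parameter-independent draw order
makes output bit-identical for a given configuration and seed.

### Default conditions

Fixed by the assay protocol: 7×10⁴ cells/well, 2% acceptor, triplicates,
lysis residual 2.4% (cholic acid; 6.1% models sodium hydroxide), 15% CV
rejection threshold, 4 correction + 2 monitoring controls, 25-plate runs.
Chosen once as realistic for a routine run and not revisited: seeding CV 3%
(0.30 reproduces the deliberate-error experiment), stain CV 2%, read noise
3.5% (sized so that per-well replicate CV lands in the 3–7% band reported
for such assays), plate gain SD 10%, plate active-efflux effect 10% (sized
from the gap between published intra- and interassay CVs), t0-reference
factor 8% (the per-plate surrogate error that makes the t0 method's
interassay CV larger), emax 18% CEC with km = 1% serum (typical CEC of
8–16% at 2% acceptor), passive fraction 4%, background 30 units,
between-donor emax CV 15%. The repeat-measurement experiment scales the
second occasion's active efflux by 0.8 — a day/batch drift of the size
implied by the published uncorrected between-day bias — so that the plate
correction has a real systematic shift to absorb.

### Problem sizes

The packaged in-silico experiments use 25 plates × 22 study sera (550
samples) for the method comparison, 28 sera measured on two occasions (2
plates each) for repeat-measurement agreement, 5 sera × 4 cell amounts ×
triplicate for the seeding-bias design, a 5-level acceptor titration for
the saturation fit, and 5 sera × 2 conditions for the cAMP contrast. These
are the package's own scaled-down designs; all complete in seconds.

### What the simulation does and does not show

Passing directional tests show that the pipeline's arithmetic interacts
with a plausible error structure the way the real assay's does: the
per-well method rejects fewer samples and has a lower interassay CV, plate
correction lowers interassay CV and between-day bias, seeding error biases
the two methods in opposite directions, and a weaker lysis raises per-well
CEC. They do **not** reproduce the real study's absolute effect sizes
(rejection rates, CV magnitudes, slope values), which depend on laboratory
practice, and the generator contains no kinetics, no cholesterol-mass
accounting, no plate-position (edge) effects, and no lysis chemistry
beyond a single residual-label fraction.

## Degenerate inputs and tie-breaks

Missing wells stay missing (never zero). Zero total fluorescence, a
non-positive t0 reference, or a missing read invalidates the affected
scope (well or plate) with a named reason. Rejection uses strict `>`;
`QCConfig.strict_boundary=False` switches to `>=`. Correction factors ≤0
leave the plate uncorrected. Grid CSVs render floats with Python's
shortest round-trip `repr`, making write→read bit-exact.

## Known limitations

* The fixed-effects seeding-bias model understates between-serum slope
  heterogeneity relative to a mixed model.
* Whether the real protocol's intra-assay CV averages corrected or
  uncorrected values is not specified; uncorrected is used (correction
  acts at plate level and cancels within a plate).
* Single t0 outlier wells are never dropped; the t0 reference is always
  the mean of all t0 wells.
* The vendor's native export format is not parsed; grids use the neutral
  CSV dialect documented in `plate_io`.
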