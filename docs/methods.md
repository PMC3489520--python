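# Methods

This note documents the models, estimators, defaults and decision bands in
`telqpcr`: what is computed, under which assumptions, and what the synthetic
data used to validate it does and does not represent.

## 1. Amplification model (simulator)

Each simulated reaction follows a logistic-depletion recurrence with a
sharpness exponent:

    A(c+1) = A(c) · (1 + (E − 1) · (1 − (A(c)/P)^h)),   A(0) = N0
    F(c)   = b + A(c) + ε,   ε ~ N(0, σ_read)

with plateau `P`, per-well baseline `b ~ N(level, σ_b)` and i.i.d. read
noise. `h = 1` is the textbook logistic; the default `h = 4` keeps growth
log-linear until shortly below the plateau, which is what SYBR-green
chemistry does (reagent depletion is late-onset — real amplification curves
are log-linear over roughly two decades of signal). With `h = 1` every
window-of-linearity fit is biased low even on noiseless data, because the
damping term bends the log curve throughout the observable range; `h = 4`
makes noiseless plates an essentially exact oracle for the estimators.

Efficiency loss at high template input — the signature of an overloaded
reaction — is modelled separately and explicitly as a linear reduction of
the effective efficiency per ng of template (`efficiency_decay`, optionally
different for the reference target).

### Starting amounts and noise structure

* Standards: a 72 → 4.5 ng two-fold five-step dilution series in triplicate
  per target and batch; `N0` proportional to input amount
  (`tel_n0_per_ng = 1.2e−5` fluorescence-equivalents/ng, an arbitrary
  optics scale).
* Reference reactions lag the telomere reactions by `ref_cq_offset = 17`
  cycles (single-copy gene vs an abundant repeat; the observed lag in this
  kind of assay is 15–20 cycles).
* Unknowns: 60 samples at 20 ng input, each with a true T/S drawn uniformly
  from 0.45–2.9 and identical in every batch.
* Per-well Cq jitter has two parts: an independent component
  (`cq_sd = 0.08` cycles) and a template-amount component shared by both
  targets of a replicate (`cq_shared_sd = 0.09` two-fold cycles). The
  shared part models multiplexing: T and S are measured in one tube, so
  pipetting error is common to both and cancels in the ratio. Per-target
  triplicate Cq SD totals ≈ 0.12 — the precision of a well-optimized assay
  — while the replicate T/S CV stays near 10%, which is the only way those
  two observations can coexist. The singleplex presets set the shared part
  to zero.
* Read noise defaults to 1% of the plateau (`σ_read = 1`, `P = 100`) —
  a deliberately hard optics regime that leaves only ~5 clean log-linear
  cycles per trace.
* NTCs contain no template. With `ntc_dimer` set, reference-target NTCs
  amplify a primer-dimer product (default apparent Cq 28) whose melt peak
  sits at 87 °C instead of the 80 °C product peak.
* Melt curves are sums of logistic drops; the negative derivative peaks at
  the requested melting temperatures. No thermodynamics is modelled.
* Determinism: every well draws from a substream keyed by the well's
  semantic identity (batch, role, target, sample, replicate), so changing
  the plate composition does not reshuffle unrelated wells, and identical
  configurations are byte-identical.

What the simulator does **not** emulate: inter-well optical crosstalk,
plate edge effects, DNA degradation over batches, melt-curve
thermodynamics, pipetting robots, or instrument-specific export formats.
Passing tests on synthetic plates therefore validate the estimators and the
QC logic, not any particular instrument's quirks.

### Assay presets

* `clean_assay_config` — the defaults: a well-optimized multiplex assay
  (telomere E 2.0, reference 1.9, batch-stable, no decay).
* `decaying_efficiency_config` — efficiency falls with template amount
  (−0.0012 E/ng telomere, −0.0004 reference: ~8 efficiency points across
  the series), with quieter optics but poorer replicate precision
  (Cq SD 0.33, fully independent — a singleplex assay on another platform).
* `inhibited_reference_config` — a badly multiplexed assay: reference
  efficiency 1.45 and batch-variable (SD 0.08), primer-dimer NTC signal
  crossing well before the sluggish reference standards.

## 2. Trace processing

**Noise scale.** Robust SD from first differences of the first 14 cycles:
the median absolute deviation backstopped by a 70th-percentile scale (the
MAD of so few differences occasionally collapses by chance, which would
wreck every downstream threshold; the backstop is consistent for Gaussian
noise and errs upward, the benign direction).

**Baseline, strict mode.** The flat pre-onset segment (cycles up to three
before the first sustained excursion above 5 noise SD) is averaged; that
anchor is then refined within ±2 standard errors by maximizing the
straightness of a fixed candidate exponential region — the line is fitted
to the region's upper half (insensitive to the constant) and scored by its
misfit to the lower points (maximally sensitive). Two details matter and
are deliberate: the candidate region is frozen before the search, because
an objective that can move points in and out of the region games itself;
and whole-region R² or residual-SS objectives are degenerate at the two
ends of the search (over-subtraction inflates R² through the total
variance; under-subtraction deflates the residual SS by compressing the log
curve), which the split objective avoids. Corrected readings ≤ 0 are
masked, never clamped. A trace whose total span is under 10 noise SD, or
with fewer than 4 points above the floor, is unusable (baseline = minimum
reading). `min` mode simply subtracts the minimum reading.

**Window of linearity.** Eligible cycles lie above the noise floor
(2 noise SD) and strictly below the cycle where the trace first exceeds 90%
of its own maximum; for visibly plateaued traces the cap tightens to 50% of
the maximum, because growth above that is already slowed by depletion. A
common 5-cycle window per batch-and-target group is placed to cover the
most traces with the highest mean log10 R²; any trace the common window
fits worse than R² = 0.998 receives an individual window of width 4–6
maximizing its own R², constrained to overlap the common window by ≥ 2
cycles (an *adjustment*, not a relocation — windows that drift from the
threshold region extrapolate the Cq and inflate its error), with an
unconstrained fallback for wells amplifying many cycles late. Searched
windows must also reach the geometric midpoint between floor and maximum,
which stops baseline-noise segments from posing as windows with spuriously
perfect R².

**Efficiency, Cq, N0.** `E = 10^slope` of the window regression; the
fractional `Cq = (log10 Nt − intercept)/slope`; `N0 = Nt/E_batch^Cq`, with
`E_batch` the iteratively trimmed batch mean efficiency (values deviating
more than 5% from the running mean are dropped one at a time, worst first).
The threshold `Nt` is chosen per target as the geometric mean of the
corrected signal at the common window's endpoints in the first batch, then
frozen for all batches; all logs are base 10, cycles are 1-based, windows
inclusive.

**Melt peaks.** Local maxima of −dF/dT above 10% of the global maximum
(with a flatness guard); a peak more than 2 °C from the product peak raises
the primer-dimer flag.

## 3. Quantification

Four methods produce per-replicate T/S, aggregated per sample as mean,
sample SD (n−1) and CV%:

| method | baseline | efficiency | amount rule |
|---|---|---|---|
| `pfaffl_lr` | strict | `10^(−1/slope)` of the Cq standard curve | `E^(Cq_cal − Cq)` |
| `pfaffl_rg` | min-fluorescence | same | same |
| `ruijter` | strict | per-reaction (window fit), trimmed batch mean for N0 | `10^((log10 N0 − b)/a)` |
| `ddcq` | strict | fixed at 2 for both targets | `2^(−ΔΔCq)` |

The calibrator is a standard dilution step present in every batch (default:
the middle step; configurable). Under Pfaffl, the ratio of two samples' T/S
is invariant to that choice. The published form `T = 10^(b−y)/a` of the
Pfaffl rule is sign-inconsistent with its own `E^(Cq_cal−Cq)` statement;
the `E^ΔCq` form is implemented (equivalently `10^((y−b)/a)` with the
calibrator at log amount 0).

Standard curves are fitted per batch, target and response (mean Cq or mean
log10 N0 per step) by OLS; the **linear dynamic range** is the widest
contiguous run of ≥ 3 steps whose own fit reaches R² ≥ 0.985 with max
|residual| ≤ 0.5 Cq (ties: longer run, then the lower-concentration end),
and the reported curve is refitted inside it.

## 4. Outlier filtering

A replicate is excluded when (i) its interpolated amount falls outside the
standard curve's linear dynamic range, or (ii) it is the Grubbs outlier
(two-sided p < 1%) of the sample's pooled per-target Cq set across batches,
or (iii) of the sample's pooled T/S set. Stragglers (1–5%) are flagged and
kept. The Grubbs p-value inverts the classical t-based critical value
`G_crit = ((n−1)/√n)·√(t²/(n−2+t²))`, `t = t_{α/(2n), n−2}`; only the
single largest G is eligible for the outlier class per pass.

Two deliberate choices here:

* **Scope.** Exclusion-grade tests run on the pooled per-sample sets
  (n = replicates × batches), not on single triplicates. At n = 3 the
  maximum attainable G (1.1547) sits a hair above the 1% critical value
  (1.15468), so the triplicate test can only fire on near-coincidence
  patterns (two values equal to ~1e−4 and one ordinary) — freak events it
  then "detects" at roughly the nominal 1% rate, eroding clean data without
  catching anything real. Triplicate-level results are kept as a reported
  straggler flag.
* **Log scale for T/S.** Replicate noise in a ratio of exponentials is
  multiplicative; a Gaussian test on the raw right-skewed ratios over-flags
  the upper tail. Cq tests stay on the natural additive scale.

Even so, any exact-level 1% test applied to ~180 clean sets is *expected*
to make about one call per study — that is what a 1% band means — so
occasional exclusion of a genuinely clean replicate is a property of the
published rule, not a defect of the implementation.

## 5. QC metrics and scorecard bands

Per target (Cq-based curves, strict baseline): LDR step coverage; NTC ΔCq
(mean NTC Cq minus mean most-diluted-standard Cq) with verdicts ok
(≥ 10 cycles), overlap (≤ 0), borderline (between), and overlap downgraded
to *dimer-explained* when the NTC melt peak sits away from the product
peak; mean and between-batch SD of the trimmed batch efficiencies;
efficiency-vs-log-amount regression (slope-zero p); mean triplicate Cq SD;
OLS of observed on expected log amounts (R², slope, t-test against slope
1); per-step CV% of per-batch mean observed log amounts across batches
(robustness; computed on log amounts, statistically odd but conventional);
adjacent-dilution two-sample t-tests, pooled variance by default (Welch
selectable), with the zero-variance conventions p = 1 (equal means) and
p = 0 (unequal).

T/S level (primary method): mean replicate CV; constancy of the standards'
T/S across dilution steps (step means pooled over batches, normalized by
the grand mean so calibrator noise is not mistaken for inaccuracy);
excluded-replicate fraction; dMinMax = max − min of the sample means,
average SD, and SD/dMinMax%; minimum pairwise inter-method R² (squared
Pearson, %).

Verdict bands (documented here, applied as pure functions of the metrics):

| criterion | best | intermediate | worst |
|---|---|---|---|
| LDR coverage | all steps | partial | none |
| NTC | ok / dimer-explained | borderline | overlap |
| magnitude E | ≥ 1.80 | 1.60–1.80 | < 1.60 |
| interbatch E SD | ≤ 0.05 | — | > 0.05 ("variable") |
| dilution E | p ≥ 0.05 | — | p < 0.05 ("variable") |
| Cq SD | ≤ 0.25 | 0.25–0.45 | > 0.45 |
| accuracy \|slope−1\| | ≤ 0.03 | 0.03–0.08 | > 0.08 |
| resolution (target) | all pairs p<0.05 | ≥ 2/3 | fewer |
| T/S CV % | ≤ 15 | 15–30 | > 30 |
| standards T/S dev | ≤ 0.10 | 0.10–0.25 | > 0.25 |
| outlier fraction | ≤ 5% | — | > 5% ("many") |
| SD/dMinMax % | ≤ 10 | 10–16 | > 16 |
| inter-method R² % | ≥ 85 | 60–85 | < 60 |

The Cq-SD and SD/dMinMax cuts are calibrated to the published per-category
exemplars of this assay family (triplicate Cq SDs of 0.12–0.2 rated high
vs 0.4+ rated low; resolution indices of 5–6% rated high vs 11–12%
intermediate and 17%+ low); the rest are round numbers chosen once. The
overall verdict is the worst band present, except that a dimer-explained
NTC overlap does not count against the assay (dimer signal does not bias
T/S). Identical metrics always give identical verdicts.

## 6. Numerical and degenerate-input choices

* OLS is the closed-form two-parameter fit; R² of a zero-variance response
  is 1 when residuals are zero, else 0.
* Grubbs with n < 3 or SD = 0 performs no test (everything kept).
* Undefined Cq (threshold above the trace maximum, below the noise floor,
  or crossing outside cycles 1..C) is a NaN flag, never an exception;
  arithmetic on it yields undefined amounts that aggregation skips.
* NTC groups with no defined Cq are automatically "ok".
* Baseline grids: 80-point coarse + 80-point refinement (full-range
  searches), 41 + 41 within the anchored ±2 SEM interval.

## 7. Problem sizes used in validation

The packaged checks run a full-size synthetic study — 4 batches × (2
targets × (5 dilution steps + 1 NTC) × 3 replicates + 60 unknowns × 2
targets × 3 replicates) ≈ 1,600 wells — for recovery and filter metrics,
one-batch noiseless plates for the analytic identities, 10,000 simulated
sets for the Grubbs null rate, and two- to three-batch plates for the
degraded-assay contrasts. On one CPU the whole test suite runs in about a
minute and the acceptance script in well under one.

## 8. Known limitations

* The strict baseline needs a flat pre-onset segment; reactions crossing
  threshold before ~cycle 8 fall back to a weaker full-range search.
* Per-well efficiency estimates carry 2–8% scatter at the default
  (hard) optics regime; only batch means are reliable to within ~1%.
* The between-batch efficiency SD includes estimator variance (mainly
  common-window placement), so with few batches a clean assay can tip over
  the 0.05 "constant" band.
* The comparative-Cq method inherits its fixed-E=2 assumption; its T/S is
  biased whenever true efficiencies differ from 2 (visible in the
  inhibited-reference preset, where it diverges from the curve-based
  methods — informative, and reported via the inter-method R²).
* Multi-reference-gene normalization, absolute telomere length, and vendor
  export parsers are out of scope.
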