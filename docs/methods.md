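# Methods

## Problem and data

Infants receive 50 mg/kg of ¹⁵N-thymidine by mouth once daily for five
days to label cells in S-phase. Uptake and elimination of the label are
monitored through urine: spontaneous voids are collected from diapers,
dried, and measured by elemental-analyzer isotope ratio mass spectrometry
(IRMS). The analysis question is kinetic: how high does urinary ¹⁵N
enrichment rise after a dose, when does it peak, and for how long does it
stay above the 0.37 % natural-abundance baseline — and whether two
clinical groups (tetralogy of Fallot labeled mostly at home; heart
failure labeled in hospital) differ in these read-outs.

## Isotope arithmetic

All measurements are carried simultaneously as δ¹⁵N (‰ vs air), isotope
ratio R = ¹⁵N/¹⁴N, and atom percent, related by

    R = R_AIR · (1 + δ/1000),    atom% = 100 · R / (1 + R)

with R_AIR = 0.003676. The rounded reciprocal convention ¹⁴N/¹⁵N = 272.0
differs from 1/R_AIR in the fourth significant figure; both are stored,
but R_AIR is authoritative for δ conversions and 272.0 is used only where
the conventional 0.0037 (0.37 %) natural-abundance figure is reproduced.
Conversions are exact and mutually consistent to relative 1e-12; domain
violations (δ ≤ −1000 ‰, atom% outside (0, 100)) raise a typed error.

Two IRMS data-reduction steps are provided:

- **Two-point normalization**: the unique affine map carrying the two
  calibration standards' measured δ onto their known δ, applied to all
  sample measurements. Degenerate (equal-known-value) standards raise.
- **Blank correction**: the size-series model δ_meas = δ_true + c/m
  (mass m in mg), fitted by OLS on the 1/mass regressor. This is the
  standard EA-IRMS small-sample blank model: a constant blank
  contribution displaces small samples more than large ones. The
  estimated ĉ/m is subtracted from each sample. Blank correction is
  applied before scale normalization by default; the order is a
  configuration choice, not a claim about any particular laboratory's
  sequence.

Control materials (glycine, peptone) are summarized per batch as mean ±
sample SD with n; a batch is flagged when its mean deviates from the
material's registered nominal by more than 3·sd/√n (a standard control
limit).

## Ingest and time normalization

Dose logs, void logs, IRMS results, and cohort metadata arrive as four
CSVs. Collection times exist in two sources: specimen-bag annotations
(minute resolution) and paper logs (rounded to the hour by caregivers).
When both are present and disagree, the minute-resolution bag time wins
and the sample is marked `reconciled`; hour-only entries are read as the
top of the hour (deterministic, no imputation). Voids timestamped before
the patient's study start (midnight of the first dose day) are physically
impossible records and are dropped with a logged reason. All timestamps
are time-zone-naive at minute resolution.

Inclusion proceeds in two stages. *Analyzable* patients have recorded
dose times and at least one timed sample; *fit-eligible* patients
additionally have at least `min_samples_for_fit` (default 9) normalized
samples. Each exclusion carries a machine-readable reason code
(`missing_times`, `no_samples`, `insufficient_samples_for_fit`, …). The
default of 9 sits between observed per-patient counts of 8 (excluded from
fitting in the reference cohort) and 13 (fitted); it is exposed as
configuration because the reference cohort itself is not perfectly
consistent on this boundary.

Each sample is then re-indexed to hours since the most recent preceding
dose (a sample exactly at a dose time belongs to that dose at 0 h).
Pre-first-dose samples go to a baseline pool; samples more than
`window_hours` (default 24, the collection protocol's stop point) after
their dose are dropped with a logged reason. Overlaying up to five
dose-relative datasets per patient multiplies the effective data density
for curve fitting.

## Enrichment kinetics

Per patient, all in-window normalized samples are pooled and fitted by
ordinary least squares with a **centered polynomial**: regressors
(t − t̄)ᵏ, k = 0…d. Centering removes the near-collinearity of raw
powers on a 0–24 h support; fitted values are invariant to the centering
choice. The default degree is 3 for every patient — one common model
across patients rather than a per-patient winner — with `select_degree`
available to reproduce the degree-selection analysis: it returns the
smallest degree whose successor improves R² by less than
`plateau_epsilon` (default 0.01), alongside the full R²-per-degree table.
Note the plateau rule is literal: data whose even orders contribute
nothing (a purely odd cubic) plateau at degree 1.

The **confidence band** is the pointwise band of the fitted mean,
ŷ(t) ± t_{(1+γ)/2, n−d−1} · SE(ŷ(t)), with SE from the coefficient
covariance s²(XᵀX)⁻¹ and the centered basis at t. A fixed ±2·SE variant
(the "mean ± 2 SD" presentation style of common curve-fitting software)
is available via `band_method="2se"`; the t-quantile is the default
because it yields genuine 95 % coverage at small residual degrees of
freedom.

**Extrema** are located from the real roots of the fitted polynomial's
first derivative inside the observed support [0, min(window, max t)],
classified against the endpoint values; the search never leaves the
support because cubic tails outside the data are artifacts. For a cubic
the derivative is quadratic, so at most two interior candidates exist;
complex roots fall back to the endpoints.

The **labeling period** is the duration over which the lower confidence
band exceeds the 0.37 % baseline: start at 0 h if the band is already
above, else at the first upcrossing; end at the first subsequent
downcrossing, or at the time of minimum fitted enrichment if the band
stays above throughout the window. Crossings are bracketed on a 0.01 h
grid and bisected to 1e-3 h on the continuous band, so the statistic is
grid-resolution independent. A band entirely below baseline yields 0
with a flag. One known corner: if the band never crosses and the fitted
minimum sits at 0 h, the statistic collapses to 0, so it is not globally
monotone in baseline or amplitude — only in the regime where the band
actually crosses (which is the regime the statistic was designed for).

## Group statistics

Between-group comparisons use Welch's unpaired t-test, computed from
group summaries (mean, SEM, n):

    t = (m₁ − m₂)/√(s₁² + s₂²),
    df = (s₁² + s₂²)² / (s₁⁴/(n₁−1) + s₂⁴/(n₂−1))

two-tailed, α = 0.05, no multiple-testing correction. The raw-value form
is exactly the summary form applied to (mean, sd/√n, n). Administration
setting (home/hospital) versus group is tested by the two-sided Fisher
exact test under the point-probability-sum rule (every table with point
probability ≤ the observed one, fixed margins). Enrichment levels are
also expressed as fold changes over the 0.37 % baseline, reported to one
decimal. p-values are held at full precision internally and rounded to
three decimals only in reports. A caveat for recomputation from printed
summaries: third-decimal agreement with p-values originally computed
from unrounded raw data is not generally achievable, because rounding
the inputs to three decimals perturbs p at that digit.

## Synthetic cohort generator

The generator defines the conditions under which the pipeline is tested.
Enrichment follows a Bateman superposition (one-compartment, first-order
absorption and elimination per oral dose); with defaults ka = 0.30 /h,
ke = 0.07 /h the analytic single-dose peak is ln(ka/ke)/(ka − ke) ≈
6.33 h, in the observed 6–7 h range, and amplitude 2.5 %·dose⁻¹ puts the
fitted peak near 2 %. These defaults are calibration targets for
recovery tests, not estimates of in vivo rate constants — the true
absorption/elimination constants are not identifiable from urine spot
sampling alone. Doses get Gaussian jitter (sd 0.5 h) around the 24 h
schedule. Voids are a gamma renewal process (shape 2, mean 2 h,
truncated at 15 min); each void is lost with probability 0.7 (dried or
missed cotton balls), which yields ≈ 18–19 collected samples per patient
over the 120 h window — the observed collection yield given that infants
void far more often than diapers are harvested. Urine enrichment is
equated to the plasma-driven excretion curve; an optional fixed
ascertainment lag (default 0 h) models collection delay. Measurement
noise is Gaussian (sd 0.1 atom %).

What the generator does *not* emulate: renal maturation, thymidine
salvage or first-pass metabolism, hydration-dependent urine
concentration, caregiver transcription errors, or inter-patient kinetic
heterogeneity beyond the configured group offsets. Passing recovery
tests therefore demonstrates that the fitting pipeline measures what the
sawtooth model produces at realistic sampling density and noise — not
that the Bateman model is the true physiology.

Every stochastic operation takes an explicit seed (or Generator); there
is no hidden global state, and identical seeds reproduce byte-identical
log files.

## Problem sizes in tests and acceptance

The Monte-Carlo checks use 500 replicates for band coverage, 100 seeded
patients for time-to-peak recovery (±1.5 h of the analytic maximum for
≥ 80 %), 200 null cohorts (5 + 5 patients) for the type-I error of the
peak-enrichment comparison, and 3 amplitude levels × 50 seeds for
labeling-period monotonicity. These sizes give binomial standard errors
of ~1–3 percentage points on the checked rates while keeping the whole
suite under ten seconds.

## Known limitations

- The cubic is a descriptive model; its extrema and band crossings are
  statistics of the fit, not mechanistic quantities.
- The labeling-period fallback (end at the fitted minimum when the band
  never crosses) is discontinuous in the band's position, as described
  above.
- Degree selection by R² plateau ignores model parsimony beyond the
  plateau threshold; it reproduces the reference analysis rather than,
  say, AIC-based selection.
- Hour-resolution log times are taken as the top of the hour, which can
  bias dose-relative times by up to 30 min for log-only samples.
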