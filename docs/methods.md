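# Methods

## Scope and data model

The package analyses single-dose 2×2 crossover absolute-bioavailability
studies: each subject receives an oral test dose and an IV infusion
reference in randomized order. Concentrations are plasma values in ng/mL at
actual sampling times in hours; doses are mg. All computation uses actual
times; nominal times are kept only for summary displays. Samples below the
assay's lower limit of quantification (LLOQ) are stored as 0 with a BLQ
flag, and a quantifiable oral pre-dose concentration is rejected as a
carryover violation rather than silently analysed.

A quantifiable concentration sandwiched between late BLQ samples is treated
like any other quantifiable point; no rule in the data model suppresses it.

## Non-compartmental analysis

**Trapezoidal rule.** The default policy is linear-up/log-down: the
logarithmic rule `Δt·(C1−C2)/ln(C1/C2)` applies only between two strictly
positive, strictly declining concentrations; rising, flat and zero-touching
segments use the arithmetic chord. This is the common industry reading of a
"linear/log" AUC method; a pure-linear policy is available for sensitivity
analyses. Zero concentrations interior to a profile therefore always get
the linear rule, which is forced mathematically (the log rule is undefined
at 0) and consistent with BLQ-as-zero handling. On strictly declining
positive segments the log-down rule never exceeds the linear rule (the
chord lies above the exponential), a property the tests assert.

**Terminal phase.** λz comes from ordinary least squares of ln C on t. The
selection of regression points is not dictated by the study conventions we
follow, so the package uses an automatic best-fit search: contiguous
windows of quantifiable points ending at the last quantifiable sample and
starting strictly after Tmax (Tmax itself excluded, configurable), choosing
the window that maximizes adjusted r² with at least three points; ties go
to the longer window. A per-profile manual window override exists for
audit-driven re-analysis, and every chosen window is written to the run
log. The phase is *well characterized* only if n ≥ 3, r² ≥ 0.9 and — once
AUC_inf is available — the extrapolated fraction is ≤ 20%; boundary values
(r² = 0.9, extrapolation = 20%) are accepted. Parameters that depend on the
terminal phase (AUC_inf, t½, CL, Vz, Vss, MRT) are withheld otherwise,
with a reason string propagated into the output table.

**Extrapolation.** `AUC_inf = AUC_last + C_last_pred/kel`, where
`C_last_pred` is the regression prediction at the last quantifiable time —
not the observed value — which shrinks the influence of a noisy final
sample.

**Steady-state volume.** The IV summary includes Vss even though no
formula is fixed by convention for it in this design; we compute
`MRT = AUMC_inf/AUC_inf − T_I/2` with AUMC by the same trapezoidal policy
applied to t·C(t), tail `c_pred·t_last/kel + c_pred/kel²`, and
`Vss = CL·MRT`. The `T_I/2` term corrects the mean residence time for the
finite 1.25 h constant-rate infusion.

**Units.** `CL = Dose/AUC_inf` converts mg→ng and mL→L internally, so 50 mg
over 5148 ng·h/mL yields 9.713 L/h with no user-side conversion.

## Descriptive summaries

Exposures, clearances and volumes are reported as geometric mean with
geometric CV% `100·√(exp(s²)−1)`, with `s` the **sample** (n−1) SD of the
logs — the conventional denominator in pharma reporting, chosen here
explicitly since either denominator is defensible. Tmax is median (range);
t½ is arithmetic mean ± SD. Dose normalization multiplies AUCs and Cmax by
`reference/administered` dose; it commutes with the geometric mean, which
ties the dose-normalized AUC row to the clearance row exactly. Report
rendering rounds to 4 significant figures; full precision is retained
internally.

## Crossover bioavailability

The mixed model has fixed effects for sequence, period and treatment (each
coded ±1/2, so the intercept is the grand adjusted mean and adjusted
treatment means weight both sequences and periods equally) and a random
subject intercept, fitted by REML through statsmodels MixedLM. The fit is
polished with a tight-tolerance BFGS pass so that on complete balanced data
it reproduces the classical crossover ANOVA (treatment effect = half the
difference between sequences of mean within-subject period differences) to
machine precision; a derivative-free fallback handles boundary cases where
the between-subject variance estimate collapses.

Degrees of freedom for the CI are the within-subject residual df
`n_obs − n_subjects − 2`, which equals the classical `n − 2` for complete
data and remains the natural containment df for the incomplete case; for
this random-intercept design it coincides with the Satterthwaite value at
the balanced design. Subjects observed in only one period are retained (the
model uses their between-subject information); a strict complete-case mode
turns any missing endpoint into an error instead. α defaults to 0.10
(two-sided 90% CI) and is configurable. σ_w is reported as √(residual
variance).

## Hepatic extraction

`E_h = CL_plasma·R_b/p/Q_h` with defaults `R_b/p = 0.985` and
`Q_h = 90 L/h` (typical 70 kg adult). An allometric mode scales `Q_h` by
`(weight/70)^0.75` when body weights are available; neither mode is claimed
to be the source of any particular published summary value, and the fixed
default is primary. Values are clipped at 1 with a warning if blood
clearance exceeds blood flow. Classification uses the conventional
boundaries: low < 0.30, high > 0.70.

## Design calculation

For a balanced crossover with `n` subjects the 90% CI half-width on the log
scale is `t(1−α/2, df)·S·√(2/n)` with `df = n−2`. Since
`df·S²/σ_w² ~ χ²(df)`, the half-width achieved with probability `p` is
`t·σ_w·√(2/n)·√(χ²_p,df/df)`; `coverage_of_halfwidth` is the exact inverse
and a Monte-Carlo simulator cross-checks both. The `√(2/n)` SE factor is
the within-subject treatment comparison: each treatment mean uses n
observations and the subject effects cancel in the difference, leaving
variance `2σ_w²/n`.

## Synthetic data generator

The generator emulates a healthy-volunteer crossover of a slowly
eliminated oral kinase inhibitor: 100 mg oral vs 50 mg IV infused over
1.25 h, oral sampling {0, 0.5, 1, 1.5, 2, 4, 6, 12, 24, 48, 72, 96, 120,
144} h, IV sampling {0, 0.75, 1.25, 1.5, 2, 3, 4, 6, 12, 24, 48, 72, 96,
120, 144} h, LLOQ 2.50 ng/mL.

Disposition is closed-form. The default is two-compartment (typical CL
9.713 L/h, Vc 100 L, Vp 205 L, Q 30 L/h, giving terminal t½ ≈ 25 h and
Vss 305 L — a mono-exponential model cannot show the Vz ≫ Vss gap these
studies exhibit), with first-order absorption ka = 0.9/h (observed Tmax
≈ 1.5 h on the sampling grid) and true F = 0.81. The one-compartment model
is retained because its AUC and λz have exact analytic values
(`AUC_inf = F·D/CL`), which the NCA tests use as oracles.

Variability has three levels, chosen to echo the study population the
package targets:

- between-subject: lognormal on CL, Vc, Vp with ln-SD 0.30 (exposure
  geometric CV ≈ 30–38%); a subject's parameters are shared by both
  periods, producing the within-subject correlation the crossover exploits;
- within-subject (inter-occasion): a lognormal whole-period exposure
  multiplier with ln-SD 0.10, the within-subject SD of ln AUC that the
  design's sample-size reasoning assumes. Proportional assay error alone
  cannot produce this, because the trapezoid averages point-level noise
  down to ~0.02 on ln AUC;
- residual: proportional error with SD 0.06 per sample (matching typical
  validated LC–MS/MS between-day precision), truncated at zero, then LLOQ
  censoring (values < 2.5 ng/mL flagged BLQ and zeroed).

Optional multiplicative period and sequence exposure effects can be
injected to exercise the fixed effects of the crossover model. Seeding
spawns one substream per subject from the study seed, so enlarging a study
never perturbs existing subjects.

The metabolite side-model forms metabolite at rate `fm·CL·Cp(t)` (mass
converted by the metabolite/parent molecular-weight ratio) with first-order
elimination; it is evaluated by exponential-decay-propagated trapezoidal
convolution on a dense grid, which is route-agnostic and exact in the grid
limit. It exists to exercise the molar metabolite-to-parent AUC ratio, not
to model any specific metabolic pathway.

**What the generator does not emulate:** actual-vs-nominal sampling-time
deviations, dropout and missed samples, time-dependent (auto-induced)
clearance, absorption lag or transit compartments, and correlated
assay-batch effects. Passing the recovery suite therefore shows the
analysis chain is correct under the stated stochastic model, not that it is
robust to every feature of real bioanalytical data.

## Problem sizes in the validation suite

The end-to-end recovery check uses 500 replicates of a 12-subject study
(the design the package targets), enough to resolve a 1% bias in the mean
estimate (replicate SE ≈ 0.13%) and ±3 points of CI coverage; the
Monte-Carlo design check uses 50 000 chi-square draws; the λz noise
recovery uses 200 replicates of a 6-point tail at 10% proportional noise.

## Known limitations

- λz window search considers only contiguous tail windows; sparse designs
  with interleaved BLQ points late in the profile may need the manual
  override.
- The mixed model assumes homoscedastic within-subject error across
  treatments; a treatment-specific residual variance is not fitted.
- No TOST/bioequivalence machinery: the package reports the ratio and CI,
  not a bioequivalence decision.
- Partial AUCs (e.g. AUC0–24) are not computed.
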