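# Methods

## Models

Disease onset is modelled cause-specifically on the age timescale. Two
parametric families represent a multistage aetiology in which *m*
rate-limiting events precede clinical onset.

**Weibull proportional-hazards family (sequential stages).** The cumulative
hazard is H(t | x) = e^{η_x} (t/L)^m with η_x = Σ_j β_j x_j over indicator-coded
categorical risk factors (the baseline level of each factor carries β = 0, so
η = 0 at baseline). This is the small-probability limit of a sequential
multistage process; *m* is real-valued — an *effective* number of steps —
because stage rates need not be constant in age. Writing
H(t) = (t e^{η/m}/L)^m exposes the two equivalent readings of a covariate
effect: a hazard ratio e^{η} (relative risk), or an age rescaling e^{η/m}
(relative aging rate). A consequence used throughout: ratios such as
H(100)/H(50) = 2^m depend only on *m*, and covariates displace the
log H–log t line vertically without changing its slope. Note the hazard is
h(t) = (m/t) e^{η}(t/L)^m, i.e. H'(t); a baseline hazard written as
(t/L)^m alone would not integrate to this H and is not used.

**Non-sequential model (NSM).** All *m* events must occur but in any order,
each at constant rate 1/L: S(t) = 1 − (1 − e^{−t/L})^m, the survival of the
maximum of *m* iid exponential(1/L) waits. Fitted without covariates by
default; the closed-form methods accept an optional proportional-hazards
multiplier on the cumulative hazard for experimentation, but no covariate
machinery is attached to the fitted NSM. At m = 1 both families reduce to
the same exponential law — a cross-family identity the tests assert.

Both families typically fit the same incidence data about equally well while
implying very different step counts, so a good fit must not be read as
evidence of a genuinely multistage biological mechanism; the value of the
fits is the parametric description (extrapolation to reference ages,
relative aging rates), not mechanism identification.

## Likelihood

Each subject contributes entry age t₀, exit age t, and an event indicator δ.
With left truncation at entry and right censoring,

    ll = Σ_i [ δ_i log f(t_i|x_i) + (1−δ_i) log S(t_i|x_i) − log S(t₀_i|x_i) ].

Optimisation is by L-BFGS-B over (log m, log L, β), making the positivity
constraints implicit; the Weibull gradient is analytic, the NSM uses finite
differences. Relative-tolerance 1e−8 on the objective; parameter bounds
m ∈ [0.01, 50], L ∈ [1e−3, 1e8], |β| ≤ 20 only guard against numerical
runaway. Standard errors come from the inverse observed information
(numerical Hessian) at the optimum, delta-method-mapped to the natural
scale; confidence intervals for m and L are computed on the log scale and
exponentiated. Starting values: β₀ from a semi-parametric Cox fit honouring
delayed entry (lifelines; skippable with `cox_start=False` in large
simulation loops, where β₀ = 0 converges identically), and (m₀, L₀) from
least squares of log Ĥ on log t of the unadjusted delayed-entry
product-limit estimator, clipped to m₀ ∈ [0.2, 20]. The NSM starts from the
Weibull m₀ with L₀ chosen to match the Weibull starting median. Rows with
missing analysis variables are dropped (complete-case). Degenerate designs
(a covariate level with no events) fall back to β₀ = 0 with a log warning;
non-convergence is reported in the results object, never silently.

## Kaplan–Meier offset correction

With age as the timescale, subjects enter observation in middle age already
disease-free, so the product-limit estimator measures only the hazard
accrued after the first observed event age t₁: Ŝ(t) ≈ exp(−[H(t) − H(t₁)]).
Writing H(t) = H1 + Ĥ(t), the pre-study offset is estimated as

    H1 ≈ (1/n) Σ_i ( H_model(t_i) − Ĥ(t_i) )

averaged over the n observed events (tied ages weighted by multiplicity;
censored rows do not enter — Ĥ is only defined at event ages, which decides
an ambiguity in the averaging convention). The corrected curve is
e^{−H1} Ŝ(t) with Greenwood variances scaled by e^{−2H1}; H1 is treated as
fixed, introducing no additional free parameters. Without the correction,
log Ĥ–log t plots of a middle-aged-entry cohort are grossly non-linear and
the apparent slope wildly overestimates m (the suite checks a bias > 2
slope units on reference simulations); with it, the slope recovers m.

## Goodness-of-fit screen and inclusion

The fitted curve is compared with the adjusted Kaplan–Meier at the distinct
event ages: X² = Σ_j (S_model(t_j) − S_adj(t_j))² / Var_adj(t_j), using only
the Kaplan–Meier (Greenwood) variance — deliberately strict in the sense
that the fit's own sampling variance is not added to the denominator.
Zero-variance points are skipped and logged; df = number of points used,
uncorrected for the three-or-so estimated parameters (subtract the
parameter count from df for a classical correction). Diseases are excluded
when the Benjamini–Hochberg q-value (statsmodels step-up, level 0.05 by
default) signals misfit, or when m̂ < 0.8 — a near-flat incidence outside
the multistage regime of interest.

Two calibration caveats, measured by the suite and deliberately not
patched over:

* Adjacent Kaplan–Meier points are strongly positively correlated, and both
  the H1 offset and the same-data MLE absorb the common component of the
  deviation. The χ² statistic's null mean is therefore far below df
  (measured stat/df ≈ 0.1–0.35 across designs), so the screen's type-I
  error at α = 0.05 is ~0 rather than ~0.05: it essentially never excludes
  a correctly-specified disease, but its rejection rate cannot be read as a
  calibrated error rate. A null-calibrated screen would need a simulated
  reference distribution, out of scope here.
* For the same reason, pointwise Greenwood bands around the adjusted curve
  (H1 fixed) understate uncertainty near the earliest event ages, where
  Greenwood variance → 0 while the H1 estimation error does not; the
  replicate-averaged fraction of event ages at which the adjusted curve
  covers the true survival within 95% bands measures ≈ 0.74–0.80 rather
  than the nominal ≈ 0.95 on common-entry reference simulations.

## Classification and aging rates

Fitted models are extrapolated at the baseline covariate profile to
F(50) = 1 − S(50) and F(100); the sporadic score F(50)²/F(100) is largest
for diseases with appreciable early risk that grows slowly. Ensemble
tertiles of the score label diseases sporadic / mid-range / late-onset
(boundary values to the lower tertile; an all-equal ensemble degenerates to
mid-range, logged). Weibull fits are reported by default; the NSM gives a
cross-family agreement view.

Relative aging rate e^{η/m} and relative risk e^{η} are tabulated per
non-baseline covariate level; multi-factor profiles sum their η before the
division by m. Effective age is t·e^{η/m}; the equivalent screening age for
a target group is reference_age · rar_ref / rar_target; the expected
first-disease age for someone aged a with Y baseline disease-free years is
(a + Y)/rar, reported rounded to whole years. Group contrasts between
sporadic and late-onset diseases use Welch's t-test per covariate level
(the equal-variance choice is not identifiable from first principles;
Welch is the safer default) with BH adjustment across rows; a zero-variance
pair with unequal means raises a degenerate-variance error rather than
fabricating a statistic.

## Synthetic cohorts

The generator emulates the structural features the analysis depends on, at
desk scale:

* entry ages from Normal(57, 8) truncated to [49, 69] (inverse-CDF sampled
  for cross-platform determinism; sd = 0 degenerates to a fixed entry age);
* onset ages drawn by inverting the closed forms conditionally on being
  event-free at entry, which implements left truncation exactly while
  keeping case counts controllable (a rejection-sampling mode exists and is
  tested to give the same truncated law);
* right censoring at entry + follow-up (default 10 years — a stand-in, as
  real cohorts have staggered calendar censoring) and optionally at an
  independent exponential competing-cancer age, mirroring cause-specific
  censoring at the first cancer other than non-melanoma skin cancer;
* categorical covariates with specified prevalences and true β, so default
  reference cohorts (n = 20,000, m = 5, L = 100, β_diabetes = 0.5) yield a
  few hundred to a few thousand cases per disease.

An episode-table generator emits synthetic hospital admissions (multiple
chapters per subject, non-primary flags, pre-entry cancers) with recorded
ground truth to exercise the preparation rules. Two brute-force simulators
serve as oracles: sums of exponential stage waits (hypoexponential; its
exact CDF, computed from the phase-type representation, approaches the
small-t Weibull form (Πλ) t^m/m!) and maxima of m exponentials (exactly the
NSM). What the generator does *not* emulate: correlated comorbidity,
disease-specific covariate structures, calendar-time and birth-cohort
effects, or registry coding noise — so green tests certify the statistical
machinery, not fidelity to any particular real cohort.

## Episode-table preparation

Episodes are assigned to WHO ICD-10 chapters by 3-character stem against an
embedded version-10 block table. (Published discussions of chapter
compositions sometimes mislabel circulatory disease as chapter XI; the WHO
scheme — IX circulatory, XI digestive — is used throughout.) Subjects with
a C00–C97 (except C44) episode strictly before entry are excluded; for each
remaining subject and chapter the earliest primary episode at/after entry
is the chapter's event, with same-age ties resolved to the lowest code and
logged. A disease (one or more 4-digit codes, matched by normalized stem
prefix within one chapter) yields one survival row per subject: an event if
the chapter-first event matches, otherwise censoring at the earliest of
study end, first post-entry qualifying cancer, or the chapter-first event
of a *different* disease in the same chapter — censoring rather than
deletion preserves the risk set under the first-per-chapter design. Ages
derived from dates use days/365.25.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the pipeline writes a
manifest (seed, versions, per-stage counts, every exclusion with its rule)
and renders figures only from exported tables. Reference problem sizes used
by the test and acceptance suites — 20,000-subject cohorts, 100 replicates
for coverage, 200 for screen calibration, 20 for the stratified scenario
detections, 10⁵ draws for distributional oracle checks — were chosen so
Monte-Carlo error is small against the asserted tolerances while a full run
stays in the minutes range on a single CPU.

## Known limitations

* No frailty or random effects; covariate effects are time-constant.
* Interval censoring and exact-date granularity are not modelled.
* The GOF screen's χ² reference is conservative (see above); it orders fits
  usefully but is not a calibrated test.
* The NSM is fitted unadjusted; covariate-adjusted NSM estimation is out of
  scope.
* Formal model selection between the families is deliberately absent: both
  usually fit, and the package treats that ambiguity as a finding rather
  than a problem to optimise away.
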