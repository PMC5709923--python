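# Methods

## The problem

A longitudinal cohort is only as trustworthy as its follow-up. The standard
screening statistic — the fraction of enrollees not lost to follow-up
("Percentage Method") — implicitly scores every dropout as if they left on
day one, so a cohort whose dropouts left in year 4 of 5 looks exactly as
bad as one whose dropouts left in month 1. `ptfr` implements person-time
alternatives that credit partial follow-up, for use when screening
prospective cohorts or EMR-derived retrospective cohorts before a
time-to-event analysis.

Notation: subject *i* has event time `T_i`, dropout (censoring) time `C_i`,
and the study ends at horizon `τ` (years). "Dropout" is any loss to
follow-up other than the event or the administrative end of study; the two
kinds of censoring are kept distinct throughout the package
(`Status.DROPOUT` vs `Status.ADMIN_CENSORED`) because every rate penalises
the former and not the latter.

## Estimands and estimators

The **person-time follow-up rate (PTFR)** is

    η_PTFR = Σ min(T_i, C_i, τ) / Σ min(T_i, τ) × 100%

— observed person-time over the person-time that would have accrued had
nobody dropped out. It is not directly computable from real data (the
denominator needs `T_i` for dropouts), which motivates four computable
quantities:

* **Percentage Method** `100·(N − #dropouts)/N` — counts heads only.
* **Clark's Completeness Index (CCI)** — observed person-time over
  potential person-time, where each dropout is imagined followed to `τ`.
  Because that denominator is the largest the no-dropout person-time can
  possibly be, `η_CCI ≤ η_PTFR` is an algebraic identity, and the CCI
  doubles as a worst-case lower bound that survives informative censoring
  (`ptfr_lower_bound`).
* **Simplified Person-Time rate (SPT)** — dropouts keep their observed
  time, everyone else (events and survivors) counts as fully followed, over
  `Nτ`. Equivalently: the mean height over `[0, τ]` of the competing-risk
  follow-up curve (below); `curve_auc` reproduces `spt_rate` to 1e-9 and a
  property test enforces the identity.
* **Formal Person-Time rate (FPT)** — estimates the PTFR denominator by
  predicting the dropouts' events from the observed data via the Turnbull
  NPMLE (below). Valid under non-informative dropout.

### A caution about the SPT "upper bound"

`η_CCI ≤ η_SPT` always holds, and `η_PTFR ≤ η_SPT` is commonly stated as
its mirror. The latter is **not** a pointwise theorem: a dropout whose
counterfactual event occurs soon after the dropout time retains most of its
no-dropout person-time in the PTFR denominator while the SPT still charges
it the full `τ` (a one-subject cohort with `C = 1`, `T = 2`, `τ = 5` gives
PTFR = 50% vs SPT = 20%). The bound is exact whenever every dropout is
event-free through `τ` (then PTFR collapses onto the CCI), and it holds on
average and in ~98% of simulated cohorts at realistic sample sizes, with
violations of ≲0.2pp at `N = 1000`. The package therefore enforces
`CCI ≤ PTFR` and `CCI ≤ SPT` as hard invariants of `FollowupReport`, but
deliberately not `PTFR ≤ SPT`.

## Interval censoring and the Turnbull NPMLE

With visits at `t_0 = 0 < t_1 < … < t_K = τ`, an event detected at visit
*k* is only known to lie in `(t_{k-1}, t_k]`; a subject lost after visit
`t_j` may fail any time in `(t_j, E]`, where the sentinel `E` (default 100
years, configurable) stands for "eventually, absent competing risks"; an
event-free survivor gets `(t_K, E]`. The event-time distribution is
estimated by the nonparametric MLE for interval-censored data: mass lives
on the maximal intersections of the observation intervals, found by an
endpoint merge-sort, and the masses solve the self-consistency equations,
iterated as an EM (uniform deterministic initialisation, tolerance 1e-8 on
the largest mass change, 10 000 iterations before a `ConvergenceWarning`).
The log-likelihood is non-decreasing along the iteration and tests assert
this on every fit. On right-censored encodings (`(t−ε, t]` with
`ε = 1e-9 y` for exact events) the NPMLE reproduces the Kaplan-Meier curve
to 1e-8, checked against lifelines.

The NPMLE is indeterminate inside a support interval; `survival` reports
the right-continuous convention (mass at the support's right endpoint). On
a regular grid the FPT only evaluates survival at visit boundaries, where
the NPMLE is unique.

## The FPT computation

Regular schedules: observed person-time uses the actuarial life-table
formula `Σ len_k (N_{k-1} − (N_Ek + N_Ck)/2)` (exits assumed mid-interval);
the no-dropout person-time runs a counterfactual cohort through the grid
with the NPMLE's conditional event probabilities
`P_k = [S(t_{k-1}) − S(t_k)]/S(t_{k-1})` (defined as 0 when `S(t_{k-1})=0`)
and the same midpoint convention. With zero dropouts the two sides are
identical and the FPT is exactly 100%.

Irregular / ad-hoc schedules: censoring is estimated by the last visit,
an event by the midpoint of its final inter-visit gap; the no-dropout
person-time is computed as `N·∫₀^τ S(t) dt` with NPMLE mass placed at
support-interval midpoints (tail supports reaching `E` contribute the full
`τ`). On a regular grid this integral reproduces the life-table recursion
exactly, which is why it was chosen where no common grid exists.

### Known biases (documented, not corrected)

* Back-dating a dropout's censoring to their last visit removes their
  partial within-interval exposure, so the NPMLE's interval hazard is
  asymptotically `E_k/(N_{k-1} − D_k)` rather than the true conditional
  probability. The resulting overestimate of the event rate — and hence an
  upward drift of the FPT — is negligible at moderate dropout but reaches
  ~+2pp at the most extreme study cell (event 50%→30%, observed dropout
  70%). Coding dropouts at their exact censoring times does not help,
  because event times remain interval-identified.
* The midpoint convention inflates the observed-person-time numerator by
  ~1% relative when most subjects exit before `τ`, while the denominator is
  nearly midpoint-neutral.
* The irregular-schedule estimator forfeits on average half a visit gap of
  observed person-time per dropout (last-visit censoring), so it drifts
  below the fixed-grid FPT as dropout grows: ~1pp at 10% dropout,
  several pp at 50%+.

## Follow-up curves

`reverse_km` is the product-limit estimator with event and censoring roles
exchanged (dropout is the "event"); censorings at tied times are processed
after dropouts, the standard convention. Because outcome events leave its
risk set, early events depress the curve even with identical dropout.
`competing_followup_curve` instead keeps events in the risk set through `τ`
(the subdistribution treatment); with administrative censoring only at `τ`
it equals `1 − (#dropouts by t)/N`, invariant to event timing, and its
AUC over `[0, τ]` divided by `τ` is the SPT as a fraction.

## Synthetic cohorts and the simulation study

`generate_cohort` draws `T ~ Exp(λ)` and `C ~ Exp(μ)` independently per
subject and observes the cohort through `τ`. Defaults are the reference
study conditions: `N = 1000`, `τ = 5` years, 5 annual visits, 1000
replicates per cell, event levels 5–50% and dropout levels 10–70%.
`λ` always solves `1 − e^{−λτ} = event level`. The dropout level admits two
readings, both implemented: `CUMULATIVE` (`1 − e^{−μτ} = level`,
symmetric with the event calibration) and `OBSERVED_FRACTION` (default:
`μ` solves `μ/(λ+μ)·(1 − e^{−(λ+μ)τ}) = level`, so the expected fraction
of subjects observed to drop out equals the nominal level; this keeps the
Percentage Method mean at `100·(1 − level)` by construction and matches the
high-event-rate cells of the reference design more faithfully).

Status classification uses the continuous times (dropout iff
`C < min(T, τ)`; a tie at `τ` is administrative censoring), exactly as the
estimator formulas define them; the visit grid enters only through the
interval-censored data handed to the FPT. Oracle event times are retained
on every record — `NEVER_EVENT` (`inf`) marks subjects event-free through
`τ` — so the true PTFR is computable per replicate from complete
information. Summaries follow the usual conventions: percent bias
`(mean estimate − mean truth)/mean truth × 100` and root-MSE against the
per-replicate truth, in percentage points.

One RNG stream per `(seed, cell, rep)` via `numpy.random.SeedSequence`
makes every cell independently reproducible and order-independent.

What the generator does *not* emulate: informative dropout (dropout
correlated with event risk), non-exponential time distributions, visit
non-attendance other than permanent dropout, and covariates. Passing tests
therefore demonstrate correctness of the estimators under non-informative
censoring, not robustness to its failure — for that, the CCI lower bound is
the package's only (deliberately conservative) answer.

Problem sizes in the shipped tests and acceptance script — 200–1000
replicates of `N = 1000`, 100–1000 small random cohorts for property
checks — were chosen so the full suite replays in a few minutes while
keeping Monte-Carlo error on cell means well under 0.1pp at 1000 reps.

## Staggered entry

With entry offsets, a `k`-year rate is computed on the subjects who entered
at least `k` years before the study closed (`entry_offset + k ≤ span`),
each truncated at the horizon: exits after it become administrative
censorings, and a dropout exactly at the horizon counts as administrative
(end-of-study censoring is not loss to follow-up). No entry-time weighting
beyond eligibility is attempted.

## Numerical conventions

* Half-open intervals `(t_{k-1}, t_k]`: an exit exactly at a visit belongs
  to the interval ending there; `t = 0` clamps into the first interval.
* Within a visit interval, an event takes precedence over a dropout when a
  single exit must be assigned (the event is ascertained at the boundary
  visit).
* Rates are computed in full precision; the CLI rounds to 1 decimal in CSV
  reports and keeps full precision in JSON.
* Times are years from each subject's entry; calendar parsing is out of
  scope (callers supply offsets).
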