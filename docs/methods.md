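# Methods

## Survival primitives

The product-limit estimator is computed with the standard tie convention:
at a tied time, events are processed before censorings, so a subject
censored at *t* is still in the risk set for an event at *t*. Greenwood's
formula supplies pointwise variances; confidence intervals use the normal
approximation on S clipped to [0, 1] (a log(−log) transform is not needed
for the diagnostics this package performs). The two-sample log-rank test is
the unstratified two-sided form: over distinct event times,
χ² = (Σ(O₁−E₁))² / ΣV with the hypergeometric variance
V = d·(n₁/n)·(1−n₁/n)·(n−d)/(n−1), referred to χ²(1). Times are days
throughout; 1 month = 30.4375 days and 1 week = 7 days in every
conversion. p-values are carried at full double precision; rounding is
presentation-only.

Degenerate inputs: an empty table, a negative time, a single-arm input to
the two-sample test, and an event-free table (the test statistic is
undefined) all raise errors rather than returning placeholders. If every
event occurs in a risk set of size one the variance is zero and the test
returns χ² = 0, p = 1 (no discriminating information).

## IPD reconstruction

Reconstruction inverts a published figure's two machine-readable summaries
— KM step coordinates and the number-at-risk table — into per-subject
(time, status) records. Within each risk-table interval the algorithm
iterates a censoring count until the at-risk count at the next anchor is
matched exactly; event counts at each coordinate drop are obtained by
rounding n·(1 − S/Ŝ), where Ŝ is the running reconstructed estimate (this
self-corrects integer rounding under digitization noise). This is the
interval-allocation scheme of the Guyot class, with two deliberate
deviations for reproducibility:

- **Determinism.** Censoring times are placed at equally spaced quantiles
  of their interval instead of random positions; identical input yields
  byte-identical IPD.
- **Event-total constraint.** When a reported total event count is given,
  censoring in the final (unanchored) interval is adjusted for at most 50
  iterations until the total matches exactly; if irreconcilable, the best
  fit is returned with a warning and a `converged=False` flag.

Subjects still at risk after the last coordinate are censored
administratively at the curve's terminal time. The companion renderer
therefore emits, besides every drop, a final flat coordinate at the arm's
largest observed time — the point where a plotted curve's trace ends.
This matters for two-sample statistics: placing end-of-follow-up censoring
at the last *event* time instead depletes the arm's risk sets and can move
the log-rank p-value materially even though each arm's own curve is
reproduced almost exactly.

Coordinate cleaning clips survival to [0, 1], enforces monotonicity by
running minimum, collapses duplicate times to the lower value and prepends
the origin (0, 1); uniform jitter of magnitude ε therefore perturbs the
cleaned curve by at most ε. Pixel extraction from figure images is out of
scope — coordinates arrive as CSV.

Practical guidance: risk-table anchors should stop below the maximum
observed time. An anchor at or beyond maximal follow-up places the
administrative-censoring cluster inside an anchored interval, where the
uniform-spreading assumption misallocates at-risk counts. Round-trip
fidelity improves with finer anchor grids up to the integer-allocation
granularity (~2/n in survival units); below that floor the error is not
strictly monotone in grid refinement, which is why the nested-grid test
allows a 2/n tolerance.

## Censoring diagnostics

Rates are censored-count / randomized arm size (intention-to-treat), per
half-open interval [start, end) in days; "first 6 months" is
[0, 182.625 d). The headline difference in percentage points is computed
from rates rounded to one decimal — the form in which such rates are
printed and compared — with exact rates exposed alongside. The excess
count is floored at zero: the flip procedure is defined only for an
experimental-arm excess. The Rosen et al. benchmark (≈2 pp, more censoring
in the *control* arm) is attached to every report as an external yardstick,
with a caveat flag because that survey's "first time-point" window need not
equal the interval analysed here.

## Flip sensitivity analysis

Each replicate draws `n_flip` subjects uniformly without replacement from
the censored target-arm subjects inside the interval and sets their status
to event at the same time (turning a censoring into a same-time event can
only shrink product-limit factors, so the post-flip curve is pointwise
below the original). Replicate r uses the counter-based child seed
`SeedSequence(seed, spawn_key=(r,))`, so increasing the replicate count
never changes earlier draws. A single random draw — what a one-off
re-analysis reports — is seed-dependent; the default here is therefore a
replicate distribution (200 recommended) summarized by the fraction of
replicates non-significant at a configurable α (default 0.05).

## Trial simulator

Per subject: a gamma frailty Z with mean 1 and variance v (v = 0 gives
Z ≡ 1); a latent event time ~ Exp(Z·λ_event(arm)); a latent censoring time
~ Exp(Z·λ_cens(arm)); administrative censoring at a fixed cutoff. Shared
frailty couples the two clocks, so v > 0 makes early censoring preferential
for event-prone subjects — the informative-censoring mechanism under
study. Event and censoring hazards are per-arm (the censoring imbalance the
diagnostics measure requires arm-specific censoring).

Pre-adjuvant failures are Bernoulli per arm and timed uniformly over the
arm's pre-adjuvant window — uniform is the declared neutral default, since
nothing is known about the real distribution of those times; the window is
(cycles−1)·cycle length + surgery-delay cap + adjuvant-delay cap for the
experimental arm (161 d = 23 wk under the defaults: 3 cycles every 21 d,
35 d, 84 d) and the adjuvant-delay cap alone for the control arm (84 d =
12 wk). With the day-84 rule ON, every such failure is assigned the event
time `max_adjuvant_delay` exactly — both biases at once: early failures
are dated later, late ones earlier — producing the characteristic single
vertical KM drop at day 84. A flag allows failures to be treated as
withdrawals (censorings at the raw time) instead of events.

### The `s1801_like` preset

Chosen once, as the package's calibrated operating point, and not adjusted
thereafter: arm sizes 154/159; exponential event hazards inverted from
2-year event-free survival of 72% (experimental) and 49% (control),
λ = −ln S(730)/730; per-arm censoring hazards solved by root-finding from
the competing-risks identity P(C<T, C<w) = λ_c/(λ_c+λ_e)·(1−e^{−(λ_c+λ_e)w})
so that the expected fraction censored within the first 6 months is 17.5%
and 11.9%; administrative cutoff at the 14.7-month median follow-up
(447.4 d). Frailty variance and pre-adjuvant failure probability are zero
in the preset so the survival calibration stays exact; both are single
knobs away when the informative-censoring or day-84 phenomena are the
object of study. Under this preset a trial yields ~70 events and an
expected log-rank z around 3, i.e. an original p near the conventional
significance boundary with substantial seed-to-seed spread — the regime in
which a flip of the ~8 expected excess censorings is informative.

### What the generator does and does not emulate

It reproduces the design's time architecture, the censoring-imbalance
magnitudes and a frailty-linked censoring mechanism. It does **not** model
staggered accrual (follow-up is a fixed cutoff, so administrative censoring
is a point mass rather than a ramp), non-exponential event-time shapes
(piecewise-constant hazards are the natural extension point), surgery
outcomes, toxicity grading or response assessment schedules. Tests passing
on these synthetics certify the pipeline's arithmetic and its qualitative
behaviour, not the clinical accuracy of any particular published estimate.

## Problem sizes and randomness

Simulation-based tests use the package's own trial scale (154/159 per arm):
round trips over 10 seeds × 2 arms, flip batteries of 200 replicates, a
2000-replication null calibration of the log-rank test at 50/arm, and a
5000-subject arm for the closed-form exponential check. All randomness
flows through `numpy.random.default_rng` seeded explicitly; replicate
streams use spawn-key derivation so results are independent of execution
order.

## Known limitations

- Reconstruction assumes censoring is spread evenly within risk-table
  intervals; heavily clustered interior censoring (other than the terminal
  administrative cluster, which is handled) degrades allocation.
- The flip analysis explores one specific violation (excess early
  censorings were events at the same time); it is a bound-style stress
  test, not an estimator of the true effect under dependent censoring
  (no IPCW or copula machinery).
- The diagnostics' benchmark constant is an external empirical average,
  not a test statistic; it carries no sampling distribution here.
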