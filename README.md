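# kmsens

Stress-testing published two-arm survival comparisons against time biases
and informative censoring.

Randomized oncology trials are usually summarized by Kaplan–Meier (KM)
curves, number-at-risk tables and a log-rank p-value. Two things can make
such a summary fragile without ever appearing in it. First, protocol rules
about *when* an event is dated — for example, assigning every failure that
occurs before the adjuvant phase the event time of day 84, regardless of
when it really happened — distort the event-time distribution (a
guarantee-time bias for early events, the converse "shorter-time" artifact
for late ones) and print a tell-tale vertical drop on the curve. Second,
censoring that is markedly heavier and earlier in one arm may be
*informative*: if toxicity withdraws the frailer patients from the
experimental arm, the KM independence assumption fails and the apparent
benefit is overstated.

`kmsens` packages the full re-analysis chain a methodologist needs to probe
both problems using only what a published figure provides:

- **`survival_core`** — self-contained product-limit estimation (Greenwood
  variance, normal-approximation CIs) and the unstratified two-sample
  log-rank test, `χ² = (O−E)²/V` with the hypergeometric variance.
- **`km_reconstruction`** — reconstruction of individual patient data (IPD)
  from digitized KM step coordinates plus the number-at-risk table
  (deterministic interval allocation in the Guyot class of algorithms,
  optional total-event constraint).
- **`censoring_diagnostics`** — per-interval, per-arm censoring rates on
  the intention-to-treat denominator, their difference in percentage
  points, the excess count, and the ~2 pp empirical benchmark (Rosen et
  al.) for between-arm censoring imbalance.
- **`flip_sensitivity`** — the conservative stress test: flip the excess
  early-censored experimental-arm subjects into events *at their censoring
  times* and re-run the log-rank test over seeded replicates.
- **`trial_simulator`** — a synthetic two-arm neoadjuvant-vs-adjuvant trial
  generator with arm-specific pre-adjuvant windows (23 vs 12 weeks under
  the default schedule), the day-84 assignment rule, shared gamma-frailty
  (informative) censoring, and a renderer that produces published-style
  curve/risk-table inputs for reconstruction round trips.
- **`pipeline` / `cli`** — a staged command-line pipeline
  (`simulate → reconstruct → diagnose → flip → report`) with run manifests.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
trial calibrated to a published phase-2 melanoma trial's operating
conditions (arm sizes 154/159, 2-year event-free survival 72% vs 49%,
first-6-month censoring 17.5% vs 11.9%, 14.7-month median follow-up):

```
$ python analysis/01_simulate.py --seed 1
pre-adjuvant windows: experimental 161 d (23 wk), control 84 d (12 wk)
simulated trial (seed 1): 154/159 subjects, events 19/47
log-rank: chi2 = 10.331, p = 0.001308

$ python analysis/02_reconstruct.py
experimental: 154 subjects, 19 events (reconstructed 19), max |dS| = 0.0005, converged = True
control: 159 subjects, 47 events (reconstructed 47), max |dS| = 0.0010, converged = True

$ python analysis/03_censoring_diagnostics.py
published counts: 27/154 (17.5%) vs 19/159 (11.9%), difference +5.6 pp, excess n = 8 (benchmark 2.0 pp, control-ward)
reconstructed synthetic IPD: 31/154 (20.1%) vs 20/159 (12.6%), difference +7.5 pp, excess n = 11 (benchmark 2.0 pp, control-ward)

$ python analysis/04_flip_sensitivity.py
flipping n = 11 excess early-censored experimental subjects
original log-rank p = 0.0009434
post-flip p over 200 replicates: median 0.07298, IQR [0.07277, 0.07311]
fraction non-significant at alpha = 0.05: 1.000
```

Reading: IPD reconstructed from nothing but the rendered curve and a
3-monthly risk table reproduces each arm's survival within 0.001 and every
event count exactly; the early censoring imbalance of this simulated trial
(+7.5 pp) far exceeds the ~2 pp empirical benchmark and points the *wrong*
way; and if those excess censored subjects had actually been events, the
originally significant comparison (p ≈ 0.001) would lose significance in
every replicate — the published effect is not robust to informative
censoring of this magnitude. `analysis/05_report.py` collects the same
numbers into `results/report.md`.

The same stages are available as a CLI, e.g.
`kmsens pipeline --seed 1 --out-dir results/run1`.

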