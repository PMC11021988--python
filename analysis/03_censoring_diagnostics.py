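#!/usr/bin/env python
"""Early censoring-imbalance diagnostics.

Two runs of the same diagnostic:
(a) on an IPD table realizing the published counts — 27 of 154
    experimental-arm and 19 of 159 control-arm subjects censored within
    the first six months — reproducing the printed arithmetic
    (17.5% vs 11.9%, 5.6 pp, excess n = 8);
(b) on the reconstructed synthetic IPD from step 02, showing the same
    diagnostic as it would be applied to digitized trial curves.
Both are contrasted with the ~2 pp empirical benchmark (more censoring in
the control arm) reported by Rosen et al. across published trials.
"""

import argparse
from pathlib import Path

import numpy as np

import kmsens as k
from kmsens.io import read_ipd_csv

SIX_MONTHS = 6 * k.DAYS_PER_MONTH

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()


def published_counts_table(seed):
    rng = np.random.default_rng(seed)
    ids, arms, times, status = [], [], [], []
    for arm, n, c in (("experimental", 154, 27), ("control", 159, 19)):
        early = rng.uniform(0.0, SIX_MONTHS, size=c)
        for i in range(n):
            ids.append(f"{arm[:3]}{i}")
            arms.append(arm)
            times.append(float(early[i]) if i < c else 500.0 + i)
            status.append(0 if i < c else 1)
    return k.make_ipd_table(ids, arms, times, status)


for label, table in (
    ("published counts", published_counts_table(args.seed)),
    ("reconstructed synthetic IPD", read_ipd_csv(args.out_dir / "ipd_reconstructed.csv")),
):
    report = k.interval_censoring_rates(table, [(0.0, SIX_MONTHS)])
    print(f"{label}: "
          f"{report.experimental_censored[0]}/{report.experimental_size} "
          f"({report.experimental_rate_display[0]}%) vs "
          f"{report.control_censored[0]}/{report.control_size} "
          f"({report.control_rate_display[0]}%), "
          f"difference {k.censoring_difference(report, 0):+.1f} pp, "
          f"excess n = {k.excess_censored(report, 0)} "
          f"(benchmark {report.benchmark_pp} pp, control-ward)")
    if label.startswith("reconstructed"):
        report.to_json(args.out_dir / "censoring_report.json")
        print(f"wrote {args.out_dir / 'censoring_report.json'}")
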