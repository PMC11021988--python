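#!/usr/bin/env python
"""Round-trip check: render published-style summaries, reconstruct IPD.

For each arm of the simulated trial, renders exact KM step coordinates and
a 3-monthly number-at-risk table (the two machine-readable summaries a
published figure provides), reconstructs per-subject data from them alone,
and reports how far the re-estimated survival curve deviates from the one
the original data give.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import kmsens as k
from kmsens.io import read_ipd_csv, write_curve_csv, write_ipd_csv, write_risk_csv

parser = argparse.ArgumentParser()
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

ipd = read_ipd_csv(args.out_dir / "ipd_simulated.csv")
parts = []
for arm in k.ARMS:
    sub = ipd[ipd["arm"] == arm]
    tmax = float(sub["time_days"].max())
    grid = np.arange(0.0, tmax, 3 * k.DAYS_PER_MONTH)
    rendered = k.render_km_coordinates(ipd, grid, arm=arm)
    write_curve_csv(rendered.coords, args.out_dir / f"curve_{arm}.csv")
    write_risk_csv(rendered.risk_times, rendered.n_at_risk, args.out_dir / f"risk_{arm}.csv")
    recon = k.reconstruct_ipd(rendered)
    parts.append(recon)

    ts = np.linspace(0.0, tmax, 500)
    err = np.max(np.abs(
        k.survival_at(k.km_estimate(sub), ts) - k.survival_at(k.km_estimate(recon), ts)
    ))
    print(f"{arm}: {len(sub)} subjects, "
          f"{int(sub['status'].sum())} events (reconstructed {recon.attrs['n_events']}), "
          f"max |dS| = {err:.4f}, converged = {recon.attrs['converged']}")

recon_all = pd.concat(parts, ignore_index=True)
write_ipd_csv(recon_all, args.out_dir / "ipd_reconstructed.csv")
print(f"wrote {args.out_dir / 'ipd_reconstructed.csv'}")
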