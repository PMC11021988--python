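"""Self-contained Kaplan-Meier estimation and two-sample log-rank testing.

Every other module in the package builds on these two primitives, so they
are implemented here rather than delegated to an external survival library;
external implementations (e.g. lifelines) serve only as cross-checks in the
test suite.

Conventions
-----------
* Times are in days. ``DAYS_PER_MONTH = 30.4375`` and ``DAYS_PER_WEEK = 7``
  are used for every unit conversion in the package.
* An IPD (individual patient data) table is a :class:`pandas.DataFrame`
  with columns ``subject_id`` (unique strings), ``arm`` (``"experimental"``
  or ``"control"``), ``time_days`` (non-negative float) and ``status``
  (1 = event, 0 = censored).
* At tied times, events are processed before censorings (the standard
  product-limit convention): a subject censored at *t* is still at risk
  for an event at *t*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_MONTH = 30.4375
DAYS_PER_WEEK = 7.0

ARM_EXPERIMENTAL = "experimental"
ARM_CONTROL = "control"
ARMS = (ARM_EXPERIMENTAL, ARM_CONTROL)

IPD_COLUMNS = ("subject_id", "arm", "time_days", "status")


def make_ipd_table(
    subject_id: Sequence[str],
    arm: Sequence[str],
    time_days: Sequence[float],
    status: Sequence[int],
) -> pd.DataFrame:
    """Assemble and validate an IPD table from column vectors."""
    df = pd.DataFrame(
        {
            "subject_id": [str(s) for s in subject_id],
            "arm": list(arm),
            "time_days": np.asarray(time_days, dtype=float),
            "status": np.asarray(status, dtype=int),
        }
    )
    validate_ipd(df)
    return df


def validate_ipd(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` on any malformed IPD table."""
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IPD table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no subjects")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id: {dup!r}")
    bad_arm = set(df["arm"].unique()) - set(ARMS)
    if bad_arm:
        raise ValueError(f"unknown arm label(s): {sorted(bad_arm)}")
    t = df["time_days"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("invalid time")
    s = df["status"].to_numpy()
    if not np.isin(s, (0, 1)).all():
        raise ValueError("status must be 0 (censored) or 1 (event)")


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier step function plus its number-at-risk table.

    ``step_times`` always starts at 0 with ``survival[0] == 1.0``; later
    entries are the distinct event times where the curve drops.
    ``variance`` is the Greenwood variance of S at each step time.
    """

    step_times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    n_events_total: int | None = None
    variance: np.ndarray | None = None
    n_events: np.ndarray | None = None  # events at each step time

    def __post_init__(self) -> None:
        st, sv = np.asarray(self.step_times, float), np.asarray(self.survival, float)
        if st.shape != sv.shape:
            raise ValueError("step_times and survival lengths differ")
        if len(st) == 0 or st[0] != 0.0 or sv[0] != 1.0:
            raise ValueError("curve must start at (0, 1.0)")
        if np.any(np.diff(st) <= 0):
            raise ValueError("step_times must be strictly ascending")
        if np.any(np.diff(sv) > 1e-12) or np.any(sv < -1e-12) or np.any(sv > 1 + 1e-12):
            raise ValueError("survival must be non-increasing within [0, 1]")
        rt, nr = np.asarray(self.risk_times, float), np.asarray(self.n_at_risk)
        if rt.shape != nr.shape:
            raise ValueError("risk_times and n_at_risk lengths differ")
        if np.any(np.diff(rt) <= 0):
            raise ValueError("risk_times must be strictly ascending")
        if np.any(np.diff(nr) > 0) or np.any(nr < 0):
            raise ValueError("n_at_risk must be non-negative and non-increasing")

    def __eq__(self, other: object) -> bool:  # array-aware equality
        if not isinstance(other, KMCurve):
            return NotImplemented
        return (
            np.array_equal(self.step_times, other.step_times)
            and np.array_equal(self.survival, other.survival)
            and np.array_equal(self.risk_times, other.risk_times)
            and np.array_equal(self.n_at_risk, other.n_at_risk)
            and self.n_events_total == other.n_events_total
        )


def km_estimate(records: pd.DataFrame, arm: str | None = None) -> KMCurve:
    """Product-limit survival estimate for one arm of an IPD table.

    Parameters
    ----------
    records : IPD table (may contain both arms if ``arm`` is given).
    arm : restrict to this arm; if ``None`` the table must be single-arm.

    Returns a :class:`KMCurve` whose risk table is evaluated at time 0 and
    at every distinct event time, with Greenwood variances attached.
    """
    validate_ipd(records)
    if arm is not None:
        records = records[records["arm"] == arm]
        if len(records) == 0:
            raise ValueError("no subjects")
    elif records["arm"].nunique() > 1:
        raise ValueError("table contains multiple arms; pass arm=...")

    t = records["time_days"].to_numpy(dtype=float)
    s = records["status"].to_numpy(dtype=int)
    n0 = len(t)

    event_times = np.unique(t[s == 1])
    # at risk at time u = subjects with time >= u (censorings at u still at risk)
    n_at = np.array([np.sum(t >= u) for u in event_times], dtype=int)
    d = np.array([np.sum((t == u) & (s == 1)) for u in event_times], dtype=int)

    surv = np.cumprod(1.0 - d / n_at)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_at > d, d / (n_at * (n_at - d)), np.nan)
    gw = surv**2 * np.cumsum(gw_terms)

    step_times = np.concatenate(([0.0], event_times))
    survival = np.concatenate(([1.0], surv))
    variance = np.concatenate(([0.0], gw))
    n_events = np.concatenate(([0], d))
    risk_times = step_times
    n_at_risk = np.concatenate(([n0], n_at))
    return KMCurve(
        step_times=step_times,
        survival=survival,
        risk_times=risk_times,
        n_at_risk=n_at_risk,
        n_events_total=int(d.sum()),
        variance=variance,
        n_events=n_events,
    )


def survival_at(curve: KMCurve, t: float | np.ndarray) -> float | np.ndarray:
    """Right-continuous evaluation of a KM curve at time(s) ``t`` (days).

    Times beyond the last step return the last survival value.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("invalid time: t must be >= 0")
    idx = np.searchsorted(curve.step_times, t_arr, side="right") - 1
    out = np.asarray(curve.survival)[idx]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def confidence_interval(curve: KMCurve, alpha: float = 0.05):
    """Pointwise normal-approximation CI on S, clipped to [0, 1]."""
    if curve.variance is None:
        raise ValueError("curve carries no Greenwood variance")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(curve.variance)
    lo = np.clip(curve.survival - half, 0.0, 1.0)
    hi = np.clip(curve.survival + half, 0.0, 1.0)
    return lo, hi


@dataclass(frozen=True)
class LogRankResult:
    """Outcome of an unstratified two-sided two-sample log-rank test.

    ``observed_events`` / ``expected_events`` are (experimental, control)
    pairs; the statistic is chi-square distributed with 1 df under the null.
    """

    statistic: float
    p_value: float
    observed_events: tuple[int, int]
    expected_events: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.statistic < 0:
            raise ValueError("statistic must be >= 0")


def logrank_test(records: pd.DataFrame) -> LogRankResult:
    """Two-sample log-rank test between the experimental and control arms.

    Statistic: (O - E)^2 / V summed over distinct event times, with the
    hypergeometric variance V; p-value from chi-square with 1 df.

    Raises ``ValueError`` for single-arm input or for tables with zero
    events (the test is undefined there).
    """
    validate_ipd(records)
    arms_present = set(records["arm"].unique())
    if arms_present != set(ARMS):
        raise ValueError("log-rank test requires both arms")

    t = records["time_days"].to_numpy(dtype=float)
    s = records["status"].to_numpy(dtype=int)
    is_exp = (records["arm"] == ARM_EXPERIMENTAL).to_numpy()

    if s.sum() == 0:
        raise ValueError("test undefined: zero events")

    event_times = np.unique(t[s == 1])
    o_minus_e = 0.0
    var = 0.0
    e1 = 0.0
    o1 = int(np.sum((s == 1) & is_exp))
    o2 = int(np.sum((s == 1) & ~is_exp))
    for u in event_times:
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & is_exp).sum())
        d = int(np.sum((t == u) & (s == 1)))
        d1 = int(np.sum((t == u) & (s == 1) & is_exp))
        e = d * n1 / n
        e1 += e
        o_minus_e += d1 - e
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    if var == 0.0:
        # degenerate: all events in risk sets of size 1; no information
        stat = 0.0
        p = 1.0
    else:
        stat = o_minus_e**2 / var
        p = float(stats.chi2.sf(stat, df=1))
    e2 = (o1 + o2) - e1
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        observed_events=(o1, o2),
        expected_events=(float(e1), float(e2)),
    )
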