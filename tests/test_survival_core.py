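"""Unit and property tests for the KM estimator and the log-rank test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kmsens as k


class TestKMEstimate:
    def test_hand_product_limit(self, tiny_table):
        curve = k.km_estimate(tiny_table)
        assert np.allclose(curve.step_times, [0.0, 1.0, 2.0])
        assert np.allclose(curve.survival, [1.0, 2 / 3, 1 / 3])
        # censoring at day 3 does not drop the curve further
        assert k.survival_at(curve, 3.0) == pytest.approx(1 / 3)

    def test_no_events_flat_at_one(self):
        df = k.make_ipd_table(
            ["a", "b", "c"], ["control"] * 3, [10.0, 10.0, 10.0], [0, 0, 0]
        )
        curve = k.km_estimate(df)
        assert np.all(curve.survival == 1.0)
        assert k.survival_at(curve, 1e6) == 1.0

    def test_ties_events_before_censorings(self):
        # censored subject at day 5 is still at risk for the day-5 event
        df = k.make_ipd_table(
            ["a", "b", "c", "d"], ["control"] * 4, [5.0, 5.0, 8.0, 9.0], [1, 0, 1, 0]
        )
        curve = k.km_estimate(df)
        assert k.survival_at(curve, 5.0) == pytest.approx(3 / 4)

    def test_conservation(self, s1801_trial):
        ipd = s1801_trial.observed
        for arm in k.ARMS:
            sub = ipd[ipd["arm"] == arm]
            curve = k.km_estimate(sub)
            n_events = int(curve.n_events.sum())
            assert n_events == curve.n_events_total == int(sub["status"].sum())
            # drops == distinct event times
            assert int(np.sum(np.diff(curve.survival) < 0)) == len(curve.step_times) - 1

    def test_invariant_to_order_and_relabel(self, two_arm_table):
        shuffled = two_arm_table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["subject_id"] = [f"z{i}" for i in range(len(shuffled))]
        for arm in k.ARMS:
            a = k.km_estimate(two_arm_table, arm=arm)
            b = k.km_estimate(shuffled, arm=arm)
            assert a == b

    def test_errors(self):
        with pytest.raises(ValueError, match="no subjects"):
            k.km_estimate(pd.DataFrame(columns=list(k.survival_core.IPD_COLUMNS)))
        with pytest.raises(ValueError, match="invalid time"):
            k.make_ipd_table(["a"], ["control"], [-1.0], [1])

    def test_greenwood_ci_bounds(self, s1801_trial):
        curve = k.km_estimate(s1801_trial.observed, arm="control")
        lo, hi = k.confidence_interval(curve)
        assert np.all((0 <= lo) & (lo <= curve.survival))
        assert np.all((curve.survival <= hi) & (hi <= 1))


class TestSurvivalAt:
    def test_time_zero_is_one(self, tiny_table):
        assert k.survival_at(k.km_estimate(tiny_table), 0.0) == 1.0

    def test_right_continuity_at_drop(self):
        df = k.make_ipd_table(
            ["a", "b"], ["control"] * 2, [84.0, 84.0], [1, 1]
        )
        curve = k.km_estimate(df)
        assert k.survival_at(curve, 84.0) == 0.0
        assert k.survival_at(curve, 83.9) == 1.0

    def test_negative_time_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            k.survival_at(k.km_estimate(tiny_table), -0.1)

    def test_exponential_calibration(self):
        # S(730) = 0.72 by construction; KM at 730 days recovers it
        cfg = k.SimulationConfig(
            n_experimental=5000,
            n_control=10,
            event_hazard={"experimental": -np.log(0.72) / 730.0, "control": 1e-3},
            admin_cutoff=1000.0,
            seed=42,
        )
        trial = k.simulate_trial(cfg)
        curve = k.km_estimate(trial.observed, arm="experimental")
        assert k.survival_at(curve, 730.0) == pytest.approx(0.72, abs=0.02)


class TestLogRank:
    def test_identical_arms_null(self, tiny_table):
        other = tiny_table.assign(arm="control", subject_id=["d", "e", "f"])
        res = k.logrank_test(pd.concat([tiny_table, other], ignore_index=True))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert sum(res.observed_events) == 4
        assert sum(res.expected_events) == pytest.approx(4.0)

    def test_arm_swap_invariance(self, two_arm_table):
        swapped = two_arm_table.assign(
            arm=two_arm_table["arm"].map(
                {"experimental": "control", "control": "experimental"}
            )
        )
        a, b = k.logrank_test(two_arm_table), k.logrank_test(swapped)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.observed_events == b.observed_events[::-1]

    def test_against_exhaustive_permutation_oracle(self):
        """Chi-square p agrees with the exact permutation-of-labels null."""
        times = np.array([2.0, 6.0, 9.0, 12.0, 1.0, 3.0, 5.0, 7.0])
        status = np.array([1, 1, 0, 1, 1, 1, 1, 0])

        def run(labels):
            df = k.make_ipd_table(
                [f"s{j}" for j in range(8)], list(labels), times, status
            )
            return k.logrank_test(df)

        observed = run(["experimental"] * 4 + ["control"] * 4)
        perm_stats = []
        for idx in combinations(range(8), 4):
            labels = ["control"] * 8
            for i in idx:
                labels[i] = "experimental"
            perm_stats.append(run(labels).statistic)
        perm_p = float(np.mean(np.asarray(perm_stats) >= observed.statistic - 1e-12))
        assert observed.p_value == pytest.approx(perm_p, abs=0.03)

    def test_errors(self, tiny_table):
        with pytest.raises(ValueError, match="both arms"):
            k.logrank_test(tiny_table)
        no_events = k.make_ipd_table(
            ["a", "b"], ["experimental", "control"], [1.0, 2.0], [0, 0]
        )
        with pytest.raises(ValueError, match="test undefined"):
            k.logrank_test(no_events)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    times=st.lists(st.floats(0.1, 100), min_size=4, max_size=20),
    data=st.data(),
)
def test_km_curve_invariants_hold_on_random_tables(times, data):
    """Any estimated curve satisfies its structural invariants."""
    status = data.draw(
        st.lists(st.integers(0, 1), min_size=len(times), max_size=len(times))
    )
    df = k.make_ipd_table(
        [f"s{i}" for i in range(len(times))],
        ["experimental"] * len(times),
        times,
        status,
    )
    curve = k.km_estimate(df)  # __post_init__ enforces invariants
    assert curve.survival[0] == 1.0
    assert np.all(np.diff(curve.survival) <= 0)
    t = df["time_days"].to_numpy()
    # risk-set bookkeeping: n_at_risk counts subjects with time >= step time
    for u, n in zip(curve.risk_times, curve.n_at_risk):
        assert n == int(np.sum(t >= u))
    # order invariance
    shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    assert k.km_estimate(shuffled) == curve
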