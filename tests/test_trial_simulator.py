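"""Tests for the synthetic trial generator and the design-window rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kmsens as k
from kmsens.trial_simulator import MEDIAN_FOLLOWUP_DAYS, censoring_hazard_for_rate


class TestDesignWindows:
    def test_default_windows_23_and_12_weeks(self):
        spec = k.DesignSpec()
        assert k.max_preadjuvant_window(spec, "experimental") == 161.0  # 23 wk
        assert k.max_preadjuvant_window(spec, "control") == 84.0  # 12 wk

    def test_degenerate_spec(self):
        spec = k.DesignSpec(
            cycle_length=0, n_neoadjuvant_cycles=0, max_surgery_delay=0, max_adjuvant_delay=0
        )
        assert k.max_preadjuvant_window(spec, "experimental") == 0.0
        assert k.max_preadjuvant_window(spec, "control") == 0.0

    def test_unknown_arm(self):
        with pytest.raises(ValueError):
            k.max_preadjuvant_window(k.DesignSpec(), "placebo")


def manual_trial(arm, raw_time, failure, design=None):
    """Single-subject SimulatedTrial with hand-set latent truth."""
    truth = pd.DataFrame(
        {
            "subject_id": ["s0"],
            "arm": [arm],
            "frailty": [1.0],
            "latent_event_time": [raw_time],
            "latent_censor_time": [np.inf],
            "preadjuvant_failure": [failure],
            "preadjuvant_failure_time": [raw_time],
            "raw_event_time": [raw_time],
            "raw_status": [1],
        }
    )
    design = design or k.DesignSpec()
    return k.SimulatedTrial(
        observed=pd.DataFrame(), truth=truth, config=k.SimulationConfig(), design=design
    )


class TestDay84Rule:
    def test_early_failure_pushed_later(self):
        # raw event at day 30 -> assigned day 84: guarantee-time bias
        out = k.apply_day84_rule(manual_trial("experimental", 30.0, True))
        assert out["time_days"].iloc[0] == 84.0
        assert out["status"].iloc[0] == 1

    def test_late_failure_pulled_earlier(self):
        # raw event at day 150 (within the 161-day window) -> day 84
        out = k.apply_day84_rule(manual_trial("experimental", 150.0, True))
        assert out["time_days"].iloc[0] == 84.0

    def test_non_failure_unchanged(self):
        out = k.apply_day84_rule(manual_trial("experimental", 300.0, False))
        assert out["time_days"].iloc[0] == 300.0

    def test_rule_signature_on_and_off(self):
        """ON: every pre-adjuvant failure sits at exactly day 84 (the KM
        vertical drop). OFF: failure times disperse within 161/84 days."""
        cfg = k.SimulationConfig(
            n_experimental=300,
            n_control=300,
            preadjuvant_failure_prob={"experimental": 0.2, "control": 0.15},
            seed=8,
        )
        on = k.simulate_trial(cfg, k.DesignSpec(day84_rule=True))
        fails = on.truth["preadjuvant_failure"].to_numpy()
        assert fails.any()
        assert (on.observed.loc[fails, "time_days"] == 84.0).all()
        assert (on.observed.loc[fails, "status"] == 1).all()

        off = k.simulate_trial(cfg, k.DesignSpec(day84_rule=False))
        ft = off.observed.loc[fails]
        exp, ctl = ft[ft["arm"] == "experimental"], ft[ft["arm"] == "control"]
        assert float(exp["time_days"].max()) <= 161.0
        assert float(ctl["time_days"].max()) <= 84.0
        assert ft["time_days"].nunique() > 10  # dispersed, not a point mass


class TestSimulateTrial:
    def test_null_hazards_all_censored_at_cutoff(self):
        cfg = k.SimulationConfig(
            n_experimental=20,
            n_control=20,
            event_hazard={"experimental": 0.0, "control": 0.0},
            admin_cutoff=730.0,
            seed=1,
        )
        trial = k.simulate_trial(cfg)
        assert (trial.observed["status"] == 0).all()
        assert (trial.observed["time_days"] == 730.0).all()

    def test_same_seed_bitwise_identical(self):
        cfg, design = k.s1801_like(seed=12)
        a = k.simulate_trial(cfg, design, seed=12)
        b = k.simulate_trial(cfg, design, seed=12)
        assert a.observed.equals(b.observed)
        assert a.truth.equals(b.truth)

    def test_frailty_couples_event_and_censor_times(self):
        base = dict(
            n_experimental=2000,
            n_control=10,
            event_hazard={"experimental": 2e-3, "control": 2e-3},
            censoring_hazard={"experimental": 1e-3, "control": 1e-3},
            seed=4,
        )
        dep = k.simulate_trial(k.SimulationConfig(frailty_variance=1.0, **base))
        ind = k.simulate_trial(k.SimulationConfig(frailty_variance=0.0, **base))
        for trial, check in ((dep, lambda r: r > 0.2), (ind, lambda r: abs(r) < 0.05)):
            sub = trial.truth[trial.truth["arm"] == "experimental"]
            rho = stats.spearmanr(
                sub["latent_event_time"], sub["latent_censor_time"]
            ).statistic
            assert check(float(rho))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            k.SimulationConfig(event_hazard={"experimental": -1e-3, "control": 1e-3})
        with pytest.raises(ValueError):
            k.SimulationConfig(frailty_variance=-0.5)


class TestRenderKMCoordinates:
    def test_no_event_arm_renders_flat_curve(self):
        df = k.make_ipd_table(
            ["a", "b", "c"], ["control"] * 3, [100.0, 200.0, 300.0], [0, 0, 0]
        )
        rendered = k.render_km_coordinates(df, [0.0, 150.0, 250.0])
        assert np.allclose(rendered.coords[:, 1], 1.0)
        assert rendered.n_at_risk.tolist() == [3, 2, 1]

    def test_empty_arm_rejected(self, s1801_trial):
        ctl_only = s1801_trial.observed.query("arm == 'control'")
        with pytest.raises(ValueError, match="empty arm"):
            k.render_km_coordinates(ctl_only, [0.0], arm="experimental")


class TestPreset:
    def test_s1801_like_calibration(self):
        """Hazards invert the published 2-year EFS; censoring hazards hit the
        published first-6-month censoring fractions in expectation."""
        cfg, design = k.s1801_like()
        assert (cfg.n_experimental, cfg.n_control) == (154, 159)
        assert np.exp(-cfg.event_hazard["experimental"] * 730.0) == pytest.approx(0.72)
        assert np.exp(-cfg.event_hazard["control"] * 730.0) == pytest.approx(0.49)
        assert cfg.admin_cutoff == pytest.approx(MEDIAN_FOLLOWUP_DAYS)
        six = 6 * k.DAYS_PER_MONTH
        for arm, target in (("experimental", 0.175), ("control", 0.119)):
            lc, le = cfg.censoring_hazard[arm], cfg.event_hazard[arm]
            lam = lc + le
            p_cens = lc / lam * (1 - np.exp(-lam * six))
            assert p_cens == pytest.approx(target, abs=1e-9)

    def test_censoring_hazard_solver_validates(self):
        with pytest.raises(ValueError):
            censoring_hazard_for_rate(1.5, 1e-3, 180.0)
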