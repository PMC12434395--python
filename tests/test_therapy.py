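import dataclasses
import math

import numpy as np
import pytest

from atcost.growth import LN2
from atcost.simulate import SimConfig, default_invivo_model, gen_drug_pulse
from atcost.therapy import (
    CourseInit,
    DrugEffectParams,
    TherapyProtocol,
    TrialSettings,
    _make_kill,
    drug_kill_rate,
    kaplan_meier_logrank,
    next_dose,
    run_course,
    run_trial,
)

DETERMINISTIC = TrialSettings(size_jitter_cv=0.0, rate_heterogeneity_cv=0.0)


def kernel_peak_time(dose: float, p: DrugEffectParams) -> float:
    frac = dose / (dose + p.ec50)
    mean = p.lag_mean * (1.0 - p.dose_acceleration * frac)
    return (p.lag_shape - 1.0) * mean / p.lag_shape


class TestDrugKillRate:
    def test_zero_dose_kills_nothing(self, drug):
        tau = np.linspace(0, drug.effect_duration, 20)
        assert np.all(drug_kill_rate(0.0, tau, drug) == 0)

    def test_emax_midpoint_at_effect_peak(self, drug):
        # at dose = EC50 the rate at the kernel peak is kill_max / 2
        peak = kernel_peak_time(drug.ec50, drug)
        assert drug_kill_rate(drug.ec50, peak, drug) == pytest.approx(drug.kill_max / 2, rel=1e-9)

    def test_saturation_plateau(self, drug):
        peak = kernel_peak_time(1e9, drug)
        assert drug_kill_rate(1e9, peak, drug) == pytest.approx(drug.kill_max, rel=1e-3)

    def test_resistant_scaling(self, drug):
        tau = 5.0
        full = drug_kill_rate(1.0, tau, drug)
        res = drug_kill_rate(1.0, tau, drug, resistant=True)
        assert res == pytest.approx(full * drug.resistance_factor)

    def test_truncated_after_effect_duration(self, drug):
        assert drug_kill_rate(1.0, drug.effect_duration + 0.1, drug) == 0.0

    def test_kernel_peak_earlier_at_higher_dose(self, drug):
        assert kernel_peak_time(1.0, drug) < kernel_peak_time(0.1, drug)

    def test_negative_time_rejected(self, drug):
        with pytest.raises(ValueError):
            drug_kill_rate(1.0, -0.5, drug)


@pytest.fixture(scope="module")
def pulse_trajectories():
    cfg = SimConfig(seed=1, noise_cv=0.0, sampling_times=tuple(np.arange(0, 28.25, 0.25)))
    from atcost.simulate import default_invitro_model

    return gen_drug_pulse(default_invitro_model(), DrugEffectParams(), [0.0, 0.1, 0.5, 1.0], cfg)


class TestDrugPulseDynamics:
    @staticmethod
    def sensitive_fraction(traj):
        s = traj.pivot("sensitive")[0].to_numpy()
        r = traj.pivot("resistant")[0].to_numpy()
        return np.asarray(traj.times, dtype=float), s / (s + r)

    def test_null_dose_matches_untreated(self, pulse_trajectories, invitro_model, noiseless_config):
        from atcost.simulate import gen_coculture

        cfg = SimConfig(seed=1, noise_cv=0.0, sampling_times=tuple(np.arange(0, 28.25, 0.25)))
        untreated = gen_coculture(invitro_model, (0.5, 0.5), 2.5e5, cfg)
        t, f0 = self.sensitive_fraction(pulse_trajectories[0.0])
        _, fu = self.sensitive_fraction(untreated)
        assert f0 == pytest.approx(fu, rel=1e-9)

    def test_nadir_deeper_and_not_later_at_higher_dose(self, pulse_trajectories):
        lags, depths = [], []
        for dose in (0.1, 0.5, 1.0):
            t, f = self.sensitive_fraction(pulse_trajectories[dose])
            post = t > 6.0
            i = np.argmin(f[post])
            lags.append(t[post][i] - 6.0)
            depths.append(f[post][i])
        assert lags[0] >= lags[1] >= lags[2]
        assert depths[0] > depths[1] > depths[2]

    def test_nadir_lag_within_observed_window(self, pulse_trajectories):
        for dose in (0.1, 0.5, 1.0):
            t, f = self.sensitive_fraction(pulse_trajectories[dose])
            post = t > 6.0
            lag = t[post][np.argmin(f[post])] - 6.0
            assert 5.0 <= lag <= 12.0

    def test_sensitive_recovers_after_nadir(self, pulse_trajectories):
        t, f = self.sensitive_fraction(pulse_trajectories[1.0])
        post = t > 6.0
        i = np.argmin(f[post])
        assert f[post][-1] > f[post][i]

    def test_resistant_nadir_monotone_in_resistance_factor(self, invitro_model):
        cfg = SimConfig(seed=1, noise_cv=0.0, sampling_times=tuple(np.arange(0, 28.5, 0.5)))
        mins = []
        for rf in (0.0, 0.5, 1.0):
            drug = DrugEffectParams(resistance_factor=rf)
            traj = gen_drug_pulse(invitro_model, drug, [1.0], cfg)[1.0]
            mins.append(traj.pivot("resistant")[0].to_numpy().min())
        assert mins[0] >= mins[1] >= mins[2]

    def test_negative_dose_rejected(self, invitro_model, drug, noiseless_config):
        with pytest.raises(ValueError):
            gen_drug_pulse(invitro_model, drug, [-0.5], noiseless_config)


class TestDoseController:
    def test_st_gives_three_doses_then_stops(self):
        st = TherapyProtocol.standard()
        assert next_dose(st, 500, 500, 60.0, n_given=0) == 60.0
        assert next_dose(st, 500, 500, 60.0, n_given=2) == 60.0
        assert next_dose(st, 500, 500, 60.0, n_given=3) == 0.0
        assert next_dose(st, 2000, 500, 60.0, n_given=5) == 0.0

    def test_at_unchanged_volume_keeps_dose(self):
        at = TherapyProtocol.adaptive()
        assert next_dose(at, 500.0, 500.0, 30.0) == 30.0

    def test_at_growth_escalates_with_cap(self):
        at = TherapyProtocol.adaptive()
        assert next_dose(at, 600.0, 500.0, 30.0) == 45.0
        assert next_dose(at, 600.0, 500.0, 60.0) == 60.0  # capped

    def test_at_shrinking_tumor_reaches_omission(self):
        # repeatedly shrinking tumor: dose halves until omitted (<1 mg/kg)
        at = TherapyProtocol.adaptive()
        dose = at.initial_dose
        doses = []
        v = 500.0
        for _ in range(10):
            new_v = v * 0.8
            dose = next_dose(at, new_v, v, dose if dose > 0 else 0.9375)
            doses.append(dose)
            v = new_v
        administered = [d for d in doses]
        assert all(b <= a for a, b in zip(administered, administered[1:]))
        assert administered[-1] == 0.0
        assert any(0 < d < 3.0 for d in administered)  # very low doses en route

    def test_vehicle_never_doses(self):
        veh = TherapyProtocol.vehicle()
        assert next_dose(veh, 2000.0, 500.0, 60.0) == 0.0

    def test_band_table_must_cover_real_line(self):
        with pytest.raises(ValueError):
            TherapyProtocol("AT", rule_table=((0.1, math.inf, 1.5), (-0.1, 0.1, 1.0)))

    def test_protocol_yaml_round_trip(self, tmp_path):
        at = TherapyProtocol.adaptive()
        path = tmp_path / "at.yaml"
        at.to_yaml(path)
        assert TherapyProtocol.from_yaml(path) == at


class TestRunCourse:
    def test_vehicle_course_equals_untreated_growth(self, invivo_model):
        from atcost.growth import simulate_competition

        init = CourseInit("m0", 8e4, 2e4, 8e4, 2e4)
        course = run_course(invivo_model, DrugEffectParams.in_vivo(), TherapyProtocol.vehicle(), init, DETERMINISTIC)
        target = course.volumes[course.volumes["flank"] == "target"].set_index("day")["volume_mm3"]
        days = np.array([d for d in target.index if d > 0])
        ode = simulate_competition(invivo_model, 8e4, 2e4, np.concatenate([[0.0], days]))
        total = (
            ode.pivot("sensitive")[0].to_numpy() + ode.pivot("resistant")[0].to_numpy()
        ) / 1e4
        assert target.loc[days].to_numpy() == pytest.approx(total[1:], rel=1e-4)

    def test_st_cumulative_dose_is_three_times_dose(self, invivo_model):
        init = CourseInit("m0", 1e5, 0.0, 1e5, 0.0)
        course = run_course(invivo_model, DrugEffectParams.in_vivo(), TherapyProtocol.standard(), init, DETERMINISTIC)
        assert course.cumulative_dose == pytest.approx(180.0)
        assert course.cumulative_dose == sum(d for _, d in course.dose_log)
        days = [d for d, _ in course.dose_log]
        assert np.diff(days) == pytest.approx([4.0, 4.0])

    def test_sensitive_tumor_regrows_after_st(self, invivo_model):
        init = CourseInit("m0", 1e5, 0.0, 1e5, 0.0)
        course = run_course(invivo_model, DrugEffectParams.in_vivo(), TherapyProtocol.standard(), init, DETERMINISTIC)
        target = course.volumes[course.volumes["flank"] == "target"].set_index("day")["volume_mm3"]
        last_dose_day = course.dose_log[-1][0]
        after = target[target.index > last_dose_day]
        nadir_day = after.idxmin()
        assert course.event_observed  # regrew to endpoint
        assert after.loc[after.index.max()] > after.min()
        assert nadir_day > last_dose_day

    def test_fully_resistant_with_zero_factor_matches_vehicle(self, invivo_model):
        drug0 = dataclasses.replace(DrugEffectParams.in_vivo(), resistance_factor=0.0)
        init = CourseInit("m0", 0.0, 1e5, 0.0, 1e5)
        events = []
        for proto in (TherapyProtocol.vehicle(), TherapyProtocol.standard(), TherapyProtocol.adaptive()):
            course = run_course(invivo_model, drug0, proto, init, DETERMINISTIC)
            events.append(course.event_day)
        assert abs(events[1] - events[0]) <= 1.0
        assert abs(events[2] - events[0]) <= 1.0

    def test_at_decisions_ignore_nontarget_flank(self, invivo_model):
        # same target burden, very different nontarget burden: the dose
        # sequence must agree while both courses are still on study
        drug = DrugEffectParams.in_vivo()
        a = run_course(
            invivo_model, drug, TherapyProtocol.adaptive(),
            CourseInit("a", 8e4, 2e4, 4e4, 1e4), DETERMINISTIC,
        )
        b = run_course(
            invivo_model, drug, TherapyProtocol.adaptive(),
            CourseInit("b", 8e4, 2e4, 8e4, 2e4), DETERMINISTIC,
        )
        n = min(len(a.dose_log), len(b.dose_log))
        assert a.dose_log[:n] == pytest.approx(b.dose_log[:n])

    def test_competitive_release_after_st(self, invivo_model):
        # resistant per-capita growth after ST exceeds the vehicle arm's
        from atcost.growth import simulate_competition

        drug = DrugEffectParams.in_vivo()
        dose_log = [(0.0, 60.0), (4.0, 60.0), (8.0, 60.0)]
        kill = _make_kill(dose_log, drug)
        days = np.linspace(0, 30, 61)
        treated = simulate_competition(invivo_model, 2.4e6, 6e5, days, kill=kill)
        vehicle = simulate_competition(invivo_model, 2.4e6, 6e5, days)
        window = (days >= 15) & (days <= 25)

        def rate(traj):
            r = traj.pivot("resistant")[0].to_numpy()
            return np.diff(np.log(r[window])).mean()

        assert rate(treated) > rate(vehicle)


def brute_force_logrank(d1, e1, d2, e2):
    """Independent Mantel-Cox computation from the risk table."""
    d1, e1 = np.asarray(d1, float), np.asarray(e1, bool)
    d2, e2 = np.asarray(d2, float), np.asarray(e2, bool)
    event_times = np.unique(np.concatenate([d1[e1], d2[e2]]))
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = float(np.sum(d1 >= t))
        n2 = float(np.sum(d2 >= t))
        o1 = float(np.sum((d1 == t) & e1))
        o2 = float(np.sum((d2 == t) & e2))
        n, o = n1 + n2, o1 + o2
        O1 += o1
        E1 += o * n1 / n
        if n > 1:
            V += o * (n1 / n) * (1 - n1 / n) * (n - o) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestKaplanMeierLogrank:
    def test_single_group_median(self):
        res = kaplan_meier_logrank({"a": (np.array([1.0, 2.0, 3.0]), np.array([True] * 3))})
        assert res.medians["a"] == pytest.approx(2.0)

    def test_identical_groups_p_one(self):
        d = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([True, True, True, True])
        res = kaplan_meier_logrank({"a": (d, e), "b": (d.copy(), e.copy())})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_risk_table(self):
        # 20-subject fixture with censoring and tied event times
        rng = np.random.default_rng(42)
        d1 = np.round(rng.exponential(10, 10), 0) + 1
        d2 = np.round(rng.exponential(20, 10), 0) + 1
        e1 = rng.random(10) < 0.8
        e2 = rng.random(10) < 0.8
        res = kaplan_meier_logrank({"a": (d1, e1), "b": (d2, e2)})
        expected = brute_force_logrank(d1, e1, d2, e2)
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_undefined_median_reported_as_none(self):
        d = np.array([5.0, 6.0, 7.0, 8.0])
        e = np.array([True, False, False, False])  # survival never crosses 0.5
        res = kaplan_meier_logrank({"a": (d, e)})
        assert res.medians["a"] is None

    def test_all_censored_warns(self):
        d = np.array([5.0, 6.0])
        e = np.array([False, False])
        with pytest.warns(UserWarning, match="all-censored"):
            kaplan_meier_logrank({"a": (d, e)})


class TestRunTrial:
    def test_separated_arms_have_expected_medians(self):
        # direct log-rank sanity on fully separated synthetic survival data
        a = (np.full(10, 5.0), np.full(10, True))
        b = (np.full(10, 10.0), np.full(10, True))
        res = kaplan_meier_logrank({"A": a, "B": b})
        assert res.medians["A"] == pytest.approx(5.0)
        assert res.medians["B"] == pytest.approx(10.0)
        assert res.p_value < 0.01

    def test_trial_smoke_and_dose_accounting(self, invivo_model):
        res = run_trial(
            invivo_model,
            DrugEffectParams.in_vivo(),
            {"80:20": 0.8},
            [TherapyProtocol.standard(), TherapyProtocol.vehicle()],
            n_per_arm=2,
            seed=0,
        )
        st = res.arm("80:20", "ST")
        assert len(st) == 2
        assert st["cumulative_dose"].to_numpy() == pytest.approx([180.0, 180.0])
        veh = res.arm("80:20", "vehicle")
        assert np.all(veh["cumulative_dose"] == 0)
        summ = res.summary()
        assert set(summ["arm"]) == {"ST", "vehicle"}

    def test_trial_reproducible(self, invivo_model):
        kw = dict(
            cohorts={"80:20": 0.8},
            arms=[TherapyProtocol.standard()],
            n_per_arm=2,
            seed=7,
        )
        r1 = run_trial(invivo_model, DrugEffectParams.in_vivo(), **kw)
        r2 = run_trial(invivo_model, DrugEffectParams.in_vivo(), **kw)
        assert r1.mice.equals(r2.mice)

    def test_empty_arm_rejected(self, invivo_model):
        with pytest.raises(ValueError):
            run_trial(invivo_model, DrugEffectParams.in_vivo(), {"80:20": 0.8}, [TherapyProtocol.standard()], n_per_arm=1)
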