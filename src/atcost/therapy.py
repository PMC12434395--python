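"""In-silico carboplatin trial engine: drug effect model, dosing
controllers (standard vs adaptive), per-mouse tumor courses and trial-level
survival / dose endpoints.

Drug effect is an Emax dose response, kill_max * dose / (dose + ec50),
shaped in time by a gamma delay kernel normalized to unit peak and
truncated at effect_duration, so the instantaneous per-day kill rate at
the effect peak of an EC50 dose is kill_max / 2.  The resistant population
receives the same rate scaled by resistance_factor.  Higher doses act
earlier: the kernel mean contracts as lag_mean * (1 - accel * dose /
(dose + ec50)).

The adaptive controller re-evaluates the dose at a fixed interval from the
fractional change of the *target* tumor volume since the last decision; it
never consults the nontarget flank.  The internal dose state can fall
below min_dose (dose omitted) and climb back on regrowth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.stats import gamma as gamma_dist

from .growth import LN2, CompetitionModel

__all__ = [
    "DrugEffectParams",
    "TherapyProtocol",
    "CourseInit",
    "TumorCourse",
    "TrialSettings",
    "TrialResult",
    "drug_kill_rate",
    "next_dose",
    "run_course",
    "run_trial",
    "kaplan_meier_logrank",
    "LogrankResult",
]


@dataclass(frozen=True)
class DrugEffectParams:
    """Dose-response and delay-kernel parameters for platinum kill.

    Units of ec50 (and doses) are mg/kg in vivo or umol/L in vitro; the
    model is agnostic.  lag_mean/lag_shape parameterize the gamma delay
    kernel (mean in days, dimensionless shape > 1); effect_duration
    truncates the kernel; resistance_factor in [0, 1] scales the kill rate
    for the resistant population; dose_acceleration in [0, 1) contracts the
    kernel mean at high dose.
    """

    kill_max: float = 1.0
    ec50: float = 0.3
    lag_mean: float = 7.0
    lag_shape: float = 8.0
    effect_duration: float = 12.0
    resistance_factor: float = 0.2
    dose_acceleration: float = 0.5

    def __post_init__(self) -> None:
        if self.kill_max < 0:
            raise ValueError("kill_max must be >= 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if not (0 <= self.resistance_factor <= 1):
            raise ValueError("resistance_factor must be in [0, 1]")
        if self.lag_shape <= 1:
            raise ValueError("lag_shape must be > 1 (kernel needs an interior peak)")
        if not (0 <= self.dose_acceleration < 1):
            raise ValueError("dose_acceleration must be in [0, 1)")

    @classmethod
    def in_vivo(cls) -> "DrugEffectParams":
        """Carboplatin preset for the mouse trial engine (doses in mg/kg)."""
        return cls(
            kill_max=1.2,
            ec50=20.0,
            lag_mean=3.0,
            lag_shape=3.0,
            effect_duration=7.0,
            resistance_factor=0.1,
            dose_acceleration=0.3,
        )


def _kernel(dose: float, tau: np.ndarray | float, p: DrugEffectParams) -> np.ndarray | float:
    """Unit-peak gamma delay kernel, dose-contracted mean, truncated."""
    emax_frac = dose / (dose + p.ec50)
    mean = p.lag_mean * (1.0 - p.dose_acceleration * emax_frac)
    scale = mean / p.lag_shape
    mode = (p.lag_shape - 1.0) * scale
    peak = gamma_dist.pdf(mode, a=p.lag_shape, scale=scale)
    val = gamma_dist.pdf(tau, a=p.lag_shape, scale=scale) / peak
    return np.where(np.asarray(tau) <= p.effect_duration, val, 0.0)


def drug_kill_rate(dose: float, time_since_dose, p: DrugEffectParams, resistant: bool = False):
    """Per-day kill rate at a given time after one dose.

    Emax dose response modulated by the delay kernel; the resistant
    population receives the rate times resistance_factor.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    tau = np.asarray(time_since_dose, dtype=float)
    if np.any(tau < 0):
        raise ValueError("time_since_dose must be >= 0")
    if dose == 0:
        out = np.zeros_like(tau)
        return float(out) if out.ndim == 0 else out
    rate = p.kill_max * dose / (dose + p.ec50) * _kernel(dose, tau, p)
    if resistant:
        rate = rate * p.resistance_factor
    return float(rate) if np.ndim(rate) == 0 else rate


# ---------------------------------------------------------------------------
# Protocols and dose controller

# (low, high, multiplier) bands on fractional volume change since the last
# dosing decision; reconstruction constrained by the printed protocol facts
# (initial 60 mg/kg, weekly interval, doses reaching <3 mg/kg or omission).
DEFAULT_AT_BANDS: tuple[tuple[float, float, float], ...] = (
    (0.10, math.inf, 1.5),
    (-0.10, 0.10, 1.0),
    (-math.inf, -0.10, 0.5),
)


@dataclass(frozen=True)
class TherapyProtocol:
    """Dosing protocol: fixed-course standard therapy, response-adaptive
    therapy, or vehicle.  Dose decisions use the target tumor only."""

    name: str
    initial_dose: float = 60.0
    interval: float = 7.0
    n_doses: int | None = None  # ST only
    rule_table: tuple[tuple[float, float, float], ...] = DEFAULT_AT_BANDS
    min_dose: float = 1.0
    max_dose: float = 60.0

    def __post_init__(self) -> None:
        if self.name not in ("ST", "AT", "vehicle"):
            raise ValueError("protocol name must be ST, AT or vehicle")
        for lo, hi, mult in self.rule_table:
            if mult < 0:
                raise ValueError("band multipliers must be >= 0")
        # bands must partition the real line
        bands = sorted(self.rule_table, key=lambda b: b[0])
        if bands[0][0] != -math.inf or bands[-1][1] != math.inf:
            raise ValueError("rule_table bands must cover the real line")
        for (lo1, hi1, _), (lo2, hi2, _) in zip(bands, bands[1:]):
            if hi1 != lo2:
                raise ValueError("rule_table bands must be contiguous")

    @classmethod
    def standard(cls, dose: float = 60.0) -> "TherapyProtocol":
        return cls("ST", initial_dose=dose, interval=4.0, n_doses=3)

    @classmethod
    def adaptive(cls, dose: float = 60.0) -> "TherapyProtocol":
        return cls("AT", initial_dose=dose, interval=7.0)

    @classmethod
    def vehicle(cls) -> "TherapyProtocol":
        return cls("vehicle", initial_dose=0.0, interval=4.0, n_doses=3)

    def to_yaml(self, path) -> None:
        d = {
            "name": self.name,
            "initial_dose": self.initial_dose,
            "interval": self.interval,
            "n_doses": self.n_doses,
            "min_dose": self.min_dose,
            "max_dose": self.max_dose,
            "rule_table": [
                [None if not math.isfinite(lo) else lo, None if not math.isfinite(hi) else hi, m]
                for lo, hi, m in self.rule_table
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TherapyProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bands = tuple(
            (
                -math.inf if lo is None else float(lo),
                math.inf if hi is None else float(hi),
                float(m),
            )
            for lo, hi, m in d.get("rule_table", [list(b) for b in DEFAULT_AT_BANDS])
        )
        return cls(
            name=d["name"],
            initial_dose=float(d.get("initial_dose", 60.0)),
            interval=float(d.get("interval", 7.0)),
            n_doses=d.get("n_doses"),
            rule_table=bands,
            min_dose=float(d.get("min_dose", 1.0)),
            max_dose=float(d.get("max_dose", 60.0)),
        )


def next_dose(
    protocol: TherapyProtocol,
    target_volume_now: float,
    target_volume_at_last_dose: float,
    last_dose: float,
    n_given: int = 0,
) -> float:
    """Administered dose (mg/kg) at the next decision point.

    ST returns the fixed dose while doses remain, then 0.  AT looks up the
    fractional target-volume change since the last decision in the band
    table, multiplies the previous internal dose, caps at max_dose, and
    returns 0 when the result falls below min_dose (dose omitted; the
    caller keeps the internal value for later re-escalation).  The
    nontarget flank is never consulted.
    """
    if protocol.name == "vehicle":
        return 0.0
    if protocol.name == "ST":
        assert protocol.n_doses is not None
        return protocol.initial_dose if n_given < protocol.n_doses else 0.0
    # AT
    if target_volume_now <= 0 or target_volume_at_last_dose <= 0:
        raise ValueError("AT decisions need positive target volumes")
    if last_dose is None:
        raise ValueError("AT decision requires the last dose record")
    dose = _at_update(protocol, target_volume_now, target_volume_at_last_dose, last_dose)
    return dose if dose >= protocol.min_dose else 0.0


def _at_update(protocol: TherapyProtocol, v_now: float, v_ref: float, current: float) -> float:
    """Internal AT dose update: band multiplier applied to the current
    internal dose, capped at max_dose (may fall below min_dose)."""
    frac = (v_now - v_ref) / v_ref
    for lo, hi, m in protocol.rule_table:
        if lo <= frac < hi or (hi == math.inf and frac >= lo):
            return min(current * m, protocol.max_dose)
    raise AssertionError("rule_table does not cover the real line")


# ---------------------------------------------------------------------------
# Tumor courses


@dataclass(frozen=True)
class CourseInit:
    """Initial cell burdens per flank (sensitive, resistant) and a
    per-mouse growth-rate multiplier."""

    mouse_id: str
    s0_target: float
    r0_target: float
    s0_nontarget: float
    r0_nontarget: float
    rate_multiplier: float = 1.0


@dataclass(frozen=True)
class TrialSettings:
    """Shared in-vivo constants for the trial engine."""

    cells_per_mm3: float = 1e4
    enroll_volume_mm3: float = 300.0
    endpoint_volume_mm3: float = 1440.0
    max_weeks_on_study: float = 20.0
    enrollment_horizon_days: float = 120.0
    size_jitter_cv: float = 0.3
    rate_heterogeneity_cv: float = 0.1
    survival_clock: str = "injection"  # or "treatment"


@dataclass
class TumorCourse:
    """One mouse: per-flank volume series, dose log and event bookkeeping.

    ``volumes`` columns: day, flank (target|nontarget), volume_mm3.
    event_day is in days on the survival clock of the settings used.
    """

    mouse_id: str
    volumes: pd.DataFrame
    dose_log: list[tuple[float, float]]
    enrollment_day: float | None
    event_day: float | None
    event_observed: bool
    protocol_name: str = ""

    @property
    def cumulative_dose(self) -> float:
        return float(sum(d for _, d in self.dose_log))

    def days_on_study(self, end_day: float | None = None) -> float:
        if self.enrollment_day is None:
            return float("nan")
        end = self.event_day if self.event_day is not None else end_day
        return float(end - self.enrollment_day)

    @property
    def dose_per_day(self) -> float:
        days = self.days_on_study()
        return self.cumulative_dose / days if days and days > 0 else float("nan")


def _make_kill(dose_log: list[tuple[float, float]], drug: DrugEffectParams):
    def kill(t: float) -> tuple[float, float]:
        ks = 0.0
        for day, dose in dose_log:
            tau = t - day
            if dose > 0 and 0.0 <= tau <= drug.effect_duration:
                ks += drug.kill_max * dose / (dose + drug.ec50) * float(_kernel(dose, tau, drug))
        return ks, ks * drug.resistance_factor

    return kill


def run_course(
    model: CompetitionModel,
    drug: DrugEffectParams,
    protocol: TherapyProtocol,
    init: CourseInit,
    settings: TrialSettings = TrialSettings(),
) -> TumorCourse:
    """Simulate one mouse from injection to endpoint or experiment end.

    Both flanks grow by the competition model (systemic drug hits both);
    enrollment occurs on the first day either flank reaches the enrollment
    volume (that flank becomes the target), dosing decisions then follow
    the protocol at its interval, and the course stops when either flank
    reaches the endpoint volume or the study window closes.
    """
    m = model.with_rate_multiplier(init.rate_multiplier)
    gs = LN2 * m.params_s.growth_rate
    gr = LN2 * m.params_r.growth_rate
    Ks = m.params_s.carrying_capacity
    Kr = m.params_r.carrying_capacity
    a_sr, a_rs = m.alpha_sr, m.alpha_rs
    cpm = settings.cells_per_mm3
    enroll_cells = settings.enroll_volume_mm3 * cpm
    endpoint_cells = settings.endpoint_volume_mm3 * cpm

    dose_log: list[tuple[float, float]] = []
    kill = _make_kill(dose_log, drug)

    def rhs(t, y):
        out = np.empty(4)
        ks, kr = kill(t)
        for i in (0, 2):
            S = max(y[i], 0.0)
            R = max(y[i + 1], 0.0)
            out[i] = gs * S * (1.0 - (S + a_sr * R) / Ks) - ks * S
            out[i + 1] = gr * R * (1.0 - (R + a_rs * S) / Kr) - kr * R
        return out

    y = np.array(
        [init.s0_target, init.r0_target, init.s0_nontarget, init.r0_nontarget], dtype=float
    )

    records: list[tuple[float, float, float]] = []  # (day, vol_flank0, vol_flank1)

    def record(day: float, state: np.ndarray) -> None:
        records.append((day, (state[0] + state[1]) / cpm, (state[2] + state[3]) / cpm))

    def integrate(t0: float, t1: float, state: np.ndarray, threshold: float | None):
        """Integrate to t1 or to the first crossing of threshold cells by
        either flank; returns (end_time, end_state, crossed)."""
        events = None
        if threshold is not None and math.isfinite(threshold):
            ev1 = lambda t, yy: yy[0] + yy[1] - threshold
            ev2 = lambda t, yy: yy[2] + yy[3] - threshold
            ev1.terminal = ev2.terminal = True
            ev1.direction = ev2.direction = 1
            events = (ev1, ev2)
        grid = np.arange(math.ceil(t0), t1 + 1e-9, 1.0)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            state,
            method="LSODA",
            rtol=1e-8,
            atol=1e-12 * max(Ks, Kr),
            events=events,
            dense_output=True,
            max_step=1.0,
        )
        if not sol.success:
            raise RuntimeError(f"course integration failed for {init.mouse_id}: {sol.message}")
        t_end = float(sol.t[-1])
        for g in grid:
            if t0 < g <= t_end + 1e-9:
                record(float(g), sol.sol(min(g, t_end)))
        crossed = events is not None and any(len(te) for te in sol.t_events)
        return t_end, sol.y[:, -1].copy(), crossed

    # phase 1: untreated growth to enrollment
    record(0.0, y)
    t = 0.0
    t, y, enrolled = integrate(0.0, settings.enrollment_horizon_days, y, enroll_cells)
    if not enrolled:
        df = pd.DataFrame(records, columns=["day", "v0", "v1"])
        return TumorCourse(init.mouse_id, _melt_volumes(df, target=0), [], None, None, False, protocol.name)
    enrollment_day = math.ceil(t - 1e-9)
    target = 0 if (y[0] + y[1]) >= (y[2] + y[3]) else 1
    # carry growth to the (integer) enrollment day
    if enrollment_day > t:
        t, y, _ = integrate(t, float(enrollment_day), y, None)
    record(float(enrollment_day), y)

    # phase 2: treatment from enrollment
    end_day = enrollment_day + settings.max_weeks_on_study * 7.0
    vol_of = lambda state: (state[2 * target] + state[2 * target + 1]) / cpm
    current = protocol.initial_dose  # internal AT dose state
    v_ref = vol_of(y)
    n_given = 0
    event_day: float | None = None
    t = float(enrollment_day)
    decision_t = t
    first = True
    while t < end_day - 1e-9:
        if abs(t - decision_t) < 1e-9:
            if protocol.name == "vehicle":
                dose = 0.0
            elif protocol.name == "ST":
                dose = next_dose(protocol, vol_of(y), v_ref, protocol.initial_dose, n_given)
            else:  # AT: update internal state, omit below min_dose
                if not first:
                    current = _at_update(protocol, vol_of(y), v_ref, current)
                dose = current if current >= protocol.min_dose else 0.0
            if dose > 0:
                dose_log.append((t, dose))
                n_given += 1
            v_ref = vol_of(y)
            decision_t = t + protocol.interval
            first = False
        t_next = min(decision_t, end_day)
        t, y, crossed = integrate(t, t_next, y, endpoint_cells)
        if crossed:
            event_day = math.ceil(t - 1e-9)
            break

    df = pd.DataFrame(records, columns=["day", "v0", "v1"])
    observed = event_day is not None
    final_day = event_day if observed else end_day
    clock0 = 0.0 if settings.survival_clock == "injection" else float(enrollment_day)
    return TumorCourse(
        init.mouse_id,
        _melt_volumes(df, target=target),
        dose_log,
        float(enrollment_day) - clock0,
        (float(final_day) - clock0) if final_day is not None else None,
        observed,
        protocol.name,
    )


def _melt_volumes(df: pd.DataFrame, target: int) -> pd.DataFrame:
    df = df.drop_duplicates(subset="day", keep="last")
    out = pd.DataFrame(
        {
            "day": np.repeat(df["day"].to_numpy(), 2),
            "flank": ["target", "nontarget"] * len(df) if target == 0 else ["nontarget", "target"] * len(df),
            "volume_mm3": np.column_stack([df["v0"], df["v1"]]).ravel(),
        }
    )
    return out.sort_values(["day", "flank"], ignore_index=True)


# ---------------------------------------------------------------------------
# Trials


@dataclass
class LogrankResult:
    medians: dict[str, float | None]
    statistic: float | None
    p_value: float | None


def kaplan_meier_logrank(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> LogrankResult:
    """Product-limit medians per group plus the two-group Mantel-Cox test.

    ``groups`` maps label -> (durations, event flags).  Medians are None
    when the survival curve never crosses 0.5 ("median survival could not
    be defined").  The chi-square statistic/p are reported for exactly two
    groups; with one group only medians are returned.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if not groups:
        raise ValueError("no groups supplied")
    medians: dict[str, float | None] = {}
    for label, (dur, ev) in groups.items():
        dur = np.asarray(dur, dtype=float)
        ev = np.asarray(ev, dtype=bool)
        if len(dur) < 1:
            raise ValueError(f"empty group {label!r}")
        if not ev.any():
            warnings.warn(f"group {label!r} is all-censored")
        km = KaplanMeierFitter().fit(dur, ev)
        med = km.median_survival_time_
        medians[label] = None if not np.isfinite(med) else float(med)
    stat = p = None
    if len(groups) == 2:
        (d1, e1), (d2, e2) = (groups[k] for k in groups)
        res = logrank_test(d1, d2, event_observed_A=e1, event_observed_B=e2)
        stat, p = float(res.test_statistic), float(res.p_value)
    return LogrankResult(medians, stat, p)


@dataclass
class TrialResult:
    """Per-mouse endpoints for every cohort x arm, with survival and dose
    summaries."""

    mice: pd.DataFrame  # cohort, arm, mouse_id, duration_weeks, observed, cumulative_dose, dose_per_day
    courses: list[TumorCourse] = field(default_factory=list, repr=False)

    def arm(self, cohort: str, arm: str) -> pd.DataFrame:
        return self.mice[(self.mice["cohort"] == cohort) & (self.mice["arm"] == arm)]

    def median_survival_weeks(self, cohort: str, arm: str) -> float | None:
        sub = self.arm(cohort, arm)
        res = kaplan_meier_logrank({arm: (sub["duration_weeks"].to_numpy(), sub["observed"].to_numpy())})
        return res.medians[arm]

    def logrank(self, cohort: str, arm_a: str, arm_b: str) -> LogrankResult:
        a, b = self.arm(cohort, arm_a), self.arm(cohort, arm_b)
        return kaplan_meier_logrank(
            {
                arm_a: (a["duration_weeks"].to_numpy(), a["observed"].to_numpy()),
                arm_b: (b["duration_weeks"].to_numpy(), b["observed"].to_numpy()),
            }
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for (cohort, arm), sub in self.mice.groupby(["cohort", "arm"]):
            med = self.median_survival_weeks(cohort, arm)
            rows.append(
                {
                    "cohort": cohort,
                    "arm": arm,
                    "n": len(sub),
                    "events": int(sub["observed"].sum()),
                    "median_weeks": med,
                    "mean_cumulative_dose": float(sub["cumulative_dose"].mean()),
                    "mean_dose_per_day": float(sub["dose_per_day"].mean()),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "arms": s.to_dict(orient="records"),
            "mice": self.mice.to_dict(orient="records"),
        }


def draw_course_inits(
    fraction_sensitive: float,
    n_mice: int,
    rng: np.random.Generator,
    injected_cells: float = 1e5,
    settings: TrialSettings = TrialSettings(),
    prefix: str = "m",
) -> list[CourseInit]:
    """Per-mouse initial conditions: independent lognormal size jitter per
    flank plus lognormal growth-rate heterogeneity across mice.

    ``injected_cells`` is the effective engrafted burden per flank (10 mm^3
    at the 1e4 cells/mm^3 convention), not the number of cells injected;
    engraftment efficiency is folded in.
    """
    if not (0 <= fraction_sensitive <= 1):
        raise ValueError("fraction_sensitive must be in [0, 1]")
    inits = []
    sig_v = math.sqrt(math.log(1 + settings.size_jitter_cv**2))
    sig_r = math.sqrt(math.log(1 + settings.rate_heterogeneity_cv**2))
    for i in range(n_mice):
        jit = np.exp(rng.normal(0.0, sig_v, size=2)) if sig_v > 0 else np.ones(2)
        rate_mult = float(np.exp(rng.normal(0.0, sig_r))) if sig_r > 0 else 1.0
        n1, n2 = injected_cells * jit[0], injected_cells * jit[1]
        inits.append(
            CourseInit(
                mouse_id=f"{prefix}{i}",
                s0_target=n1 * fraction_sensitive,
                r0_target=n1 * (1 - fraction_sensitive),
                s0_nontarget=n2 * fraction_sensitive,
                r0_nontarget=n2 * (1 - fraction_sensitive),
                rate_multiplier=rate_mult,
            )
        )
    return inits


def run_trial(
    model: CompetitionModel,
    drug: DrugEffectParams,
    cohorts: dict[str, float],
    arms: list[TherapyProtocol],
    n_per_arm: int,
    seed: int = 0,
    settings: TrialSettings = TrialSettings(),
    keep_courses: bool = False,
) -> TrialResult:
    """Simulate a full multi-arm trial.

    ``cohorts`` maps a label (e.g. "80:20") to the injected sensitive
    fraction.  Each cohort x arm gets n_per_arm mice with independent
    initial-size jitter and growth-rate heterogeneity.  Survival durations
    are in weeks on the configured clock; mice alive at the study end are
    censored.
    """
    if n_per_arm < 2:
        raise ValueError("need n >= 2 mice per arm")
    rng = np.random.default_rng(seed)
    rows = []
    courses = []
    for cohort_label, fs in cohorts.items():
        for arm in arms:
            inits = draw_course_inits(
                fs, n_per_arm, rng, settings=settings, prefix=f"{cohort_label}-{arm.name}-"
            )
            for init in inits:
                course = run_course(model, drug, arm, init, settings)
                if course.enrollment_day is None:
                    continue
                end_rel = course.event_day
                rows.append(
                    {
                        "cohort": cohort_label,
                        "arm": arm.name,
                        "mouse_id": init.mouse_id,
                        "enrollment_day": course.enrollment_day,
                        "duration_weeks": end_rel / 7.0,
                        "observed": course.event_observed,
                        "cumulative_dose": course.cumulative_dose,
                        "dose_per_day": course.dose_per_day,
                    }
                )
                if keep_courses:
                    courses.append(course)
    return TrialResult(pd.DataFrame(rows), courses)
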