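"""Logistic and two-population competition growth models.

Growth rates are expressed throughout in doublings/day; internal
integrators convert to intrinsic exponential rates via ln 2.  The
competition model is the standard two-species Lotka-Volterra-logistic
system,

    dS/dt = ln2 * gs * S * (1 - (S + a_sr * R) / Ks)
    dR/dt = ln2 * gr * R * (1 - (R + a_rs * S) / Kr)

which reduces to two independent logistic curves when both interaction
coefficients are zero.  That decoupled system is the "predicted from
monoculture" null used to detect competition in coculture data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

LN2 = math.log(2.0)

__all__ = [
    "PopulationParams",
    "CompetitionModel",
    "Trajectory",
    "logistic_solution",
    "simulate_competition",
    "LogisticGrowthModel",
    "LogisticGrowthResults",
    "fit_monoculture",
    "predict_coculture",
    "competition_deviation",
    "sample_prediction_draws",
    "DeviationResult",
]


@dataclass(frozen=True)
class PopulationParams:
    """Per-population logistic growth parameters.

    growth_rate is in doublings/day (may be <= 0); carrying_capacity in
    cells and must be positive.
    """

    growth_rate: float
    carrying_capacity: float
    label: str = "population"

    def __post_init__(self) -> None:
        if not math.isfinite(self.growth_rate):
            raise ValueError("growth_rate must be finite")
        if not (self.carrying_capacity > 0):
            raise ValueError("carrying_capacity must be > 0")


@dataclass(frozen=True)
class CompetitionModel:
    """Paired sensitive/resistant logistic parameters plus interaction terms.

    alpha_sr is the per-capita effect of the resistant population on the
    sensitive one, alpha_rs the converse.  alpha = 1 on both sides models a
    fully shared resource pool (one effective carrying capacity).
    """

    params_s: PopulationParams
    params_r: PopulationParams
    alpha_sr: float = 1.0
    alpha_rs: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_sr < 0 or self.alpha_rs < 0:
            raise ValueError("competition coefficients must be >= 0")

    def with_rate_multiplier(self, m: float) -> "CompetitionModel":
        """Scale both growth rates (per-mouse heterogeneity)."""
        return CompetitionModel(
            replace(self.params_s, growth_rate=self.params_s.growth_rate * m),
            replace(self.params_r, growth_rate=self.params_r.growth_rate * m),
            self.alpha_sr,
            self.alpha_rs,
        )


TRAJECTORY_COLUMNS = [
    "time_days",
    "population",
    "count",
    "replicate",
    "condition",
    "seeding_ratio",
]


@dataclass
class Trajectory:
    """Tidy per-population count time series.

    ``data`` has columns time_days, population, count, replicate,
    condition, seeding_ratio.  ``ground_truth`` carries the generating
    parameters when the trajectory is synthetic.
    """

    data: pd.DataFrame
    condition: str = ""
    seeding_ratio: str = ""
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("time_days", "population", "count") if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory missing columns: {missing}")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=0)
        if "condition" not in self.data.columns:
            self.data = self.data.assign(condition=self.condition)
        if "seeding_ratio" not in self.data.columns:
            self.data = self.data.assign(seeding_ratio=self.seeding_ratio)
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be >= 0")
        for (_, _), grp in self.data.groupby(["population", "replicate"]):
            t = grp["time_days"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing within a series")

    @classmethod
    def from_arrays(
        cls,
        times: Sequence[float],
        counts: Mapping[str, np.ndarray],
        condition: str = "",
        seeding_ratio: str = "",
        ground_truth: object | None = None,
    ) -> "Trajectory":
        """Build a trajectory from arrays shaped (n_times,) or (n_rep, n_times)."""
        times = np.asarray(times, dtype=float)
        rows = []
        for pop, arr in counts.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            for rep in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_days": times,
                            "population": pop,
                            "count": arr[rep],
                            "replicate": rep,
                            "condition": condition,
                            "seeding_ratio": seeding_ratio,
                        }
                    )
                )
        data = pd.concat(rows, ignore_index=True)
        return cls(data, condition, seeding_ratio, ground_truth)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.data["time_days"].to_numpy())

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.data["replicate"].nunique())

    def pivot(self, population: str) -> pd.DataFrame:
        """Wide table for one population: index time, one column per replicate."""
        sub = self.data[self.data["population"] == population]
        if sub.empty:
            raise KeyError(f"population {population!r} not in trajectory")
        return sub.pivot_table(index="time_days", columns="replicate", values="count")

    def plot(self, ax=None):
        """Mean +/- SD abundance per population over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for pop in self.populations:
            wide = self.pivot(pop)
            m = wide.mean(axis=1)
            s = wide.std(axis=1)
            ax.plot(wide.index, m, label=pop)
            ax.fill_between(wide.index, m - s, m + s, alpha=0.2)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("cells")
        ax.legend()
        return ax


def logistic_solution(n0: float, p: PopulationParams, t) -> np.ndarray:
    """Closed-form logistic curve N(t) with N(0)=n0 and ceiling K.

    The intrinsic exponential rate is ln2 * growth_rate so that
    growth_rate is in doublings/day: with K >> n0, N(1 day) = 2 n0 at
    growth_rate 1.
    """
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    t = np.asarray(t, dtype=float)
    if n0 == 0:
        return np.zeros_like(t)
    K = p.carrying_capacity
    r = LN2 * p.growth_rate
    with np.errstate(over="ignore"):
        denom = 1.0 + (K / n0 - 1.0) * np.exp(-r * t)
    return K / denom


def simulate_competition(
    model: CompetitionModel,
    n0_s: float,
    n0_r: float,
    times,
    kill: Callable[[float], tuple[float, float]] | None = None,
    rtol: float = 1e-10,
    atol: float | None = None,
) -> Trajectory:
    """Integrate the two-population competition ODE on a time grid.

    ``kill``, if given, maps absolute time to per-day removal rates
    (kappa_s, kappa_r) subtracted from the per-capita growth of each
    population (used for drug-pulse and therapy simulations).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    if n0_s < 0 or n0_r < 0:
        raise ValueError("initial counts must be >= 0")
    gs = LN2 * model.params_s.growth_rate
    gr = LN2 * model.params_r.growth_rate
    Ks = model.params_s.carrying_capacity
    Kr = model.params_r.carrying_capacity
    a_sr, a_rs = model.alpha_sr, model.alpha_rs

    def rhs(t, y):
        S, R = y
        S = max(S, 0.0)
        R = max(R, 0.0)
        dS = gs * S * (1.0 - (S + a_sr * R) / Ks)
        dR = gr * R * (1.0 - (R + a_rs * S) / Kr)
        if kill is not None:
            ks, kr = kill(t)
            dS -= ks * S
            dR -= kr * R
        return (dS, dR)

    if atol is None:
        atol = 1e-10 * max(Ks, Kr)
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        (float(n0_s), float(n0_r)),
        t_eval=times,
        method="DOP853" if kill is None else "LSODA",
        rtol=rtol,
        atol=atol,
        max_step=0.5 if kill is not None else np.inf,
    )
    if not sol.success:
        raise RuntimeError(
            f"competition integration failed ({sol.message}); "
            f"params: gs={model.params_s.growth_rate}, gr={model.params_r.growth_rate}, "
            f"Ks={Ks}, Kr={Kr}, alpha=({a_sr},{a_rs})"
        )
    S = np.clip(sol.y[0], 0.0, None)
    R = np.clip(sol.y[1], 0.0, None)
    return Trajectory.from_arrays(times, {"sensitive": S, "resistant": R})


def predict_coculture(
    params_s: PopulationParams,
    params_r: PopulationParams,
    n0_s: float,
    n0_r: float,
    times,
) -> Trajectory:
    """Independent-growth null: each population grows logistically from its
    coculture seeding density, ignoring the other (alpha = 0)."""
    model = CompetitionModel(params_s, params_r, alpha_sr=0.0, alpha_rs=0.0)
    return simulate_competition(model, n0_s, n0_r, times)


# ---------------------------------------------------------------------------
# Monoculture fitting


class LogisticGrowthModel:
    """Nonlinear least-squares logistic fit to count data.

    By default the fit is on log-counts (multiplicative measurement-noise
    assumption); pass ``log_scale=False`` for linear-scale residuals.
    Replicates enter as independent points.
    """

    def __init__(self, times, counts, log_scale: bool = True, label: str = "population"):
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if times.shape != counts.shape:
            raise ValueError("times and counts must be aligned 1-d arrays")
        keep = counts > 0
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            warnings.warn(f"dropping {self.n_dropped} nonpositive counts before logistic fit")
        self.times = times[keep]
        self.counts = counts[keep]
        if len(self.counts) == 0:
            raise ValueError("no positive counts to fit")
        self.log_scale = log_scale
        self.label = label

    @classmethod
    def from_trajectory(cls, traj: Trajectory, population: str, **kw) -> "LogisticGrowthModel":
        sub = traj.data[traj.data["population"] == population]
        if sub.empty:
            raise KeyError(f"population {population!r} not in trajectory")
        return cls(sub["time_days"].to_numpy(), sub["count"].to_numpy(), label=population, **kw)

    # theta = (growth_rate, log K, log n0)
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        r, logK, logn0 = theta
        p = PopulationParams(r, math.exp(logK), self.label)
        pred = logistic_solution(math.exp(logn0), p, self.times)
        pred = np.clip(pred, 1e-300, None)
        if self.log_scale:
            return np.log(pred) - np.log(self.counts)
        return pred - self.counts

    def _heuristic_start(self) -> np.ndarray:
        t, y = self.times, self.counts
        K0 = float(np.max(y)) * 1.05
        n00 = float(np.exp(np.mean(np.log(y[t == t.min()]))))
        # early log-slope, in doublings/day
        half = t <= np.median(t)
        if half.sum() >= 2 and np.ptp(t[half]) > 0:
            slope = np.polyfit(t[half], np.log2(y[half]), 1)[0]
        else:
            slope = 0.5
        r0 = float(np.clip(slope, 0.01, 3.0))
        return np.array([r0, math.log(K0), math.log(max(n00, 1e-6))])

    def fit(self, n_restarts: int = 5, seed: int = 0) -> "LogisticGrowthResults":
        """Fit by NLS from a data-driven start, with latin-hypercube
        restarts if the first attempt fails to converge."""
        theta0 = self._heuristic_start()
        starts = [theta0]
        best = None
        for i, th in enumerate(starts):
            try:
                sol = least_squares(self._residuals, th, method="lm", max_nfev=2000)
            except Exception:
                sol = None
            if sol is not None and sol.success and (best is None or sol.cost < best.cost):
                best = sol
            if best is not None and best.success and i == 0:
                break
            if i == 0 and (best is None or not best.success) and n_restarts > 0:
                sampler = qmc.LatinHypercube(d=3, seed=seed)
                u = sampler.random(n_restarts)
                lo = np.array([theta0[0] * 0.25, theta0[1] - 1.0, theta0[2] - 1.0])
                hi = np.array([theta0[0] * 4.0, theta0[1] + 1.5, theta0[2] + 1.0])
                starts.extend(lo + u * (hi - lo))
        if best is None:
            raise RuntimeError(
                f"logistic fit did not converge after {1 + n_restarts} starts"
            )
        return LogisticGrowthResults(self, best)


@dataclass
class LogisticGrowthResults:
    """Results of a logistic growth fit: point estimates, standard errors
    (delta method from the Jacobian), fit diagnostics and flags."""

    model: LogisticGrowthModel
    _sol: object = field(repr=False)

    def __post_init__(self) -> None:
        sol = self._sol
        r, logK, logn0 = sol.x
        self.growth_rate = float(r)
        self.carrying_capacity = float(math.exp(logK))
        self.n0 = float(math.exp(logn0))
        n, p = len(self.model.counts), 3
        dof = max(n - p, 1)
        sigma2 = 2.0 * sol.cost / dof
        J = sol.jac
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        self._cov = cov  # on the (growth_rate, log K, log n0) scale
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.bse = {
            "growth_rate": float(se[0]),
            "carrying_capacity": float(self.carrying_capacity * se[1]),
            "n0": float(self.n0 * se[2]),
        }
        resid = sol.fun
        obs = (
            np.log(self.model.counts) if self.model.log_scale else self.model.counts
        )
        tss = float(np.sum((obs - obs.mean()) ** 2))
        self.rsquared = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
        self.converged = bool(sol.success)
        self.flags: list[str] = []
        y = self.model.counts
        if np.ptp(np.log2(y)) < 0.5:
            self.flags.append("growth_rate_unidentifiable")
        if len(np.unique(self.model.times)) < 5 or float(np.max(y)) < 0.5 * self.carrying_capacity:
            self.flags.append("carrying_capacity_unidentifiable")

    @property
    def params(self) -> PopulationParams:
        return PopulationParams(self.growth_rate, self.carrying_capacity, self.model.label)

    def sample_params(self, n_draws: int, seed: int = 0) -> list[PopulationParams]:
        """Parameter draws from the asymptotic normal of the fit (on the
        (growth_rate, log K) scale); used to propagate fit uncertainty
        into downstream predictions."""
        rng = np.random.default_rng(seed)
        mean = np.array([self.growth_rate, math.log(self.carrying_capacity)])
        cov = self._cov[:2, :2]
        draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
        return [
            PopulationParams(float(r), float(math.exp(logk)), self.model.label)
            for r, logk in draws
        ]

    def predict(self, times) -> np.ndarray:
        return logistic_solution(self.n0, self.params, times)

    def to_dict(self) -> dict:
        return {
            "label": self.model.label,
            "growth_rate": self.growth_rate,
            "carrying_capacity": self.carrying_capacity,
            "n0": self.n0,
            "bse": self.bse,
            "rsquared": self.rsquared,
            "converged": self.converged,
            "flags": self.flags,
            "n_obs": int(len(self.model.counts)),
            "n_dropped": self.model.n_dropped,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            f"Logistic growth fit: {d['label']}",
            "=" * 44,
            f"{'growth rate (doublings/day)':34s}{d['growth_rate']:10.4f}  (SE {self.bse['growth_rate']:.4f})",
            f"{'carrying capacity (cells)':34s}{d['carrying_capacity']:10.4g}  (SE {self.bse['carrying_capacity']:.3g})",
            f"{'initial count n0 (cells)':34s}{d['n0']:10.4g}",
            f"{'R^2 (log scale)' if self.model.log_scale else 'R^2':34s}{d['rsquared']:10.4f}",
            f"{'n obs / dropped':34s}{d['n_obs']:6d} / {d['n_dropped']}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def fit_monoculture(
    traj: Trajectory, population: str | None = None, log_scale: bool = True, seed: int = 0
) -> LogisticGrowthResults:
    """Fit a logistic model to one population of a (mono)culture trajectory."""
    if population is None:
        pops = traj.populations
        if len(pops) != 1:
            raise ValueError("trajectory has multiple populations; specify one")
        population = pops[0]
    return LogisticGrowthModel.from_trajectory(traj, population).fit(seed=seed)


# ---------------------------------------------------------------------------
# Competition detection


@dataclass
class DeviationResult:
    """Per-population mean log2(observed/predicted) with a confidence
    interval; negative values mean suppression below the independent-growth
    null."""

    table: pd.DataFrame  # population, mean_log2_dev, ci_low, ci_high, n_replicates
    conf: float
    method: str

    def deviation(self, population: str) -> tuple[float, float, float]:
        row = self.table[self.table["population"] == population]
        if row.empty:
            raise KeyError(population)
        r = row.iloc[0]
        return float(r["mean_log2_dev"]), float(r["ci_low"]), float(r["ci_high"])


def sample_prediction_draws(
    fit_s: "LogisticGrowthResults",
    fit_r: "LogisticGrowthResults",
    n0_s: float,
    n0_r: float,
    times,
    n_draws: int = 100,
    seed: int = 0,
) -> list[Trajectory]:
    """Independent-growth predictions under parameter draws from the two
    monoculture fits (closed-form logistics; the alpha = 0 null)."""
    times = np.asarray(times, dtype=float)
    draws_s = fit_s.sample_params(n_draws, seed=seed)
    draws_r = fit_r.sample_params(n_draws, seed=seed + 1)
    return [
        Trajectory.from_arrays(
            times,
            {
                "sensitive": logistic_solution(n0_s, ps, times),
                "resistant": logistic_solution(n0_r, pr, times),
            },
        )
        for ps, pr in zip(draws_s, draws_r)
    ]


def competition_deviation(
    observed: Trajectory,
    predicted: Trajectory,
    conf: float = 0.95,
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
    prediction_draws: Sequence[Trajectory] | None = None,
) -> DeviationResult:
    """Mean-over-time log2 deviation of observed coculture counts from the
    independent-growth prediction, per population.

    Time grids are inner-joined.  The interval is a Student-t interval over
    replicate means by default (``method="bootstrap"`` gives a percentile
    bootstrap over replicates instead; with triplicates the t interval is
    the better calibrated of the two).  When the prediction comes from
    fitted monoculture parameters its own uncertainty is usually the
    dominant error term; pass ``prediction_draws`` (see
    :func:`sample_prediction_draws`) to fold that spread into the interval.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    rows = []
    for pop in observed.populations:
        obs = observed.pivot(pop)
        pred = predicted.pivot(pop)
        pred_mean = pred.mean(axis=1)  # deterministic prediction (single replicate)
        common = obs.index.intersection(pred_mean.index)
        if len(common) == 0:
            raise ValueError(f"no overlapping time points for population {pop!r}")
        p = pred_mean.loc[common]
        if (p <= 0).any():
            raise ValueError("predicted counts must be positive")
        dev = np.log2(obs.loc[common].to_numpy() / p.to_numpy()[:, None])
        rep_means = np.nanmean(dev, axis=0)
        n = len(rep_means)
        m = float(np.mean(rep_means))
        # spread of the prediction itself under parameter uncertainty
        sd_pred = 0.0
        if prediction_draws:
            offsets = []
            for draw in prediction_draws:
                dp = draw.pivot(pop).mean(axis=1).loc[common]
                offsets.append(float(np.mean(np.log2(dp.to_numpy() / p.to_numpy()))))
            sd_pred = float(np.std(offsets, ddof=1))
        if n < 2 and sd_pred == 0.0:
            lo = hi = m
        elif method == "bootstrap":
            idx = rng.integers(0, n, size=(n_boot, n))
            boots = rep_means[idx].mean(axis=1)
            boots = boots + rng.normal(0.0, sd_pred, size=n_boot)
            lo, hi = np.quantile(boots, [(1 - conf) / 2, 1 - (1 - conf) / 2])
        else:
            se_rep = float(np.std(rep_means, ddof=1)) / math.sqrt(n) if n > 1 else 0.0
            se = math.sqrt(se_rep**2 + sd_pred**2)
            tcrit = stats.t.ppf(1 - (1 - conf) / 2, df=max(n - 1, 1))
            lo, hi = m - tcrit * se, m + tcrit * se
        rows.append(
            {
                "population": pop,
                "mean_log2_dev": m,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_replicates": n,
            }
        )
    return DeviationResult(pd.DataFrame(rows), conf, method)
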