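"""Fitness-gap estimation from sensitive:resistant ratio series.

Under exponential growth log2(S/R)(t) = log2(S0/R0) + (gs - gr) * t, so
the OLS slope of the log2 ratio against time estimates the fitness gap
g = gs - gr directly in doublings/day, independent of the seeding
composition.  Series collected at other seeding ratios are aligned by
shifting each one in time so that its first point falls exactly on the
reference line, then all points are pooled into a single refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth import Trajectory

__all__ = [
    "RatioSeries",
    "FitnessFit",
    "ratio_series",
    "fit_reference_slope",
    "align_and_pool",
    "FitnessGapModel",
]


@dataclass
class RatioSeries:
    """log2(S/R) per time point per replicate for one seeding ratio.

    ``data`` columns: time_days, log2_ratio, replicate.
    """

    data: pd.DataFrame
    seeding_ratio: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in ("time_days", "log2_ratio") if c not in self.data.columns]
        if missing:
            raise ValueError(f"ratio series missing columns: {missing}")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=0)
        if not np.all(np.isfinite(self.data["log2_ratio"])):
            raise ValueError("log2 ratios must be finite")

    @property
    def first_time(self) -> float:
        return float(self.data["time_days"].min())

    @property
    def first_log2_ratio(self) -> float:
        """Mean log2 ratio across replicates at the earliest time point."""
        t0 = self.first_time
        return float(self.data.loc[self.data["time_days"] == t0, "log2_ratio"].mean())

    def shifted(self, time_offset: float) -> pd.DataFrame:
        out = self.data.copy()
        out["time_days"] = out["time_days"] + time_offset
        out["seeding_ratio"] = self.seeding_ratio
        return out


def ratio_series(
    traj: Trajectory,
    sensitive: str = "sensitive",
    resistant: str = "resistant",
    log_base: float = 2.0,
    pseudocount: float = 0.0,
) -> RatioSeries:
    """log2(S count / R count) per time/replicate from a coculture trajectory.

    Points where either count is zero are dropped with a warning and
    counted in ``n_dropped``; passing ``pseudocount`` > 0 adds it to every
    count instead of dropping (off by default: a pseudocount biases the
    slope when one population nears extinction).  Natural-log or log10
    input conventions elsewhere can be converted via ``log_base``.
    """
    s = traj.pivot(sensitive)
    r = traj.pivot(resistant)
    common = s.index.intersection(r.index)
    s, r = s.loc[common], r.loc[common]
    rows = []
    n_dropped = 0
    for rep in s.columns.intersection(r.columns):
        sv = s[rep].to_numpy() + pseudocount
        rv = r[rep].to_numpy() + pseudocount
        ok = (sv > 0) & (rv > 0)
        n_dropped += int((~ok).sum())
        rows.append(
            pd.DataFrame(
                {
                    "time_days": np.asarray(common)[ok],
                    "log2_ratio": np.log(sv[ok] / rv[ok]) / math.log(log_base),
                    "replicate": rep,
                }
            )
        )
    data = pd.concat(rows, ignore_index=True)
    if data.empty:
        raise ValueError("all ratio points dropped (zero counts everywhere)")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} ratio points with zero counts")
    return RatioSeries(data, seeding_ratio=traj.seeding_ratio, n_dropped=n_dropped)


@dataclass
class FitnessFit:
    """Fitted fitness gap g = gs - gr (doublings/day) with uncertainty.

    ``offsets`` maps each seeding-ratio label to the time shift applied
    during alignment (0 for the reference series); ``data`` holds the
    (aligned) points that entered the fit.
    """

    g: float
    intercept: float
    stderr_g: float
    r_squared: float
    offsets: dict[str, float]
    data: pd.DataFrame = field(repr=False)
    residual_rms: float = 0.0
    stderr_g_cluster: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return int(len(self.data))

    def predict(self, times) -> np.ndarray:
        return self.intercept + self.g * np.asarray(times, dtype=float)

    def to_dict(self) -> dict:
        return {
            "g_doublings_per_day": self.g,
            "intercept_log2": self.intercept,
            "stderr_g": self.stderr_g,
            "stderr_g_cluster": self.stderr_g_cluster,
            "r_squared": self.r_squared,
            "offsets_days": self.offsets,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "warnings": self.warnings,
        }

    def summary(self) -> str:
        lines = [
            "Fitness gap fit  (slope of log2 S:R ratio vs time)",
            "=" * 50,
            f"{'g = gs - gr (doublings/day)':34s}{self.g:10.4f}  (SE {self.stderr_g:.4f})",
            f"{'intercept (log2 units)':34s}{self.intercept:10.4f}",
            f"{'R^2':34s}{self.r_squared:10.4f}",
            f"{'points':34s}{self.n_points:10d}",
        ]
        for label, off in self.offsets.items():
            lines.append(f"  offset[{label}] = {off:+.3f} days")
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


def _ols_fit(data: pd.DataFrame, offsets: dict[str, float], warns: list[str]) -> FitnessFit:
    t = data["time_days"].to_numpy(dtype=float)
    y = data["log2_ratio"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("zero time variance in ratio series")
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    resid = y - res.predict(X)
    return FitnessFit(
        g=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr_g=float(res.bse[1]),
        r_squared=float(res.rsquared),
        offsets=offsets,
        data=data.reset_index(drop=True),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        warnings=warns,
    )


def fit_reference_slope(series: RatioSeries) -> FitnessFit:
    """OLS line through one (reference) ratio series; slope is g.

    Replicates enter as independent points.  Requires >= 3 time points.
    """
    if series.data["time_days"].nunique() < 3:
        raise ValueError("need >= 3 time points to fit the reference slope")
    data = series.data.copy()
    data["seeding_ratio"] = series.seeding_ratio
    return _ols_fit(data, {series.seeding_ratio: 0.0}, [])


def align_and_pool(
    reference_fit: FitnessFit,
    other_series: list[RatioSeries],
    cluster_bootstrap: int = 0,
    seed: int = 0,
) -> FitnessFit:
    """Shift each non-reference series in time so its first point falls on
    the reference line, pool all aligned points, and refit.

    The offset solves intercept + g*(t_first + offset) = y_first, i.e.
    offset = (y_first - intercept)/g - t_first.  When the reference slope
    is exactly 0 the time offset is undefined; each series is then shifted
    vertically onto the intercept instead, with a warning.
    """
    warns = list(reference_fit.warnings)
    offsets = dict(reference_fit.offsets)
    frames = [reference_fit.data.copy()]
    for series in other_series:
        y0, t0 = series.first_log2_ratio, series.first_time
        if reference_fit.g == 0:
            warnings.warn("reference slope is 0; falling back to intercept-only alignment")
            warns.append(f"intercept_alignment[{series.seeding_ratio}]")
            shifted = series.shifted(0.0)
            shifted["log2_ratio"] += reference_fit.intercept - y0
            offsets[series.seeding_ratio] = 0.0
        else:
            offset = (y0 - reference_fit.intercept) / reference_fit.g - t0
            shifted = series.shifted(offset)
            offsets[series.seeding_ratio] = float(offset)
        frames.append(shifted)
    pooled = pd.concat(frames, ignore_index=True)
    fit = _ols_fit(pooled, offsets, warns)
    if cluster_bootstrap > 0:
        fit.stderr_g_cluster = _cluster_bootstrap_se(pooled, cluster_bootstrap, seed)
    return fit


def _cluster_bootstrap_se(pooled: pd.DataFrame, n_boot: int, seed: int) -> float:
    """Replicate-cluster bootstrap SE of the pooled slope: resample whole
    replicates (within each seeding ratio) with replacement."""
    rng = np.random.default_rng(seed)
    groups = pooled.groupby(["seeding_ratio", "replicate"], dropna=False)
    keys = list(groups.groups)
    by_ratio: dict[str, list] = {}
    for ratio, rep in keys:
        by_ratio.setdefault(ratio, []).append((ratio, rep))
    slopes = []
    for _ in range(n_boot):
        frames = []
        for ratio, members in by_ratio.items():
            picks = rng.integers(0, len(members), size=len(members))
            frames.extend(groups.get_group(members[p]) for p in picks)
        df = pd.concat(frames, ignore_index=True)
        t = df["time_days"].to_numpy()
        y = df["log2_ratio"].to_numpy()
        if len(np.unique(t)) < 2:
            continue
        slopes.append(np.polyfit(t, y, 1)[0])
    return float(np.std(slopes, ddof=1)) if len(slopes) > 1 else float("nan")


class FitnessGapModel:
    """Convenience model: reference fit plus alignment-and-pooling in one
    `.fit()` call, statsmodels-style.

    ``reference`` selects the series used for the initial line (by seeding
    ratio label); the convention in low-resource experiments is the lowest
    sensitive seeding ratio.
    """

    def __init__(self, series: list[RatioSeries], reference: str | int = 0):
        if not series:
            raise ValueError("no ratio series supplied")
        if isinstance(reference, int):
            self.reference = series[reference]
        else:
            matches = [s for s in series if s.seeding_ratio == reference]
            if not matches:
                raise KeyError(f"no series with seeding ratio {reference!r}")
            self.reference = matches[0]
        self.others = [s for s in series if s is not self.reference]

    def fit(self, cluster_bootstrap: int = 0, seed: int = 0) -> FitnessFit:
        ref = fit_reference_slope(self.reference)
        if not self.others:
            return ref
        return align_and_pool(ref, self.others, cluster_bootstrap=cluster_bootstrap, seed=seed)
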