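"""Synthetic-data generators with known ground truth.

Every generator is driven by a single seed in :class:`SimConfig`; per
dataset sub-streams are spawned deterministically from the seed and a
stream label, and are recorded in the attached :class:`GroundTruth`, so
identical configs give byte-identical outputs.

Count noise is multiplicative lognormal with a stated coefficient of
variation (cell counting error scales with the count); the log-noise has
zero mean so log-scale estimators see unbiased residuals.  Copy-number
segment noise is additive Gaussian on the observed (purity-diluted)
profile.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import CompetitionModel, PopulationParams, Trajectory, logistic_solution, simulate_competition
from .subclone import SegmentProfile
from .therapy import DrugEffectParams, TherapyProtocol, TrialSettings, TumorCourse, draw_course_inits, drug_kill_rate, run_course

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SampleSeries",
    "default_invitro_model",
    "default_invivo_model",
    "gen_monoculture",
    "gen_coculture",
    "gen_drug_pulse",
    "gen_mouse_cohort",
    "gen_cn_series",
]

# baseline clonal copy-number distribution over {1..6}: an aneuploid,
# 2-3-centred genome typical of high-grade serous ovarian cancer
HGSC_CN_STATES = np.array([1, 2, 3, 4, 5, 6])
HGSC_CN_PROBS = np.array([0.08, 0.40, 0.25, 0.15, 0.08, 0.04])


@dataclass(frozen=True)
class SimConfig:
    """Global generator configuration.

    noise_cv: CV of multiplicative count noise (dimensionless);
    cn_noise_sd: additive segment noise in copy-number units;
    sampling_times: measurement days, strictly increasing.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_cv: float = 0.05
    cn_noise_sd: float = 0.05
    sampling_times: tuple[float, ...] = tuple(float(t) for t in range(0, 16))

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.cn_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.sampling_times, dtype=float)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be nonempty and strictly increasing")

    def rng(self, stream: str) -> tuple[np.random.Generator, int]:
        """Deterministic sub-stream: (generator, recorded sub-seed)."""
        sub = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, sub))), sub


@dataclass
class GroundTruth:
    """Generating parameters attached to every synthetic dataset."""

    sub_seed: int
    true_params_s: PopulationParams | None = None
    true_params_r: PopulationParams | None = None
    true_competition: tuple[float, float] | None = None  # (alpha_sr, alpha_rs)
    true_subclone_ratios: np.ndarray | None = None
    true_resistant_segments: dict[int, int] = field(default_factory=dict)
    decoy_segments: tuple[int, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_subclone_ratios is not None:
            r = np.asarray(self.true_subclone_ratios, dtype=float)
            if np.any((r < 0) | (r > 1)):
                raise ValueError("true subclone ratios must lie in [0, 1]")
        for delta in self.true_resistant_segments.values():
            if int(delta) == 0:
                raise ValueError("resistant-segment deltas must be nonzero integers")


def default_invitro_model() -> CompetitionModel:
    """Low-resource coculture preset: shared resource pool (alpha = 1),
    fitness gap 0.08 doublings/day."""
    return CompetitionModel(
        PopulationParams(0.50, 2e6, "sensitive"),
        PopulationParams(0.42, 2e6, "resistant"),
        alpha_sr=1.0,
        alpha_rs=1.0,
    )


def default_invivo_model() -> CompetitionModel:
    """Subcutaneous xenograft preset.

    Scaled to the 1e4 cells/mm^3 volume convention: the carrying capacity
    of 2.5e7 cells corresponds to a 2500 mm^3 flank tumor, comfortably
    above the 1440 mm^3 humane endpoint so that untreated tumors progress
    while competition still bites near endpoint sizes.
    """
    return CompetitionModel(
        PopulationParams(0.35, 2.5e7, "sensitive"),
        PopulationParams(0.27, 2.5e7, "resistant"),
        alpha_sr=1.0,
        alpha_rs=1.0,
    )


def _lognoise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def _ratio_label(fs: float, fr: float) -> str:
    return f"{round(fs * 100)}:{round(fr * 100)}"


def gen_monoculture(
    params: PopulationParams,
    n0: float,
    config: SimConfig,
    condition: str = "low_resource",
) -> Trajectory:
    """Monoculture counts: closed-form logistic at the sampling times,
    multiplied by lognormal noise with CV ``config.noise_cv``."""
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    times = np.asarray(config.sampling_times, dtype=float)
    rng, sub = config.rng(f"monoculture/{params.label}/{condition}")
    clean = logistic_solution(n0, params, times)
    counts = clean[None, :] * _lognoise(rng, config.noise_cv, (config.n_replicates, len(times)))
    gt = GroundTruth(sub, true_params_s=params, extras={"n0": n0})
    return Trajectory.from_arrays(
        times, {params.label: counts}, condition=condition, ground_truth=gt
    )


def gen_coculture(
    model: CompetitionModel,
    seeding: tuple[float, float],
    total_n0: float,
    config: SimConfig,
    condition: str = "low_resource",
) -> Trajectory:
    """Coculture counts: numerically integrated competition dynamics with
    measurement noise applied per replicate."""
    fs, fr = seeding
    if not (0 <= fs <= 1 and 0 <= fr <= 1):
        raise ValueError("seeding fractions must lie in [0, 1]")
    if abs(fs + fr - 1.0) > 1e-9:
        raise ValueError("seeding fractions must sum to 1")
    times = np.asarray(config.sampling_times, dtype=float)
    label = _ratio_label(fs, fr)
    rng, sub = config.rng(f"coculture/{label}/{condition}")
    clean = simulate_competition(model, total_n0 * fs, total_n0 * fr, times)
    counts = {}
    for pop in ("sensitive", "resistant"):
        base = clean.pivot(pop)[0].to_numpy()
        counts[pop] = base[None, :] * _lognoise(rng, config.noise_cv, (config.n_replicates, len(times)))
    gt = GroundTruth(
        sub,
        true_params_s=model.params_s,
        true_params_r=model.params_r,
        true_competition=(model.alpha_sr, model.alpha_rs),
        extras={"total_n0": total_n0, "seeding": (fs, fr)},
    )
    return Trajectory.from_arrays(times, counts, condition, label, gt)


def gen_drug_pulse(
    model: CompetitionModel,
    drug: DrugEffectParams,
    dose_series: Sequence[float],
    config: SimConfig,
    pulse_day: float = 6.0,
    seeding: tuple[float, float] = (0.5, 0.5),
    total_n0: float = 2.5e5,
) -> dict[float, Trajectory]:
    """One trajectory per dose: a single drug pulse on ``pulse_day`` acts
    through the delayed Emax kill model; dose 0 reproduces the untreated
    coculture exactly."""
    times = np.asarray(config.sampling_times, dtype=float)
    if not (times[0] <= pulse_day <= times[-1]):
        raise ValueError("pulse day must lie within the sampling window")
    out: dict[float, Trajectory] = {}
    for dose in dose_series:
        if dose < 0:
            raise ValueError("doses must be >= 0")
        if dose == 0:
            kill = None
        else:
            def kill(t, dose=dose):
                tau = t - pulse_day
                if tau < 0 or tau > drug.effect_duration:
                    return 0.0, 0.0
                ks = drug_kill_rate(dose, tau, drug)
                return ks, ks * drug.resistance_factor

        fs, fr = seeding
        clean = simulate_competition(model, total_n0 * fs, total_n0 * fr, times, kill=kill)
        rng, sub = config.rng(f"pulse/{dose}")
        counts = {}
        for pop in ("sensitive", "resistant"):
            base = clean.pivot(pop)[0].to_numpy()
            counts[pop] = base[None, :] * _lognoise(
                rng, config.noise_cv, (config.n_replicates, len(times))
            )
        gt = GroundTruth(
            sub,
            true_params_s=model.params_s,
            true_params_r=model.params_r,
            true_competition=(model.alpha_sr, model.alpha_rs),
            extras={"dose": dose, "pulse_day": pulse_day},
        )
        out[float(dose)] = Trajectory.from_arrays(
            times, counts, f"pulse_dose_{dose}", _ratio_label(fs, fr), gt
        )
    return out


def gen_mouse_cohort(
    ratio_mix: float,
    n_mice: int,
    model: CompetitionModel,
    config: SimConfig,
    settings: TrialSettings = TrialSettings(),
    drug: DrugEffectParams | None = None,
    protocol: TherapyProtocol | None = None,
) -> list[TumorCourse]:
    """Untreated (vehicle) tumor courses for ``n_mice`` mice injected with
    the given sensitive fraction in both flanks; initial sizes carry
    independent lognormal jitter and growth rates per-mouse heterogeneity."""
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng, _ = config.rng(f"cohort/{ratio_mix}/{n_mice}")
    drug = drug or DrugEffectParams.in_vivo()
    protocol = protocol or TherapyProtocol.vehicle()
    inits = draw_course_inits(ratio_mix, n_mice, rng, settings=settings)
    return [run_course(model, drug, protocol, init, settings) for init in inits]


@dataclass
class SampleSeries:
    """Longitudinal copy-number profiles for one synthetic patient."""

    patient_id: str
    baseline: SegmentProfile
    later: list[SegmentProfile]
    manifest: pd.DataFrame
    ground_truth: GroundTruth | None = None

    @property
    def profiles(self) -> list[SegmentProfile]:
        return [self.baseline, *self.later]


def _segment_coordinates(n_segments: int) -> pd.DataFrame:
    """Deterministic BED-like coordinates: segments laid out contiguously
    over chromosomes 1..22, 5 Mb each, 0-based half-open."""
    per_chrom = math.ceil(n_segments / 22)
    chroms, starts, ends = [], [], []
    for j in range(n_segments):
        c = j // per_chrom + 1
        i = j % per_chrom
        chroms.append(str(c))
        starts.append(i * 5_000_000)
        ends.append((i + 1) * 5_000_000)
    return pd.DataFrame({"chromosome": chroms, "start": starts, "end": ends})


def gen_cn_series(
    n_segments: int,
    n_resistant_segments: int,
    ratio_trajectory: Sequence[float],
    purities: Sequence[float],
    config: SimConfig,
    days: Sequence[float] | None = None,
    decoy_fraction: float = 0.05,
    patient_id: str = "P1",
    marker_intercept: float = 60.0,
    marker_scale: float = 2e4,
    marker_noise_sd: float = 8.0,
) -> SampleSeries:
    """Longitudinal segment profiles with an emergent resistant subclone.

    The first entry of ``ratio_trajectory``/``purities`` is the baseline
    (diagnostic) sample.  Observed segment CN at sample t is

        purity * [(1 - r_t) * c0 + r_t * (c0 + delta)] + (1 - purity) * 2
        + N(0, cn_noise_sd)

    with nonzero integer deltas on resistant segments only.  A fraction of
    the clonal segments ("decoys") receive a transient, non-monotone
    perturbation emulating unrelated ongoing copy-number instability.  A
    CA125-like marker is generated per sample, linear in the per-interval
    subclone growth rate (plus noise).
    """
    ratios = np.asarray(ratio_trajectory, dtype=float)
    purities = np.asarray(purities, dtype=float)
    if not (0 < n_resistant_segments < n_segments):
        raise ValueError("need 0 < n_resistant_segments < n_segments")
    if np.any((ratios < 0) | (ratios > 1)):
        raise ValueError("subclone ratios must lie in [0, 1]")
    if np.any((purities <= 0) | (purities > 1)):
        raise ValueError("purities must lie in (0, 1]")
    if len(ratios) != len(purities):
        raise ValueError("ratio_trajectory and purities must be aligned")
    n_samples = len(ratios)
    if days is None:
        days = np.arange(n_samples, dtype=float) * 60.0
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("sample days must be strictly increasing")

    rng, sub = config.rng(f"cn/{patient_id}")
    coords = _segment_coordinates(n_segments)
    c0 = rng.choice(HGSC_CN_STATES, size=n_segments, p=HGSC_CN_PROBS).astype(float)
    resistant_idx = rng.choice(n_segments, size=n_resistant_segments, replace=False)
    deltas = np.zeros(n_segments)
    for j in resistant_idx:
        choices = [d for d in (-2, -1, 1, 2) if c0[j] + d >= 0]
        deltas[j] = rng.choice(choices)
    non_resistant = np.setdiff1d(np.arange(n_segments), resistant_idx)
    n_decoys = int(round(decoy_fraction * len(non_resistant)))
    decoys = rng.choice(non_resistant, size=n_decoys, replace=False) if n_decoys else np.array([], dtype=int)

    profiles = []
    for t in range(n_samples):
        tumor_cn = (1.0 - ratios[t]) * c0 + ratios[t] * (c0 + deltas)
        if t > 0 and len(decoys) and n_samples >= 3:
            # transient "other CNA": present in exactly one interior sample
            # (a perturbation in the final sample would be indistinguishable
            # from late-emerging resistance and is not generated)
            for j in decoys:
                hit = 1 + (int(j) % max(n_samples - 2, 1))
                if t == hit:
                    amp = 0.15 + 0.3 * ((int(j) * 2654435761) % 1000) / 1000.0
                    sign = 1.0 if (int(j) % 2 == 0) else -1.0
                    tumor_cn = tumor_cn.copy()
                    tumor_cn[j] += sign * amp
        obs = purities[t] * tumor_cn + (1.0 - purities[t]) * 2.0
        if config.cn_noise_sd > 0:
            obs = obs + rng.normal(0.0, config.cn_noise_sd, size=n_segments)
        seg = coords.copy()
        seg["copy_number"] = obs
        profiles.append(
            SegmentProfile(seg, sample_id=f"{patient_id}-s{t}", day=float(days[t]), purity=float(purities[t]))
        )

    # marker linear in the per-interval subclone growth rate
    marker = np.empty(n_samples)
    marker_rng, _ = config.rng(f"cn-marker/{patient_id}")
    for t in range(n_samples):
        rate = 0.0 if t == 0 else (ratios[t] - ratios[t - 1]) / (days[t] - days[t - 1])
        marker[t] = marker_intercept + marker_scale * rate
        if marker_noise_sd > 0:
            marker[t] += marker_rng.normal(0.0, marker_noise_sd)
    manifest = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "patient_id": patient_id,
            "day": days,
            "purity": purities,
            "marker_value": marker,
        }
    )
    gt = GroundTruth(
        sub,
        true_subclone_ratios=ratios,
        true_resistant_segments={int(j): int(deltas[j]) for j in resistant_idx},
        decoy_segments=tuple(int(j) for j in decoys),
        extras={"baseline_cn": c0, "days": days},
    )
    return SampleSeries(patient_id, profiles[0], profiles[1:], manifest, gt)
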