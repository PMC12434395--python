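"""End-to-end pipeline: simulate -> fit growth -> estimate fitness ->
in-silico trial -> track subclone -> correlate with tumor burden.

A run is described by a YAML/dict config with a global seed and per-stage
parameter blocks; every run writes its resolved config next to its outputs
and a report listing the artifacts produced.  The global seed fully
determines all stochastic outputs, and no stage mutates its inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitness import FitnessGapModel, ratio_series
from .growth import fit_monoculture
from .io import dump_json, load_patient_profiles, validate_inputs, write_sample_series, write_trajectory
from .simulate import SimConfig, default_invitro_model, default_invivo_model, gen_cn_series, gen_coculture, gen_monoculture
from .subclone import bootstrap_ci, call_resistance_segments, correlate_burden, subclone_growth_rate
from .therapy import DrugEffectParams, TherapyProtocol, TrialSettings, run_trial

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "demo_config"]

log = logging.getLogger("atcost")

STAGES = ("simulate", "fit_growth", "fitness", "trial", "subclone", "correlate")

_KNOWN_KEYS = {"seed", "out_dir", "stages", "simulate", "fitness", "trial", "subclone", "log_level"}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    out_dir: str = "atcost_run"
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    trial: dict = field(default_factory=dict)
    subclone: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        stages = tuple(d.get("stages", STAGES))
        for s in stages:
            if s not in STAGES:
                raise PipelineError(f"unknown stage {s!r}; valid: {STAGES}")
        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "atcost_run")),
            stages=stages,
            simulate=dict(d.get("simulate", {})),
            fitness=dict(d.get("fitness", {})),
            trial=dict(d.get("trial", {})),
            subclone=dict(d.get("subclone", {})),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            "simulate": self.simulate,
            "fitness": self.fitness,
            "trial": self.trial,
            "subclone": self.subclone,
            "log_level": self.log_level,
        }


def demo_config(seed: int = 0) -> dict:
    """Small synthetic end-to-end demonstration configuration."""
    return {
        "seed": seed,
        "stages": list(STAGES),
        "simulate": {
            "total_n0": 2.5e5,
            "seeding_ratios": [[0.85, 0.15], [0.5, 0.5], [0.15, 0.85]],
            "n_patients": 3,
            "n_segments": 80,
            "n_resistant_segments": 20,
            "ratio_trajectory": [0.0, 0.15, 0.35, 0.55],
            "purities": [0.6, 0.5, 0.7, 0.65],
            "sample_days": [0, 60, 120, 180],
        },
        "fitness": {"reference": "15:85"},
        "trial": {"cohorts": {"80:20": 0.8}, "n_per_arm": 2, "arms": ["AT", "ST", "vehicle"]},
        "subclone": {"n_boot": 150, "subsample_fraction": 0.75},
    }


def _stage_simulate(cfg: RunConfig, out: Path, artifacts: list[str]) -> None:
    blk = cfg.simulate
    sim = SimConfig(seed=cfg.seed, noise_cv=blk.get("noise_cv", 0.05), cn_noise_sd=blk.get("cn_noise_sd", 0.05))
    model = default_invitro_model()
    total_n0 = float(blk.get("total_n0", 2.5e5))
    for params, frac in ((model.params_s, 1.0), (model.params_r, 1.0)):
        traj = gen_monoculture(params, total_n0 * frac, sim)
        path = out / f"monoculture_{params.label}.tsv"
        write_trajectory(traj, path)
        artifacts.append(path.name)
    for fs, fr in blk.get("seeding_ratios", [[0.85, 0.15], [0.5, 0.5], [0.15, 0.85]]):
        traj = gen_coculture(model, (fs, fr), total_n0, sim)
        path = out / f"coculture_{round(fs * 100)}_{round(fr * 100)}.tsv"
        write_trajectory(traj, path)
        artifacts.append(path.name)
    # longitudinal copy-number cohort
    ratios = np.asarray(blk.get("ratio_trajectory", [0.0, 0.15, 0.35, 0.55]), dtype=float)
    purities = blk.get("purities", [0.6, 0.5, 0.7, 0.65])
    days = np.asarray(blk.get("sample_days", [0, 60, 120, 180]), dtype=float)
    series = []
    # patients differ in sampling cadence (subclone tempo varies; the
    # trajectory amplitude stays well identified)
    day_scale = [1.0, 1.5, 0.75]
    for i in range(int(blk.get("n_patients", 3))):
        series.append(
            gen_cn_series(
                int(blk.get("n_segments", 80)),
                int(blk.get("n_resistant_segments", 20)),
                ratios,
                purities,
                sim,
                days=days * day_scale[i % len(day_scale)],
                patient_id=f"P{i + 1}",
            )
        )
    manifest = write_sample_series(series, out / "cn")
    artifacts.append(str(manifest.relative_to(out)))


def _stage_fit_growth(cfg: RunConfig, out: Path, artifacts: list[str]) -> dict:
    from .io import read_trajectory

    fits = {}
    for label in ("sensitive", "resistant"):
        path = out / f"monoculture_{label}.tsv"
        if not path.exists():
            raise PipelineError("fit_growth requires stage 'simulate' outputs (monoculture TSVs)")
        res = fit_monoculture(read_trajectory(path), population=label)
        fits[label] = res.to_dict()
    dump_json(fits, out / "growth_fits.json")
    artifacts.append("growth_fits.json")
    return fits


def _stage_fitness(cfg: RunConfig, out: Path, artifacts: list[str]) -> dict:
    from .io import read_trajectory

    paths = sorted(out.glob("coculture_*.tsv"))
    if not paths:
        raise PipelineError("fitness requires stage 'simulate' outputs (coculture TSVs)")
    series = [ratio_series(read_trajectory(p)) for p in paths]
    reference = cfg.fitness.get("reference")
    if reference is None:
        # lowest sensitive seeding fraction
        reference = min(series, key=lambda s: int(s.seeding_ratio.split(":")[0])).seeding_ratio
    fit = FitnessGapModel(series, reference=reference).fit(
        cluster_bootstrap=int(cfg.fitness.get("cluster_bootstrap", 200)), seed=cfg.seed
    )
    dump_json(fit.to_dict(), out / "fitness.json")
    aligned = fit.data
    aligned.to_csv(out / "fitness_aligned.tsv", sep="\t", index=False)
    artifacts.extend(["fitness.json", "fitness_aligned.tsv"])
    return fit.to_dict()


def _stage_trial(cfg: RunConfig, out: Path, artifacts: list[str]) -> dict:
    blk = cfg.trial
    name_map = {
        "AT": TherapyProtocol.adaptive(),
        "ST": TherapyProtocol.standard(),
        "vehicle": TherapyProtocol.vehicle(),
    }
    arms = [name_map[a] for a in blk.get("arms", ["AT", "ST", "vehicle"])]
    result = run_trial(
        default_invivo_model(),
        DrugEffectParams.in_vivo(),
        cohorts={k: float(v) for k, v in blk.get("cohorts", {"80:20": 0.8}).items()},
        arms=arms,
        n_per_arm=int(blk.get("n_per_arm", 2)),
        seed=cfg.seed,
        settings=TrialSettings(),
    )
    dump_json(result.to_dict(), out / "trial.json")
    result.mice.to_csv(out / "trial_mice.tsv", sep="\t", index=False)
    artifacts.extend(["trial.json", "trial_mice.tsv"])
    return result.to_dict()


def _stage_subclone(cfg: RunConfig, out: Path, artifacts: list[str]) -> dict:
    manifest = out / "cn" / "manifest.tsv"
    if not manifest.exists():
        raise PipelineError("subclone requires stage 'simulate' outputs (cn/manifest.tsv)")
    blk = cfg.subclone
    patients = load_patient_profiles(manifest)
    results = {}
    for patient, profiles in patients.items():
        baseline, later = profiles[0], profiles[1:]
        segs = call_resistance_segments(
            baseline,
            later,
            shift_threshold=float(blk.get("shift_threshold", 0.1)),
            monotone_tolerance=float(blk.get("monotone_tolerance", 0.05)),
        )
        est = bootstrap_ci(
            baseline,
            later,
            segs,
            n_boot=int(blk.get("n_boot", 150)),
            subsample_fraction=float(blk.get("subsample_fraction", 0.75)),
            seed=cfg.seed,
        )
        d = est.to_dict()
        d["baseline_day"] = baseline.day
        results[patient] = d
    dump_json(results, out / "subclone.json")
    artifacts.append("subclone.json")
    return results


def _stage_correlate(cfg: RunConfig, out: Path, artifacts: list[str]) -> dict:
    import json

    sub_path = out / "subclone.json"
    manifest_path = out / "cn" / "manifest.tsv"
    if not sub_path.exists():
        raise PipelineError("correlate requires stage 'subclone' output (subclone.json)")
    from .io import read_manifest
    from .subclone import SubcloneEstimate

    with open(sub_path) as fh:
        sub = json.load(fh)
    manifest = read_manifest(manifest_path)
    rates, markers = [], []
    for patient, d in sub.items():
        est = SubcloneEstimate(
            sample_ids=d["sample_ids"],
            days=np.asarray(d["days"], dtype=float),
            ratios=np.asarray(d["subclonal_ratio"], dtype=float),
            deltas={int(k): v for k, v in d["deltas"].items()},
        )
        table = subclone_growth_rate(est, baseline_day=float(d["baseline_day"]))
        pm = manifest[manifest["patient_id"] == patient].set_index("day")["marker_value"]
        for row in table.itertuples():
            if row.end_day in pm.index:
                rates.append(row.rate_per_day)
                markers.append(float(pm.loc[row.end_day]))
    corr = correlate_burden(rates, markers)
    dump_json(corr.to_dict(), out / "correlation.json")
    artifacts.append("correlation.json")
    return corr.to_dict()


def run_pipeline(config: RunConfig | dict, out_dir=None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run report (also written to ``report.json``).  Outputs of
    completed stages survive a downstream failure.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    artifacts: list[str] = ["resolved_config.yaml"]
    warn_msgs: list[str] = []
    runners = {
        "simulate": _stage_simulate,
        "fit_growth": _stage_fit_growth,
        "fitness": _stage_fitness,
        "trial": _stage_trial,
        "subclone": _stage_subclone,
        "correlate": _stage_correlate,
    }
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        log.info("running stage %s", stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            runners[stage](config, out, artifacts)
        warn_msgs.extend(f"{stage}: {w.message}" for w in caught)
    report = {
        "version": __version__,
        "seed": config.seed,
        "stages": ordered,
        "artifacts": sorted(set(artifacts)),
        "warnings": warn_msgs,
    }
    dump_json(report, out / "report.json")
    return report
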