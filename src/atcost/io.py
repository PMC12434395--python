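"""Tabular and JSON I/O conventions shared by all stages.

Trajectories travel as tidy TSV (time_days, population, count, replicate,
condition, seeding_ratio); copy-number profiles as BED-like TSV per sample
(chromosome, start, end, copy_number; 0-based half-open) plus a samples
manifest TSV (sample_id, patient_id, day, purity, marker_value).  Fits and
estimates are serialized as JSON with sorted keys so identical runs give
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import TRAJECTORY_COLUMNS, Trajectory
from .subclone import SEGMENT_COLUMNS, SegmentProfile

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_segments",
    "read_segments",
    "write_sample_series",
    "read_manifest",
    "load_patient_profiles",
    "harmonize_profiles",
    "dump_json",
    "ValidationReport",
    "validate_inputs",
]

MANIFEST_COLUMNS = ["sample_id", "patient_id", "day", "purity", "marker_value"]


def write_trajectory(traj: Trajectory, path) -> None:
    traj.data[TRAJECTORY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> Trajectory:
    data = pd.read_csv(path, sep="\t")
    cond = str(data["condition"].iloc[0]) if "condition" in data else ""
    ratio = str(data["seeding_ratio"].iloc[0]) if "seeding_ratio" in data else ""
    return Trajectory(data, condition=cond, seeding_ratio=ratio)


def write_segments(profile: SegmentProfile, path) -> None:
    profile.segments[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path, sample_id: str, day: float, purity: float) -> SegmentProfile:
    seg = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return SegmentProfile(seg, sample_id=sample_id, day=day, purity=purity)


def write_sample_series(series_list, out_dir) -> Path:
    """Write per-sample BED-like TSVs and a pooled manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests = []
    for series in series_list:
        for prof in series.profiles:
            write_segments(prof, out_dir / f"{prof.sample_id}.segments.tsv")
        manifests.append(series.manifest)
    manifest = pd.concat(manifests, ignore_index=True)
    path = out_dir / "manifest.tsv"
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "patient_id", "day", "purity") if c not in m.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return m


def load_patient_profiles(manifest_path, min_segment_length: float = 1e6) -> dict[str, list[SegmentProfile]]:
    """Load and harmonize all samples per patient, ordered by day.

    Segment files are looked up next to the manifest as
    ``<sample_id>.segments.tsv``.
    """
    manifest_path = Path(manifest_path)
    m = read_manifest(manifest_path).sort_values(["patient_id", "day"])
    out: dict[str, list[SegmentProfile]] = {}
    for patient, grp in m.groupby("patient_id", sort=True):
        profiles = [
            read_segments(
                manifest_path.parent / f"{row.sample_id}.segments.tsv",
                sample_id=str(row.sample_id),
                day=float(row.day),
                purity=float(row.purity),
            )
            for row in grp.itertuples()
        ]
        out[str(patient)] = harmonize_profiles(profiles, min_segment_length)
    return out


def harmonize_profiles(
    profiles: Sequence[SegmentProfile], min_length: float = 1e6
) -> list[SegmentProfile]:
    """Intersect segment breakpoints across samples of one patient.

    Each atomic interval covered by every sample becomes a shared segment
    carrying each sample's copy number; intervals shorter than
    ``min_length`` are dropped.  Profiles that already share an identical
    segmentation pass through unchanged.
    """
    base = profiles[0].segments[["chromosome", "start", "end"]].reset_index(drop=True)
    if all(
        len(p.segments) == len(base)
        and p.segments[["chromosome", "start", "end"]].reset_index(drop=True).equals(base)
        for p in profiles[1:]
    ):
        return list(profiles)
    chroms = sorted(set().union(*[set(p.segments["chromosome"]) for p in profiles]))
    pieces: dict[str, list[dict]] = {p.sample_id: [] for p in profiles}
    for chrom in chroms:
        cuts = sorted(
            set().union(
                *[
                    set(p.segments.loc[p.segments["chromosome"] == chrom, "start"])
                    | set(p.segments.loc[p.segments["chromosome"] == chrom, "end"])
                    for p in profiles
                ]
            )
        )
        for lo, hi in zip(cuts, cuts[1:]):
            if hi - lo < min_length:
                continue
            vals = []
            for p in profiles:
                sub = p.segments[
                    (p.segments["chromosome"] == chrom)
                    & (p.segments["start"] <= lo)
                    & (p.segments["end"] >= hi)
                ]
                vals.append(float(sub["copy_number"].iloc[0]) if len(sub) else None)
            if any(v is None for v in vals):
                continue
            for p, v in zip(profiles, vals):
                pieces[p.sample_id].append(
                    {"chromosome": chrom, "start": lo, "end": hi, "copy_number": v}
                )
    return [
        SegmentProfile(pd.DataFrame(pieces[p.sample_id]), p.sample_id, p.day, p.purity)
        for p in profiles
    ]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {"ok": self.ok, "errors": self.errors, "warnings": self.warnings}


def validate_inputs(paths: Sequence) -> ValidationReport:
    """Schema/sanity checks for trajectory, segment and manifest TSVs.

    The file kind is inferred from its columns.  Fatal problems (missing
    columns, overlapping segments, non-monotone days) go to ``errors``;
    recoverable oddities go to ``warnings``.
    """
    report = ValidationReport()
    for path in paths:
        path = Path(path)
        name = path.name
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            report.errors.append(f"{name}: unreadable ({exc})")
            continue
        cols = set(df.columns)
        if {"time_days", "population", "count"} <= cols:
            if (df["count"] < 0).any():
                report.errors.append(f"{name}: negative counts")
            rep = df["replicate"] if "replicate" in cols else 0
            for key, grp in df.assign(_rep=rep).groupby(["population", "_rep"]):
                if np.any(np.diff(grp["time_days"].to_numpy()) <= 0):
                    report.errors.append(f"{name}: non-monotone times for {key}")
            if (df["count"] == 0).any():
                report.warnings.append(f"{name}: zero counts present")
        elif set(SEGMENT_COLUMNS) <= cols:
            if (df["end"] <= df["start"]).any():
                report.errors.append(f"{name}: segments with end <= start")
            for chrom, grp in df.groupby("chromosome"):
                g = grp.sort_values("start")
                if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                    report.errors.append(f"{name}: overlapping segments on chromosome {chrom}")
            if (df["copy_number"] < 0).any():
                report.warnings.append(f"{name}: negative copy numbers")
        elif {"sample_id", "patient_id", "day", "purity"} <= cols:
            for patient, grp in df.groupby("patient_id"):
                if np.any(np.diff(grp.sort_index()["day"].to_numpy()) <= 0):
                    report.errors.append(f"{name}: non-monotone sampling days for {patient}")
            if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
                report.errors.append(f"{name}: purity outside (0, 1]")
        else:
            report.errors.append(f"{name}: unrecognized schema (columns {sorted(cols)})")
    return report
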