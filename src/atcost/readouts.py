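"""Measurement transforms: caliper tumor volume, resistant abundance from
labelled counts, and relative DNA quantification by the ddCt method with a
standard-curve calibration."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CaliperMeasure",
    "CtRecord",
    "tumor_volume",
    "resistant_abundance",
    "AbundanceResult",
    "ddct_ratio",
    "StandardCurve",
    "calibrate_standard_curve",
]


@dataclass(frozen=True)
class CaliperMeasure:
    """One caliper measurement of a flank tumor (diameters in mm)."""

    short_diameter: float
    long_diameter: float
    day: float = 0.0
    flank: str = "target"

    def __post_init__(self) -> None:
        if self.short_diameter < 0 or self.long_diameter < 0:
            raise ValueError("diameters must be >= 0")


def tumor_volume(m: CaliperMeasure | None = None, short: float | None = None, long: float | None = None) -> float:
    """Ellipsoid caliper volume, pi * short^2 * long / 6, in mm^3.

    If the recorded short diameter exceeds the long one the two are
    swapped with a warning (caliper logs are noisy) rather than raising.
    """
    if m is not None:
        short, long = m.short_diameter, m.long_diameter
    if short is None or long is None:
        raise ValueError("provide a CaliperMeasure or both diameters")
    if short < 0 or long < 0:
        raise ValueError("diameters must be >= 0")
    if short > long:
        warnings.warn("short diameter exceeds long diameter; swapping")
        short, long = long, short
    return math.pi * short**2 * long / 6.0


class AbundanceResult(NamedTuple):
    count: float
    rule: str  # "rfp" or "total_minus_gfp"


def resistant_abundance(total: float, gfp_positive: float, rfp_positive: float | None = None) -> AbundanceResult:
    """Resistant cell count from labelled populations.

    Uses the direct RFP+ count when available, otherwise total - GFP+.
    The rule used is recorded in the result.
    """
    if not (0 <= gfp_positive <= total):
        raise ValueError("need 0 <= gfp_positive <= total")
    if rfp_positive is not None:
        if rfp_positive < 0:
            raise ValueError("rfp_positive must be >= 0")
        return AbundanceResult(float(rfp_positive), "rfp")
    return AbundanceResult(float(total - gfp_positive), "total_minus_gfp")


@dataclass(frozen=True)
class CtRecord:
    """qPCR threshold cycles for a target gene and a reference gene
    (GAPDH-style normalizer) in one sample."""

    ct_target: float
    ct_reference: float
    sample_id: str = ""
    calibrator: bool = False

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("Ct values must be finite and positive")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_ratio(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative quantity 2^(-ddCt) x 100 (percent of calibrator).

    ddCt = (Ct_target - Ct_reference)_sample - (same)_calibrator.  Assumes
    100% amplification efficiency, as the 2^(-ddCt) form implies.
    """
    ddct = sample.dct - calibrator.dct
    return 100.0 * 2.0 ** (-ddct)


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration of measured 2^(-ddCt)x100 values against known input
    ratios; maps future measurements back to the input-ratio scale."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def to_input(self, measured) -> np.ndarray:
        """Invert the calibration: measured percent -> input-ratio percent."""
        return (np.asarray(measured, dtype=float) - self.intercept) / self.slope

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "n": self.n,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "StandardCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["slope"], d["intercept"], d["r_squared"], d["n"])


def calibrate_standard_curve(measured: Sequence[float], known_input: Sequence[float]) -> StandardCurve:
    """Fit measured = slope*known + intercept by OLS and report Pearson R^2.

    Requires >= 3 paired points and nonzero variance in the known inputs.
    """
    measured = np.asarray(measured, dtype=float)
    known = np.asarray(known_input, dtype=float)
    if measured.shape != known.shape or measured.ndim != 1:
        raise ValueError("measured and known_input must be aligned 1-d sequences")
    if len(measured) < 3:
        raise ValueError("need >= 3 paired points for a standard curve")
    if np.ptp(known) == 0:
        raise ValueError("zero variance in known_input")
    res = stats.linregress(known, measured)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(measured),
    )
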