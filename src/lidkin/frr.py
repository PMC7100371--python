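"""Pump-offset calibration and corrected fragmentation-ratio curves.

The visible probe's fragmentation ratio FRR is the fraction of the radical
population it fragments:

    FRR = IF_Vis / (IF_Vis + IR)

The UV pump contributes silver-free fragments too, at a constant ratio
α = IF_UV / IF_Ag to its silver-containing fragments, so the measurable
silver-free intensity IF overstates IF_Vis.  α is calibrated from
negative-delay (probe-first) control spectra and the corrected ratio

    FRR = (IF − α·IF_Ag) / (IR + IF − α·IF_Ag)

is computed per spectrum, then averaged per delay with its standard error
of the mean over the acquisition repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import ChannelIntensities

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaCalibration",
    "FrrPoint",
    "FrrCurve",
    "CalibrationError",
    "estimate_alpha",
    "compute_frr",
    "build_curve",
]


class CalibrationError(ValueError):
    """Raised when the pump ratio α cannot be determined."""


@dataclass(frozen=True)
class AlphaCalibration:
    """Pooled pump ratio α = ΣIF / ΣIF_Ag over control spectra."""

    alpha: float
    n_control: int
    se_alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.se_alpha < 0 or self.n_control < 1:
            raise ValueError("invalid calibration")


@dataclass(frozen=True)
class FrrPoint:
    """Per-delay mean fragmentation ratio with its standard error."""

    delay: float
    frr_mean: float
    frr_sem: float
    n: int
    samples: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.frr_sem < 0:
            raise ValueError("invalid FRR point")


@dataclass
class FrrCurve:
    """Delay-ordered FRR curve, with negative-delay controls kept aside."""

    points: list[FrrPoint]
    controls: list[FrrPoint] = field(default_factory=list)

    def delays(self) -> np.ndarray:
        return np.array([p.delay for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delay_s": [p.delay for p in self.points],
                "frr_mean": [p.frr_mean for p in self.points],
                "frr_sem": [p.frr_sem for p in self.points],
                "n": [p.n for p in self.points],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrrCurve":
        points = [
            FrrPoint(float(r.delay_s), float(r.frr_mean), float(r.frr_sem), int(r.n))
            for r in df.itertuples()
        ]
        points.sort(key=lambda p: p.delay)
        return cls(points=points)


def estimate_alpha(controls: list[ChannelIntensities]) -> AlphaCalibration:
    """Calibrate α from negative-delay control spectra.

    Uses the pooled ratio ΣIF / ΣIF_Ag rather than a mean of per-spectrum
    ratios (less biased at low counts).  The standard error follows from
    Poisson counting statistics on the two pooled sums:
    Var(α) ≈ (ΣIF + α²·ΣIF_Ag) / (ΣIF_Ag)².
    """
    if not controls:
        raise CalibrationError("no control spectra supplied")
    if any(c.delay >= 0 for c in controls):
        raise CalibrationError("controls must all have negative delay")
    f = float(sum(c.i_f for c in controls))
    g = float(sum(c.i_f_ag for c in controls))
    if g == 0:
        raise CalibrationError("total silver-containing intensity is zero; α undefined")
    alpha = f / g
    se = math.sqrt(f + alpha * alpha * g) / g
    return AlphaCalibration(alpha=alpha, n_control=len(controls), se_alpha=se)


def compute_frr(
    channels: ChannelIntensities, alpha: float, *, floor: bool = True
) -> float:
    """Corrected fragmentation ratio of one spectrum.

    The corrected numerator IF − α·IF_Ag is floored at 0 by default (noise
    can push it negative; FRR is a population fraction), which bounds the
    result in [0, 1].  Pass ``floor=False`` to keep negative excursions
    for bias studies.  An empty spectrum (zero numerator and IR) gives 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    num = channels.i_f - alpha * channels.i_f_ag
    if floor:
        num = max(num, 0.0)
    den = channels.i_r + num
    if den == 0.0:
        logger.warning(
            "empty spectrum at delay %.3g s (replicate %d); FRR set to 0",
            channels.delay,
            channels.replicate_id,
        )
        return 0.0
    return num / den


def _aggregate(delay: float, values: np.ndarray, keep_samples: bool) -> FrrPoint:
    n = values.size
    # identical repeats give an exact 0, not mean-subtraction rounding dust
    if n == 1 or np.ptp(values) == 0.0:
        sem = 0.0
    else:
        sem = float(values.std(ddof=1) / math.sqrt(n))
    return FrrPoint(
        delay=delay,
        frr_mean=float(values.mean()),
        frr_sem=sem,
        n=n,
        samples=tuple(values) if keep_samples else None,
    )


def build_curve(
    dataset: list[ChannelIntensities],
    calib: AlphaCalibration | float,
    *,
    floor: bool = True,
    keep_samples: bool = False,
) -> FrrCurve:
    """Per-delay mean FRR with SEM over repeats.

    Positive delays form the curve (sorted by delay); negative-delay
    controls are aggregated the same way but reported separately in
    ``FrrCurve.controls``.  ``keep_samples`` retains the per-spectrum FRR
    values on each point for nonparametric bootstrapping.
    """
    if not dataset:
        raise ValueError("empty dataset")
    alpha = calib.alpha if isinstance(calib, AlphaCalibration) else float(calib)
    by_delay: dict[float, list[float]] = {}
    for ch in dataset:
        by_delay.setdefault(ch.delay, []).append(compute_frr(ch, alpha, floor=floor))
    points, controls = [], []
    for delay in sorted(by_delay):
        point = _aggregate(delay, np.asarray(by_delay[delay]), keep_samples)
        (controls if delay < 0 else points).append(point)
    return FrrCurve(points=points, controls=controls)
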