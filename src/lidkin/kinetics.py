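"""Mono-exponential proton-transfer kinetics: fitting, bootstrap, aggregation.

Above ~30 μs (once the metastable silver complex has dissociated) the
fragmentation ratio decays as

    FRR(t) = offset − amplitude · (1 − exp(−t / tau2))

toward a non-zero end level, because the distonic end state still absorbs
the probe.  ``tau2`` is the internal proton-transfer time constant.
Uncertainty is quantified by a parametric bootstrap — each per-delay mean
is resampled from Normal(mean, SEM), the fit repeated, and the spread of
the refitted parameters reported.  Day-level replicate fits are combined
by inverse-variance (1/σ²) weighting.

Decays slower than the 20 ms delay window cannot be resolved; such fits
are censored and reported as a lower bound (τ₂ > 5 ms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .frr import FrrCurve, FrrPoint

__all__ = [
    "DecayFit",
    "ReplicateSummary",
    "FitError",
    "decay_model",
    "fit_decay",
    "censor_slow",
    "weighted_average",
]

#: Parameter bounds (offset, amplitude, tau2): FRR is a fraction, small
#: negative amplitudes are allowed for pathological rises, and tau2 is
#: confined to the physically resolvable decade span around the delay window.
_BOUNDS_LO = np.array([0.0, -0.5, 1e-6])
_BOUNDS_HI = np.array([1.0, 1.0, 1.0])

DEFAULT_T_MIN = 30e-6
DEFAULT_N_BOOT = 10_000
CENSOR_BOUND = 5e-3


class FitError(RuntimeError):
    """Raised when a decay fit cannot be performed."""


def decay_model(t, offset, amplitude, tau2):
    """offset − amplitude·(1 − exp(−t/tau2))."""
    return offset - amplitude * (1.0 - np.exp(-np.asarray(t) / tau2))


@dataclass(frozen=True)
class DecayFit:
    """Fitted decay parameters with bootstrap uncertainties.

    ``offset``/``amplitude``/``tau2`` are the means of the bootstrap
    parameter draws; ``sigma_*`` their standard deviations.  ``censored``
    marks decays the delay window cannot resolve, with ``bound`` the
    reported lower limit on tau2.  ``reliable`` is False when more than
    20% of bootstrap refits failed to converge.
    """

    offset: float
    amplitude: float
    tau2: float
    sigma_offset: float
    sigma_amplitude: float
    sigma_tau2: float
    n_boot: int
    seed: int | None
    n_points: int
    censored: bool = False
    bound: float | None = None
    reliable: bool = True
    t_min: float = DEFAULT_T_MIN
    param_draws: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.censored and not self.tau2 > 0:
            raise ValueError("tau2 must be positive for an uncensored fit")
        if min(self.sigma_offset, self.sigma_amplitude, self.sigma_tau2) < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @property
    def tau2_us(self) -> float:
        return self.tau2 * 1e6

    def describe(self) -> str:
        if self.censored:
            return f"tau2 > {self.bound * 1e6:.0f} us (censored)"
        return f"tau2 = {self.tau2_us:.0f} +/- {self.sigma_tau2 * 1e6:.0f} us"

    def to_dict(self) -> dict:
        return {
            "fit_offset": self.offset,
            "amplitude": self.amplitude,
            "tau2_s": self.tau2,
            "sigma_offset": self.sigma_offset,
            "sigma_amplitude": self.sigma_amplitude,
            "sigma_tau2_s": self.sigma_tau2,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_points": self.n_points,
            "censored": self.censored,
            "bound_s": self.bound,
            "reliable": self.reliable,
            "t_min_s": self.t_min,
        }

    def to_json(self, path: str | Path, **extra) -> None:
        Path(path).write_text(json.dumps({**self.to_dict(), **extra}, indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "DecayFit":
        return cls(
            offset=d["fit_offset"],
            amplitude=d["amplitude"],
            tau2=d["tau2_s"],
            sigma_offset=d["sigma_offset"],
            sigma_amplitude=d["sigma_amplitude"],
            sigma_tau2=d["sigma_tau2_s"],
            n_boot=d["n_boot"],
            seed=d.get("seed"),
            n_points=d["n_points"],
            censored=d.get("censored", False),
            bound=d.get("bound_s"),
            reliable=d.get("reliable", True),
            t_min=d.get("t_min_s", DEFAULT_T_MIN),
        )


def _residuals(p, t, y, w):
    return (decay_model(t, *p) - y) * w


def _jacobian(p, t, y, w):
    offset, amplitude, tau2 = p
    e = np.exp(-t / tau2)
    jac = np.empty((t.size, 3))
    jac[:, 0] = 1.0
    jac[:, 1] = -(1.0 - e)
    jac[:, 2] = amplitude * e * t / tau2**2
    return jac * w[:, None]


def _point_fit(t, y, w, x0):
    res = least_squares(
        _residuals,
        x0,
        jac=_jacobian,
        bounds=(_BOUNDS_LO, _BOUNDS_HI),
        args=(t, y, w),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    return res.x, bool(res.success)


def _start_values(t, y):
    offset = float(np.clip(y[0], 0.0, 1.0))
    amplitude = float(np.clip(y[0] - y[-1], -0.4, 0.9))
    if abs(amplitude) < 1e-3:
        amplitude = 1e-3
    tau2 = float(np.clip(np.median(t), 1e-6, 1.0))
    return np.array([offset, amplitude, tau2])


def fit_decay(
    curve: FrrCurve | Sequence[FrrPoint],
    t_min: float = DEFAULT_T_MIN,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    weighted: bool = True,
    bootstrap: str = "parametric",
    auto_censor: bool = True,
    keep_draws: bool = True,
) -> DecayFit:
    """Fit the decay to all points with delay > ``t_min``.

    The point fit is a bounded trust-region least squares, weighted
    1/SEM² (unit weights when any SEM is zero or ``weighted=False``).
    Bootstrap modes:

    - ``"parametric"`` (default): each per-delay mean is redrawn from
      Normal(mean, SEM) and refit, ``n_boot`` times.
    - ``"nonparametric"``: the per-spectrum FRR values stored on each
      point (``build_curve(..., keep_samples=True)``) are resampled with
      replacement per delay.

    Reported parameters are the mean of the bootstrap draws; sigmas their
    standard deviation.  Deterministic for a fixed ``seed``.  With
    ``auto_censor`` the slow-decay censoring rule is applied before
    returning.
    """
    points = curve.points if isinstance(curve, FrrCurve) else list(curve)
    fit_pts = [p for p in points if p.delay > t_min]
    if len(fit_pts) < 4:
        raise FitError(
            f"need >= 4 points above t_min={t_min:g} s, have {len(fit_pts)}"
        )
    t = np.array([p.delay for p in fit_pts])
    y = np.array([p.frr_mean for p in fit_pts])
    sem = np.array([p.frr_sem for p in fit_pts])
    if weighted and np.all(sem > 0):
        w = 1.0 / sem
    else:
        w = np.ones_like(t)

    x0 = _start_values(t, y)
    x_hat, _ = _point_fit(t, y, w, x0)

    if bootstrap == "nonparametric":
        samples = [p.samples for p in fit_pts]
        if any(s is None for s in samples):
            raise FitError(
                "nonparametric bootstrap needs per-spectrum samples; "
                "build the curve with keep_samples=True"
            )
        samples = [np.asarray(s) for s in samples]
    elif bootstrap != "parametric":
        raise ValueError(f"unknown bootstrap mode {bootstrap!r}")

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    n_fail = 0
    for b in range(n_boot):
        if bootstrap == "parametric":
            y_b = rng.normal(y, sem)
        else:
            y_b = np.array(
                [rng.choice(s, size=s.size, replace=True).mean() for s in samples]
            )
        draws[b], ok = _point_fit(t, y_b, w, x_hat)
        if not ok:
            n_fail += 1

    center = draws.mean(axis=0)
    spread = draws.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(3)
    fit = DecayFit(
        offset=float(center[0]),
        amplitude=float(center[1]),
        tau2=float(center[2]),
        sigma_offset=float(spread[0]),
        sigma_amplitude=float(spread[1]),
        sigma_tau2=float(spread[2]),
        n_boot=n_boot,
        seed=seed,
        n_points=len(fit_pts),
        reliable=(n_fail <= 0.2 * n_boot),
        t_min=t_min,
        param_draws=draws if keep_draws else None,
    )
    return censor_slow(fit) if auto_censor else fit


def censor_slow(
    fit: DecayFit, t_max_window: float = 20e-3, bound: float = CENSOR_BOUND
) -> DecayFit:
    """Censor decays the delay window cannot resolve.

    A fit is censored — reported as ``tau2 > bound`` (5 ms default, i.e.
    ">5000 μs") — when the fitted tau2 exceeds the bound or when the
    amplitude is not resolved at 2σ (flat curve).  ``bound`` must not
    exceed the widest measured delay ``t_max_window``.
    """
    if bound > t_max_window:
        raise ValueError("censoring bound cannot exceed the delay window")
    if fit.censored:
        return fit
    if fit.tau2 > bound or fit.amplitude < 2.0 * fit.sigma_amplitude:
        return replace(fit, censored=True, bound=bound)
    return fit


@dataclass(frozen=True)
class ReplicateSummary:
    """Inverse-variance weighted combination of day-level replicate fits."""

    tau2_mean: float
    sigma: float
    n_replicates: int
    replicates: tuple[tuple[float, float], ...]

    @property
    def tau2_mean_us(self) -> float:
        return self.tau2_mean * 1e6


def weighted_average(replicates: Sequence[tuple[float, float]]) -> ReplicateSummary:
    """Combine replicate (tau2, sigma) pairs by 1/σ² weighting.

    tau2_mean = Σ(τᵢ/σᵢ²)/Σ(1/σᵢ²);  σ = (Σ 1/σᵢ²)^(−1/2).

    The combined mean lies in the convex hull of the replicate values and
    the combined σ never exceeds the smallest replicate σ.  Censored fits
    must be excluded upstream; any σ ≤ 0 is rejected.
    """
    if not replicates:
        raise ValueError("no replicates to average")
    tau = np.array([r[0] for r in replicates], dtype=float)
    sig = np.array([r[1] for r in replicates], dtype=float)
    if np.any(sig <= 0):
        raise ValueError("all replicate sigmas must be positive")
    w = 1.0 / sig**2
    return ReplicateSummary(
        tau2_mean=float((tau * w).sum() / w.sum()),
        sigma=float(1.0 / math.sqrt(w.sum())),
        n_replicates=len(replicates),
        replicates=tuple((float(a), float(b)) for a, b in replicates),
    )
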