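"""Forward simulator for pump–probe photofragmentation experiments.

Emulates the measurement chain on silver-cationized Trp/His peptides:
a UV pump photoexcites the [peptide, Ag]+ complex, electron transfer and
neutral-Ag loss (time constant ``tau1``) leave a radical peptide cation
whose charge migrates to histidine by intramolecular proton transfer
(``tau2``), converting it into a distonic ion.  A delayed visible probe
fragments the radical population with a yield that depends on where the
charge sits, which is what the fragmentation ratio tracks.

Rendered spectra contain the surviving parent, probe-induced silver-free
loss channels (M−129 / M−185, or m/z 130 / 186 for His-free peptides),
and pump-induced fragments: silver-containing species as Ag-isotope
doublets plus silver-free species at a fixed ratio ``alpha_true`` feeding
the same loss channels — the background the pipeline's α correction
removes.  Channel intensities carry Poisson (ion-counting) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .isotopes import (
    AG107_ABUNDANCE,
    AG107_MASS,
    AG109_ABUNDANCE,
    AG_DOUBLET_SPLIT,
    INDOLE_LOSS,
    TRP_CTERM_LOSS,
)
from .spectra import Spectrum

__all__ = [
    "KineticParams",
    "DelaySchedule",
    "SyntheticDataset",
    "simulate_populations",
    "channel_positions",
    "expected_channels",
    "expected_frr",
    "render_spectrum",
    "generate_experiment",
]

_EQUAL_TAU_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth parameters of the simulated photo-physics.

    Attributes
    ----------
    tau1 : float
        Lifetime (s) of the metastable [radical peptide, Ag0] complex
        before neutral-silver loss.
    tau2 : float
        Proton-transfer time constant (s), radical → distonic.
    n0 : float
        Mean pump-generated radical population per spectrum (ion counts).
    probe_yield_radical, probe_yield_distonic : float
        Probe fragmentation probabilities of the radical and distonic
        forms; the distonic yield must not exceed the radical yield.
    pump_frag_ag : float
        Mean pump-induced silver-containing fragment count per spectrum.
    alpha_true : float
        Pump-induced silver-free : silver-containing fragment ratio.
    channel_split : float
        Fraction of silver-free fragments landing in the 129-loss channel
        (the remainder goes to the 185-loss channel).
    has_histidine : bool
        With histidine the charge stays on the large fragment (channels at
        M−129 / M−185); without it the small fragment keeps the charge
        (channels at m/z 130 / 186).
    parent_mz : float
        m/z of the radical peptide cation M (z = 1).
    """

    tau1: float = 200e-9
    tau2: float = 825e-6
    n0: float = 2000.0
    probe_yield_radical: float = 0.25
    probe_yield_distonic: float = 0.10
    pump_frag_ag: float = 500.0
    alpha_true: float = 0.4
    channel_split: float = 0.65
    has_histidine: bool = True
    parent_mz: float = 755.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")
        for name in ("probe_yield_radical", "probe_yield_distonic", "channel_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.probe_yield_distonic > self.probe_yield_radical:
            raise ValueError("probe_yield_distonic must not exceed probe_yield_radical")
        if self.alpha_true < 0 or self.pump_frag_ag < 0 or self.n0 < 0:
            raise ValueError("counts and ratios must be non-negative")


@dataclass(frozen=True)
class DelaySchedule:
    """Delay list design: log-spaced positive delays plus negative controls."""

    n_delays: int = 200
    t_min: float = 50e-9
    t_max: float = 20e-3
    n_negative: int = 5
    n_repeats: int = 120

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_delays < 1:
            raise ValueError("n_repeats and n_delays must be >= 1")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")

    def positive_delays(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_delays)

    def negative_delays(self) -> np.ndarray:
        if self.n_negative == 0:
            return np.empty(0)
        return -1e-3 * np.arange(self.n_negative, 0, -1, dtype=float)

    def all_delays(self) -> np.ndarray:
        return np.concatenate([self.negative_delays(), self.positive_delays()])


def simulate_populations(params: KineticParams, t):
    """Population fractions (complex, radical, distonic) at delay ``t``.

    Sequential first-order kinetics complex → radical → distonic with
    rate constants 1/tau1 and 1/tau2:

        c(t) = exp(-t/tau1)
        r(t) = tau2/(tau2 - tau1) * (exp(-t/tau2) - exp(-t/tau1))
        d(t) = 1 - c(t) - r(t)

    The degenerate tau1 == tau2 case uses r(t) = (t/tau) exp(-t/tau).
    Accepts scalar or array ``t`` (must be >= 0); fractions each lie in
    [0, 1] and sum to 1 to numerical precision.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("delay must be non-negative (controls are pre-pump)")
    tau1, tau2 = params.tau1, params.tau2
    c = np.exp(-t / tau1)
    if abs(tau1 - tau2) <= _EQUAL_TAU_RTOL * max(tau1, tau2):
        r = (t / tau2) * np.exp(-t / tau2)
    else:
        r = tau2 / (tau2 - tau1) * (np.exp(-t / tau2) - np.exp(-t / tau1))
    d = np.maximum(1.0 - c - r, 0.0)
    if t.ndim == 0:
        return float(c), float(r), float(d)
    return c, r, d


def channel_positions(params: KineticParams) -> dict[str, float]:
    """m/z of every rendered channel, keyed by channel label."""
    m = params.parent_mz
    if params.has_histidine:
        free_lo, free_hi = m - INDOLE_LOSS, m - TRP_CTERM_LOSS
    else:
        free_lo, free_hi = float(INDOLE_LOSS + 1), float(TRP_CTERM_LOSS + 1)
    pump_ag = m + AG107_MASS - INDOLE_LOSS
    return {
        "parent": m,
        "free_129": free_lo,
        "free_185": free_hi,
        "pump_ag_107": pump_ag,
        "pump_ag_109": pump_ag + AG_DOUBLET_SPLIT,
    }


def expected_channels(params: KineticParams, t: float) -> dict[str, float]:
    """Noise-free expected intensity of every channel at delay ``t``.

    Negative delays represent probe-before-pump controls: the pump still
    fires, so pump channels are present, but no radical exists at probe
    time and the parent pool survives intact.
    """
    if t < 0:
        probe = 0.0
        parent = params.n0
    else:
        c, r, d = simulate_populations(params, t)
        probe = params.n0 * (
            r * params.probe_yield_radical + d * params.probe_yield_distonic
        )
        parent = params.n0 * (
            c
            + r * (1.0 - params.probe_yield_radical)
            + d * (1.0 - params.probe_yield_distonic)
        )
    free_total = probe + params.alpha_true * params.pump_frag_ag
    return {
        "parent": parent,
        "free_129": params.channel_split * free_total,
        "free_185": (1.0 - params.channel_split) * free_total,
        "pump_ag_107": AG107_ABUNDANCE * params.pump_frag_ag,
        "pump_ag_109": AG109_ABUNDANCE * params.pump_frag_ag,
    }


def expected_frr(params: KineticParams, t: float) -> float:
    """Closed-form expected fragmentation ratio after exact α correction.

    With the pump background removed exactly, FRR(t) is the probe-induced
    fragment fraction of the radical/distonic pool.  For t >> tau1 it
    reduces to the mono-exponential
    ``probe_yield_radical - (probe_yield_radical - probe_yield_distonic)
    * (1 - exp(-t/tau2))``.
    """
    if t < 0:
        return 0.0
    c, r, d = simulate_populations(params, t)
    probe = params.n0 * (
        r * params.probe_yield_radical + d * params.probe_yield_distonic
    )
    parent = params.n0 * (
        c
        + r * (1.0 - params.probe_yield_radical)
        + d * (1.0 - params.probe_yield_distonic)
    )
    if probe == 0.0:
        return 0.0
    return probe / (probe + parent)


def _sample_spectrum(
    positions: dict[str, float],
    means: dict[str, float],
    delay: float,
    replicate_id: int,
    rng: np.random.Generator | None,
    meta: dict[str, Any] | None = None,
) -> Spectrum:
    labels = list(positions)
    mz = np.array([positions[k] for k in labels])
    mu = np.array([means[k] for k in labels])
    inten = mu if rng is None else rng.poisson(mu).astype(float)
    keep = inten > 0
    order = np.argsort(mz[keep])
    return Spectrum(
        mz=mz[keep][order],
        intensity=inten[keep][order],
        delay=delay,
        replicate_id=replicate_id,
        meta=meta or {},
    )


def render_spectrum(
    params: KineticParams,
    t: float,
    seed: int | None = None,
    *,
    replicate_id: int = 0,
    noise: bool = True,
) -> Spectrum:
    """Render one centroid spectrum at pump–probe delay ``t``.

    With ``noise=True`` each channel is an independent Poisson draw around
    its expectation (the Ag doublet is thinned into its two isotopologues);
    with ``noise=False`` intensities equal the expectations exactly.
    """
    rng = np.random.default_rng(seed) if noise else None
    return _sample_spectrum(
        channel_positions(params), expected_channels(params, t), t, replicate_id, rng
    )


@dataclass
class SyntheticDataset:
    """A generated experiment plus the ground truth that produced it."""

    spectra: list[Spectrum]
    params: KineticParams
    schedule: DelaySchedule
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def truth(self) -> dict[str, Any]:
        return {
            "params": asdict(self.params),
            "schedule": asdict(self.schedule),
            "seed": self.seed,
        }

    def __len__(self) -> int:
        return len(self.spectra)


def generate_experiment(
    params: KineticParams,
    schedule: DelaySchedule,
    seed: int,
    *,
    noise: bool = True,
) -> SyntheticDataset:
    """Generate a full pump–probe dataset.

    Produces ``(n_delays + n_negative) * n_repeats`` spectra.  Each
    spectrum's random stream is keyed by ``(seed, delay index, repeat)``
    through ``numpy.random.SeedSequence``, so the output is bit-identical
    for a given seed and unaffected by changing later repeat counts.
    """
    delays = schedule.all_delays()
    positions = channel_positions(params)
    spectra: list[Spectrum] = []
    for di, t in enumerate(delays):
        means = expected_channels(params, float(t))
        for rep in range(schedule.n_repeats):
            rng = (
                np.random.default_rng(np.random.SeedSequence([seed, di, rep]))
                if noise
                else None
            )
            spectra.append(_sample_spectrum(positions, means, float(t), rep, rng))
    return SyntheticDataset(spectra=spectra, params=params, schedule=schedule, seed=seed)
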