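"""High-level chains from raw spectra to fitted proton-transfer kinetics."""

from __future__ import annotations

import logging
from typing import Sequence

from .fragments import ChannelIntensities, build_channel_table, quantify_channels
from .frr import AlphaCalibration, FrrCurve, build_curve, estimate_alpha
from .kinetics import DEFAULT_N_BOOT, DEFAULT_T_MIN, DecayFit, fit_decay
from .spectra import PeakWindow, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["quantify_dataset", "process_spectra", "analyze_dataset"]


def quantify_dataset(
    spectra: Sequence[Spectrum],
    parent_mz: float,
    channel_table: Sequence[PeakWindow] | None = None,
    *,
    has_histidine: bool = True,
) -> list[ChannelIntensities]:
    """Integrate IR/IF/IF_Ag for every spectrum in a dataset."""
    if channel_table is None:
        channel_table = build_channel_table(parent_mz, has_histidine=has_histidine)
    return [quantify_channels(s, parent_mz, channel_table) for s in spectra]


def process_spectra(
    spectra: Sequence[Spectrum],
    parent_mz: float,
    channel_table: Sequence[PeakWindow] | None = None,
    *,
    has_histidine: bool = True,
    floor: bool = True,
    keep_samples: bool = False,
) -> tuple[FrrCurve, AlphaCalibration]:
    """Quantify channels, calibrate α on the controls, build the FRR curve."""
    channels = quantify_dataset(
        spectra, parent_mz, channel_table, has_histidine=has_histidine
    )
    controls = [c for c in channels if c.delay < 0]
    calib = estimate_alpha(controls)
    logger.info(
        "alpha = %.4f +/- %.4f from %d control spectra",
        calib.alpha,
        calib.se_alpha,
        calib.n_control,
    )
    curve = build_curve(channels, calib, floor=floor, keep_samples=keep_samples)
    return curve, calib


def analyze_dataset(
    spectra: Sequence[Spectrum],
    parent_mz: float,
    channel_table: Sequence[PeakWindow] | None = None,
    *,
    has_histidine: bool = True,
    t_min: float = DEFAULT_T_MIN,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> tuple[DecayFit, FrrCurve, AlphaCalibration]:
    """Full single-dataset chain: spectra → α → FRR curve → decay fit."""
    curve, calib = process_spectra(
        spectra, parent_mz, channel_table, has_histidine=has_histidine
    )
    fit = fit_decay(curve, t_min=t_min, n_boot=n_boot, seed=seed)
    return fit, curve, calib
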