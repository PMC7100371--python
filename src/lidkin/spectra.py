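"""Centroided mass-spectrum container, I/O, and windowed peak integration.

The pipeline's atomic input is a single centroided spectrum tagged with the
pump–probe delay at which it was acquired.  Negative delays (probe before
pump) are legal and mark control acquisitions used for pump-offset
calibration.  Datasets are stored as JSON-lines (one spectrum per line) or
long-format CSV; an mzML adapter is available when pyteomics is installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "PeakWindow",
    "SpectrumParseError",
    "integrate_peak",
    "read_dataset",
    "write_dataset",
    "read_csv_dataset",
    "write_csv_dataset",
    "read_mzml",
]


class SpectrumParseError(ValueError):
    """Raised when a dataset file contains a malformed or invalid record."""


@dataclass
class Spectrum:
    """One centroided mass spectrum with pump–probe metadata.

    Parameters
    ----------
    mz : ndarray
        Centroid mass-to-charge values in Th, strictly increasing.
    intensity : ndarray
        Non-negative centroid intensities (arbitrary units / ion counts),
        same length as ``mz``.
    delay : float
        Pump–probe delay in seconds.  Negative values flag control spectra
        recorded with the probe preceding the pump.
    replicate_id : int
        Non-negative acquisition repeat index within a delay.
    meta : dict
        Free-form tags (peptide name, trap pressure label, ...).
    """

    mz: np.ndarray
    intensity: np.ndarray
    delay: float
    replicate_id: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if not np.isfinite(self.delay):
            raise ValueError("delay must be finite")
        if self.replicate_id < 0:
            raise ValueError("replicate_id must be >= 0")

    @property
    def is_control(self) -> bool:
        """True for negative-delay (probe-first) control acquisitions."""
        return self.delay < 0

    @property
    def total_ion_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class PeakWindow:
    """Inclusive integration window ``center ± half_width`` for one channel."""

    center: float
    half_width: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


def integrate_peak(spectrum: Spectrum, window: PeakWindow) -> float:
    """Sum centroid intensities with ``|mz - center| <= half_width``.

    Returns 0.0 when no centroid falls inside the window; boundaries are
    inclusive on both sides.
    """
    lo = np.searchsorted(spectrum.mz, window.lo, side="left")
    hi = np.searchsorted(spectrum.mz, window.hi, side="right")
    return float(spectrum.intensity[lo:hi].sum())


# ---------------------------------------------------------------------------
# JSON-lines dataset dialect:
#   {"delay_s": float, "replicate": int, "mz": [...], "intensity": [...],
#    "meta": {...}}
# ---------------------------------------------------------------------------

def _spectrum_to_record(s: Spectrum) -> dict[str, Any]:
    return {
        "delay_s": s.delay,
        "replicate": int(s.replicate_id),
        "mz": s.mz.tolist(),
        "intensity": s.intensity.tolist(),
        "meta": s.meta,
    }


def _record_to_spectrum(rec: dict[str, Any], lineno: int) -> Spectrum:
    try:
        return Spectrum(
            mz=np.asarray(rec["mz"], dtype=float),
            intensity=np.asarray(rec["intensity"], dtype=float),
            delay=float(rec["delay_s"]),
            replicate_id=int(rec.get("replicate", 0)),
            meta=dict(rec.get("meta", {})),
        )
    except KeyError as exc:
        raise SpectrumParseError(f"line {lineno}: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise SpectrumParseError(f"line {lineno}: {exc}") from exc


def write_dataset(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as JSON-lines; floats use shortest round-trip repr."""
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            fh.write(json.dumps(_spectrum_to_record(s)) + "\n")


def read_dataset(path: str | Path) -> list[Spectrum]:
    """Read a JSON-lines dataset.

    Returns all spectra (controls retained) sorted by ``(replicate_id,
    delay)``.  Malformed rows raise :class:`SpectrumParseError` naming the
    line number; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SpectrumParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            spectra.append(_record_to_spectrum(rec, lineno))
    if not spectra:
        logger.warning("dataset %s is empty", path)
    spectra.sort(key=lambda s: (s.replicate_id, s.delay))
    return spectra


def iter_dataset(path: str | Path) -> Iterator[Spectrum]:
    """Stream spectra from a JSON-lines dataset without sorting."""
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                yield _record_to_spectrum(json.loads(line), lineno)


def write_csv_dataset(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in long format (replicate, delay_s, mz, intensity)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "replicate": s.replicate_id,
                    "delay_s": s.delay,
                    "mz": s.mz,
                    "intensity": s.intensity,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_csv_dataset(path: str | Path) -> list[Spectrum]:
    """Read a long-format CSV dataset (columns replicate, delay_s, mz, intensity)."""
    df = pd.read_csv(path)
    required = {"replicate", "delay_s", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SpectrumParseError(f"CSV missing columns: {sorted(missing)}")
    spectra = []
    for (rep, delay), grp in df.groupby(["replicate", "delay_s"], sort=False):
        grp = grp.sort_values("mz")
        spectra.append(
            Spectrum(
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                delay=float(delay),
                replicate_id=int(rep),
            )
        )
    spectra.sort(key=lambda s: (s.replicate_id, s.delay))
    return spectra


def read_mzml(path: str | Path, delay_key: str = "delay_s") -> list[Spectrum]:
    """Import centroided spectra from mzML (requires pyteomics).

    The pump–probe delay is looked up in each spectrum's user parameters
    under ``delay_key``; spectra without it get delay 0.
    """
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("mzML import requires the 'pyteomics' package") from exc
    spectra = []
    with _mzml.read(str(path)) as reader:
        for i, rec in enumerate(reader):
            order = np.argsort(rec["m/z array"])
            spectra.append(
                Spectrum(
                    mz=np.asarray(rec["m/z array"])[order],
                    intensity=np.asarray(rec["intensity array"])[order],
                    delay=float(rec.get(delay_key, 0.0)),
                    replicate_id=i,
                    meta={"id": rec.get("id", "")},
                )
            )
    return spectra
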