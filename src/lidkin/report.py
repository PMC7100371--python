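"""Summary tables and FRR-curve plots.

Tables mirror the field's reporting convention: one row per system with
the inverse-variance weighted mean τ₂ (μs), its combined σ, and the
individual replicate fits; unresolvably slow systems appear as
">BOUND" lower bounds.  All plot error bars are 2σ (95.4% window).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frr import FrrCurve
from .kinetics import CENSOR_BOUND, DecayFit, ReplicateSummary, decay_model

logger = logging.getLogger(__name__)

__all__ = ["SummaryRow", "report_table", "parse_summary_table", "plot_frr_curve"]


@dataclass(frozen=True)
class SummaryRow:
    """One reporting row, in μs (table-facing units)."""

    system: str
    summary: ReplicateSummary | None = None
    censored_bound_us: float | None = None

    @classmethod
    def from_summary(
        cls, system: str, summary: ReplicateSummary, *, units: str = "us"
    ) -> "SummaryRow":
        """Wrap a :class:`ReplicateSummary`; ``units="s"`` converts to μs."""
        if units == "s":
            scale = 1e6
            summary = ReplicateSummary(
                tau2_mean=summary.tau2_mean * scale,
                sigma=summary.sigma * scale,
                n_replicates=summary.n_replicates,
                replicates=tuple((t * scale, s * scale) for t, s in summary.replicates),
            )
        elif units != "us":
            raise ValueError("units must be 's' or 'us'")
        return cls(system=system, summary=summary)

    @classmethod
    def censored(cls, system: str, bound_us: float = CENSOR_BOUND * 1e6) -> "SummaryRow":
        return cls(system=system, censored_bound_us=bound_us)


def _fmt_replicates(summary: ReplicateSummary) -> str:
    return ";".join(f"{t:g}/{s:g}" for t, s in summary.replicates)


def report_table(rows: Sequence[SummaryRow], *, fmt: str = "csv") -> str:
    """Render summary rows as CSV (default) or Markdown.

    Columns: system, tau2_us, sigma_us, n_replicates, replicates (each
    replicate as ``tau/sigma``, ``;``-separated).  Censored systems render
    as ``>BOUND`` with empty σ; rows with neither a summary nor a bound
    are omitted with a warning.
    """
    records = []
    for row in rows:
        if row.censored_bound_us is not None:
            records.append(
                {
                    "system": row.system,
                    "tau2_us": f">{row.censored_bound_us:g}",
                    "sigma_us": "",
                    "n_replicates": 0,
                    "replicates": "",
                }
            )
        elif row.summary is not None and row.summary.n_replicates > 0:
            records.append(
                {
                    "system": row.system,
                    "tau2_us": f"{row.summary.tau2_mean:g}",
                    "sigma_us": f"{row.summary.sigma:g}",
                    "n_replicates": row.summary.n_replicates,
                    "replicates": _fmt_replicates(row.summary),
                }
            )
        else:
            logger.warning("system %s has no replicates; row omitted", row.system)
    df = pd.DataFrame.from_records(
        records, columns=["system", "tau2_us", "sigma_us", "n_replicates", "replicates"]
    )
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "markdown":
        return df.to_markdown(index=False)
    raise ValueError("fmt must be 'csv' or 'markdown'")


def parse_summary_table(text: str) -> list[SummaryRow]:
    """Inverse of :func:`report_table` for the CSV format."""
    df = pd.read_csv(io.StringIO(text), dtype={"tau2_us": str, "replicates": str})
    rows: list[SummaryRow] = []
    for rec in df.itertuples():
        tau_field = str(rec.tau2_us)
        if tau_field.startswith(">"):
            rows.append(SummaryRow.censored(rec.system, float(tau_field[1:])))
            continue
        reps = tuple(
            (float(t), float(s))
            for t, s in (pair.split("/") for pair in str(rec.replicates).split(";"))
        )
        rows.append(
            SummaryRow(
                system=rec.system,
                summary=ReplicateSummary(
                    tau2_mean=float(tau_field),
                    sigma=float(rec.sigma_us),
                    n_replicates=int(rec.n_replicates),
                    replicates=reps,
                ),
            )
        )
    return rows


def plot_frr_curve(
    curve: FrrCurve,
    fit: DecayFit | None = None,
    path: str | Path | None = None,
    *,
    title: str | None = None,
):
    """FRR vs delay on a log time axis, 2σ error bars, fitted decay overlay.

    When the fit carries bootstrap parameter draws, a 2σ model band is
    shaded around the fitted curve.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.5, 4.0))
    t = curve.delays()
    y = np.array([p.frr_mean for p in curve.points])
    err = 2.0 * np.array([p.frr_sem for p in curve.points])
    ax.errorbar(t * 1e6, y, yerr=err, fmt="o", ms=3, lw=0.8, capsize=2, label="FRR (2σ)")
    if fit is not None and not fit.censored:
        tt = np.geomspace(max(fit.t_min, t.min()), t.max(), 300)
        ax.plot(tt * 1e6, decay_model(tt, fit.offset, fit.amplitude, fit.tau2),
                color="crimson", label=fit.describe())
        if fit.param_draws is not None:
            models = np.array(
                [decay_model(tt, *p) for p in fit.param_draws[:500]]
            )
            lo = models.mean(axis=0) - 2 * models.std(axis=0)
            hi = models.mean(axis=0) + 2 * models.std(axis=0)
            ax.fill_between(tt * 1e6, lo, hi, color="crimson", alpha=0.2, lw=0)
    ax.set_xscale("log")
    ax.set_xlabel("pump–probe delay (μs)")
    ax.set_ylabel("fragmentation ratio")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
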