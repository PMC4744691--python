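"""Optional figures: activity traces and the cross-method regression."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activity import PmaxrateResult
from .comparison import RegressionResult
from .core import PsiSeries

__all__ = ["plot_activity", "plot_regression"]


def plot_activity(
    result: PmaxrateResult,
    psi: PsiSeries,
    path: str,
    log_time: bool = False,
) -> None:
    """Two-panel figure: cumulative AE + Ψ trace above, raw and smoothed
    activity below, with the peak time marked."""
    rates = result.rates
    if rates is None:
        raise ValueError("result carries no rate series to plot")
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)

    grid = rates.grid_times_min
    cum = np.cumsum(rates.raw_rate)  # proportional to cumulative count
    ax0.plot(grid, cum, "k-", lw=1.2, label="cumulative AE (arb.)")
    ax0.set_ylabel("cumulative AE (arb. units)")
    axp = ax0.twinx()
    axp.plot(psi.times_s / 60.0, psi.psi_mpa, "o--", color="tab:blue", mfc="none")
    axp.set_ylabel("Ψ (MPa)", color="tab:blue")

    ax1.plot(grid, rates.raw_rate, "ks", ms=2.5, label="raw activity")
    ax1.plot(grid, rates.smoothed_rate, "r-", lw=1.5, label="smoothed")
    ax1.axvline(result.t_max_min, color="r", ls=":", lw=1.2)
    ax1.set_xlabel("time (min)")
    ax1.set_ylabel("AE activity (hits min$^{-1}$)")
    ax1.legend(frameon=False, fontsize=8)
    ax1.set_title(
        f"P$_{{maxrate}}$ = {result.pmaxrate_mpa:.2f} MPa at "
        f"t = {result.t_max_min:.0f} min",
        fontsize=9,
    )
    if log_time:
        ax1.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(result: RegressionResult, path: str) -> None:
    """P_maxrate vs P50 in tension magnitudes with the OLS line, 95%
    confidence band and the 1:1 reference."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if result.x_magnitude is not None and result.y_magnitude is not None:
        ax.plot(result.x_magnitude, result.y_magnitude, "ko", mfc="none")
    band = result.ci_band
    if band is not None:
        g = band["grid_magnitude_mpa"]
        ax.plot(g, band["mean"], "r-", lw=1.5)
        ax.plot(g, band["lo"], "r--", lw=0.8)
        ax.plot(g, band["hi"], "r--", lw=0.8)
        lim = [0, float(max(g.max(), band["hi"].max())) * 1.05]
        ax.plot(lim, lim, "k:", lw=0.8)
    ax.set_xlabel("|P$_{50}$| (MPa)")
    ax.set_ylabel("|P$_{maxrate}$| (MPa)")
    ax.set_title(
        f"slope {result.slope:.2f}, intercept {result.intercept:.2f}, "
        f"R² {result.r2:.2f} (n = {result.n})",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
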