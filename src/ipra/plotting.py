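"""Plots: exposure/hazard overlap curves, IMoE bars, uncertainty contributions."""

from __future__ import annotations

import numpy as np

from .exposure import exceedance_curve
from .risk import ImoeResult
from .sensitivity import FactorialResult

__all__ = ["plot_exposure_hazard", "plot_imoe_bars", "plot_contributions"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_exposure_hazard(result: ImoeResult, ax=None):
    """Exceedance curve of usual exposure against the cumulative IBMD curve.

    The overlap of the two curves indicates the amount of risk present; the
    exposure curve starts at 1 because every individual has some long-term
    intake.
    """
    ax = _axes(ax)
    if result.nominal_iexp is None or result.nominal_ibmd is None:
        raise ValueError("result carries no nominal exposure/hazard samples")
    exc = exceedance_curve(result.nominal_iexp)
    ax.plot(exc["x"], exc["fraction_exceeding"], "--", label="IEXP exceedance")
    ib = np.sort(result.nominal_ibmd)
    ax.plot(ib, np.arange(1, ib.size + 1) / ib.size, "-", label="IBMD cumulative")
    unit = (
        "mg/kg BW/day"
        if result.config.dose_metric.metric == "mass"
        else "$10^{12}$ N/kg BW/day"
    )
    ax.set_xscale("log")
    ax.set_xlabel(f"dose ({unit})")
    ax.set_ylabel("fraction of population")
    ax.legend()
    return ax


def plot_imoe_bars(result: ImoeResult, ax=None):
    """IMoE bar graph: boxes between variability percentiles, one-sided whiskers."""
    ax = _axes(ax)
    bars = result.bars()
    for i, bar in enumerate(bars):
        y = len(bars) - i
        ax.barh(
            y,
            bar.box_upper - bar.box_lower,
            left=bar.box_lower,
            height=0.5,
            color="#9ecae1",
            edgecolor="k",
        )
        ax.plot([bar.whisker_lower, bar.box_lower], [y, y], "k-")
        ax.plot([bar.box_upper, bar.whisker_upper], [y, y], "k-")
        ax.plot([bar.median, bar.median], [y - 0.25, y + 0.25], "k--")
        ax.text(
            bar.whisker_upper,
            y + 0.3,
            f"p{bar.lower_level:g}-p{bar.upper_level:g}",
            fontsize=8,
        )
    ax.axvline(1.0, color="r", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("individual margin of exposure (IMoE)")
    ax.set_yticks([])
    return ax


def plot_contributions(result: FactorialResult, ax=None):
    """Percent contribution of each uncertainty source to the target percentile."""
    ax = _axes(ax)
    contrib = result.fit.contributions
    ax.bar(range(len(contrib)), contrib.to_numpy(), color="#3182bd")
    ax.set_xticks(range(len(contrib)))
    ax.set_xticklabels(contrib.index, rotation=45, ha="right")
    ax.set_ylabel(f"contribution to uncertainty of p{result.target_percentile:g} (%)")
    ax.set_title(f"additive model explains {result.fit.variance_explained:.2f} % of variance")
    return ax
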