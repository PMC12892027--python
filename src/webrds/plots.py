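"""Optional figures (requires matplotlib): enrollment curve, degree
distribution and convergence traces. Data series for every figure are
also available as tidy frames from the corresponding modules."""

from __future__ import annotations

import pandas as pd

from .analysis import ConvergenceTrace
from .degrees import degree_histogram


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_enrollment_curve(forest_participants: pd.DataFrame, ax=None):
    """Cumulative enrollments by day (the stall under a low incentive shows
    up as a flat segment)."""
    ax = _axes(ax)
    days = forest_participants["day"].sort_values()
    ax.step(days, range(1, len(days) + 1), where="post")
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative enrollments")
    return ax


def plot_degree_distribution(records: pd.DataFrame, ax=None):
    """Histogram of the operative network size after imputation."""
    ax = _axes(ax)
    hist = degree_histogram(records)
    ax.bar(hist["degree"], hist["count"], width=0.9)
    ax.set_xlabel("reported network size")
    ax.set_ylabel("respondents")
    return ax


def plot_convergence(trace: ConvergenceTrace, ax=None):
    """Cumulative sample proportion in enrollment order, with the final
    stabilization window shaded."""
    ax = _axes(ax)
    frame = trace.to_frame()
    ax.plot(frame["enrollment_index"], frame["cumulative_value"])
    n = len(frame)
    w = max(1, int(round(trace.window_frac * n)))
    ax.axvspan(n - w, n, alpha=0.15)
    ax.axhline(frame["cumulative_value"].iloc[-1], ls="--", lw=0.8)
    label = trace.variable if trace.category is None else f"{trace.variable}={trace.category}"
    ax.set_xlabel("enrollment index")
    ax.set_ylabel(f"cumulative proportion ({label})")
    return ax
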