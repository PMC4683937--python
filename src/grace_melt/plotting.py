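"""Diagnostic plots: raw melts, −dF/dT overlays, and normalized-curve panels."""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .curves import MeltRun
from .panel import AmpliconPanel
from .signal import negative_derivative, normalize_between, place_windows, smooth


def _select(run: MeltRun, sample_ids: Iterable[str] | None):
    ids = list(sample_ids) if sample_ids else list(run.curves)
    return [(sid, run.curves[sid]) for sid in ids]


def plot_raw(run: MeltRun, sample_ids=None, ax=None):
    ax = ax or plt.subplots()[1]
    for sid, curve in _select(run, sample_ids):
        ax.plot(curve.temperatures_c, curve.fluorescence, label=sid, lw=1)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("fluorescence (a.u.)")
    ax.set_title("raw melt curves")
    return ax


def plot_derivative(run: MeltRun, panel: AmpliconPanel, sample_ids=None, ax=None):
    """−dF/dT overlay with amplicon Tms marked; one peak per amplicon."""
    ax = ax or plt.subplots()[1]
    for sid, curve in _select(run, sample_ids):
        d = negative_derivative(smooth(curve))
        ax.plot(d.temperatures_c, d.values, label=sid, lw=1)
    for amp in panel.amplicons:
        ax.axvline(amp.tm_c, color="grey", ls=":", lw=0.8)
        ax.annotate(amp.gene_name, (amp.tm_c, ax.get_ylim()[1]), ha="center", fontsize=8)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("−dF/dT")
    return ax


def plot_normalized(run: MeltRun, panel: AmpliconPanel, stage, sample_ids=None, ax=None):
    """Stage-normalized curves with the normalization windows shaded."""
    ax = ax or plt.subplots()[1]
    windows = place_windows(run, panel, stage)
    for sid, curve in _select(run, sample_ids):
        n = normalize_between(curve, windows)
        ax.plot(n.temperatures_c, n.values, label=sid, lw=1)
    for lo, hi in (windows.pre_window, windows.post_window):
        ax.axvspan(lo, hi, color="grey", alpha=0.3)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("normalized fluorescence (%)")
    ax.set_title(f"two-window normalization ({stage})")
    return ax


def plot_run_summary(run: MeltRun, panel: AmpliconPanel, sample_ids=None):
    """Raw, derivative and both normalization stages in one figure."""
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    plot_raw(run, sample_ids, axes[0, 0])
    plot_derivative(run, panel, sample_ids, axes[0, 1])
    plot_normalized(run, panel, "reference_vs_target1", sample_ids, axes[1, 0])
    plot_normalized(run, panel, "target1_vs_target2", sample_ids, axes[1, 1])
    fig.tight_layout()
    return fig
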