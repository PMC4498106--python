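"""Figure analogues built from emitted tables (never from simulator state).

Every function accepts the DataFrame written by the corresponding protocol
runner (or its CSV re-read), so published figures can be regenerated from the
CSV alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_frequency_histogram",
    "plot_frequency_map",
    "plot_traces",
    "plot_amplitude_curves",
]


def _save(fig, path):
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_frequency_histogram(sweep: pd.DataFrame, path=None):
    """Histogram of main harmonics from a sensitivity sweep."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(sweep["main_harmonic_hz"], bins=np.arange(0, 31, 1), color="0.3")
    ax.axvspan(13, 30, color="tab:red", alpha=0.12, label="beta band")
    ax.set_xlabel("main harmonic (Hz)")
    ax.set_ylabel("runs")
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_frequency_map(grid_table: pd.DataFrame, pair: tuple[str, str], path=None):
    """Heatmap of main harmonic vs two scaled parameters."""
    a, b = f"{pair[0]}_factor", f"{pair[1]}_factor"
    piv = grid_table.pivot_table(index=b, columns=a, values="main_harmonic_hz")
    fig, ax = plt.subplots(figsize=(4.6, 3.8))
    im = ax.pcolormesh(piv.columns, piv.index, piv.values, shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="main harmonic (Hz)")
    ax.plot(1.0, 1.0, "kx", markersize=10, label="nominal")
    ax.set_xlabel(f"{pair[0]} scale factor")
    ax.set_ylabel(f"{pair[1]} scale factor")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_traces(rates: pd.DataFrame, stim_onset_ms: float | None = 500.0, path=None):
    """Mean STN and GPe rate traces from a long-format rates table."""
    fig, ax = plt.subplots(figsize=(6.4, 3.2))
    for name, color in (("STN", "k"), ("GPe", "tab:red")):
        sub = rates[rates["population"] == name]
        mean = sub.groupby("time_ms")["rate_spk_s"].mean()
        ax.plot(mean.index, mean.values, color=color, lw=0.9, label=name)
    if stim_onset_ms is not None:
        ax.axvline(stim_onset_ms, color="tab:blue", ls="--", lw=1, label="stimulation on")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("mean rate (spk/s)")
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_amplitude_curves(table: pd.DataFrame, x: str, path=None):
    """Residual amplitude vs degeneracy (protocol C) or delay T (protocol E).

    ``x`` is "degeneracy" or "T_ms"; one curve per gain kc, averaged over
    seeds, with the unstimulated pre-onset amplitude as reference.
    """
    fig, ax = plt.subplots(figsize=(5, 3.4))
    gains = sorted(table["kc"].unique())
    shades = np.linspace(0.65, 0.0, len(gains))
    for kc, shade in zip(gains, shades):
        sub = table[table["kc"] == kc].groupby(x)["post_amplitude_spk"].mean()
        ax.plot(sub.index, sub.values, "o-", color=str(shade), label=f"kc = {kc:g}")
    ref = table["pre_amplitude_spk"].mean()
    ax.axhline(ref, color="tab:red", ls="--", lw=1, label="no stimulation")
    ax.set_xlabel({"degeneracy": "photosensitization degeneracy", "T_ms": "delay T (ms)"}.get(x, x))
    ax.set_ylabel("residual amplitude (spk/s)")
    ax.legend(frameon=False)
    return _save(fig, path)
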