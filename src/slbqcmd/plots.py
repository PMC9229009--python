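"""Diagnostic figures: Δf/ΔD vs time and the ΔD-vs-Δf phase plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .traces import FlowMarkers, QCMDTrace


def plot_trace(trace: QCMDTrace, markers: FlowMarkers | None = None, path=None):
    """Two-panel figure: Δf (top) and ΔD (bottom) for every harmonic."""
    fig, (ax_f, ax_d) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    for n in trace.harmonics:
        ax_f.plot(trace.time, trace.delta_f[n], label=f"n={n}", lw=0.8)
        ax_d.plot(trace.time, trace.delta_D[n], lw=0.8)
    if markers is not None:
        for ax in (ax_f, ax_d):
            ax.axvline(markers.t_start, color="k", ls=":", lw=0.8)
            ax.axvline(markers.t_rinse, color="k", ls="--", lw=0.8)
    ax_f.set_ylabel("Δf (Hz)")
    ax_d.set_ylabel("ΔD (1e-6)")
    ax_d.set_xlabel("time (min)")
    ax_f.legend(fontsize=8, ncol=3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_phase(trace: QCMDTrace, harmonic: int = 3, path=None):
    """ΔD vs Δf with the frequency axis reversed (rightward = mass gain)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(trace.delta_f[harmonic], trace.delta_D[harmonic], ".", ms=2)
    ax.invert_xaxis()
    ax.set_xlabel("Δf (Hz), reversed")
    ax.set_ylabel("ΔD (1e-6)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
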