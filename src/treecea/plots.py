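"""Matplotlib figures for the uncertainty and sensitivity outputs."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .oneway_sensitivity import TornadoEntry
from .uncertainty import CEACCurve, NMBCurve, PSASample, deltas, plane_summary

__all__ = ["plot_ceac", "plot_nmb", "plot_plane", "plot_tornado"]


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ceac(curve: CEACCurve, label: str = "reference", path: str | Path | None = None):
    """Acceptability of the reference arm (and its complement) along the WTP grid."""
    fig, ax = plt.subplots()
    grid = np.asarray(curve.wtp_grid)
    probs = np.asarray(curve.prob_acceptable)
    ax.plot(grid, probs, label=label)
    ax.plot(grid, 1.0 - probs, linestyle="--", label=f"not {label}")
    ax.set_xlabel("willingness to pay (TWD per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return _finish(fig, path)


def plot_nmb(curve: NMBCurve, path: str | Path | None = None):
    """Mean incremental net monetary benefit with its replicate percentile band."""
    fig, ax = plt.subplots()
    grid = np.asarray(curve.wtp_grid)
    ax.plot(grid, curve.mean_inmb, label="mean incremental NMB")
    ax.fill_between(grid, curve.lower, curve.upper, alpha=0.25,
                    label=f"{curve.band[0]:g}-{curve.band[1]:g} percentile")
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xlabel("willingness to pay (TWD per QALY)")
    ax.set_ylabel("incremental NMB (TWD)")
    ax.legend()
    return _finish(fig, path)


def plot_plane(samples: list[PSASample], wtp: float | None = None,
               path: str | Path | None = None):
    """Replicate scatter on the cost-effectiveness plane with the 95% ellipse."""
    fig, ax = plt.subplots()
    dc, de = deltas(samples)
    ax.scatter(de, dc, s=6, alpha=0.4)
    summ = plane_summary(samples)
    cov = np.asarray(summ.covariance)
    vals, vecs = np.linalg.eigh(cov[::-1, ::-1])  # (effect, cost) ordering
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.vstack([np.cos(theta), np.sin(theta)])
    ellipse = (vecs @ (np.sqrt(summ.ellipse_chi2 * vals)[:, None] * circle))
    ax.plot(summ.mean_delta_effect + ellipse[0],
            summ.mean_delta_cost + ellipse[1], color="C1", label="95% ellipse")
    ax.plot(summ.mean_delta_effect, summ.mean_delta_cost, "k+", markersize=10)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, color="grey", linestyle=":", label="WTP threshold")
    ax.axhline(0, color="grey", linewidth=0.8)
    ax.axvline(0, color="grey", linewidth=0.8)
    ax.set_xlabel("incremental effect (QALYs)")
    ax.set_ylabel("incremental cost (TWD)")
    ax.legend()
    return _finish(fig, path)


def plot_tornado(entries: list[TornadoEntry], path: str | Path | None = None):
    """Horizontal tornado bars, widest (most influential) on top."""
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    base = entries[0].base_output if entries else 0.0
    ypos = np.arange(len(entries))[::-1]
    for y, e in zip(ypos, entries):
        lo, hi = sorted((e.low_output, e.high_output))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="C0", alpha=0.8)
    ax.axvline(base, color="k", linewidth=1.0, label="base case")
    ax.set_yticks(ypos)
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel(f"{entries[0].metric if entries else ''} output")
    ax.legend()
    return _finish(fig, path)
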