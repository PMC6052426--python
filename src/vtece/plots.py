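"""Plots for the sensitivity analyses: incremental cost-effectiveness
plane, cost-effectiveness acceptability curve, and tornado diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import PSAResult, TornadoRow


def plot_ce_plane(result: PSAResult, path: str | Path,
                  wtp: float | None = None) -> Path:
    """Scatter of (incremental QALYs, incremental costs) per draw."""
    lam = result.wtp if wtp is None else wtp
    de = np.array([d.delta_qaly for d in result.draws])
    dc = np.array([d.delta_cost for d in result.draws])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(de, dc, s=6, alpha=0.4, linewidths=0)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    lim = max(abs(de).max(), 1e-4)
    xs = np.array([-lim, lim])
    ax.plot(xs, lam * xs, "--", color="grey", lw=1,
            label=f"WTP £{lam:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs (edoxaban - warfarin)")
    ax.set_ylabel("Incremental costs (£)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(lambdas, probs, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lambdas, probs)
    ax.set_xlabel("Willingness-to-pay (£/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tornado(rows: list[TornadoRow], base_nmb: float, path: str | Path,
                 top: int = 10) -> Path:
    rows = rows[:top]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(rows) + 1.2))
    labels = [r.parameter.split(".", 1)[-1] for r in rows]
    y = np.arange(len(rows))[::-1]
    for yi, r in zip(y, rows):
        lo, hi = sorted((r.nmb_low, r.nmb_high))
        ax.barh(yi, hi - lo, left=lo, height=0.6, color="#4477aa")
    ax.axvline(base_nmb, color="k", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Net monetary benefit (£)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
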