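"""Presentation-only plots: trajectories, input functions, bifurcations.

Matplotlib is imported lazily; nothing here is exercised by analyses or
tests — the figures just mirror the tabular outputs.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _fig, ax = plt.subplots()
    return ax


def plot_trajectory(traj, ax=None, species=None, phenotype_map=None):
    """Line per species; optional phenotype-zone shading on the y-axis."""
    ax = _ax(ax)
    for name in species or traj.species:
        ax.plot(traj.t, traj.series(name), label=name)
    for b in traj.meta.get("breakpoints", ()):
        ax.axvline(b, color="0.8", lw=0.8, zorder=0)
    if phenotype_map is not None:
        edges = (0.0,) + phenotype_map.boundaries + (max(1.0, traj.states.max()),)
        for lo, hi, zone in zip(edges, edges[1:], phenotype_map.zones):
            ax.axhspan(lo, hi, alpha=0.06)
            ax.text(traj.t[-1], 0.5 * (lo + hi), zone, fontsize=7,
                    ha="right", va="center")
    ax.set_xlabel("time (a.u.)")
    ax.set_ylabel("level (a.u.)")
    ax.legend(fontsize=8)
    return ax


def plot_input_functions(specs: dict, grid, ax=None):
    """Overlay the linear/saturated/sigmoidal transfer curves."""
    from .circuits import input_response

    ax = _ax(ax)
    for name, spec in specs.items():
        ax.plot(grid, input_response(spec, grid), label=name)
    ax.set_xlabel("SOX10 level (a.u.)")
    ax.set_ylabel("steady MITF output (a.u.)")
    ax.legend()
    return ax


def plot_bifurcation(diagram, ax=None):
    """Stable branches solid, unstable dashed, folds marked."""
    ax = _ax(ax)
    stable_x, stable_y, unstable_x, unstable_y = [], [], [], []
    for value, fps in zip(diagram.grid, diagram.fixed_points):
        for fp in fps:
            (stable_x if fp.stable else unstable_x).append(value)
            (stable_y if fp.stable else unstable_y).append(fp.sox10)
    ax.plot(stable_x, stable_y, "k.", ms=4, label="stable")
    ax.plot(unstable_x, unstable_y, "r.", ms=2, label="unstable")
    for fold in (diagram.fold_left, diagram.fold_right):
        if fold is not None:
            ax.axvline(fold, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel(diagram.parameter)
    ax.set_ylabel("steady SOX10 (a.u.)")
    ax.set_title(f"switching: {diagram.reversibility}")
    ax.legend(fontsize=8)
    return ax


def plot_hysteresis(result, ax=None):
    """Up/down quasi-static sweeps with arrows indicating direction."""
    ax = _ax(ax)
    ax.plot(result.grid_up, result.sox10_up, "-o", ms=3, label="up sweep")
    ax.plot(result.grid_down, result.sox10_down, "-s", ms=3, label="down sweep")
    for thr in (result.threshold_up, result.threshold_down):
        if thr is not None:
            ax.axvline(thr, color="0.6", ls=":", lw=0.8)
    ax.set_xlabel("ATF2 activity (a.u.)")
    ax.set_ylabel("steady SOX10 (a.u.)")
    ax.legend(fontsize=8)
    return ax
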