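"""Rendering of group profiles with fitted curves and circular phase plots.

Purely derived displays: two-day group-mean profiles overlaid with their
cosinor fit, and 24 h circular ("Rayleigh") plots of per-subject acrophases
with group mean vectors.  The clock dial is drawn with 00:00 at the top,
hours increasing clockwise and 12:00 at the bottom.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import circular, cosinor
from .data import SubjectProfile

GROUP_COLORS = {
    "control": "navy",
    "depression": "magenta",
    "recovery": "green",
    "mania": "orange",
}


def plot_group_profile(profiles: list[SubjectProfile], ax=None, label=None):
    """Pointwise group mean +/- SEM over elapsed time, with the cosinor fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    slots: dict[float, list[float]] = {}
    for p in profiles:
        for s in p.present:
            slots.setdefault(s.elapsed_time, []).append(s.value)
    t = np.array(sorted(slots))
    mean = np.array([np.mean(slots[e]) for e in t])
    sem = np.array(
        [np.std(slots[e], ddof=1) / math.sqrt(len(slots[e]))
         if len(slots[e]) > 1 else 0.0
         for e in t]
    )
    group = profiles[0].group
    color = GROUP_COLORS.get(group, "gray")
    ax.errorbar(t, mean, yerr=sem, fmt="o", color=color,
                label=label or group, capsize=3)
    params = cosinor.fit_group_mean(profiles)
    tt = np.linspace(t.min(), t.max(), 300)
    ax.plot(tt, cosinor.predict(params, tt,
                                anchor=profiles[0].schedule.anchor),
            "-", color=color, alpha=0.7)
    ax.set_xlabel("elapsed time since day-1 08:00 (h)")
    ax.set_ylabel(f"{profiles[0].analyte} concentration")
    ax.legend()
    return ax


def plot_rayleigh(acrophases_by_group: dict[str, np.ndarray],
                  weights_by_group: dict[str, np.ndarray] | None = None,
                  ax=None):
    """Per-subject acrophase arrows and group mean vectors on a 24 h dial.

    ``acrophases_by_group`` maps group label -> clock hours; optional
    ``weights_by_group`` (e.g. per-subject fit R^2) scales the individual
    arrow lengths.
    """
    if ax is None:
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(2 * np.pi * np.arange(0, 24, 3) / 24.0)
    ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 24, 3)])
    ax.set_yticklabels([])
    ax.set_ylim(0, 1.05)
    for group, acro in acrophases_by_group.items():
        acro = np.asarray(acro, dtype=float) % 24.0
        if acro.size == 0:
            continue
        color = GROUP_COLORS.get(group, "gray")
        if weights_by_group and group in weights_by_group:
            lengths = np.clip(np.asarray(weights_by_group[group]), 0, 1)
        else:
            lengths = np.full(acro.size, 0.9)
        theta = 2.0 * np.pi * acro / 24.0
        for th, ln in zip(theta, lengths):
            ax.annotate(
                "", xy=(th, ln), xytext=(th, 0.0),
                arrowprops=dict(arrowstyle="->", color=color, alpha=0.5),
            )
        summ = circular.mean_vector(circular.phase_angle(acro))
        if summ.mean_direction_defined:
            ax.annotate(
                "", xy=(summ.mean_angle, summ.resultant_length),
                xytext=(summ.mean_angle, 0.0),
                arrowprops=dict(arrowstyle="-|>", color=color, lw=2.5),
            )
        ax.plot([], [], color=color, label=group)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    return ax
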