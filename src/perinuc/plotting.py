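"""Convenience plots for ribbon profiles, zoning summaries and FRAP fits."""

from __future__ import annotations

import numpy as np

from .chipseq import RibbonProfile
from .frap import FrapFit, one_phase_association


def plot_ribbon(profile: RibbonProfile, ax=None, color="C0"):
    """Median line with min-max ribbon, one panel per chromosome region."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = profile.windows
    mid = (df["start"] + df["end"]) / 2.0
    ax.fill_between(mid, df["min"], df["max"], alpha=0.3, color=color, lw=0)
    ax.plot(mid, df["median"], color=color)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("normalized depth")
    return ax


def plot_zoning(summary_frame, ax=None):
    """Bar chart of Zone-I percentages with the 33% random expectation line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = summary_frame["strain"] + "\n" + summary_frame["stage"]
    ax.bar(labels, 100.0 * summary_frame["zone1_fraction"], color="C0")
    ax.axhline(100.0 / 3.0, color="red", ls="--", label="random (33%)")
    ax.set_ylabel("% cells with locus in Zone I")
    ax.legend()
    return ax


def plot_frap(times, intensities, fit: FrapFit | None = None, ax=None):
    """Averaged recovery points with the fitted one-phase-association curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(times, intensities, "o", ms=3, label="mean recovery")
    if fit is not None and not fit.immobile:
        tt = np.linspace(0, max(times), 200)
        ax.plot(
            tt,
            one_phase_association(tt, fit.k, fit.y0, fit.plateau),
            label=f"fit: T1/2={fit.half_life:.2f}s, plateau={fit.plateau:.2f}",
        )
    ax.set_xlabel("time post-bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax
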