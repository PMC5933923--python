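"""FRAP quantitation and one-phase-association fitting.

A photobleached region of interest (ROI) recovers as fluorophores exchange
with the unbleached pool.  Each timepoint is normalized as

    y(t) = (roi(t) - background(t)) / (pre_roi - pre_background)

so the pre-bleach signal is 1.0 by construction (background is an
equal-size region beside the nucleus).  Recovery is fitted with the
one-phase association model

    Y(t) = Y0 + (P - Y0) * (1 - exp(-k t))

whose plateau P is the mobile fraction and half-life T1/2 = ln2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

K_BOUNDS = (1e-6, 1e3)  # 1/s


@dataclass
class FrapTrace:
    """Raw ROI/background sums for one cell; t=0 is immediately post-bleach."""

    times: np.ndarray
    roi_sum: np.ndarray
    background_sum: np.ndarray
    pre_roi_sum: float
    pre_background_sum: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_sum = np.asarray(self.roi_sum, dtype=float)
        self.background_sum = np.asarray(self.background_sum, dtype=float)
        if not (len(self.times) == len(self.roi_sum) == len(self.background_sum)):
            raise ValueError("times/roi/background lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pre_roi_sum - self.pre_background_sum <= 0:
            raise ValueError("pre-bleach ROI must exceed pre-bleach background")


@dataclass
class FrapFit:
    """One-phase-association parameters; T1/2 * k = ln 2 by construction."""

    k: float
    y0: float
    plateau: float
    half_life: float
    r_squared: float | None
    n_points: int
    immobile: bool = False

    @property
    def mobile_fraction(self) -> float:
        return self.plateau


def normalize_trace(
    trace: FrapTrace, mode: str = "subtracted"
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized recovery series (times, intensities).

    ``mode='subtracted'`` (default) divides background-subtracted ROI by the
    background-subtracted pre-bleach ROI, keeping the series on a 0-1 scale;
    ``mode='literal'`` divides by the raw pre-bleach ROI sum.
    """
    if mode not in ("subtracted", "literal"):
        raise ValueError("mode must be 'subtracted' or 'literal'")
    denom = (
        trace.pre_roi_sum - trace.pre_background_sum
        if mode == "subtracted"
        else trace.pre_roi_sum
    )
    if denom <= 0:
        raise ValueError("nonpositive normalization denominator")
    return trace.times.copy(), (trace.roi_sum - trace.background_sum) / denom


def average_traces(
    traces: Sequence[FrapTrace],
    mode: str = "subtracted",
    time_tolerance: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean normalized intensity per timepoint across cells -> (t, mean, n)."""
    if not traces:
        raise ValueError("no traces")
    t0, y0 = normalize_trace(traces[0], mode=mode)
    ys = [y0]
    for tr in traces[1:]:
        t, y = normalize_trace(tr, mode=mode)
        if len(t) != len(t0) or np.max(np.abs(t - t0)) > time_tolerance:
            raise ValueError(f"trace {tr.cell_id!r}: time grid mismatch")
        ys.append(y)
    return t0, np.mean(ys, axis=0), len(traces)


def one_phase_association(t: np.ndarray, k: float, y0: float, plateau: float) -> np.ndarray:
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start values from a log-linear estimate of the rate."""
    y0 = float(y[0])
    n_tail = max(1, len(y) // 4)
    plateau = float(np.mean(y[-n_tail:]))
    span = plateau - y0
    k = math.log(2.0) / max(t[-1] / 5.0, 1e-9)
    if span > 0:
        frac = (plateau - y) / span
        ok = (frac > 1e-3) & (frac < 1.0) & (t > 0)
        if ok.sum() >= 2:
            slope = np.polyfit(t[ok], np.log(frac[ok]), 1)[0]
            if slope < 0:
                k = -float(slope)
    return float(np.clip(k, *K_BOUNDS)), y0, plateau


def fit_recovery(
    times: Sequence[float], intensities: Sequence[float]
) -> FrapFit:
    """Bounded least-squares fit of the one-phase association model.

    A flat series is degenerate (nothing recovers or nothing was bleached):
    it is flagged immobile with plateau = Y0 and no R².
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")

    sstot = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y) == 0.0:
        return FrapFit(
            k=float("nan"), y0=float(y[0]), plateau=float(y[0]),
            half_life=float("nan"), r_squared=None, n_points=len(t), immobile=True,
        )

    k0, y00, p0 = _initial_guess(t, y)
    lo = [K_BOUNDS[0], min(y.min(), y00) - 1.0, min(y.min(), p0) - 1.0]
    hi = [K_BOUNDS[1], max(y.max(), y00) + 1.0, max(y.max(), p0) + 1.0]
    res = least_squares(
        lambda p: one_phase_association(t, *p) - y,
        x0=[k0, y00, p0],
        bounds=(lo, hi),
        method="trf",
    )
    if not res.success:
        raise RuntimeError(f"recovery fit failed to converge: {res.message}")
    k, y0, plateau = (float(v) for v in res.x)
    if k <= K_BOUNDS[0] * 1.01 or k >= K_BOUNDS[1] * 0.99:
        raise RuntimeError(f"rate estimate k={k:.3g}/s at bound; fit unreliable")
    ssres = float(np.sum(res.fun**2))
    return FrapFit(
        k=k, y0=y0, plateau=plateau,
        half_life=math.log(2.0) / k,
        r_squared=1.0 - ssres / sstot,
        n_points=len(t),
    )


def fit_traces(
    traces: Sequence[FrapTrace], mode: str = "subtracted"
) -> tuple[FrapFit, np.ndarray, np.ndarray, int]:
    """Average normalized traces, fit the mean recovery -> (fit, t, mean, n)."""
    t, mean, n = average_traces(traces, mode=mode)
    return fit_recovery(t, mean), t, mean, n


# ---------------------------------------------------------------------------
# TSV interchange: columns cell, t, roi, background, pre_roi, pre_background

FRAP_COLUMNS = ["cell", "t", "roi", "background", "pre_roi", "pre_background"]


def write_traces_tsv(traces: Sequence[FrapTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell": tr.cell_id,
                    "t": tr.times,
                    "roi": tr.roi_sum,
                    "background": tr.background_sum,
                    "pre_roi": tr.pre_roi_sum,
                    "pre_background": tr.pre_background_sum,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path) -> list[FrapTrace]:
    df = pd.read_csv(path, sep="\t")
    missing = set(FRAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for cell, grp in df.groupby("cell", sort=False):
        grp = grp.sort_values("t")
        traces.append(
            FrapTrace(
                times=grp["t"].to_numpy(),
                roi_sum=grp["roi"].to_numpy(),
                background_sum=grp["background"].to_numpy(),
                pre_roi_sum=float(grp["pre_roi"].iloc[0]),
                pre_background_sum=float(grp["pre_background"].iloc[0]),
                cell_id=str(cell),
            )
        )
    return traces
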