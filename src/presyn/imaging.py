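"""Quantification of presynaptic Ca2+-reporter image stacks.

Per-ROI fractional fluorescence change dF/F0 with F0 taken as the average of
the three prestimulus frames, a responsiveness threshold of 3 background
SDs on the maximal dF/F0, ordinary-least-squares slopes of dF/F0 during and
right after the stimulus train (data points 6-13 and 14-20 of the acquired
5-Hz series, 1-based), and pairing of imaging metrics with simultaneously
recorded train metrics for a descriptive rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import AnalysisConfig, ImagingStack, ValidationError

__all__ = [
    "RoiTrace",
    "DffMetrics",
    "compute_dff",
    "background_noise_sd",
    "detect_responsive",
    "dff_metrics",
    "pair_with_train",
]


@dataclass
class RoiTrace:
    """Per-ROI dF/F0 series."""

    roi_origin: tuple          # (row, col) of the ROI's upper-left pixel
    roi_size: int
    dff: np.ndarray            # per frame
    background_sd: float       # in dF/F0 units
    f0: float                  # mean prestimulus fluorescence of the ROI
    valid: bool = True
    responsive: bool = False


@dataclass
class DffMetrics:
    """Summary metrics of one ROI trace."""

    max_dff: float
    slope_hfs: float      # dF/F0 per frame, during-train points
    slope_post: float     # dF/F0 per frame, post-train points
    responsive: bool


def _roi_mean_series(stack: ImagingStack, origin: tuple, size: int) -> np.ndarray:
    r, c = origin
    rows, cols = stack.frames.shape[1:]
    if r < 0 or c < 0 or r + size > rows or c + size > cols:
        raise ValidationError("ROI extends outside the frame")
    return stack.frames[:, r: r + size, c: c + size].mean(axis=(1, 2))


def background_noise_sd(
    stack: ImagingStack,
    exclude: Sequence[tuple] = (),
    roi_size: int = 4,
) -> float:
    """SD of prestimulus background dF/F0, pooled over ROI-sized tiles.

    The frame area is tiled into ``roi_size`` blocks; tiles overlapping any
    excluded (synapse) ROI are dropped.  Each remaining tile is converted to
    a dF/F0 series exactly like a synapse ROI and the pooled SD over the
    prestimulus frames — the only epoch guaranteed signal-free — is taken.
    Because the p prestimulus frames also define F0, their dF/F0 variance is
    (1 - 1/p) of a single frame's while a post-stimulus frame's is
    (1 + 1/p); the pooled SD is therefore rescaled by sqrt((p+1)/(p-1)) so
    that the returned value is an unbiased noise scale for the
    post-stimulus frames against which responsiveness is judged.
    """
    rows, cols = stack.frames.shape[1:]
    pres = stack.prestimulus_frames
    samples = []
    for r in range(0, rows - roi_size + 1, roi_size):
        for c in range(0, cols - roi_size + 1, roi_size):
            if any(
                r < er + roi_size and er < r + roi_size
                and c < ec + roi_size and ec < c + roi_size
                for er, ec in exclude
            ):
                continue
            series = stack.frames[:pres, r: r + roi_size, c: c + roi_size].mean(axis=(1, 2))
            f0 = series.mean()
            if f0 > 0:
                samples.append(series / f0 - 1.0)
    if not samples:
        raise ValidationError("no background tiles available")
    pooled = np.concatenate(samples)
    correction = math.sqrt((pres + 1.0) / (pres - 1.0)) if pres > 1 else 1.0
    return float(np.std(pooled, ddof=1)) * correction


def compute_dff(
    stack: ImagingStack,
    roi: tuple,
    config: Optional[AnalysisConfig] = None,
    background_sd: Optional[float] = None,
) -> RoiTrace:
    """dF/F0 for one ROI: F0 is the ROI mean over the 3 prestimulus frames.

    ``dff[n] = (F_n - F_0) / F_0`` for every acquired frame.  A
    non-positive F0 marks the ROI invalid rather than producing infinities.
    ``background_sd`` may be passed in to avoid recomputing it per ROI.
    """
    config = config or AnalysisConfig()
    if stack.prestimulus_frames < 3:
        raise ValidationError("need >= 3 prestimulus frames for F0")
    size = config.dff_roi_size
    series = _roi_mean_series(stack, roi, size)
    f0 = float(series[: stack.prestimulus_frames].mean())
    if background_sd is None:
        background_sd = background_noise_sd(stack, exclude=[roi], roi_size=size)
    if f0 <= 0:
        return RoiTrace(
            roi_origin=tuple(roi), roi_size=size,
            dff=np.full(series.size, math.nan),
            background_sd=background_sd, f0=f0, valid=False,
        )
    return RoiTrace(
        roi_origin=tuple(roi), roi_size=size,
        dff=series / f0 - 1.0,
        background_sd=background_sd, f0=f0,
    )


def detect_responsive(
    roi_traces: Sequence[RoiTrace],
    config: Optional[AnalysisConfig] = None,
) -> list:
    """Flag ROIs whose fluorescence rise exceeds 3 background SDs (strict >)."""
    config = config or AnalysisConfig()
    out = []
    for rt in roi_traces:
        rt.responsive = bool(
            rt.valid and np.nanmax(rt.dff) > config.dff_sd_mult * rt.background_sd
        )
        if rt.responsive:
            out.append(rt)
    return out


def _ols_slope(y: np.ndarray, points: tuple) -> float:
    """OLS slope of y vs frame index over 1-based inclusive ``points``."""
    a, b = points
    if b > y.size:
        raise ValidationError(
            f"stack has {y.size} frames, fewer than the requested point {b}"
        )
    x = np.arange(a, b + 1, dtype=float)
    seg = y[a - 1: b]
    xm = x.mean()
    return float(np.sum((x - xm) * (seg - seg.mean())) / np.sum((x - xm) ** 2))


def dff_metrics(
    roi_trace: RoiTrace,
    config: Optional[AnalysisConfig] = None,
) -> DffMetrics:
    """Maximal dF/F0 and the during-/post-train slopes of one ROI.

    Slopes are OLS fits of dF/F0 against data-point index over the
    configured 1-based inclusive ranges of the whole acquired series
    (defaults: points 6-13 during the train, 14-20 right after it).
    """
    config = config or AnalysisConfig()
    y = roi_trace.dff
    return DffMetrics(
        max_dff=float(np.nanmax(y)),
        slope_hfs=_ols_slope(y, config.slope_hfs_points),
        slope_post=_ols_slope(y, config.slope_post_points),
        responsive=roi_trace.responsive,
    )


def pair_with_train(
    imaging_by_cell: dict,
    train_by_cell: dict,
) -> tuple:
    """Join per-cell imaging metrics with per-cell train metrics.

    ``imaging_by_cell`` maps cell id -> :class:`DffMetrics`;
    ``train_by_cell`` maps cell id -> :class:`~presyn.train.TrainMetrics`.
    Returns ``(table, unmatched_ids)`` where the table has one row per
    matched cell with ``slope_hfs``, ``slope_post``, ``max_dff`` and
    ``replenishment_rate`` columns plus a Spearman rank correlation between
    during-train slope and replenishment rate in ``table.attrs``.
    """
    matched = sorted(set(imaging_by_cell) & set(train_by_cell))
    unmatched = sorted(set(imaging_by_cell) ^ set(train_by_cell))
    rows = []
    for cid in matched:
        im = imaging_by_cell[cid]
        tm = train_by_cell[cid]
        rows.append(
            dict(
                cell=cid,
                slope_hfs=im.slope_hfs,
                slope_post=im.slope_post,
                max_dff=im.max_dff,
                replenishment_rate=tm.replenishment_rate_per_s,
                ste_ratio=tm.ste_ratio,
            )
        )
    table = pd.DataFrame(rows, columns=[
        "cell", "slope_hfs", "slope_post", "max_dff",
        "replenishment_rate", "ste_ratio",
    ])
    if len(table) >= 2:
        rho = spearmanr(table["slope_hfs"], table["replenishment_rate"]).statistic
        table.attrs["spearman_slope_vs_replenishment"] = float(rho)
    return table, unmatched
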