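"""Scratch-wound closure kinetics.

The wound in a brightfield frame is the low-texture region: a local
variance map separates the smooth denuded band from the grainy cell
lawn.  Kinetics follow the standard normalisation — wound area as a
fraction of the area at t = 0 — plus a per-front migration velocity
derived from the wound width (two fronts advance, so the width shrinks
at twice the front velocity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

from .datatypes import WoundSeries
from .exceptions import UndefinedRatioError

__all__ = ["WoundConfig", "WoundResult", "segment_wound", "wound_kinetics"]


@dataclass
class WoundConfig:
    """Wound segmentation and kinetics parameters.

    variance_window : side (px) of the local-variance window.
    var_threshold : absolute variance below which a pixel counts as
        wound; None = automatic (Otsu on the standard-deviation map when
        the frame is bimodal, else an absolute homogeneity cutoff).
    homogeneous_cutoff : frame-median variance below this means the
        whole frame is wound texture; above, with no bimodal split, the
        frame is fully confluent.
    bimodality_ratio : minimum high/low class-mean variance ratio for a
        frame to count as containing both textures.
    min_span : minimum fraction of the scratch axis the wound component
        must span.
    closure_fraction : wound-area fraction at or below which the wound
        counts as closed.
    """

    variance_window: int = 9
    var_threshold: Optional[float] = None
    homogeneous_cutoff: float = 2.5e-3
    bimodality_ratio: float = 4.0
    min_span: float = 0.5
    closure_fraction: float = 0.01


def _local_variance(img: np.ndarray, window: int) -> np.ndarray:
    m = ndimage.uniform_filter(img, window)
    m2 = ndimage.uniform_filter(img * img, window)
    return np.clip(m2 - m * m, 0.0, None)


def segment_wound(image: np.ndarray, config: Optional[WoundConfig] = None,
                  scratch_axis: int = 0) -> np.ndarray:
    """Segment the wound (low-texture region) of one frame.

    Returns a boolean mask; an empty mask is a valid result (closed
    wound), a full-frame mask means the frame is all wound texture.  The
    candidate low-variance region must form one connected component
    spanning at least ``min_span`` of the scratch axis.
    """
    cfg = config or WoundConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_wound expects a single-channel image")
    var = _local_variance(img, cfg.variance_window)

    if cfg.var_threshold is not None:
        low = var < cfg.var_threshold
    else:
        sd = np.sqrt(var)
        lo_med = np.median(var)
        thr = filters.threshold_otsu(sd) if np.ptp(sd) > 0 else 0.0
        low_cls = var[sd <= thr]
        high_cls = var[sd > thr]
        bimodal = (
            low_cls.size > 0
            and high_cls.size > 0
            and high_cls.mean() > cfg.bimodality_ratio * max(low_cls.mean(), 1e-12)
        )
        if bimodal:
            low = sd <= thr
        elif lo_med < cfg.homogeneous_cutoff:
            return np.ones_like(img, dtype=bool)   # frame is all wound texture
        else:
            return np.zeros_like(img, dtype=bool)  # fully confluent

    lab = measure.label(low, connectivity=1)
    if lab.max() == 0:
        return np.zeros_like(img, dtype=bool)
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1] + 1
    span_len = img.shape[scratch_axis]
    for cand in order:
        comp = lab == cand
        extent = np.ptp(np.nonzero(comp.any(axis=1 - scratch_axis))[0]) + 1
        if extent >= cfg.min_span * span_len:
            return comp
    return np.zeros_like(img, dtype=bool)


@dataclass
class WoundResult:
    """Closure kinetics of one wound series."""

    timepoints: np.ndarray          # h
    areas: np.ndarray               # um^2 (replicate-averaged)
    fractions: np.ndarray           # area / area(0); fractions[0] == 1
    closure_time: Optional[float]   # h, or None if never closed
    velocity: float                 # per-front, um/h
    velocity_total: float           # total gap closure rate, um/h
    widths: np.ndarray              # um

    def summary(self) -> str:
        rows = "\n".join(
            f"  {t:6.1f} h  area {a:12.1f} um^2  fraction {fr:6.3f}"
            for t, a, fr in zip(self.timepoints, self.areas, self.fractions)
        )
        closure = f"{self.closure_time:.1f} h" if self.closure_time is not None else "not reached"
        return (
            "Scratch-wound kinetics\n" + "=" * 40 + f"\n{rows}\n"
            f"  closure     {closure}\n"
            f"  velocity    {self.velocity:.3f} um/h per front "
            f"({self.velocity_total:.3f} um/h total)"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.timepoints, "area_um2": self.areas,
             "fraction": self.fractions, "width_um": self.widths}
        )

    def plot(self, ax=None):
        """Plot the wound-area fraction against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.timepoints, self.fractions, "o-")
        if self.closure_time is not None:
            ax.axvline(self.closure_time, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("wound area fraction")
        ax.set_ylim(-0.05, 1.05)
        return ax


def wound_kinetics(series: WoundSeries, config: Optional[WoundConfig] = None) -> WoundResult:
    """Quantify wound closure over a time series.

    Replicate frames at a timepoint (an entry of ``series.images`` that
    is a list) are segmented independently and their areas averaged.
    The wound width is area divided by the wound extent along the
    scratch axis; the per-front velocity is the mean over open intervals
    of ``(W_i - W_{i+1}) / (2 (t_{i+1} - t_i))``.
    """
    cfg = config or WoundConfig()
    px = series.pixel_size
    areas_um2, widths_um = [], []
    span_px = np.asarray(series.images[0] if not isinstance(series.images[0], list)
                         else series.images[0][0]).shape[series.scratch_axis]
    length_um = span_px * px
    for frame in series.images:
        reps = frame if isinstance(frame, list) else [frame]
        rep_areas = []
        for im in reps:
            mask = segment_wound(im, cfg, series.scratch_axis)
            rep_areas.append(mask.sum() * px**2)
        area = float(np.mean(rep_areas))
        areas_um2.append(area)
        widths_um.append(area / length_um)
    areas_um2 = np.asarray(areas_um2)
    widths_um = np.asarray(widths_um)
    if areas_um2[0] == 0:
        raise UndefinedRatioError("initial wound area is zero; fractions undefined")
    fractions = areas_um2 / areas_um2[0]
    fractions[0] = 1.0  # exact by definition

    closed = np.flatnonzero(fractions <= cfg.closure_fraction)
    closure_time = float(series.timepoints[closed[0]]) if closed.size else None

    t = series.timepoints
    vels, vels_any = [], []
    for i in range(len(t) - 1):
        if fractions[i] <= cfg.closure_fraction:
            break  # wound already closed; later intervals carry no motion
        dt = t[i + 1] - t[i]
        v = (widths_um[i] - widths_um[i + 1]) / (2.0 * dt)
        vels_any.append(v)
        # an interval in which the wound closes underestimates the front
        # speed (closure happened before t_{i+1}); use fully open ones
        if fractions[i + 1] > cfg.closure_fraction:
            vels.append(v)
    if vels:
        velocity = float(np.mean(vels))
    elif vels_any:
        velocity = float(vels_any[0])  # closed within the first interval: lower bound
    else:
        velocity = 0.0
    return WoundResult(
        timepoints=t,
        areas=areas_um2,
        fractions=fractions,
        closure_time=closure_time,
        velocity=velocity,
        velocity_total=2.0 * velocity,
        widths=widths_um,
    )
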