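"""The eight 1 Hz feature modalities and 8x60 epoch assembly.

Modalities: 1-s moving-average filtered + downsampled O2Hb / HHb / TSI,
spline-interpolated HR and RR, and three windowed statistics on 1-s windows
with 50% overlap — normalized std (std/|mean|), normalized IQR (IQR/|median|)
and the O2Hb-HHb Pearson correlation — each interpolated from 2 Hz to 1 Hz.
Concentration-change signals have near-zero means/medians, so both
normalizations carry an epsilon floor.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .types import FeatureEpoch, HemodynamicSeries, ModalitySet, SleepStateTimeline, VitalsSeries

EPS_NORM = 1e-6  # uM floor for |mean| / |median| normalization


def moving_average_downsample(series: np.ndarray, fs: float = 100.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """1-s centered moving average, sampled once per integer second.

    Returns (times_s, values); a T-second input yields T output samples
    (edge windows are shrunk by the 'nearest' convention).
    """
    n = int(round(fs))
    if len(series) < n:
        raise ValueError("need at least 1 s of data for the moving average")
    smooth = uniform_filter1d(np.asarray(series, dtype=float), size=n, mode="nearest")
    values = smooth[::n]
    return np.arange(len(values), dtype=float), values


def _window_starts(n_samples: int, fs: float) -> np.ndarray:
    """Starts of 1-s windows with 50% overlap (stride 0.5 s), full windows only."""
    n_win, n_str = int(round(fs)), int(round(fs / 2))
    return np.arange(0, n_samples - n_win + 1, n_str)


def _windowed_to_1hz(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline the 2 Hz window statistics onto integer seconds (no extrapolation)."""
    t0, t1 = int(np.ceil(times[0])), int(np.floor(times[-1]))
    t = np.arange(t0, t1 + 1, dtype=float)
    return t, CubicSpline(times, values)(t)


def moving_std_norm(o2hb: np.ndarray, fs: float = 100.0, eps: float = EPS_NORM
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized moving std: per 1-s window (50% overlap), std / max(|mean|, eps)."""
    x = np.asarray(o2hb, dtype=float)
    starts = _window_starts(len(x), fs)
    n_win = int(round(fs))
    views = sliding_window_view(x, n_win)[starts]
    vals = views.std(axis=1, ddof=0) / np.maximum(np.abs(views.mean(axis=1)), eps)
    centers = (starts + n_win / 2.0) / fs
    return _windowed_to_1hz(centers, vals)


def moving_iqr_norm(o2hb: np.ndarray, fs: float = 100.0, eps: float = EPS_NORM
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized moving IQR: per 1-s window, IQR / max(|median|, eps)."""
    x = np.asarray(o2hb, dtype=float)
    starts = _window_starts(len(x), fs)
    n_win = int(round(fs))
    views = sliding_window_view(x, n_win)[starts]
    q75, q25 = np.percentile(views, [75, 25], axis=1)  # linear interpolation quantiles
    vals = (q75 - q25) / np.maximum(np.abs(np.median(views, axis=1)), eps)
    centers = (starts + n_win / 2.0) / fs
    return _windowed_to_1hz(centers, vals)


def moving_correlation(o2hb: np.ndarray, hhb: np.ndarray, fs: float = 100.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed O2Hb-HHb Pearson r; degenerate (constant) windows yield 0.

    Strong positive r marks motion artifacts, strong negative r is the
    activation signature; the interpolated series is clipped to [-1, 1].
    """
    x = np.asarray(o2hb, dtype=float)
    y = np.asarray(hhb, dtype=float)
    if x.shape != y.shape:
        raise ValueError("o2hb and hhb length mismatch")
    starts = _window_starts(len(x), fs)
    n_win = int(round(fs))
    vx = sliding_window_view(x, n_win)[starts]
    vy = sliding_window_view(y, n_win)[starts]
    vx = vx - vx.mean(axis=1, keepdims=True)
    vy = vy - vy.mean(axis=1, keepdims=True)
    denom = np.sqrt((vx**2).sum(axis=1) * (vy**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (vx * vy).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    centers = (starts + n_win / 2.0) / fs
    t, vals = _windowed_to_1hz(centers, r)
    return t, np.clip(vals, -1.0, 1.0)


def build_modalities(h: HemodynamicSeries, v: VitalsSeries) -> ModalitySet:
    """Assemble the eight series on the intersection of their valid 1 Hz spans."""
    if v.hr_1hz is None or v.times_1hz is None:
        raise ValueError("vitals must be interpolated to 1 Hz first")
    if h.tsi is None:
        raise ValueError("missing TSI channel: modality 'tsi_f' cannot be built")
    fs = h.sample_rate
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    series["o2hb_f"] = moving_average_downsample(h.o2hb, fs)
    series["hhb_f"] = moving_average_downsample(h.hhb, fs)
    series["tsi_f"] = moving_average_downsample(h.tsi, fs)
    series["hr_1hz"] = (v.times_1hz, v.hr_1hz)
    series["rr_1hz"] = (v.times_1hz, v.rr_1hz)
    series["mov_std"] = moving_std_norm(h.o2hb, fs)
    series["mov_iqr"] = moving_iqr_norm(h.o2hb, fs)
    series["mov_corr"] = moving_correlation(h.o2hb, h.hhb, fs)

    # nearest-second alignment: every modality's grid is integer seconds by
    # construction; intersect the spans
    t_lo = max(int(round(t[0])) for t, _ in series.values())
    t_hi = min(int(round(t[-1])) for t, _ in series.values())
    if t_hi < t_lo:
        raise ValueError("modalities have no common time span")
    grid = np.arange(t_lo, t_hi + 1, dtype=float)
    aligned = {}
    for name, (t, vals) in series.items():
        i0 = int(round(grid[0] - round(t[0])))
        aligned[name] = np.asarray(vals)[i0:i0 + len(grid)]
    return ModalitySet(times=grid, **aligned)


def epochize(m: ModalitySet, timeline: SleepStateTimeline,
             recording_id: str = "rec", subject_id: str = "sub",
             invalid_mask: np.ndarray | None = None,
             invalid_tolerance: float = 0.10) -> list[FeatureEpoch]:
    """Cut the modality set into labeled 8x60 epochs.

    Wake epochs are excluded (binary AS-vs-QS task); epochs not fully covered
    by the modality grid are dropped, as are epochs whose fraction of
    invalid-marked seconds exceeds ``invalid_tolerance``.
    """
    mat = m.matrix()
    t0 = int(m.times[0])
    epochs: list[FeatureEpoch] = []
    for k, label in enumerate(timeline.labels):
        if label == "Wake":
            continue
        start = timeline.start_time + k * timeline.epoch_duration
        i = int(start) - t0
        if i < 0 or i + 60 > mat.shape[1]:
            continue  # epoch not fully covered by the feature grid
        if invalid_mask is not None:
            frac = float(np.mean(invalid_mask[i:i + 60]))
            if frac > invalid_tolerance:
                continue
        epochs.append(FeatureEpoch(matrix=mat[:, i:i + 60], label=label,
                                   epoch_start=start, recording_id=recording_id,
                                   subject_id=subject_id))
    if not epochs:
        raise ValueError("no usable epochs after exclusion rules")
    return epochs
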