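"""Signal-quality rating (1-5) per window and best-channel selection.

A simplified three-stage re-implementation of the published SQI outline:
band-pass preprocess, reject very low-quality windows (flat / railed /
spiked), accept very high-quality windows (cardiac-band power dominance),
and grade the rest monotonically in the cardiac-band power ratio. The
trained thresholds of the original algorithm are not public; defaults here
are explicit config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import HemodynamicSeries, QualityRating

CARDIAC_BAND = (1.5, 4.0)  # Hz


@dataclass
class QualityConfig:
    bandpass: tuple[float, float] = (0.5, 5.0)  # Hz, 4th-order zero-phase
    flat_rel_range: float = 1e-10  # peak-to-peak relative to median |signal|
    rail_fraction: float = 0.2  # fraction of samples pinned at an extreme
    spike_z: float = 12.0  # robust z-score beyond which a window scores 1
    high_quality_ratio: float = 0.75  # cardiac power ratio for score 5
    intermediate_edges: tuple[float, float] = (0.25, 0.5)  # scores 2|3|4


def _cardiac_power_ratio(x: np.ndarray, fs: float) -> float:
    freqs, psd = signal.periodogram(x, fs=fs, detrend="linear")
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        return 0.0
    sel = (freqs >= CARDIAC_BAND[0]) & (freqs <= CARDIAC_BAND[1])
    return float(np.trapezoid(psd[sel], freqs[sel]) / total)


def _rate_one(raw: np.ndarray, filt: np.ndarray, fs: float, cfg: QualityConfig) -> int:
    at_rail = (raw == raw.max()) | (raw == raw.min())
    if at_rail.mean() >= cfg.rail_fraction:  # stage 1: railed
        return 1
    med = np.median(filt)
    mad = np.median(np.abs(filt - med))
    if mad > 0 and np.max(np.abs(filt - med)) / (1.4826 * mad) > cfg.spike_z:
        return 1  # stage 1: spike artifact
    # the ratio denominator is the full raw-window power so broadband noise
    # actually depresses the score (the band-passed signal would hide it)
    ratio = _cardiac_power_ratio(raw, fs)
    if ratio >= cfg.high_quality_ratio:  # stage 2: very high quality
        return 5
    lo, hi = cfg.intermediate_edges  # stage 3: monotone 2-4
    if ratio < lo:
        return 2
    if ratio < hi:
        return 3
    return 4


def rate_windows(h: HemodynamicSeries, window: float = 10.0, stride: float = 5.0,
                 cfg: QualityConfig | None = None) -> list[QualityRating]:
    """Score every full window of a channel's band-passed tHb on the 1-5 scale."""
    cfg = cfg or QualityConfig()
    if window < 5.0:
        raise ValueError("quality window must be at least 5 s")
    fs = h.sample_rate
    n_win = int(round(window * fs))
    n_str = int(round(stride * fs))
    thb = h.thb
    if len(thb) < n_win:
        raise ValueError("series shorter than one quality window")
    # flat/railed windows would blow up the filter scale checks, so the
    # band-pass is applied only when the series has any dynamics at all
    if np.ptp(thb) > 0:
        sos = signal.butter(4, cfg.bandpass, btype="bandpass", fs=fs, output="sos")
        filt = signal.sosfiltfilt(sos, thb)
    else:
        filt = thb
    ratings = []
    for start in range(0, len(thb) - n_win + 1, n_str):
        raw_win = thb[start:start + n_win]
        # flat/rail detection on the raw dynamics, spectral grading on filtered
        if np.ptp(raw_win) <= cfg.flat_rel_range * max(np.median(np.abs(raw_win)), 1e-300):
            score = 1
        else:
            score = _rate_one(raw_win, filt[start:start + n_win], fs, cfg)
        ratings.append(QualityRating(window_start=start / fs, window_length=window,
                                     score=score, channel_id=h.channel_id))
    return ratings


def select_channel(ratings_per_channel: dict[int, list[QualityRating]]) -> int:
    """Channel with the highest mean score; ties break to the lowest index."""
    if not ratings_per_channel:
        raise ValueError("no channels rated")
    means = {ch: float(np.mean([r.score for r in rs]))
             for ch, rs in ratings_per_channel.items()}
    best = max(means.values())
    return min(ch for ch, m in means.items() if m == best)
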