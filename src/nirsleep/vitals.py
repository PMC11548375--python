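"""Spectral HR/RR extraction from the total-hemoglobin signal.

HR: dominant frequency of each 30-s tHb window (stride 7.5 s) inside an
adaptive cardiac band. RR: same procedure applied to a normalized-IQR
envelope of tHb (IQR over 1-s sub-windows, stride 0.1 s, divided by the
sub-window median magnitude). Bands re-center on the median of the last five
estimates +/- 0.5 Hz, clipped to hard physiological limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.interpolate import CubicSpline

from .types import VitalsSeries

HR_HARD_BAND = (1.3, 4.2)  # Hz
RR_HARD_BAND = (0.25, 1.7)  # Hz


@dataclass
class AdaptiveBandState:
    """Current search band plus the recent estimates that steer it."""

    band: tuple[float, float]
    hard_limits: tuple[float, float]
    half_width: float = 0.5
    history_len: int = 5
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (self.hard_limits[0] <= lo < hi <= self.hard_limits[1]):
            raise ValueError(
                f"band {self.band} outside hard limits {self.hard_limits}"
            )

    def update(self, freq: float) -> None:
        self.history.append(freq)
        if len(self.history) > self.history_len:
            self.history.pop(0)
        center = float(np.median(self.history))
        lo = max(self.hard_limits[0], center - self.half_width)
        hi = min(self.hard_limits[1], center + self.half_width)
        if lo < hi:
            self.band = (lo, hi)


def default_hr_band() -> AdaptiveBandState:
    return AdaptiveBandState(band=(1.5, 4.0), hard_limits=HR_HARD_BAND)


def default_rr_band() -> AdaptiveBandState:
    return AdaptiveBandState(band=(0.3, 1.5), hard_limits=RR_HARD_BAND)


def sliding_windows(series: np.ndarray, fs: float, window: float = 30.0,
                    stride: float = 7.5) -> tuple[np.ndarray, np.ndarray]:
    """Segment a series into full windows starting at 0, stride, 2*stride, ...

    Returns (segments, center_times); the trailing partial window is dropped,
    so count = floor((T - window) / stride) + 1.
    """
    n_win = int(round(window * fs))
    n_str = int(round(stride * fs))
    if len(series) < n_win:
        raise ValueError(
            f"series of {len(series) / fs:.1f} s shorter than one {window} s window"
        )
    n_seg = (len(series) - n_win) // n_str + 1
    starts = np.arange(n_seg) * n_str
    segs = np.stack([series[s:s + n_win] for s in starts])
    centers = (starts + n_win / 2.0) / fs
    return segs, centers


def dominant_frequency(segment: np.ndarray, fs: float,
                       band: tuple[float, float],
                       grid_spacing: float = 0.005,
                       min_prominence: float = 8.0) -> float | None:
    """Argmax frequency of the tapered, zero-padded magnitude spectrum in band.

    Linear detrend, Hann taper, zero-padding to a grid no coarser than
    ``grid_spacing`` Hz, parabolic refinement around the discrete peak; ties
    break toward the lower frequency (first argmax). Returns None ("no
    estimate") when the segment carries no signal or the in-band peak is not
    prominent: a genuine oscillation towers (>70x) over the in-band median
    magnitude, whereas noise peaks at only ~2-5x the median.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= fs / 2.0):
        raise ValueError(f"band {band} not within [0, Nyquist={fs / 2}]")
    x = np.asarray(segment, dtype=float)
    x = signal.detrend(x, type="linear")
    if np.max(np.abs(x)) < 1e-12:
        return None
    x = x * np.hanning(len(x))
    n_fft = next_fast_len(max(len(x), int(np.ceil(fs / grid_spacing))))
    mag = np.abs(rfft(x, n=n_fft))
    freqs = rfftfreq(n_fft, d=1.0 / fs)
    sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if sel.size == 0:
        raise ValueError(f"band {band} contains no spectral bins")
    k = sel[int(np.argmax(mag[sel]))]
    if mag[k] < 1e-12:
        return None
    if min_prominence > 0 and mag[k] < min_prominence * np.median(mag[sel]):
        return None
    # parabolic (quadratic) sub-bin refinement on the magnitude spectrum
    if 0 < k < len(mag) - 1:
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2.0 * b + c
        if denom != 0.0:
            delta = 0.5 * (a - c) / denom
            if abs(delta) <= 1.0:
                return float(np.clip(freqs[k] + delta * (freqs[1] - freqs[0]), lo, hi))
    return float(freqs[k])


def iqr_envelope(x: np.ndarray, fs: float, sub_window: float = 0.5,
                 sub_stride: float = 0.1, eps: float = 1e-6
                 ) -> tuple[np.ndarray, float]:
    """Normalized-IQR amplitude envelope of a signal.

    IQR of each ``sub_window``-second window (stride ``sub_stride``),
    normalized by the median magnitude of the whole signal (floored at eps)
    so the envelope is gain-invariant but keeps its amplitude modulation —
    per-window normalization would cancel the respiratory modulation it is
    built to expose. The sub-window acts as a boxcar smoother with a spectral
    null at 1/sub_window Hz, so it must be short enough to keep the
    respiratory band in its passband (0.5 s places the null at 2 Hz, above
    the 1.7 Hz hard limit). Returns the envelope and its rate 1/sub_stride.
    """
    n_win = int(round(sub_window * fs))
    n_str = int(round(sub_stride * fs))
    if len(x) < n_win:
        raise ValueError("signal shorter than one envelope sub-window")
    views = sliding_window_view(x, n_win)[::n_str]
    q75, q25 = np.percentile(views, [75, 25], axis=1)
    med_mag = max(float(np.median(np.abs(x))), eps)
    return (q75 - q25) / med_mag, 1.0 / sub_stride


def _extract(series: np.ndarray, fs: float, state: AdaptiveBandState,
             window: float, stride: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    segs, centers = sliding_windows(series, fs, window, stride)
    freqs = np.empty(len(segs))
    flagged = np.zeros(len(segs), dtype=bool)
    prev: float | None = None
    for i, seg in enumerate(segs):
        f = dominant_frequency(seg, fs, state.band)
        if f is None:
            flagged[i] = True
            f = prev if prev is not None else 0.5 * (state.band[0] + state.band[1])
        else:
            state.update(f)
        freqs[i] = f
        prev = f
    return freqs, flagged, centers


def extract_vitals(thb: np.ndarray, fs: float = 100.0,
                   window: float = 30.0, stride: float = 7.5,
                   hr_state: AdaptiveBandState | None = None,
                   rr_state: AdaptiveBandState | None = None,
                   bandpass: tuple[float, float] = (0.3, 5.0)) -> VitalsSeries:
    """Windowed HR (BPM) and RR (EPM) estimates from a tHb trace.

    The trace is zero-phase band-pass filtered (4th-order Butterworth) to
    suppress drift before both the cardiac spectrum and the IQR envelope are
    formed. Flagged windows (no spectral peak) hold the previous value.
    """
    hr_state = hr_state or default_hr_band()
    rr_state = rr_state or default_rr_band()
    sos = signal.butter(4, bandpass, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, thb)

    hr_f, hr_flag, centers = _extract(filt, fs, hr_state, window, stride)

    # Envelope is formed on the cardiac-band signal so that the respiratory
    # information enters only through amplitude modulation of the pulse.
    # Motion spikes produce envelope excursions far beyond the respiratory
    # modulation; such samples are replaced by interpolation over a robust
    # (median + MAD) bound so one artifact cannot dominate a 30-s spectrum.
    sos_c = signal.butter(4, HR_HARD_BAND, btype="bandpass", fs=fs, output="sos")
    cardiac = signal.sosfiltfilt(sos_c, thb)
    env, env_fs = iqr_envelope(cardiac, fs)
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    if mad > 0:
        outlier = env > med + 6.0 * 1.4826 * mad
        if outlier.any() and not outlier.all():
            idx = np.arange(len(env))
            env = env.copy()
            env[outlier] = np.interp(idx[outlier], idx[~outlier], env[~outlier])
    env = env - np.mean(env)
    # edge-pad the envelope to the full recording duration so RR windows
    # line up one-to-one with the HR windows
    n_env = int(round(len(thb) / fs * env_fs))
    if len(env) < n_env:
        env = np.concatenate([env, np.full(n_env - len(env), env[-1])])
    rr_f, rr_flag, _ = _extract(env, env_fs, rr_state, window, stride)
    m = min(len(hr_f), len(rr_f))
    return VitalsSeries(times=centers[:m], hr=60.0 * hr_f[:m], rr=60.0 * rr_f[:m],
                        hr_flagged=hr_flag[:m], rr_flagged=rr_flag[:m],
                        window=window, stride=stride)


def interpolate_1hz(v: VitalsSeries) -> VitalsSeries:
    """Cubic-spline interpolation of the windowed estimates onto integer seconds.

    Evaluation spans [first window center, last window center]; no
    extrapolation. Requires at least four estimates.
    """
    if len(v.times) < 4:
        raise ValueError("cubic spline interpolation needs at least 4 estimates")
    t0 = int(np.ceil(v.times[0]))
    t1 = int(np.floor(v.times[-1]))
    t = np.arange(t0, t1 + 1, dtype=float)
    v.times_1hz = t
    v.hr_1hz = CubicSpline(v.times, v.hr)(t)
    v.rr_1hz = CubicSpline(v.times, v.rr)(t)
    return v
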