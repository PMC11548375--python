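"""Synthetic neonatal NIRS generator.

Produces, from one seed: a per-minute AS/QS/Wake timeline, smooth
state-conditional ground-truth HR/RR traces, a two-channel dual-wavelength
100 Hz raw-intensity recording whose implied tHb carries cardiac and
respiratory oscillations tracking the truth, a slowly varying TSI series,
and a 0.4 Hz monitor-style reference. Sleep architecture is a semi-Markov
chain with geometric dwell times in minutes. State-conditional variability
defaults (AS wander ~2.5x QS, higher motion rate) are modeling assumptions,
not published cohort values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import BeerLambertParams, ExtinctionTable, forward_optical_densities
from .types import (
    GroundTruth,
    RawIntensityRecording,
    ReferenceVitals,
    SleepStateTimeline,
    STATES,
)

HR_HARD_LIMITS = (80.0, 250.0)  # BPM
RR_HARD_LIMITS = (15.0, 100.0)  # EPM


def _default_hr_ranges() -> dict[str, tuple[float, float]]:
    return {"AS": (125.0, 170.0), "QS": (110.0, 155.0), "Wake": (130.0, 175.0)}


def _default_rr_ranges() -> dict[str, tuple[float, float]]:
    return {"AS": (40.0, 70.0), "QS": (30.0, 55.0), "Wake": (45.0, 75.0)}


@dataclass
class SimulationConfig:
    seed: int = 0
    duration: float = 30.0  # minutes
    hr_range_by_state: dict[str, tuple[float, float]] = field(default_factory=_default_hr_ranges)
    rr_range_by_state: dict[str, tuple[float, float]] = field(default_factory=_default_rr_ranges)
    hr_wander_sd: float = 0.35  # BPM per 1-s step, scaled per state
    rr_wander_sd: float = 0.30  # EPM per 1-s step
    wander_scale_by_state: dict[str, float] = field(
        default_factory=lambda: {"AS": 1.0, "QS": 0.4, "Wake": 1.2}
    )
    cardiac_amplitude: float = 0.45  # uM on tHb
    resp_amplitude: float = 0.25  # uM on tHb
    am_depth: float = 0.45  # respiratory AM of the cardiac amplitude
    drift_amplitude: float = 1.5  # uM slow baseline wander
    noise_sd: float = 0.08  # uM-equivalent white noise per chromophore
    motion_rate_by_state: dict[str, float] = field(
        default_factory=lambda: {"AS": 0.25, "QS": 0.03, "Wake": 0.8}
    )
    motion_amplitude: float = 8.0  # uM spike scale
    state_dwell_distribution: dict[str, float] = field(
        default_factory=lambda: {"AS": 7.0, "QS": 5.0, "Wake": 1.5}
    )
    qs_fraction: float = 0.26
    wake_fraction: float = 0.05
    channel2_noise_scale: float = 3.0
    reference_jitter_sd: float = 0.0  # BPM/EPM on the 0.4 Hz reference
    sample_rate: float = 100.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    tsi_mean: float = 70.0  # %
    tsi_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.duration < 3:
            raise ValueError("simulated duration must be at least 3 minutes")
        for name in ("cardiac_amplitude", "resp_amplitude", "drift_amplitude",
                     "noise_sd", "motion_amplitude", "hr_wander_sd", "rr_wander_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for s, (lo, hi) in self.hr_range_by_state.items():
            if not (HR_HARD_LIMITS[0] <= lo <= hi <= HR_HARD_LIMITS[1]):
                raise ValueError(f"HR range for {s} outside {HR_HARD_LIMITS} BPM")
        for s, (lo, hi) in self.rr_range_by_state.items():
            if not (RR_HARD_LIMITS[0] <= lo <= hi <= RR_HARD_LIMITS[1]):
                raise ValueError(f"RR range for {s} outside {RR_HARD_LIMITS} EPM")
        for s, m in self.state_dwell_distribution.items():
            if m <= 0:
                raise ValueError(f"mean dwell for {s} must be positive minutes")
        for s, r in self.motion_rate_by_state.items():
            if r < 0:
                raise ValueError(f"motion rate for {s} must be non-negative")
        if not (0.0 <= self.qs_fraction <= 1.0 and 0.0 <= self.wake_fraction < 1.0):
            raise ValueError("state fractions must lie in [0, 1]")


def simulate_timeline(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> SleepStateTimeline:
    """Semi-Markov AS/QS/Wake dwell sequence targeting the configured QS fraction.

    Entry probabilities are proportional to target_fraction / mean_dwell so
    that time occupancy is proportional to the target fractions; dwell times
    are geometric in whole minutes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_epochs = int(round(config.duration))
    fractions = {
        "QS": config.qs_fraction,
        "Wake": config.wake_fraction,
        "AS": max(0.0, 1.0 - config.qs_fraction - config.wake_fraction),
    }
    dwell = config.state_dwell_distribution
    entry = np.array([fractions[s] / dwell[s] for s in STATES])
    if entry.sum() == 0:
        raise ValueError("all state fractions are zero")
    frac = np.array([fractions[s] for s in STATES])
    labels: list[str] = []
    counts = np.zeros(len(STATES))
    horizon = sum(dwell.values())  # keeps early draws stochastic
    while len(labels) < n_epochs:
        # deficit-based entry: states below their target occupancy are
        # favored, so realized fractions track the targets with negative
        # feedback while dwells stay geometric
        deficit = np.maximum(frac * (len(labels) + horizon) - counts, 0.0)
        w = deficit * entry
        if w.sum() == 0:
            w = entry.copy()
        current_i = rng.choice(len(STATES), p=w / w.sum())
        current = STATES[current_i]
        stay = int(rng.geometric(1.0 / dwell[current]))  # support >= 1
        if w.sum() > 0 and deficit[current_i] > 0:
            stay = min(stay, max(1, int(np.ceil(deficit[current_i]))))
        labels.extend([current] * stay)
        counts[current_i] += stay
    return SleepStateTimeline(labels=labels[:n_epochs])


def _state_per_second(timeline: SleepStateTimeline) -> list[str]:
    out: list[str] = []
    for lab in timeline.labels:
        out.extend([lab] * int(timeline.epoch_duration))
    return out


def _walk_trace(states: list[str], ranges: dict[str, tuple[float, float]],
                sd: float, scales: dict[str, float],
                rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting random walk toward each state's range midpoint, clipped."""
    n = len(states)
    x = np.empty(n)
    mids = {s: 0.5 * (lo + hi) for s, (lo, hi) in ranges.items()}
    if sd == 0.0:
        return np.array([mids[s] for s in states])
    theta = 0.02  # gentle pull keeps the trace inside the state range
    lo0, hi0 = ranges[states[0]]
    x[0] = np.clip(mids[states[0]] + rng.normal(0.0, 2.0 * sd), lo0, hi0)
    for t in range(1, n):
        s = states[t]
        lo, hi = ranges[s]
        step = theta * (mids[s] - x[t - 1]) + rng.normal(0.0, sd * scales.get(s, 1.0))
        x[t] = np.clip(x[t - 1] + step, lo, hi)
    return x


def simulate_vitals(timeline: SleepStateTimeline, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> GroundTruth:
    """State-conditional smooth HR/RR traces (1 Hz) plus motion-artifact spans."""
    if len(timeline) == 0:
        raise ValueError("timeline is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    states = _state_per_second(timeline)
    hr = _walk_trace(states, config.hr_range_by_state, config.hr_wander_sd,
                     config.wander_scale_by_state, rng)
    rr = _walk_trace(states, config.rr_range_by_state, config.rr_wander_sd,
                     config.wander_scale_by_state, rng)
    artifacts: list[tuple[float, float]] = []
    for k, lab in enumerate(timeline.labels):
        n_art = rng.poisson(config.motion_rate_by_state.get(lab, 0.0))
        for _ in range(n_art):
            start = 60.0 * k + rng.uniform(0.0, 58.0)
            length = rng.uniform(0.3, 2.0)
            artifacts.append((start, min(start + length, timeline.duration_s)))
    return GroundTruth(hr_trace=hr, rr_trace=rr,
                       artifact_intervals=sorted(artifacts), timeline=timeline)


def _upsample(trace_1hz: np.ndarray, fs: float) -> np.ndarray:
    n = len(trace_1hz)
    t_hi = np.arange(int(n * fs)) / fs
    return np.interp(t_hi, np.arange(n, dtype=float), trace_1hz)


def simulate_recording(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ext: ExtinctionTable | None = None,
    params: BeerLambertParams | None = None,
) -> tuple[RawIntensityRecording, ReferenceVitals]:
    """Synthesize raw intensities whose implied tHb tracks the ground truth.

    Concentration traces are built first (cardiac sinusoid at HR/60 with
    respiratory amplitude modulation, additive respiratory component, drift,
    motion spikes and baseline steps, white noise), then pushed through the
    forward modified Beer-Lambert model with G = 0 — G cancels in
    concentration changes — and exponentiated into intensities.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    ext = ext or ExtinctionTable()
    params = params or BeerLambertParams()
    fs = config.sample_rate
    n = int(truth.timeline.duration_s * fs)
    dt = 1.0 / fs

    hr_hi = _upsample(truth.hr_trace, fs)
    rr_hi = _upsample(truth.rr_trace, fs)
    phase_c = 2.0 * np.pi * np.cumsum(hr_hi / 60.0) * dt
    phase_r = 2.0 * np.pi * np.cumsum(rr_hi / 60.0) * dt

    resp = np.sin(phase_r)
    card_amp = config.cardiac_amplitude * (1.0 + config.am_depth * resp)
    cardiac = card_amp * np.sin(phase_c)

    # O2Hb and HHb pulse in phase (arterial inflow) with a 0.35 HHb share so
    # tHb keeps the full oscillation.
    o2hb = 0.75 * cardiac + 0.65 * config.resp_amplitude * resp
    hhb = 0.25 * cardiac + 0.35 * config.resp_amplitude * resp

    if config.drift_amplitude > 0:
        for arr, scale in ((o2hb, 1.0), (hhb, 0.6)):
            w = rng.normal(0.0, 1.0, n)
            drift = np.cumsum(w)
            drift -= np.linspace(drift[0], drift[-1], n)
            peak = np.max(np.abs(drift)) or 1.0
            arr += scale * config.drift_amplitude * drift / peak

    t = np.arange(n) * dt
    for a, b in truth.artifact_intervals:
        mask = (t >= a) & (t < b)
        if not mask.any():
            continue
        spike = config.motion_amplitude * rng.uniform(0.4, 1.0)
        shape = np.hanning(mask.sum() + 2)[1:-1]  # smooth, positively correlated
        o2hb[mask] += spike * shape
        hhb[mask] += 0.8 * spike * shape
        if rng.random() < 0.3:  # occasional baseline step after the artifact
            step = config.motion_amplitude * 0.15 * rng.normal()
            o2hb[t >= b] += step
            hhb[t >= b] += 0.8 * step

    if config.noise_sd > 0:
        o2hb = o2hb + rng.normal(0.0, config.noise_sd, n)
        hhb = hhb + rng.normal(0.0, config.noise_sd, n)

    od_clean = forward_optical_densities(o2hb, hhb, list(config.wavelengths),
                                         ext, params)
    od_scale = np.abs(od_clean).max() or 1.0
    channels = []
    for ch in range(2):
        od = od_clean.copy()
        if ch == 1 and config.noise_sd > 0:
            extra = config.channel2_noise_scale * config.noise_sd / 0.45
            od = od + rng.normal(0.0, extra * od_scale * 0.1, od.shape)
        I0 = 10_000.0 * (1.0 + 0.1 * ch)
        channels.append(I0 * 10.0 ** (-od))
    intensities = np.stack(channels)  # (2, n_wl, n)

    tsi = config.tsi_mean + config.tsi_sd * np.sin(
        2.0 * np.pi * t / 600.0 + rng.uniform(0, 2 * np.pi)
    ) + rng.normal(0.0, 0.05, n).cumsum() * 0.001

    rec = RawIntensityRecording(
        sample_rate=fs, wavelengths=list(config.wavelengths),
        intensities=intensities, source_detector_distance=params.pathlength,
        tsi=tsi,
    )

    t_ref = np.arange(0.0, truth.timeline.duration_s, 1.0 / 0.4)
    t_truth = np.arange(len(truth.hr_trace), dtype=float)
    hr_ref = np.interp(t_ref, t_truth, truth.hr_trace)
    rr_ref = np.interp(t_ref, t_truth, truth.rr_trace)
    if config.reference_jitter_sd > 0:
        hr_ref = hr_ref + rng.normal(0.0, config.reference_jitter_sd, hr_ref.shape)
        rr_ref = rr_ref + rng.normal(0.0, config.reference_jitter_sd, rr_ref.shape)
    ref = ReferenceVitals(hr=hr_ref, rr=rr_ref)
    return rec, ref


def simulate(config: SimulationConfig) -> tuple[
    RawIntensityRecording, ReferenceVitals, GroundTruth
]:
    """One-call simulation: timeline -> vitals -> recording, all from one seed."""
    rng = np.random.default_rng(config.seed)
    timeline = simulate_timeline(config, rng)
    truth = simulate_vitals(timeline, config, rng)
    rec, ref = simulate_recording(truth, config, rng)
    return rec, ref, truth
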