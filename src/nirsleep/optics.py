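"""Modified Beer-Lambert conversion: raw intensities -> OD -> concentration changes.

OD uses the base-10 convention, OD(t, w) = -log10(I(t, w) / I0(w)); the
reference intensity I0 is the mean over an initial baseline window, so all
outputs are concentration *changes* relative to that baseline and the
constant scattering-loss term cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import HemodynamicSeries, RawIntensityRecording

#: Default molar extinction coefficients, cm^-1 mM^-1, after Cope (1991).
#: NOT device values — the study device's wavelengths are unpublished; these
#: are conventional dual-wavelength CW-NIRS defaults and are overridable.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (0.5862, 1.5458),  # (eps_O2Hb, eps_HHb)
    850.0: (1.0580, 0.6910),
}

#: Default differential path-length factor per wavelength (neonatal head,
#: flagged assumption — unpublished for the study device).
DEFAULT_DPF: dict[float, float] = {760.0: 5.1, 850.0: 4.7}


@dataclass
class ExtinctionTable:
    """wavelength (nm) -> (eps_O2Hb, eps_HHb) in cm^-1 mM^-1."""

    coefficients: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )

    def __post_init__(self) -> None:
        if len(self.coefficients) < 2:
            raise ValueError("extinction table needs at least two wavelengths")
        for wl, (eo, eh) in self.coefficients.items():
            if eo <= 0 or eh <= 0:
                raise ValueError(f"non-positive extinction coefficient at {wl} nm")

    def matrix(self, wavelengths: list[float]) -> np.ndarray:
        """(n_wavelengths, 2) matrix of [eps_O2Hb, eps_HHb] rows."""
        try:
            rows = [self.coefficients[w] for w in wavelengths]
        except KeyError as e:
            raise KeyError(f"no extinction coefficients for wavelength {e} nm") from e
        E = np.asarray(rows, dtype=float)
        if np.linalg.cond(E.T @ E) > 1e12:
            raise ValueError(
                "extinction matrix is numerically singular for wavelengths "
                f"{wavelengths}; chromophores cannot be separated"
            )
        return E


@dataclass
class BeerLambertParams:
    """DPF per wavelength, optode separation (cm), optional scattering loss G.

    G is retained for completeness but never estimated: baseline differencing
    of OD removes any constant offset before the inversion.
    """

    dpf: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_DPF))
    pathlength: float = 3.0
    scattering_loss: float = 0.0

    def __post_init__(self) -> None:
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")
        for wl, d in self.dpf.items():
            if d <= 0:
                raise ValueError(f"DPF must be positive (wavelength {wl} nm)")


@dataclass
class OpticalDensitySeries:
    """Baseline-referenced OD change per channel and wavelength (dimensionless)."""

    od: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    wavelengths: list[float]
    sample_rate: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density contains non-finite values")


def optical_density(
    rec: RawIntensityRecording, baseline_window: float = 10.0
) -> OpticalDensitySeries:
    """OD(t, w) = -log10(I(t, w) / I0(w)).

    I0 is the per-channel, per-wavelength mean intensity over the first
    ``baseline_window`` seconds unless the recording carries an explicit
    reference intensity.
    """
    I = rec.intensities
    if rec.reference_intensity is not None:
        I0 = np.asarray(rec.reference_intensity, dtype=float)[..., None]
    else:
        n0 = max(1, min(rec.n_samples, int(round(baseline_window * rec.sample_rate))))
        I0 = I[:, :, :n0].mean(axis=2, keepdims=True)
    od = -np.log10(I / I0)
    return OpticalDensitySeries(od=od, wavelengths=list(rec.wavelengths),
                                sample_rate=rec.sample_rate)


def concentration_changes(
    od: OpticalDensitySeries,
    ext: ExtinctionTable | None = None,
    params: BeerLambertParams | None = None,
    tsi: np.ndarray | None = None,
    channel: int = 0,
) -> HemodynamicSeries:
    """Invert OD(w) = eps(w) . dc . DPF(w) . l for dc = (dO2Hb, dHHb) in uM.

    Solved per sample by least squares over wavelengths (exact for two
    wavelengths). Concentrations come out in mM from the cm^-1 mM^-1
    extinction units and are returned in uM.
    """
    ext = ext or ExtinctionTable()
    params = params or BeerLambertParams()
    E = ext.matrix(od.wavelengths)  # (n_wl, 2)
    dpf = np.array([params.dpf.get(w, np.nan) for w in od.wavelengths])
    if np.any(~np.isfinite(dpf)):
        missing = [w for w, d in zip(od.wavelengths, dpf) if not np.isfinite(d)]
        raise ValueError(f"no DPF configured for wavelengths {missing}")
    A = E * (dpf * params.pathlength)[:, None]  # (n_wl, 2)
    # pinv once, apply to every sample of the requested channel
    dc_mM = np.linalg.pinv(A) @ od.od[channel]  # (2, n_samples)
    o2hb, hhb = dc_mM * 1e3
    return HemodynamicSeries(o2hb=o2hb, hhb=hhb, sample_rate=od.sample_rate,
                             tsi=tsi, channel_id=channel)


def convert_recording(
    rec: RawIntensityRecording,
    ext: ExtinctionTable | None = None,
    params: BeerLambertParams | None = None,
    baseline_window: float = 10.0,
) -> list[HemodynamicSeries]:
    """Full conversion of every channel of a raw recording."""
    od = optical_density(rec, baseline_window=baseline_window)
    return [
        concentration_changes(od, ext, params, tsi=rec.tsi, channel=ch)
        for ch in range(rec.n_channels)
    ]


def total_hemoglobin(h: HemodynamicSeries) -> np.ndarray:
    """tHb = O2Hb + HHb, elementwise."""
    if h.o2hb.shape != h.hhb.shape:
        raise ValueError("o2hb and hhb length mismatch")
    return h.o2hb + h.hhb


def forward_optical_densities(
    o2hb_uM: np.ndarray,
    hhb_uM: np.ndarray,
    wavelengths: list[float],
    ext: ExtinctionTable | None = None,
    params: BeerLambertParams | None = None,
) -> np.ndarray:
    """Forward model OD(w, t) from known concentration changes (uM).

    The exact inverse of :func:`concentration_changes`; used by the simulator
    to synthesize intensities and by round-trip tests.
    """
    ext = ext or ExtinctionTable()
    params = params or BeerLambertParams()
    E = ext.matrix(wavelengths)
    dpf = np.array([params.dpf[w] for w in wavelengths])
    A = E * (dpf * params.pathlength)[:, None]
    dc_mM = np.stack([o2hb_uM, hhb_uM]) * 1e-3
    return A @ dc_mM  # (n_wl, n_samples)
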