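"""Readers and writers: SNIRF (HDF5) and CSV for raw NIRS, CSV for reference
vitals, annotations, vitals estimates, feature tables, and manifests.

The SNIRF writer emits a minimal valid v1.0 layout (one data block, raw CW
intensities, TSI as an aux series); the CSV dialect is one row per sample
with ``time_s`` plus ``ch{c}_wl{w}`` intensity columns and optional
``tsi_pct``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import RecordingManifest
from .types import (
    RawIntensityRecording,
    ReferenceVitals,
    SleepStateTimeline,
    STATES,
    VitalsSeries,
)


# ---------------------------------------------------------------------------
# SNIRF


def write_snirf(path: str | Path, rec: RawIntensityRecording) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs1")
        data = nirs.create_group("data1")
        n_ch, n_wl, n = rec.intensities.shape
        cols = rec.intensities.reshape(n_ch * n_wl, n).T  # (n_samples, n_meas)
        data.create_dataset("dataTimeSeries", data=cols)
        data.create_dataset("time", data=np.array([0.0, 1.0 / rec.sample_rate]))
        k = 1
        for ch in range(n_ch):
            for wl in range(n_wl):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)  # raw CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
        d = rec.source_detector_distance
        probe.create_dataset("sourcePos3D",
                             data=np.array([[0.0, 2.0 * ch, 0.0] for ch in range(n_ch)]))
        probe.create_dataset("detectorPos3D",
                             data=np.array([[d, 2.0 * ch, 0.0] for ch in range(n_ch)]))
        if rec.tsi is not None:
            aux = nirs.create_group("aux1")
            aux.create_dataset("name", data="TSI")
            aux.create_dataset("dataTimeSeries", data=np.asarray(rec.tsi, dtype=float))
            aux.create_dataset("time", data=np.array([0.0, 1.0 / rec.sample_rate]))


def read_snirf(path: str | Path, expected_rate: float | None = 100.0
               ) -> RawIntensityRecording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs1" in f:
            nirs = f["nirs1"]
        elif "nirs" in f:
            nirs = f["nirs"]
        else:
            raise ValueError(f"{path}: no /nirs group; not a SNIRF file")
        data = nirs["data1"]
        cols = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if len(time) == 2:  # [start, dt] convention
            dt = float(time[1] - time[0])
        else:
            dts = np.diff(time)
            if np.any(dts <= 0):
                raise ValueError(f"{path}: non-monotone timestamps")
            dt = float(np.median(dts))
        sample_rate = 1.0 / dt
        if expected_rate is not None and abs(sample_rate - expected_rate) > 0.01 * expected_rate:
            raise ValueError(
                f"{path}: sampling rate {sample_rate:.2f} Hz does not match the "
                f"declared {expected_rate} Hz"
            )
        wavelengths = [float(w) for w in np.asarray(nirs["probe/wavelengths"])]
        if len(wavelengths) < 2:
            raise ValueError(f"{path}: modified Beer-Lambert needs >= 2 wavelengths, "
                             f"found {len(wavelengths)}")
        mls = sorted((k for k in data.keys() if k.startswith("measurementList")),
                     key=lambda s: int(s[len("measurementList"):]))
        src = [int(np.asarray(data[m]["sourceIndex"])) for m in mls]
        wli = [int(np.asarray(data[m]["wavelengthIndex"])) for m in mls]
        n_ch = max(src)
        n_wl = max(wli)
        n = cols.shape[0]
        intens = np.empty((n_ch, n_wl, n))
        for col, (s, w) in enumerate(zip(src, wli)):
            intens[s - 1, w - 1] = cols[:, col]
        src_pos = np.asarray(nirs["probe/sourcePos3D"])
        det_pos = np.asarray(nirs["probe/detectorPos3D"])
        sd_dist = float(np.linalg.norm(det_pos[0] - src_pos[0]))
        tsi = None
        if "aux1" in nirs:
            tsi = np.asarray(nirs["aux1/dataTimeSeries"])
    return RawIntensityRecording(
        sample_rate=sample_rate, wavelengths=wavelengths, intensities=intens,
        source_detector_distance=sd_dist, tsi=tsi, recording_id=path.stem,
    )


# ---------------------------------------------------------------------------
# CSV dialects


def write_nirs_csv(path: str | Path, rec: RawIntensityRecording) -> None:
    cols = {"time_s": rec.timestamps()}
    for ch in range(rec.n_channels):
        for wi, wl in enumerate(rec.wavelengths):
            cols[f"ch{ch + 1}_wl{int(wl)}"] = rec.intensities[ch, wi]
    if rec.tsi is not None:
        cols["tsi_pct"] = rec.tsi
    pd.DataFrame(cols).to_csv(path, index=False)


def read_nirs_csv(path: str | Path, source_detector_distance: float = 3.0
                  ) -> RawIntensityRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    chans: dict[int, dict[float, np.ndarray]] = {}
    for col in df.columns:
        if col.startswith("ch") and "_wl" in col:
            ch_s, wl_s = col[2:].split("_wl")
            chans.setdefault(int(ch_s), {})[float(wl_s)] = df[col].to_numpy()
    if not chans:
        raise ValueError(f"{path}: no ch{{i}}_wl{{nm}} intensity columns found")
    wavelengths = sorted(next(iter(chans.values())).keys())
    if len(wavelengths) < 2:
        raise ValueError(f"{path}: modified Beer-Lambert needs >= 2 wavelengths")
    intens = np.stack([
        np.stack([chans[ch][w] for w in wavelengths])
        for ch in sorted(chans)
    ])
    tsi = df["tsi_pct"].to_numpy() if "tsi_pct" in df.columns else None
    return RawIntensityRecording(
        sample_rate=1.0 / float(np.median(np.diff(t))), wavelengths=wavelengths,
        intensities=intens, source_detector_distance=source_detector_distance,
        tsi=tsi, recording_id=Path(path).stem,
    )


def read_nirs(path: str | Path) -> RawIntensityRecording:
    """Dispatch on extension: .snirf/.h5 -> SNIRF, .csv -> CSV dialect."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such NIRS file: {p}")
    if p.suffix in (".snirf", ".h5", ".hdf5"):
        return read_snirf(p)
    return read_nirs_csv(p)


def write_reference_vitals(path: str | Path, ref: ReferenceVitals) -> None:
    pd.DataFrame({"time_s": ref.times(), "hr_bpm": ref.hr, "rr_epm": ref.rr}
                 ).to_csv(path, index=False)


def read_reference_vitals(path: str | Path) -> ReferenceVitals:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.4
    return ReferenceVitals(hr=df["hr_bpm"].to_numpy(), rr=df["rr_epm"].to_numpy(),
                           sample_rate=rate)


def write_annotations(path: str | Path, timeline: SleepStateTimeline) -> None:
    pd.DataFrame({"epoch_start_s": timeline.epoch_starts(),
                  "label": timeline.labels}).to_csv(path, index=False)


def read_annotations(path: str | Path) -> SleepStateTimeline:
    df = pd.read_csv(path)
    bad = sorted(set(df["label"]) - set(STATES))
    if bad:
        raise ValueError(
            f"{path}: unknown label token(s) {bad}; allowed tokens are {list(STATES)}"
        )
    if not df["epoch_start_s"].is_monotonic_increasing:
        df = df.sort_values("epoch_start_s")  # sorted with warning downstream
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    if len(starts) > 1:
        gaps = np.diff(starts)
        if np.any(gaps < 60.0 - 1e-9):
            raise ValueError(f"{path}: overlapping one-minute epochs")
    return SleepStateTimeline(labels=list(df["label"]), start_time=float(starts[0]))


def write_vitals(path: str | Path, v: VitalsSeries) -> None:
    pd.DataFrame({
        "time_s": v.times, "hr_bpm": v.hr, "rr_epm": v.rr,
        "hr_flagged": v.hr_flagged.astype(int), "rr_flagged": v.rr_flagged.astype(int),
    }).to_csv(path, index=False)


def write_vitals_1hz(path: str | Path, v: VitalsSeries) -> None:
    if v.times_1hz is None:
        raise ValueError("vitals not interpolated to 1 Hz")
    pd.DataFrame({"time_s": v.times_1hz, "hr_bpm": v.hr_1hz, "rr_epm": v.rr_1hz}
                 ).to_csv(path, index=False)


def write_manifest(path: str | Path, manifests: list[RecordingManifest]) -> None:
    rows = [vars(m) for m in manifests]
    Path(path).write_text(json.dumps(rows, indent=2))


def read_manifest(path: str | Path) -> list[RecordingManifest]:
    rows = json.loads(Path(path).read_text())
    return [RecordingManifest(**r) for r in rows]
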