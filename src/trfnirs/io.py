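"""File formats, run configuration and provenance logging.

Three on-disk dialects bind the pipeline stages together:

* **moment dialect** — tab-separated text, one header line, one row per
  frame/channel/wavelength: ``time_s  channel  wavelength_nm  N
  mean_tof_ps  var_ps2``.
* **histogram dialect** — tab-separated text, one row per
  frame/channel/wavelength with the DTOF bin counts as trailing columns.
* **SNIRF-style container** — an HDF5 layout following the SNIRF
  convention for time-domain data (``/formatVersion``, ``/nirs/...``),
  written and read with h5py.

Every artifact carries the run-config hash and seed so any stage can be
re-run bit-identically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .moments import MomentSeries

__all__ = [
    "RunConfig",
    "RunLog",
    "write_moment_series",
    "read_moment_series",
    "write_dtof_frames",
    "read_dtof_frames",
    "write_snirf_style",
    "read_snirf_style",
]

MOMENT_COLUMNS = ["time_s", "channel", "wavelength_nm", "N", "mean_tof_ps", "var_ps2"]


class FormatError(ValueError):
    """Malformed on-disk artifact."""


@dataclass
class RunConfig:
    """Flat, fully serializable key/value run configuration."""

    values: dict[str, object] = field(default_factory=dict)

    @classmethod
    def defaults(cls) -> "RunConfig":
        return cls(values={
            "lead_in_rest_s": 30.0, "n_cycles": 5, "task_s": 30.0,
            "cycle_rest_s": 30.0, "frame_interval_s": 0.3,
            "wavelengths_nm": "760,830", "source_detector_cm": 3.0,
            "bin_ps": 16.0, "rep_rate_mhz": 80.0,
            "stop_band_hz": "0.08,1.5", "filter_order": 5,
            "mara_window_s": 2.0, "mara_threshold_factor": 3.0,
            "detrend_order": 1,
            "activation_amplitude": 5.0, "physio_amplitudes": "1,1,1",
            "physio_freqs_hz": "0.1,0.2,1.0", "noise_sd": 5.0,
            "corpus_n_per_class": 50, "noise_range": "1,10",
            "seed": 0,
        })

    def hash(self) -> str:
        text = "\n".join(f"{k}={self.values[k]}" for k in sorted(self.values))
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        lines = [f"{k}={self.values[k]}" for k in sorted(self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{ln}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            try:
                values[k] = int(v)
            except ValueError:
                try:
                    values[k] = float(v)
                except ValueError:
                    values[k] = v
        return cls(values=values)


@dataclass
class RunLog:
    """Append-only provenance log: one record per executed stage."""

    path: Path

    def append(self, stage: str, **info: object) -> None:
        parts = [stage] + [f"{k}={v}" for k, v in info.items()]
        with open(self.path, "a") as fh:
            fh.write("\t".join(str(p) for p in parts) + "\n")

    def records(self) -> list[str]:
        p = Path(self.path)
        return p.read_text().splitlines() if p.exists() else []


# ---------------------------------------------------------------- moments

def write_moment_series(series: MomentSeries, path: str | Path,
                        config_hash: str = "") -> None:
    rows = []
    times = series.times_s
    for (ch, wl), arr in series.data.items():
        for i in range(arr.shape[0]):
            rows.append((times[i], ch, wl, arr[i, 0], arr[i, 1], arr[i, 2]))
    df = pd.DataFrame(rows, columns=MOMENT_COLUMNS)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write(f"# frame_interval_s={series.frame_interval_s}\n")
        fh.write(f"# baseline_window={series.baseline_window[0]},"
                 f"{series.baseline_window[1]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_moment_series(path: str | Path) -> MomentSeries:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in MOMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if (df["N"] < 0).any():
        raise FormatError(f"{path}: negative photon count")
    frame_interval = float(meta.get("frame_interval_s", 0.3))
    bl = meta.get("baseline_window", "0,100").split(",")
    data = {}
    for (ch, wl), g in df.groupby(["channel", "wavelength_nm"], sort=False):
        g = g.sort_values("time_s")
        data[(str(ch), float(wl))] = g[["N", "mean_tof_ps", "var_ps2"]].to_numpy()
    return MomentSeries(data=data, frame_interval_s=frame_interval,
                        baseline_window=(int(bl[0]), int(bl[1])))


# --------------------------------------------------------------- histograms

def write_dtof_frames(
    frames: dict[tuple[str, float], np.ndarray],
    path: str | Path,
    bin_ps: float = 16.0,
    frame_interval_s: float = 0.3,
    config_hash: str = "",
) -> None:
    """Histogram dialect: one row per frame, counts as trailing columns."""
    any_frames = next(iter(frames.values()))
    n_bins = any_frames.shape[1]
    header = ["time_s", "channel", "wavelength_nm"] + [
        f"bin{i:04d}" for i in range(n_bins)]
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        fh.write(f"# bin_ps={bin_ps}\n")
        fh.write(f"# frame_interval_s={frame_interval_s}\n")
        fh.write("\t".join(header) + "\n")
        for (ch, wl), arr in frames.items():
            for i, row in enumerate(arr):
                counts = "\t".join(str(int(c)) for c in row)
                fh.write(f"{i * frame_interval_s:.6g}\t{ch}\t{wl:g}\t{counts}\n")


def read_dtof_frames(
    path: str | Path,
) -> tuple[dict[tuple[str, float], np.ndarray], float, float]:
    """Read the histogram dialect -> (frames, bin_ps, frame_interval_s)."""
    meta: dict[str, str] = {}
    rows: dict[tuple[str, float], list[np.ndarray]] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:3] != ["time_s", "channel", "wavelength_nm"]:
                    raise FormatError(f"{path}:{ln}: unexpected header {header[:3]}")
                continue
            if len(parts) != len(header):
                raise FormatError(f"{path}:{ln}: expected {len(header)} fields, "
                                  f"got {len(parts)}")
            counts = np.array(parts[3:], dtype=float)
            if (counts < 0).any():
                raise FormatError(f"{path}:{ln}: negative count")
            rows.setdefault((parts[1], float(parts[2])), []).append(counts)
    frames = {k: np.vstack(v).astype(np.int64) for k, v in rows.items()}
    return (frames, float(meta.get("bin_ps", 16.0)),
            float(meta.get("frame_interval_s", 0.3)))


# ------------------------------------------------------------- SNIRF-style

def write_snirf_style(
    frames: dict[tuple[str, float], np.ndarray],
    path: str | Path,
    bin_ps: float = 16.0,
    frame_interval_s: float = 0.3,
    source_detector_cm: float = 3.0,
) -> None:
    """Write DTOF frames into a SNIRF-convention HDF5 container.

    Layout: ``/formatVersion``, ``/nirs/data1/time`` and one
    ``/nirs/data1/dtof/<channel>/wl<wavelength>`` dataset per measurement
    (n_frames x n_bins), with bin width and geometry as attributes.
    """
    any_frames = next(iter(frames.values()))
    n_frames = any_frames.shape[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0-td-style")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("time", data=np.arange(n_frames) * frame_interval_s)
        data.attrs["bin_ps"] = bin_ps
        data.attrs["source_detector_cm"] = source_detector_cm
        grp = data.create_group("dtof")
        for (ch, wl), arr in frames.items():
            g = grp.require_group(str(ch))
            g.create_dataset(f"wl{wl:g}", data=arr, compression="gzip")


def read_snirf_style(
    path: str | Path,
) -> tuple[dict[tuple[str, float], np.ndarray], float, float]:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        time = np.asarray(data["time"])
        dt = float(time[1] - time[0]) if time.size > 1 else 0.3
        bin_ps = float(data.attrs["bin_ps"])
        frames = {}
        for ch in data["dtof"]:
            for key in data[f"dtof/{ch}"]:
                wl = float(key[2:])
                frames[(ch, wl)] = np.asarray(data[f"dtof/{ch}/{key}"])
    return frames, bin_ps, dt


def read_recording(path: str | Path, dialect: str):
    """Dispatch on dialect: 'moments', 'histogram' or 'snirf'."""
    if dialect == "moments":
        return read_moment_series(path)
    if dialect == "histogram":
        return read_dtof_frames(path)
    if dialect == "snirf":
        return read_snirf_style(path)
    raise FormatError(f"unknown dialect {dialect!r}")
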