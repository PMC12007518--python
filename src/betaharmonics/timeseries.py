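"""Multichannel sampled time-series container and plain-file / EEG-format I/O.

The in-memory unit convention is microvolts (µV) throughout the package.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeries",
    "save_timeseries",
    "load_timeseries",
    "read_timeseries",
    "write_fif",
]


@dataclass
class TimeSeries:
    """Sampled voltage signal(s), shape (n_channels, n_samples), in µV.

    Parameters
    ----------
    samples
        2-D array (channels x time); a 1-D array is promoted to one channel.
    rate
        Sampling rate in Hz, > 0.
    channel_labels
        One label per channel.
    meta
        Free-form provenance record (generator echo, seeds, source file).
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 1-D or 2-D array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.samples[i]

    def pick(self, label: str) -> "TimeSeries":
        """Single-channel view as a new TimeSeries."""
        return TimeSeries(
            self.channel(label)[np.newaxis, :],
            self.rate,
            [label],
            dict(self.meta),
        )


def save_timeseries(ts: TimeSeries, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.f64`` (raw little-endian float64, C order) plus a
    ``<base>.json`` sidecar holding rate, labels, shape and meta.

    Round-trips exactly: :func:`load_timeseries` restores bit-identical data.
    """
    base = Path(base)
    bin_path = base.with_suffix(".f64")
    json_path = base.with_suffix(".json")
    data = np.ascontiguousarray(ts.samples, dtype="<f8")
    data.tofile(bin_path)
    sidecar = {
        "format": "betaharmonics-timeseries",
        "rate": ts.rate,
        "channel_labels": ts.channel_labels,
        "n_channels": ts.n_channels,
        "n_samples": ts.n_samples,
        "dtype": "<f8",
        "order": "C",
        "data_file": bin_path.name,
        "meta": ts.meta,
    }
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return bin_path, json_path


def load_timeseries(path: str | Path) -> TimeSeries:
    """Load a time series written by :func:`save_timeseries`.

    ``path`` may be the JSON sidecar or the base path without suffix.
    """
    path = Path(path)
    json_path = path if path.suffix == ".json" else path.with_suffix(".json")
    sidecar = json.loads(json_path.read_text())
    if sidecar.get("format") != "betaharmonics-timeseries":
        raise ValueError(f"{json_path} is not a betaharmonics sidecar")
    bin_path = json_path.parent / sidecar["data_file"]
    data = np.fromfile(bin_path, dtype=sidecar["dtype"])
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    return TimeSeries(
        data, sidecar["rate"], sidecar["channel_labels"], sidecar.get("meta", {})
    )


def write_fif(ts: TimeSeries, path: str | Path) -> Path:
    """Export as an MNE FIF raw file (µV are converted to volts)."""
    import mne

    info = mne.create_info(ts.channel_labels, ts.rate, ch_types="eeg")
    raw = mne.io.RawArray(ts.samples * 1e-6, info, verbose="error")
    path = Path(path)
    raw.save(path, overwrite=True, verbose="error")
    return path


def _from_mne_raw(raw, path: Path) -> TimeSeries:
    data = raw.get_data() * 1e6  # volts -> µV
    return TimeSeries(
        data,
        float(raw.info["sfreq"]),
        list(raw.ch_names),
        {"source_file": str(path)},
    )


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a recording: BrainVision (.vhdr), EDF (.edf), FIF (.fif) via MNE,
    or the package's own binary + JSON sidecar (.json / bare base path)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in ("", ".json", ".f64"):
        return load_timeseries(path.with_suffix(".json"))
    import mne

    readers = {
        ".vhdr": mne.io.read_raw_brainvision,
        ".edf": mne.io.read_raw_edf,
        ".fif": mne.io.read_raw_fif,
    }
    if suffix not in readers:
        raise ValueError(f"unsupported recording format: {path.name}")
    raw = readers[suffix](path, preload=True, verbose="error")
    return _from_mne_raw(raw, path)
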