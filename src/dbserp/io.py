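"""File formats: EDF signals, event tables, feature tables, configs, reports.

EDF is the exchange format for signals (the acquisition system's native format
is proprietary).  Reading goes through MNE's EDF reader; writing uses a
minimal EDF writer implemented here (16-bit, 1-second data records, one
physical range per channel), since the environment provides no EDF export.
Events travel in a sidecar TSV with columns ``onset_sample`` (authoritative),
``onset_ms`` and ``label``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FormatError, PipelineConfig, Recording, SessionMeta, ValidationError
from .simulate import SimulationConfig

EDF_DIG_MAX = 32767


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if isinstance(value, float):
        s = f"{value:.10g}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a Recording as plain EDF (16-bit, 1 s records).

    The sampling rate must be an integer.  The signal is zero-padded to a
    whole number of seconds; each channel gets a symmetric physical range
    covering its extremes, so quantization error is bounded by
    max|x| / 32767 per channel.
    """
    if abs(recording.fs - round(recording.fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(recording.fs))
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : recording.n_samples] = recording.data
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)

    header = b""
    header += _fmt(0, 8)  # version
    header += _fmt(recording.meta.patient_id, 80)
    header += _fmt(recording.meta.session_id, 80)
    header += _fmt("01.01.00", 8)
    header += _fmt("00.00.00", 8)
    header += _fmt(256 * (1 + n_ch), 8)
    header += _fmt("", 44)
    header += _fmt(n_records, 8)
    header += _fmt(1, 8)  # record duration, seconds
    header += _fmt(n_ch, 4)
    for name in recording.channel_names:
        header += _fmt(name, 16)
    header += b"".join(_fmt("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_fmt("uV", 8) for _ in range(n_ch))
    header += b"".join(_fmt(-float(m), 8) for m in phys_max)
    header += b"".join(_fmt(float(m), 8) for m in phys_max)
    header += b"".join(_fmt(-EDF_DIG_MAX - 1, 8) for _ in range(n_ch))
    header += b"".join(_fmt(EDF_DIG_MAX, 8) for _ in range(n_ch))
    header += b"".join(_fmt("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_fmt(fs, 8) for _ in range(n_ch))
    header += b"".join(_fmt("", 32) for _ in range(n_ch))

    # invert the reader's affine map exactly: physical = (d - dig_min) * 2m/65535 - m
    span = 2.0 * phys_max[:, None] / 65535.0
    digital = np.clip(
        np.round((padded + phys_max[:, None]) / span) - 32768,
        -32768,
        EDF_DIG_MAX,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def write_events(recording: Recording, path) -> None:
    """Write the recording's events as a TSV sidecar."""
    df = pd.DataFrame(
        {
            "onset_sample": recording.events,
            "onset_ms": recording.events * 1000.0 / recording.fs,
            "label": recording.event_labels,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Read an event TSV; ``onset_sample`` is authoritative over ``onset_ms``."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse event table {path}: {exc}") from exc
    if "onset_sample" in df.columns:
        raw = df["onset_sample"].to_numpy()
        if not np.all(np.equal(np.mod(raw, 1), 0)):
            raise ValidationError("onset_sample values must be integers")
        onsets = raw.astype(np.int64)
    elif "onset_ms" in df.columns:
        onsets = np.round(df["onset_ms"].to_numpy() * fs / 1000.0).astype(np.int64)
    else:
        raise FormatError(f"{path}: need an onset_sample or onset_ms column")
    if (onsets < 0).any():
        bad = onsets[onsets < 0]
        raise ValidationError(f"negative event onsets: {bad[:10].tolist()}")
    labels = (
        df["label"].astype(str).to_numpy()
        if "label" in df.columns
        else np.full(onsets.size, "stim", dtype=object)
    )
    return onsets, labels


def read_recording(
    path, events_path=None, meta: SessionMeta | None = None, strict: bool = True
) -> Recording:
    """Read an EDF file (via MNE) plus an optional event TSV into a Recording.

    With ``strict`` (default), events beyond the recording end raise a
    validation error listing the offenders; otherwise they are dropped with a
    warning count.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse EDF {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    fs = float(raw.info["sfreq"])
    n = data_uv.shape[1]
    events = np.empty(0, dtype=np.int64)
    labels = None
    if events_path is not None:
        events, labels = read_events(events_path, fs)
        beyond = events >= n
        if beyond.any():
            if strict:
                raise ValidationError(
                    f"{int(beyond.sum())} event(s) beyond recording end "
                    f"({n} samples): {events[beyond][:10].tolist()}"
                )
            warnings.warn(
                f"dropping {int(beyond.sum())} event(s) beyond recording end",
                stacklevel=2,
            )
            events, labels = events[~beyond], labels[~beyond]
    return Recording(
        data=data_uv,
        fs=fs,
        channel_names=list(raw.ch_names),
        events=events,
        event_labels=labels,
        meta=meta or SessionMeta(),
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a sessions x features table as CSV (header encodes the keys)."""
    if table.empty:
        raise ValidationError("feature table is empty")
    table.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col="session_id")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc


def _config_to_dict(config) -> dict:
    if isinstance(config, PipelineConfig):
        d = config.to_dict()
        d["kind"] = "pipeline"
    elif isinstance(config, SimulationConfig):
        d = dataclasses.asdict(config)
        d["epoch_window_ms"] = list(config.epoch_window_ms)
        d["templates"] = {
            r: {roi: list(c) for roi, c in rois.items()}
            for r, rois in config.templates.items()
        }
        d["kind"] = "simulation"
    else:
        raise ValidationError(f"unknown config type {type(config)}")
    return d


def save_config(config, path) -> None:
    """Save a config as YAML (or JSON if the suffix is .json)."""
    d = _config_to_dict(config)
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh)


def load_config(path):
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    kind = d.pop("kind", "pipeline")
    if kind == "pipeline":
        return PipelineConfig.from_dict(d)
    d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
    d["templates"] = {
        r: {roi: tuple(c) for roi, c in rois.items()} for r, rois in d["templates"].items()
    }
    return SimulationConfig(**d)


def save_report(report: dict, path) -> None:
    """Write a machine-readable JSON report."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def save_epochs(epochs, path) -> None:
    """Store an Epochs container as compressed .npz (the documented binary
    format: arrays ``data``, ``onsets`` plus scalar/str metadata)."""
    np.savez_compressed(
        path,
        data=epochs.data,
        onsets=epochs.onsets,
        fs=epochs.fs,
        tmin_ms=epochs.tmin_ms,
        channel_names=np.array(epochs.channel_names, dtype=object),
        n_dropped=epochs.n_dropped,
        meta=np.array(
            [
                epochs.meta.patient_id,
                epochs.meta.contact_id,
                epochs.meta.region_label,
                epochs.meta.montage_id,
                epochs.meta.session_id,
            ],
            dtype=object,
        ),
    )


def load_epochs(path):
    from .erp import Epochs

    with np.load(path, allow_pickle=True) as z:
        meta = z["meta"]
        return Epochs(
            data=z["data"],
            fs=float(z["fs"]),
            tmin_ms=float(z["tmin_ms"]),
            channel_names=[str(c) for c in z["channel_names"]],
            onsets=z["onsets"],
            n_dropped=int(z["n_dropped"]),
            meta=SessionMeta(*[str(m) for m in meta]),
        )
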