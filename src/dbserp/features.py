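"""Engineered ERP features over predefined post-stimulus windows.

Seven scalar features are computed per (location, window): max/min peak
amplitude, max/min peak latency, peak-to-peak, signed area under the curve,
and energy.  Locations are the 64 individual channels plus the nine ROI
averages; windows are half-open intervals in ms after stimulus onset.

"Energy" is ambiguous between the conventional signal energy (integral of the
squared trace, the default here) and the literal square of the windowed
integral; both are implemented (``energy_mode``).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .core import DEFAULT_WINDOWS_MS, Montage, ValidationError
from .erp import ERP, roi_average

FEATURE_KINDS = (
    "max_amp",
    "min_amp",
    "max_latency",
    "min_latency",
    "peak_to_peak",
    "auc",
    "energy",
)

SEP = "__"  # column key: f"{location}{SEP}{window}{SEP}{kind}"


def feature_key(location: str, window: str, kind: str) -> str:
    return f"{location}{SEP}{window}{SEP}{kind}"


def parse_feature_key(key: str) -> tuple[str, str, str]:
    location, window, kind = key.rsplit(SEP, 2)
    return location, window, kind


def window_feature(
    trace: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    kind: str,
    energy_mode: str = "integral_of_square",
) -> float:
    """One scalar feature of ``trace`` restricted to the half-open window."""
    w0, w1 = window_ms
    mask = (times_ms >= w0) & (times_ms < w1)
    if not mask.any():
        raise ValidationError(f"window {window_ms} outside the trace span")
    seg = trace[mask]
    t = times_ms[mask]
    if kind == "max_amp":
        return float(seg.max())
    if kind == "min_amp":
        return float(seg.min())
    if kind == "max_latency":
        return float(t[int(np.argmax(seg))])  # argmax: earliest index on ties
    if kind == "min_latency":
        return float(t[int(np.argmin(seg))])
    if kind == "peak_to_peak":
        return float(seg.max() - seg.min())
    if kind == "auc":
        return float(np.trapezoid(seg, t))
    if kind == "energy":
        if energy_mode == "integral_of_square":
            return float(np.trapezoid(seg**2, t))
        if energy_mode == "square_of_integral":
            return float(np.trapezoid(seg, t) ** 2)
        raise ValidationError(f"unknown energy_mode {energy_mode!r}")
    raise ValidationError(f"unknown feature kind {kind!r}")


def extract_features(
    erp: ERP,
    roi_map: dict[str, list[str]] | Montage | None = None,
    windows_ms: dict[str, tuple[float, float]] | None = None,
    energy_mode: str = "integral_of_square",
) -> pd.Series:
    """All engineered features of one session's ERP, as a flat Series.

    With a 64-channel ERP, the nine ROIs and the four default windows this is
    7 x 4 x (64 + 9) = 2,044 values.
    """
    windows_ms = windows_ms or DEFAULT_WINDOWS_MS
    t0, t1 = erp.times_ms[0], erp.times_ms[-1]
    for name, (w0, w1) in windows_ms.items():
        if w0 < t0 or w1 > t1 + 1000.0 / erp.fs:
            raise ValidationError(f"window {name!r}={w0, w1} outside ERP span ({t0}, {t1})")
    blocks: list[tuple[str, np.ndarray]] = list(zip(erp.channel_names, erp.data))
    if roi_map is not None:
        roi_erp = roi_average(erp, roi_map)
        blocks += list(zip(roi_erp.channel_names, roi_erp.data))
    times = erp.times_ms
    values: dict[str, float] = {}
    for location, trace in blocks:
        for wname, wint in windows_ms.items():
            for kind in FEATURE_KINDS:
                values[feature_key(location, wname, kind)] = window_feature(
                    trace, times, wint, kind, energy_mode
                )
    return pd.Series(values)


def build_feature_table(
    erps: Iterable[ERP],
    roi_map: dict[str, list[str]] | Montage | None = None,
    windows_ms: dict[str, tuple[float, float]] | None = None,
    energy_mode: str = "integral_of_square",
) -> pd.DataFrame:
    """Sessions x features table with region labels and provenance columns.

    Row index is the session id; leading columns ``region`` and ``patient_id``
    come from each ERP's metadata, the remaining columns are feature keys.
    """
    rows, meta_rows, index = [], [], []
    ref_channels: list[str] | None = None
    for erp in erps:
        if ref_channels is None:
            ref_channels = list(erp.channel_names)
        elif list(erp.channel_names) != ref_channels:
            raise ValidationError("sessions have inconsistent channel sets")
        rows.append(extract_features(erp, roi_map, windows_ms, energy_mode))
        meta_rows.append((erp.meta.region_label, erp.meta.patient_id))
        index.append(erp.meta.session_id)
    if not rows:
        raise ValidationError("no sessions")
    table = pd.DataFrame(rows, index=pd.Index(index, name="session_id"))
    if table.isna().any().any():
        raise ValidationError("feature table contains missing values")
    table.insert(0, "patient_id", [m[1] for m in meta_rows])
    table.insert(0, "region", [m[0] for m in meta_rows])
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything except label/provenance)."""
    return [c for c in table.columns if SEP in c]
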