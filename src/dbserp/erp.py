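"""Epoching, trial averaging, normalization, ROI reduction and stability.

The evoked response potential (ERP) of a session is the average of all trials
(epochs) time-locked to the stimulus, one per pulse, over a -50 to +150 ms
window.  The stability analysis asks how many trials the average needs before
a scalar feature of it (typically the max-peak latency in a window) stops
moving.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Montage, Recording, ROI_NAMES, SessionMeta, ValidationError


@dataclass
class Epochs:
    """Trial-segmented EEG: ``data`` is (n_trials, n_channels, n_samples) uV."""

    data: np.ndarray
    fs: float
    tmin_ms: float
    channel_names: list[str]
    onsets: np.ndarray
    n_dropped: int = 0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("epochs data must be 3-D")
        if self.data.shape[0] < 1:
            raise ValidationError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[2]) * 1000.0 / self.fs


@dataclass
class ERP:
    """Per-session (or per-group) average: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    se: np.ndarray
    n_trials: int
    fs: float
    tmin_ms: float
    channel_names: list[str]
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        if self.data.shape != self.se.shape:
            raise ValidationError("data and se shapes differ")
        if np.any(self.se < 0):
            raise ValidationError("standard error must be >= 0")

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.data.shape[1]) * 1000.0 / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready export: time column in ms plus one column per channel."""
        df = pd.DataFrame(self.data.T, columns=self.channel_names)
        df.insert(0, "time_ms", self.times_ms)
        return df


def extract_epochs(
    recording: Recording, window_ms: tuple[float, float] = (-50.0, 150.0)
) -> Epochs:
    """Cut one epoch per event; events whose window exceeds the recording are
    dropped (and counted in ``n_dropped``)."""
    if recording.events.size == 0:
        raise ValidationError("recording has no events")
    t0, t1 = window_ms
    fs = recording.fs
    n_samp = int(round((t1 - t0) * fs / 1000.0))
    start_off = int(round(t0 * fs / 1000.0))
    starts = recording.events + start_off
    ok = (starts >= 0) & (starts + n_samp <= recording.n_samples)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise ValidationError("no event has a full epoch inside the recording")
    starts = starts[ok]
    idx = starts[:, None] + np.arange(n_samp)
    data = recording.data[:, idx].transpose(1, 0, 2)
    return Epochs(
        data=np.ascontiguousarray(data),
        fs=fs,
        tmin_ms=t0,
        channel_names=list(recording.channel_names),
        onsets=recording.events[ok].copy(),
        n_dropped=n_dropped,
        meta=dataclasses.replace(recording.meta),
    )


def average_epochs(epochs: Epochs) -> ERP:
    """Arithmetic mean over trials; SE is the (n-1) SD over trials / sqrt(n)."""
    n = epochs.n_trials
    mean = epochs.data.mean(axis=0)
    if n > 1:
        se = epochs.data.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.zeros_like(mean)
    return ERP(
        data=mean,
        se=se,
        n_trials=n,
        fs=epochs.fs,
        tmin_ms=epochs.tmin_ms,
        channel_names=list(epochs.channel_names),
        meta=dataclasses.replace(epochs.meta),
    )


def zscore_erp(erp: ERP, mean: np.ndarray | None = None, sd: np.ndarray | None = None) -> ERP:
    """Standardize each channel over the epoch time course (mean 0, SD 1).

    ``mean``/``sd`` (per channel) may be supplied to normalize with pooled
    statistics instead of the session's own (see :func:`zscore_erps_pooled`).
    """
    if mean is None:
        mean = erp.data.mean(axis=1)
    if sd is None:
        sd = erp.data.std(axis=1, ddof=0)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [erp.channel_names[i] for i in flat]
        raise ValidationError(f"zero-variance channel(s): {names}")
    data = (erp.data - mean[:, None]) / sd[:, None]
    out = dataclasses.replace(erp)
    out.data = data
    out.se = erp.se / sd[:, None]
    return out


def zscore_erps_pooled(erps: list[ERP]) -> list[ERP]:
    """z-score a session set with per-channel statistics pooled across all
    sessions (the alternative reading of normalizing "for all conditions")."""
    if not erps:
        raise ValidationError("no ERPs")
    stacked = np.concatenate([e.data for e in erps], axis=1)
    mean = stacked.mean(axis=1)
    sd = stacked.std(axis=1, ddof=0)
    return [zscore_erp(e, mean=mean, sd=sd) for e in erps]


def roi_average(erp: ERP, roi_map: dict[str, list[str]] | Montage) -> ERP:
    """Reduce channels to the nine ROI virtual channels (unweighted means)."""
    if isinstance(roi_map, Montage):
        roi_map = roi_map.roi_map
    rois = [r for r in ROI_NAMES if r in roi_map]
    if not rois:
        raise ValidationError("roi_map contains none of the canonical ROIs")
    traces, ses = [], []
    for roi in rois:
        members = roi_map[roi]
        if not members:
            raise ValidationError(f"ROI {roi!r} is empty")
        rows = [erp.channel_names.index(m) for m in members]
        traces.append(erp.data[rows].mean(axis=0))
        # SE of a mean of channels: combine per-channel SEs assuming independence
        ses.append(np.sqrt((erp.se[rows] ** 2).sum(axis=0)) / len(rows))
    out = dataclasses.replace(erp)
    out.data = np.array(traces)
    out.se = np.array(ses)
    out.channel_names = rois
    return out


def group_average(erps: list[ERP]) -> ERP:
    """Across-session mean trace with across-session standard error."""
    if not erps:
        raise ValidationError("no ERPs to average")
    ref = erps[0]
    for e in erps[1:]:
        if e.data.shape != ref.data.shape or e.channel_names != ref.channel_names:
            raise ValidationError("ERPs have mismatched shapes or channels")
        if (e.tmin_ms, e.fs) != (ref.tmin_ms, ref.fs):
            raise ValidationError("ERPs have mismatched windows")
    stack = np.stack([e.data for e in erps])
    n = len(erps)
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ERP(
        data=mean,
        se=se,
        n_trials=n,
        fs=ref.fs,
        tmin_ms=ref.tmin_ms,
        channel_names=list(ref.channel_names),
        meta=SessionMeta(session_id="group"),
    )


def topographic_frame(erp: ERP, times_ms: list[float]) -> pd.DataFrame:
    """Per-channel scalp values at selected times, for external topoplotting."""
    t = erp.times_ms
    rows = []
    for tm in times_ms:
        j = int(np.argmin(np.abs(t - tm)))
        rows.append(pd.Series(erp.data[:, j], index=erp.channel_names, name=float(t[j])))
    df = pd.DataFrame(rows)
    df.index.name = "time_ms"
    return df


@dataclass
class StabilityResult:
    """Feature estimates on first-N-trial averages and the stable trial count."""

    n_grid: np.ndarray
    estimates: np.ndarray
    reference: float
    tolerance: float
    n_stable: int
    stable: bool  # False if only the full-trial estimate is within tolerance


def stability_curve(
    epochs: Epochs,
    location: str,
    window_ms: tuple[float, float],
    kind: str = "max_latency",
    roi_map: dict[str, list[str]] | Montage | None = None,
    n_grid: np.ndarray | None = None,
    tolerance: float = 2.0,
) -> StabilityResult:
    """Feature-vs-trial-count curve on cumulative (first-N) trial averages.

    ``location`` is a channel name or ROI name (the latter needs ``roi_map``).
    ``n_stable`` is the smallest grid N such that every estimate at N' >= N is
    within ``tolerance`` of the full-trial (max grid) estimate.
    """
    from .features import window_feature  # local import to avoid a cycle

    if n_grid is None:
        n_grid = np.arange(100, epochs.n_trials + 1, 100)
        if n_grid.size == 0:
            n_grid = np.array([epochs.n_trials])
    n_grid = np.asarray(sorted(set(int(n) for n in n_grid)))
    if n_grid.size == 0 or n_grid[0] < 1 or n_grid[-1] > epochs.n_trials:
        raise ValidationError("n_grid must lie in [1, n_trials]")
    if location in epochs.channel_names:
        trial_traces = epochs.data[:, epochs.channel_names.index(location), :]
    else:
        if isinstance(roi_map, Montage):
            roi_map = roi_map.roi_map
        if roi_map is None or location not in roi_map:
            raise ValidationError(f"unknown location {location!r}")
        rows = [epochs.channel_names.index(m) for m in roi_map[location]]
        trial_traces = epochs.data[:, rows, :].mean(axis=1)
    csum = np.cumsum(trial_traces, axis=0)
    times = epochs.times_ms
    full = csum[-1] / epochs.n_trials
    in_win = (times >= window_ms[0]) & (times < window_ms[1])
    if kind.endswith("latency") and np.ptp(full[in_win]) == 0:
        raise ValidationError(f"latency feature undefined: flat window at {location!r}")
    estimates = np.array(
        [
            window_feature(csum[n - 1] / n, times, window_ms, kind)
            for n in n_grid
        ]
    )
    reference = float(estimates[-1])
    within = np.abs(estimates - reference) <= tolerance
    # smallest grid index from which every estimate stays within tolerance;
    # the reference point itself is always within, so the index exists
    bad = np.flatnonzero(~within)
    first_ok_idx = 0 if bad.size == 0 else int(bad[-1]) + 1
    return StabilityResult(
        n_grid=n_grid,
        estimates=estimates,
        reference=reference,
        tolerance=tolerance,
        n_stable=int(n_grid[first_ok_idx]),
        stable=first_ok_idx < n_grid.size - 1 or n_grid.size == 1,
    )
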