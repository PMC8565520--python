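"""The four-step EEG cleaning chain plus 128->64 channel unification.

Order of operations (applied by :func:`clean`):

1. DC removal per channel.
2. Stimulus-artifact detection on the across-channel mean signal (threshold in
   SD units) and replacement by first-degree (linear) interpolation.
3. Average re-referencing.
4. Zero-phase ("two-way") windowed-sinc FIR band-pass, 0.5-40 Hz by default.

Detection uses the across-channel mean because the stimulus artifact is
synchronous on all electrodes; the SD is computed over the whole recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Montage, PipelineConfig, Recording, ValidationError


@dataclass(frozen=True)
class ArtifactSpan:
    """Half-open sample span flagged as stimulus artifact."""

    start: int
    end: int
    peak_abs_value: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"empty span [{self.start}, {self.end})")


def remove_dc(recording: Recording) -> Recording:
    """Subtract each channel's mean over the whole recording."""
    out = recording.copy_with()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def detect_stim_artifacts(
    recording: Recording, threshold_sd: float = 3.0, margin_ms: float = 2.0
) -> list[ArtifactSpan]:
    """Flag samples where the across-channel mean deviates beyond a threshold.

    Samples with ``|m(t) - mean(m)| > threshold_sd * SD(m)`` (m = channel-mean
    signal) are flagged; contiguous runs are extended by ``margin_ms`` on each
    side and overlapping runs merged.
    """
    if recording.n_samples == 0:
        raise ValidationError("empty recording")
    m = recording.data.mean(axis=0)
    dev = np.abs(m - m.mean())
    thresh = threshold_sd * m.std()
    flagged = dev > thresh
    if not flagged.any():
        return []
    margin = int(round(margin_ms * recording.fs / 1000.0))
    n = m.size
    # run-length encode the flagged mask
    idx = np.flatnonzero(flagged)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.r_[0, breaks + 1]]
    ends = idx[np.r_[breaks, idx.size - 1]] + 1
    starts = np.maximum(starts - margin, 0)
    ends = np.minimum(ends + margin, n)
    spans: list[ArtifactSpan] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            spans.append(ArtifactSpan(cur_s, cur_e, float(dev[cur_s:cur_e].max())))
            cur_s, cur_e = int(s), int(e)
    spans.append(ArtifactSpan(cur_s, cur_e, float(dev[cur_s:cur_e].max())))
    return spans


def interpolate_artifacts(recording: Recording, spans: list[ArtifactSpan]) -> Recording:
    """Replace flagged spans with the line joining the surrounding clean samples.

    Every sample outside the spans is bit-identical to the input.  A span that
    touches a recording boundary is filled by holding the nearest clean value
    (with a warning).
    """
    out = recording.copy_with()
    if not spans:
        return out
    n = out.n_samples
    mask = np.zeros(n, dtype=bool)
    for sp in spans:
        if not (0 <= sp.start < sp.end <= n):
            raise ValidationError(f"span [{sp.start}, {sp.end}) outside recording")
        mask[sp.start : sp.end] = True
    if mask[0] or mask[-1]:
        warnings.warn(
            "artifact span touches the recording boundary; holding nearest clean value",
            stacklevel=2,
        )
    if mask.all():
        raise ValidationError("spans cover the whole recording; nothing to anchor on")
    clean_idx = np.flatnonzero(~mask)
    bad_idx = np.flatnonzero(mask)
    for c in range(out.n_channels):
        out.data[c, bad_idx] = np.interp(bad_idx, clean_idx, out.data[c, clean_idx])
    return out


def rereference_average(recording: Recording) -> Recording:
    """Re-reference to the instantaneous mean of all channels."""
    out = recording.copy_with()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def _bandpass_kernel(fs: float, low: float, high: float) -> np.ndarray:
    """Windowed-sinc band-pass kernel: high-pass (0.5 Hz transition) cascaded
    with low-pass (5 Hz transition), Hamming windows."""
    trans_lo, trans_hi = 0.5, 5.0

    def _numtaps(trans: float) -> int:
        n = int(np.ceil(3.3 * fs / trans))
        return n + 1 if n % 2 == 0 else n

    hp = sps.firwin(_numtaps(trans_lo), low, fs=fs, pass_zero=False, window="hamming")
    lp = sps.firwin(_numtaps(trans_hi), high, fs=fs, pass_zero=True, window="hamming")
    return np.convolve(hp, lp)


_KERNEL_CACHE: dict[tuple[float, float, float], np.ndarray] = {}


def bandpass_filter(recording: Recording, low: float = 0.5, high: float = 40.0) -> Recording:
    """Zero-phase FIR band-pass (applied forward and backward).

    The kernel is a windowed-sinc design (0.5 Hz transition at the low edge,
    5 Hz at the high edge); applying it twice via FFT convolution on a
    reflection-padded signal gives zero phase, so smooth peaks do not shift.
    """
    if not 0 < low < high:
        raise ValidationError(f"bad band ({low}, {high})")
    if high >= recording.fs / 2:
        raise ValidationError(f"high edge {high} Hz >= Nyquist {recording.fs / 2} Hz")
    key = (recording.fs, low, high)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = _bandpass_kernel(recording.fs, low, high)
    kernel = _KERNEL_CACHE[key]
    ntaps = kernel.size
    pad = ntaps
    if recording.n_samples <= pad:
        pad = recording.n_samples - 1
    x = recording.data
    # odd reflection at the edges, as in filtfilt, to limit transients
    left = 2 * x[:, :1] - x[:, pad:0:-1]
    right = 2 * x[:, -1:] - x[:, -2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right], axis=1)
    y = sps.fftconvolve(xp, kernel[None, :], mode="same", axes=1)
    y = sps.fftconvolve(y, kernel[None, ::-1], mode="same", axes=1)
    out = recording.copy_with()
    out.data = y[:, pad : pad + recording.n_samples]
    return out


def unify_montage(
    recording: Recording, montage_src: Montage, montage_dst: Montage, k: int = 3
) -> Recording:
    """Interpolate a recording onto a target montage (e.g. 128 -> 64 channels).

    Each target channel is the inverse-distance-weighted average of its ``k``
    nearest source channels; a target coincident with a source copies it.
    """
    if montage_src.montage_id == montage_dst.montage_id:
        raise ValidationError("source and target montages are identical")
    src_names = [n for n in recording.channel_names if n in montage_src.positions]
    if len(src_names) != recording.n_channels:
        raise ValidationError("recording channels missing from source montage")
    src_pos = montage_src.position_array(src_names)
    dst_names = montage_dst.channel_names
    dst_pos = montage_dst.position_array(dst_names)
    data = np.empty((len(dst_names), recording.n_samples))
    for i, p in enumerate(dst_pos):
        d = np.linalg.norm(src_pos - p, axis=1)
        order = np.argsort(d)[:k]
        dk = d[order]
        if dk[0] < 1e-12:
            data[i] = recording.data[order[0]]
            continue
        w = 1.0 / dk
        w /= w.sum()
        data[i] = w @ recording.data[order]
    out = recording.copy_with(data=data, channel_names=dst_names)
    out.meta.montage_id = montage_dst.montage_id
    return out


def clean(
    recording: Recording, config: PipelineConfig | None = None
) -> tuple[Recording, list[ArtifactSpan]]:
    """Run the full cleaning chain in the prescribed order."""
    config = config or PipelineConfig()
    rec = remove_dc(recording)
    spans = detect_stim_artifacts(rec, config.artifact_threshold_sd)
    rec = interpolate_artifacts(rec, spans)
    rec = rereference_average(rec)
    rec = bandpass_filter(rec, *config.filter_band_hz)
    return rec, spans
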