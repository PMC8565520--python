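"""Core domain types for the DBS evoked-potential localization pipeline.

The pipeline operates on scalp EEG recorded while an implanted lead delivers
low-frequency stimulation (3 or 5 Hz) to one contact at a time.  Each session is
one (patient, contact) pair whose stimulation site is labelled as zona incerta
(ZI, dorsal to the subthalamic nucleus), dorso-lateral STN (DLR, motor) or
ventro-medial STN (VMR, associative-limbic).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

REGIONS = ("ZI", "DLR", "VMR")

#: The nine scalp regions of interest: three anterior-posterior rows
#: (frontal, fronto-central, occipito-parietal) by three lateral columns
#: (left, medial, right).
ROI_NAMES = (
    "left_frontal",
    "medial_frontal",
    "right_frontal",
    "left_fronto_central",
    "medial_fronto_central",
    "right_fronto_central",
    "left_occipital_parietal",
    "medial_occipital_parietal",
    "right_occipital_parietal",
)

PIPELINE_CHANNEL_COUNTS = (64, 128)


class ValidationError(ValueError):
    """Raised when data violate a documented invariant."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed."""


@dataclass
class SessionMeta:
    """Session-level metadata attached to a recording."""

    patient_id: str = "unknown"
    contact_id: str = "unknown"
    region_label: str = "unknown"  # one of REGIONS, or "unknown"
    montage_id: str = "EGI64"  # "EGI64" or "EGI128"
    session_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.region_label not in REGIONS + ("unknown",):
            raise ValidationError(
                f"region_label must be one of {REGIONS + ('unknown',)}, "
                f"got {self.region_label!r}"
            )


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per row of ``data``.
    events : ndarray of int
        Stimulus onsets as 0-based sample indices into ``data``.
    event_labels : ndarray of str, optional
        One label per event ("stim" by default).
    meta : SessionMeta
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    event_labels: np.ndarray | None = None
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        self.events = np.asarray(self.events, dtype=np.int64)
        bad = self.events[(self.events < 0) | (self.events >= self.n_samples)]
        if bad.size:
            raise ValidationError(
                f"{bad.size} event(s) outside [0, {self.n_samples}): "
                f"{bad[:10].tolist()}"
            )
        if self.event_labels is None:
            self.event_labels = np.full(self.events.size, "stim", dtype=object)
        else:
            self.event_labels = np.asarray(self.event_labels, dtype=object)
            if self.event_labels.size != self.events.size:
                raise ValidationError("event_labels length must match events")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with ``changes`` applied (data is copied)."""
        kwargs = dict(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            events=self.events.copy(),
            event_labels=np.array(self.event_labels, dtype=object),
            meta=dataclasses.replace(self.meta),
        )
        kwargs.update(changes)
        return Recording(**kwargs)

    def validate_for_pipeline(self) -> None:
        """Check invariants required at pipeline entry (64/128 channels)."""
        if self.n_channels not in PIPELINE_CHANNEL_COUNTS:
            raise ValidationError(
                f"pipeline entry requires {PIPELINE_CHANNEL_COUNTS} channels, "
                f"got {self.n_channels}"
            )


@dataclass
class Montage:
    """Electrode positions plus the scalp ROI grouping.

    positions maps channel name -> (x, y, z) on the unit sphere, with +x right,
    +y anterior, +z superior.  roi_map maps each of the nine ROI names to its
    member channels.
    """

    positions: dict[str, tuple[float, float, float]]
    roi_map: dict[str, list[str]] = field(default_factory=dict)
    montage_id: str = "custom"

    def __post_init__(self) -> None:
        for roi, chans in self.roi_map.items():
            missing = [c for c in chans if c not in self.positions]
            if missing:
                raise ValidationError(f"ROI {roi!r} references unknown channels {missing}")

    def validate_rois(self) -> None:
        """Require exactly the nine canonical ROI names, each non-empty."""
        if set(self.roi_map) != set(ROI_NAMES):
            raise ValidationError(
                f"roi_map must contain exactly the 9 ROIs {ROI_NAMES}, "
                f"got {sorted(self.roi_map)}"
            )
        for roi in ROI_NAMES:
            if not self.roi_map[roi]:
                raise ValidationError(f"ROI {roi!r} is empty")

    @property
    def channel_names(self) -> list[str]:
        return list(self.positions)

    def position_array(self, names: list[str] | None = None) -> np.ndarray:
        names = self.channel_names if names is None else names
        return np.array([self.positions[n] for n in names], dtype=float)


# Feature windows, in ms after stimulus onset, half-open [start, end).
DEFAULT_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "very_early": (5.0, 25.0),
    "early": (45.0, 55.0),
    "middle": (50.0, 100.0),
    "late": (100.0, 149.0),
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain.

    Defaults follow the study protocol: stimulus artifacts detected at 3 SD on
    the across-channel mean, a 0.5-40 Hz two-way FIR band-pass, epochs from
    -50 to +150 ms around each pulse, four post-stimulus feature windows, an
    MRMR size grid, a linear-SVM C grid, and 5-fold cross-validation.
    """

    artifact_threshold_sd: float = 3.0
    filter_band_hz: tuple[float, float] = (0.5, 40.0)
    epoch_window_ms: tuple[float, float] = (-50.0, 150.0)
    windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS_MS)
    )
    mrmr_k_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 40, 60, 80)
    mrmr_k: int = 25
    svm_c_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 0.5, 1.0, 2.0)
    cv_folds: int = 5
    rng_seed: int = 0
    # Feature-stage options (see docs/methods.md for the ambiguities they cover)
    energy_mode: str = "integral_of_square"  # or "square_of_integral"
    features_on_zscored: bool = False
    # Statistics / classification options
    welch_ttest: bool = False
    mrmr_criterion: str = "MID"  # or "MIQ"
    select_within_folds: bool = True
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if not self.artifact_threshold_sd >= 0:
            raise ValidationError("artifact_threshold_sd must be >= 0")
        lo, hi = self.filter_band_hz
        if not 0 < lo < hi:
            raise ValidationError(f"bad filter band {self.filter_band_hz}")
        t0, t1 = self.epoch_window_ms
        if not (t0 < 0 <= t1) and not (t0 <= 0 < t1):
            raise ValidationError("epoch window must contain 0")
        for name, (w0, w1) in self.windows_ms.items():
            if not (0 <= w0 < w1 <= t1):
                raise ValidationError(
                    f"window {name!r}={w0, w1} must lie in the post-stimulus "
                    f"part of the epoch (0, {t1}]"
                )
        if not self.mrmr_k_grid or not self.svm_c_grid:
            raise ValidationError("grids must be non-empty")
        if self.energy_mode not in ("integral_of_square", "square_of_integral"):
            raise ValidationError(f"unknown energy_mode {self.energy_mode!r}")
        if self.mrmr_criterion not in ("MID", "MIQ"):
            raise ValidationError(f"unknown mrmr_criterion {self.mrmr_criterion!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_band_hz"] = list(self.filter_band_hz)
        d["epoch_window_ms"] = list(self.epoch_window_ms)
        d["windows_ms"] = {k: list(v) for k, v in self.windows_ms.items()}
        d["mrmr_k_grid"] = list(self.mrmr_k_grid)
        d["svm_c_grid"] = list(self.svm_c_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("filter_band_hz", "epoch_window_ms"):
            if key in d:
                d[key] = tuple(d[key])
        if "windows_ms" in d:
            d["windows_ms"] = {k: tuple(v) for k, v in d["windows_ms"].items()}
        for key in ("mrmr_k_grid", "svm_c_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
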