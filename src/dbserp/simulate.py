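"""Synthetic EEG cohorts with the statistical structure of DBS evoked responses.

The generator emulates the study conditions: low-frequency stimulus trains
(5 Hz for 8 min or 3 Hz for 13.3 min, 2,400 pulses either way) delivered to a
contact in one of three regions (ZI / DLR / VMR), scalp responses concentrated
medially and ipsilaterally over fronto-central cortex with region-dependent
peak latencies, a large biphasic stimulus artifact at every pulse, and a
1/f + alpha + white background.

Evoked components are Gaussian-windowed ~20 Hz cosines — the "series of
diminishing waves" look of cortical responses to subthalamic stimulation —
whose dominant positive peak lands at the configured latency.  No microvolt
amplitudes are reported for this kind of recording, so all amplitudes here are
package conventions (documented in docs/methods.md); latencies follow the
reported region medians.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Montage, Recording, REGIONS, ROI_NAMES, SessionMeta, ValidationError
from .montage import make_montage, roi_centroid

#: Evoked component per (region, ROI): (latency_ms, amplitude_uv, width_ms).
#: Latencies at the medial / right fronto-central ROIs and the occipital row
#: follow the reported per-region medians; the left frontal ROI is silent
#: (contralateral to stimulation, no differentiation observed there).
DEFAULT_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "ZI": {
        "medial_fronto_central": (77.0, 5.5, 20.0),
        "right_fronto_central": (73.5, 4.0, 20.0),
        "left_fronto_central": (75.0, 2.5, 20.0),
        "medial_frontal": (76.0, 3.0, 20.0),
        "right_frontal": (74.0, 2.2, 20.0),
        "medial_occipital_parietal": (80.0, 1.2, 20.0),
        "right_occipital_parietal": (78.0, 1.0, 20.0),
        "left_occipital_parietal": (79.0, 0.8, 20.0),
    },
    "DLR": {
        "medial_fronto_central": (69.0, 5.2, 20.0),
        "right_fronto_central": (62.0, 3.7, 20.0),
        "left_fronto_central": (68.0, 2.4, 20.0),
        "medial_frontal": (68.0, 2.8, 20.0),
        "right_frontal": (63.0, 2.1, 20.0),
        "medial_occipital_parietal": (71.0, 1.15, 20.0),
        "right_occipital_parietal": (70.0, 0.95, 20.0),
        "left_occipital_parietal": (72.0, 0.8, 20.0),
    },
    "VMR": {
        "medial_fronto_central": (67.0, 4.8, 20.0),
        "right_fronto_central": (64.0, 3.4, 20.0),
        "left_fronto_central": (66.0, 2.2, 20.0),
        "medial_frontal": (66.0, 2.6, 20.0),
        "right_frontal": (65.0, 2.0, 20.0),
        "medial_occipital_parietal": (92.0, 1.1, 20.0),
        "right_occipital_parietal": (88.0, 0.9, 20.0),
        "left_occipital_parietal": (90.0, 0.8, 20.0),
    },
}

CARRIER_HZ = 20.0  # natural frequency of the damped evoked oscillation


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic session / cohort.

    Defaults are the study conditions: 5 Hz for 480 s (2,400 pulses), 1 kHz
    sampling, 64 channels, cohort of 61 sessions (ZI 20 / DLR 23 / VMR 18),
    between-session latency jitter of 3 ms SD and amplitude gain within
    +/-20%.
    """

    stim_freq_hz: float = 5.0
    duration_s: float = 480.0
    fs: float = 1000.0
    n_channels: int = 64
    templates: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_TEMPLATES.items()}
    )
    #: Scales region-specific deviations of latency/amplitude from the
    #: across-region mean template; 0 removes all region information.
    effect_scale: float = 1.0
    #: Global multiplier on all evoked amplitudes; 0 gives background only.
    evoked_gain: float = 1.0
    artifact_amplitude_uv: float = 275.0  # ~50x the largest evoked amplitude
    artifact_duration_ms: float = 2.0  # biphasic: first half +, second half -
    noise_pink_sd_uv: float = 12.0
    noise_pink_exponent: float = 1.0
    noise_white_sd_uv: float = 10.0
    noise_alpha_sd_uv: float = 6.0  # narrowband power at 10 Hz
    epoch_window_ms: tuple[float, float] = (-50.0, 150.0)
    cohort_counts: dict[str, int] = field(
        default_factory=lambda: {"ZI": 20, "DLR": 23, "VMR": 18}
    )
    latency_jitter_sd_ms: float = 3.0
    #: Independent per-ROI latency scatter (SD, ms) on top of the global
    #: jitter.  Weak, distant sources are timed less reliably; the defaults
    #: are calibrated so the simulated between-session effect sizes match the
    #: reported t-statistics for the three headline comparisons.
    roi_latency_jitter_sd_ms: dict[str, float] = field(
        default_factory=lambda: {
            "left_frontal": 6.0,
            "medial_frontal": 6.0,
            "right_frontal": 6.0,
            "left_fronto_central": 7.0,
            "medial_fronto_central": 6.0,
            "right_fronto_central": 9.0,
            "left_occipital_parietal": 20.0,
            "medial_occipital_parietal": 20.0,
            "right_occipital_parietal": 20.0,
        }
    )
    amplitude_gain_range: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        n_pulses = self.stim_freq_hz * self.duration_s
        if abs(n_pulses - round(n_pulses)) > 1e-9:
            raise ValidationError(
                f"stim_freq x duration = {n_pulses} must be an integer pulse count"
            )
        for region, rois in self.templates.items():
            for roi, (lat, _amp, _w) in rois.items():
                if not 0.0 < lat < 150.0:
                    raise ValidationError(
                        f"latency {lat} ms for ({region}, {roi}) outside (0, 150)"
                    )
        if any(v < 0 for v in self.cohort_counts.values()):
            raise ValidationError("cohort counts must be >= 0")

    @property
    def n_pulses(self) -> int:
        return int(round(self.stim_freq_hz * self.duration_s))


@dataclass
class SimulatedSession:
    """A synthetic recording together with its generating ground truth."""

    recording: Recording
    region: str
    session_id: str
    patient_id: str
    seed: int
    #: roi -> (latency_ms, amplitude_uv) of the net injected ROI trace
    #: (after jitter/gain and the zero-mean spatial projection)
    ground_truth: dict[str, tuple[float, float]]
    #: net evoked scalp field, (n_channels, n_post_samples), uV
    evoked_field: np.ndarray | None = None


def _effective_component(
    config: SimulationConfig, region: str, roi: str
) -> tuple[float, float, float]:
    """Component after applying effect_scale toward the across-region mean."""
    comps = {r: config.templates[r].get(roi, (70.0, 0.0, 20.0)) for r in config.templates}
    lat, amp, width = comps[region]
    if config.effect_scale != 1.0:
        mean_lat = float(np.mean([c[0] for c in comps.values()]))
        mean_amp = float(np.mean([c[1] for c in comps.values()]))
        s = config.effect_scale
        lat = mean_lat + s * (lat - mean_lat)
        amp = mean_amp + s * (amp - mean_amp)
    return lat, amp * config.evoked_gain, width


def make_evoked_template(
    region: str,
    roi: str,
    config: SimulationConfig | None = None,
    latency_shift_ms: float = 0.0,
    gain: float = 1.0,
) -> np.ndarray:
    """Evoked waveform for one (region, ROI), over the full epoch span.

    Returns an array covering ``config.epoch_window_ms`` (half-open) at
    ``config.fs``; zero before stimulus onset.  The waveform is a Gaussian-
    windowed cosine at ~20 Hz whose dominant positive peak sits at the
    configured latency.
    """
    config = config or SimulationConfig()
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    if roi not in ROI_NAMES:
        raise ValidationError(f"unknown ROI {roi!r}")
    lat, amp, width = _effective_component(config, region, roi)
    lat = lat + latency_shift_ms
    amp = amp * gain
    t0, t1 = config.epoch_window_ms
    n = int(round((t1 - t0) * config.fs / 1000.0))
    t_ms = t0 + np.arange(n) * 1000.0 / config.fs
    wave = (
        amp
        * np.exp(-((t_ms - lat) ** 2) / (2.0 * width**2))
        * np.cos(2.0 * np.pi * CARRIER_HZ * (t_ms - lat) / 1000.0)
    )
    wave[t_ms < 0] = 0.0
    return wave


def background_noise(
    n_channels: int, n_samples: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """1/f + alpha + white background, independent across channels (uV).

    The three components are independent Gaussian processes, so they are
    sampled jointly as one process whose power spectrum is the sum of the
    component spectra (one spectral draw and one inverse FFT per channel).
    """
    from scipy.fft import irfft, next_fast_len, rfftfreq

    nfft = next_fast_len(max(n_samples, 2))
    freqs = rfftfreq(nfft, d=1.0 / config.fs)
    with np.errstate(divide="ignore"):
        pink_env = np.where(freqs > 0, freqs ** (-config.noise_pink_exponent / 2.0), 0.0)
    alpha_env = np.exp(-((freqs - 10.0) ** 2) / (2.0 * 1.0**2))
    white_env = np.ones_like(freqs)
    total_sq = np.zeros_like(freqs)
    for env, sd in (
        (pink_env, config.noise_pink_sd_uv),
        (alpha_env, config.noise_alpha_sd_uv),
        (white_env, config.noise_white_sd_uv),
    ):
        if sd <= 0:
            continue
        # scale so the component's real-signal variance is sd^2
        # (each retained frequency contributes 4 E_k^2 / nfft^2)
        var = 4.0 * np.sum(env**2) / nfft**2
        total_sq += (sd**2 / var) * env**2
    if not total_sq.any():
        return np.zeros((n_channels, n_samples))
    total_env = np.sqrt(total_sq)
    spec = total_env * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    return irfft(spec, n=nfft, axis=1)[:, :n_samples]


def _roi_channel_weights(montage: Montage) -> dict[str, dict[str, float]]:
    """Spatial spread of each ROI template onto its member channels.

    Weight 1 at the channel nearest the ROI centroid, falling off linearly to
    0.5 at the ROI edge (the member farthest from the centroid).
    """
    weights: dict[str, dict[str, float]] = {}
    for roi, members in montage.roi_map.items():
        if not members:
            weights[roi] = {}
            continue
        centroid = roi_centroid(montage, roi)
        pos = montage.position_array(members)
        dist = np.linalg.norm(pos - centroid, axis=1)
        dmax = dist.max()
        if dmax == 0:
            w = np.ones_like(dist)
        else:
            w = 1.0 - 0.5 * dist / dmax
        weights[roi] = dict(zip(members, w))
    return weights


def simulate_session(
    config: SimulationConfig,
    region: str,
    seed: int,
    montage: Montage | None = None,
    latency_shift_ms: float | dict[str, float] = 0.0,
    gain: float = 1.0,
    meta: SessionMeta | None = None,
) -> SimulatedSession:
    """Generate one continuous stimulation session.

    The recording is the sum of (i) the region's evoked template, spread from
    each ROI onto its member channels, time-locked to every pulse, (ii) a
    biphasic stimulus artifact at each onset on all channels, and (iii) the
    1/f + alpha + white background.  The signal is padded with a short lead-in
    and an epoch-length tail so that every pulse supports a full epoch.
    """
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    montage = montage or make_montage(config.n_channels)
    rng = np.random.default_rng(seed)
    fs = config.fs
    period = fs / config.stim_freq_hz
    n_pulses = config.n_pulses
    n_pre = int(round(-config.epoch_window_ms[0] * fs / 1000.0))
    n_post = int(round(config.epoch_window_ms[1] * fs / 1000.0))
    offset = n_pre + int(round(0.1 * fs))  # lead-in: pre-window + 100 ms
    onsets = offset + np.round(np.arange(n_pulses) * period).astype(np.int64)
    n_samples = int(onsets[-1] + n_post + int(round(0.05 * fs)))

    names = montage.channel_names
    n_ch = len(names)
    signal = background_noise(n_ch, n_samples, config, rng)

    # evoked activity: one epoch-shaped contribution per channel
    post_len = n_post  # template support is [0, n_post) relative to onset
    epoch_contrib = np.zeros((n_ch, post_len))
    ch_index = {n: i for i, n in enumerate(names)}
    weights = _roi_channel_weights(montage)
    if isinstance(latency_shift_ms, dict):
        roi_shift = latency_shift_ms
    else:
        roi_shift = {roi: float(latency_shift_ms) for roi in ROI_NAMES}
    for roi in ROI_NAMES:
        tpl_full = make_evoked_template(
            region, roi, config, latency_shift_ms=roi_shift.get(roi, 0.0), gain=gain
        )
        tpl = tpl_full[-post_len:] if post_len <= tpl_full.size else np.pad(
            tpl_full, (0, post_len - tpl_full.size)
        )
        for ch, w in weights.get(roi, {}).items():
            epoch_contrib[ch_index[ch]] += w * tpl
    # Scalp potentials carry no net monopole: an average-referenced field sums
    # to zero over the sensors at every instant.  Project the evoked field
    # accordingly, so average re-referencing downstream leaves it unchanged.
    epoch_contrib -= epoch_contrib.mean(axis=0, keepdims=True)

    # ground truth = the net injected ROI traces (after the projection)
    truth: dict[str, tuple[float, float]] = {}
    t_post = np.arange(post_len) * 1000.0 / fs
    for roi in ROI_NAMES:
        members = montage.roi_map.get(roi, [])
        if not members:
            truth[roi] = (float("nan"), 0.0)
            continue
        trace = epoch_contrib[[ch_index[c] for c in members]].mean(axis=0)
        win = (t_post >= 40.0) & (t_post < 120.0)
        j = int(np.argmax(trace[win]))
        truth[roi] = (float(t_post[win][j]), float(trace[win][j]))
    if epoch_contrib.any():
        idx = (onsets[:, None] + np.arange(post_len)).ravel()
        tiled = np.tile(epoch_contrib, (1, n_pulses))
        if period >= post_len:  # epochs disjoint: fancy indexing is safe
            signal[:, idx] += tiled
        else:  # overlapping epochs need accumulation
            for c in range(n_ch):
                np.add.at(signal[c], idx, tiled[c])

    # biphasic stimulus artifact, identical on all channels
    n_art = max(2, int(round(config.artifact_duration_ms * fs / 1000.0)))
    art = np.full(n_art, -config.artifact_amplitude_uv)
    art[: n_art // 2] = config.artifact_amplitude_uv
    if config.artifact_amplitude_uv != 0:
        aidx = (onsets[:, None] + np.arange(n_art)).ravel()
        signal[:, aidx] += np.tile(art, n_pulses)

    meta = meta or SessionMeta(
        region_label=region,
        montage_id=montage.montage_id,
        session_id=f"sim-{region}-{seed}",
    )
    rec = Recording(
        data=signal, fs=fs, channel_names=names, events=onsets, meta=meta
    )
    return SimulatedSession(
        recording=rec,
        region=region,
        session_id=meta.session_id,
        patient_id=meta.patient_id,
        seed=seed,
        ground_truth=truth,
        evoked_field=epoch_contrib,
    )


def cohort_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Roster of the cohort: session_id, patient_id, region, per-session seed.

    Deterministic given ``config.seed``; no signals are synthesised.  Region
    labels are shuffled across the roster and sessions are grouped four per
    virtual patient, mimicking four lead contacts per implant.
    """
    rng = np.random.default_rng(config.seed)
    labels = [r for r in ("ZI", "DLR", "VMR") for _ in range(config.cohort_counts.get(r, 0))]
    labels = list(rng.permutation(np.array(labels, dtype=object)))
    seeds = rng.integers(0, 2**31 - 1, size=len(labels))
    rows = []
    for i, (region, s) in enumerate(zip(labels, seeds)):
        rows.append(
            dict(
                session_id=f"S{i + 1:03d}",
                patient_id=f"P{i // 4 + 1:02d}",
                contact_id=f"E{i % 4}",
                region=str(region),
                seed=int(s),
            )
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig, montage: Montage | None = None):
    """Yield the cohort's sessions one at a time (lazily, to bound memory).

    Between-session variability: a latency shift drawn from N(0, jitter_sd)
    and an amplitude gain drawn uniformly from 1 +/- amplitude_gain_range,
    both per session, from the session's own seed.
    """
    montage = montage or make_montage(config.n_channels)
    manifest = cohort_manifest(config)
    for row in manifest.itertuples(index=False):
        srng = np.random.default_rng(row.seed)
        global_shift = float(srng.normal(0.0, config.latency_jitter_sd_ms))
        shift = {
            roi: global_shift
            + float(srng.normal(0.0, config.roi_latency_jitter_sd_ms.get(roi, 0.0)))
            for roi in ROI_NAMES
        }
        g = float(srng.uniform(1.0 - config.amplitude_gain_range, 1.0 + config.amplitude_gain_range))
        meta = SessionMeta(
            patient_id=row.patient_id,
            contact_id=row.contact_id,
            region_label=row.region,
            montage_id=montage.montage_id,
            session_id=row.session_id,
        )
        sess = simulate_session(
            config,
            row.region,
            seed=int(srng.integers(0, 2**31 - 1)),
            montage=montage,
            latency_shift_ms=shift,
            gain=g,
            meta=meta,
        )
        sess.patient_id = row.patient_id
        sess.session_id = row.session_id
        yield sess


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``config`` with all region information removed."""
    config = config or SimulationConfig()
    return dataclasses.replace(config, effect_scale=0.0)
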