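import numpy as np
import pytest

from dbserp import (
    Recording,
    ValidationError,
    bandpass_filter,
    clean,
    detect_stim_artifacts,
    extract_epochs,
    interpolate_artifacts,
    remove_dc,
    rereference_average,
    unify_montage,
)
from dbserp.core import Montage
from dbserp.preprocess import ArtifactSpan


def _rec(data, fs=1000.0, events=()):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = [f"C{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, channel_names=names, events=np.array(events, dtype=np.int64))


class TestRemoveDC:
    def test_constant_channel_becomes_zero(self):
        out = remove_dc(_rec(np.full((1, 100), 7.0)))
        assert np.allclose(out.data, 0.0)

    def test_offset_sinusoid_recentred(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        out = remove_dc(_rec(x + 3.0))
        assert np.allclose(out.data[0], x - x.mean(), atol=1e-12)

    def test_variance_preserved(self, rng):
        x = rng.normal(2.0, 3.0, size=(4, 500))
        out = remove_dc(_rec(x))
        assert np.allclose(out.data.var(axis=1), x.var(axis=1))
        assert np.all(np.abs(out.data.mean(axis=1)) < 1e-9 * out.data.std(axis=1))

    def test_idempotent(self, rng):
        r = _rec(rng.normal(size=(3, 400)))
        once = remove_dc(r)
        twice = remove_dc(once)
        assert np.allclose(once.data, twice.data)


class TestDetectArtifacts:
    def test_uniform_noise_below_threshold_gives_no_spans(self, rng):
        # uniform(-a, a) has max deviation a = sqrt(3) SD < 3 SD
        x = rng.uniform(-1.0, 1.0, size=(1, 5000))
        r = remove_dc(_rec(x))
        assert detect_stim_artifacts(r, threshold_sd=3.0) == []

    def test_injected_spikes_found_as_two_spans(self, rng):
        x = rng.normal(0, 1.0, size=(4, 4000))
        x[:, 1000] += 10 * x.std() * 4  # same-sign spike on all channels
        x[:, 2000] += 10 * x.std() * 4
        spans = detect_stim_artifacts(remove_dc(_rec(x)))
        assert len(spans) == 2
        assert spans[0].start <= 1000 < spans[0].end
        assert spans[1].start <= 2000 < spans[1].end

    def test_zero_threshold_flags_everything(self, rng):
        r = remove_dc(_rec(rng.normal(size=(2, 300))))
        spans = detect_stim_artifacts(r, threshold_sd=0.0)
        assert len(spans) == 1
        assert (spans[0].start, spans[0].end) == (0, 300)

    def test_empty_recording_rejected(self):
        r = Recording(data=np.empty((2, 0)), fs=1000.0, channel_names=["a", "b"])
        with pytest.raises(ValidationError):
            detect_stim_artifacts(r)


class TestInterpolate:
    def test_line_through_a_line_is_identity(self):
        ramp = np.arange(200, dtype=float)
        out = interpolate_artifacts(_rec(ramp), [ArtifactSpan(50, 80, 1.0)])
        assert np.allclose(out.data[0], ramp)

    def test_spike_bounded_by_anchors(self, rng):
        x = rng.normal(size=300)
        x[100:105] += 50.0
        out = interpolate_artifacts(_rec(x), [ArtifactSpan(100, 105, 50.0)])
        hi = max(x[99], x[105])
        lo = min(x[99], x[105])
        assert np.all(out.data[0, 100:105] <= hi + 1e-12)
        assert np.all(out.data[0, 100:105] >= lo - 1e-12)

    def test_samples_outside_spans_untouched(self, rng):
        x = rng.normal(size=(3, 200))
        out = interpolate_artifacts(_rec(x), [ArtifactSpan(20, 40, 1.0)])
        mask = np.ones(200, dtype=bool)
        mask[20:40] = False
        assert np.array_equal(out.data[:, mask], x[:, mask])

    def test_empty_span_list_is_identity(self, rng):
        x = rng.normal(size=(2, 100))
        out = interpolate_artifacts(_rec(x), [])
        assert np.array_equal(out.data, x)

    def test_boundary_span_warns_and_holds(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(UserWarning, match="boundary"):
            out = interpolate_artifacts(_rec(x), [ArtifactSpan(0, 10, 1.0)])
        assert np.allclose(out.data[0, :10], x[10])


class TestRereference:
    def test_single_channel_becomes_zero(self):
        out = rereference_average(_rec(np.sin(np.arange(100.0))))
        assert np.allclose(out.data, 0.0)

    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.normal(size=100)
        out = rereference_average(_rec(np.vstack([x, -x])))
        assert np.allclose(out.data, np.vstack([x, -x]))

    def test_column_means_zero_and_idempotent(self, rng):
        r = _rec(rng.normal(size=(64, 1000)))
        out = rereference_average(r)
        assert np.all(np.abs(out.data.mean(axis=0)) < 1e-9)
        again = rereference_average(out)
        assert np.allclose(out.data, again.data)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(10.0, 0.95, 1.05), (60.0, 0.0, 0.1)],
    )
    def test_sinusoid_gain(self, freq, lo, hi):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass_filter(_rec(x))
        mid = slice(5000, 15000)  # avoid edge transients
        ratio = out.data[0, mid].std() / x[mid].std()
        assert lo <= ratio <= hi

    def test_dc_rejected(self):
        out = bandpass_filter(_rec(np.full((1, 20000), 5.0)))
        assert np.abs(out.data[0, 5000:15000]).max() < 0.05 * 5.0

    def test_smooth_peak_does_not_shift(self):
        t = np.arange(4000)
        x = np.exp(-((t - 2000) ** 2) / (2 * 15.0**2))
        out = bandpass_filter(_rec(x))
        assert abs(int(np.argmax(out.data[0])) - 2000) < 1

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass_filter(_rec(np.zeros(1000)), 0.5, 600.0)


class TestUnifyMontage:
    @staticmethod
    def _montages():
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts[:, 2] = np.abs(pts[:, 2])
        src = Montage(
            positions={f"S{i}": tuple(p) for i, p in enumerate(pts)},
            montage_id="src",
        )
        dst = Montage(
            positions={f"D{i}": tuple(p) for i, p in enumerate(pts[::2] + 1e-3)},
            montage_id="dst",
        )
        return src, dst

    def test_constant_field_preserved(self, rng):
        src, dst = self._montages()
        s = rng.normal(size=200)
        rec = Recording(
            data=np.tile(s, (len(src.positions), 1)),
            fs=1000.0,
            channel_names=list(src.positions),
        )
        out = unify_montage(rec, src, dst)
        assert out.n_channels == len(dst.positions)
        assert np.allclose(out.data, s[None, :])

    def test_coincident_channel_copies_source(self, rng):
        src, _ = self._montages()
        dst = Montage(
            positions={"D0": src.positions["S3"]}, montage_id="dst"
        )
        rec = Recording(
            data=rng.normal(size=(len(src.positions), 50)),
            fs=1000.0,
            channel_names=list(src.positions),
        )
        out = unify_montage(rec, src, dst)
        assert np.array_equal(out.data[0], rec.data[3])

    def test_smooth_field_recovered(self, montage128, montage64):
        # a linear function of position is reproduced well by local averaging
        pos_src = montage128.position_array()
        field = 1.0 + pos_src[:, 0] + 0.5 * pos_src[:, 1]
        rec = Recording(
            data=np.repeat(field[:, None], 20, axis=1),
            fs=1000.0,
            channel_names=montage128.channel_names,
        )
        out = unify_montage(rec, montage128, montage64)
        pos_dst = montage64.position_array()
        expected = 1.0 + pos_dst[:, 0] + 0.5 * pos_dst[:, 1]
        err = np.sqrt(np.mean((out.data[:, 0] - expected) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(expected**2))

    def test_identical_montage_ids_rejected(self, montage64, rng):
        rec = Recording(
            data=rng.normal(size=(64, 10)),
            fs=1000.0,
            channel_names=montage64.channel_names,
        )
        with pytest.raises(ValidationError):
            unify_montage(rec, montage64, montage64)


class TestCleaningChain:
    def test_no_residual_artifact_in_former_spans(self, short_session, config):
        """After cleaning, former artifact spans are no more extreme than the
        rest of the signal on any channel (the 275 uV transients are gone)."""
        rec = short_session.recording
        spans = detect_stim_artifacts(remove_dc(rec), config.artifact_threshold_sd)
        assert spans, "detector should fire on stimulus artifacts"
        cleaned, _ = clean(rec, config)
        in_span = np.zeros(rec.n_samples, dtype=bool)
        for sp in spans:
            in_span[sp.start : sp.end] = True
        x = cleaned.data
        assert np.abs(x[:, in_span]).max() <= np.abs(x[:, ~in_span]).max()

    def test_cleaning_preserves_evoked_waveform(self, noiseless_session, config):
        """Cleaning changes the 5-149 ms evoked waveform by < 5 % RMS."""
        sess = noiseless_session
        cleaned, _ = clean(sess.recording, config)
        epochs = extract_epochs(cleaned, config.epoch_window_ms)
        erp = epochs.data.mean(axis=0)
        t = epochs.times_ms
        mask = (t >= 5) & (t < 149)
        truth = sess.evoked_field[:, 5:149]
        diff = erp[:, mask] - truth
        # the DC of a periodic stimulus train is unobservable after high-pass
        # filtering: compare waveforms up to a per-channel constant offset
        diff -= diff.mean(axis=1, keepdims=True)
        rel = np.sqrt((diff**2).mean()) / np.sqrt((truth**2).mean())
        assert rel < 0.05

    def test_detector_fires_on_every_pulse(self, short_session, config):
        rec = short_session.recording
        spans = detect_stim_artifacts(remove_dc(rec), config.artifact_threshold_sd)
        covered = np.zeros(rec.n_samples, dtype=bool)
        for sp in spans:
            covered[sp.start : sp.end] = True
        assert all(covered[e] for e in rec.events)
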