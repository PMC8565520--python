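import numpy as np
import pytest

from dbserp import (
    ERP,
    Recording,
    ValidationError,
    average_epochs,
    extract_epochs,
    group_average,
    roi_average,
    stability_curve,
    zscore_erp,
)
from dbserp.erp import Epochs, topographic_frame


def _recording_with_events(n_ch=4, n_samp=5000, events=(1000, 2000, 3000), rng=None):
    rng = rng or np.random.default_rng(0)
    return Recording(
        data=rng.normal(size=(n_ch, n_samp)),
        fs=1000.0,
        channel_names=[f"C{i}" for i in range(n_ch)],
        events=np.array(events, dtype=np.int64),
    )


def _epochs_from(data, fs=1000.0, tmin=-50.0):
    data = np.asarray(data, dtype=float)
    return Epochs(
        data=data,
        fs=fs,
        tmin_ms=tmin,
        channel_names=[f"C{i}" for i in range(data.shape[1])],
        onsets=np.arange(data.shape[0]),
    )


class TestExtractEpochs:
    def test_window_has_200_samples_at_1khz(self):
        ep = extract_epochs(_recording_with_events())
        assert ep.data.shape == (3, 4, 200)
        assert ep.times_ms[0] == -50.0
        assert ep.times_ms[-1] == 149.0

    def test_partial_window_events_dropped_and_counted(self):
        rec = _recording_with_events(events=(10, 1000, 4990))
        ep = extract_epochs(rec)
        assert ep.n_trials == 1
        assert ep.n_dropped == 2
        assert ep.n_trials + ep.n_dropped == rec.events.size

    def test_epoch_values_match_manual_slice(self):
        rec = _recording_with_events(events=(1234,))
        ep = extract_epochs(rec)
        assert np.array_equal(ep.data[0], rec.data[:, 1184:1384])

    def test_no_events_rejected(self):
        rec = _recording_with_events(events=())
        with pytest.raises(ValidationError):
            extract_epochs(rec)

    def test_full_simulated_session_yields_one_epoch_per_pulse(self, short_session):
        ep = extract_epochs(short_session.recording)
        assert ep.n_trials == short_session.recording.events.size
        assert ep.n_dropped == 0


class TestAverageEpochs:
    def test_identical_trials_average_to_themselves_with_zero_se(self, rng):
        trial = rng.normal(size=(3, 200))
        ep = _epochs_from(np.stack([trial] * 5))
        erp = average_epochs(ep)
        assert np.allclose(erp.data, trial)
        assert np.allclose(erp.se, 0.0)
        assert erp.n_trials == 5

    def test_antisymmetric_pair_averages_to_zero(self, rng):
        x = rng.normal(size=(2, 100))
        erp = average_epochs(_epochs_from(np.stack([x, -x])))
        assert np.allclose(erp.data, 0.0)

    def test_sqrt_n_residual_against_template(self, rng):
        template = np.sin(np.linspace(0, 6, 200))[None, :]
        sigma, n = 2.0, 400
        trials = template + rng.normal(0, sigma, size=(n, 1, 200))
        erp = average_epochs(_epochs_from(trials))
        residual = np.sqrt(np.mean((erp.data - template) ** 2))
        assert residual == pytest.approx(sigma / np.sqrt(n), rel=0.15)

    def test_linearity_in_scaling(self, rng):
        data = rng.normal(size=(7, 2, 50))
        a = average_epochs(_epochs_from(3.0 * data))
        b = average_epochs(_epochs_from(data))
        assert np.allclose(a.data, 3.0 * b.data)


class TestZscore:
    def test_per_channel_mean_zero_sd_one(self, rng):
        erp = average_epochs(_epochs_from(rng.normal(2, 5, size=(4, 3, 100))))
        z = zscore_erp(erp)
        assert np.allclose(z.data.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.data.std(axis=1), 1.0)

    def test_affine_invariance(self, rng):
        erp = average_epochs(_epochs_from(rng.normal(size=(4, 2, 100))))
        scaled = ERP(
            data=3.5 * erp.data + 7.0,
            se=3.5 * erp.se,
            n_trials=erp.n_trials,
            fs=erp.fs,
            tmin_ms=erp.tmin_ms,
            channel_names=erp.channel_names,
        )
        assert np.allclose(zscore_erp(erp).data, zscore_erp(scaled).data)

    def test_flat_channel_rejected_by_name(self, rng):
        data = rng.normal(size=(1, 3, 50))
        data[:, 1, :] = 4.0
        with pytest.raises(ValidationError, match="C1"):
            zscore_erp(average_epochs(_epochs_from(data)))


class TestRoiAverage:
    def test_identical_members_reproduce_trace(self, montage64, rng):
        trace = rng.normal(size=100)
        data = np.tile(trace, (64, 1))
        erp = ERP(
            data=data, se=np.zeros_like(data), n_trials=1, fs=1000.0,
            tmin_ms=-50.0, channel_names=montage64.channel_names,
        )
        out = roi_average(erp, montage64)
        assert out.channel_names == list(montage64.roi_map)
        assert np.allclose(out.data, trace[None, :])

    def test_matches_bruteforce_mean(self, montage64, rng):
        data = rng.normal(size=(64, 80))
        erp = ERP(
            data=data, se=np.abs(rng.normal(size=(64, 80))), n_trials=9,
            fs=1000.0, tmin_ms=-50.0, channel_names=montage64.channel_names,
        )
        out = roi_average(erp, montage64)
        for i, roi in enumerate(out.channel_names):
            rows = [montage64.channel_names.index(c) for c in montage64.roi_map[roi]]
            assert np.allclose(out.data[i], data[rows].mean(axis=0))

    def test_empty_roi_rejected(self, rng):
        erp = ERP(
            data=rng.normal(size=(2, 10)), se=np.zeros((2, 10)), n_trials=1,
            fs=1000.0, tmin_ms=0.0, channel_names=["a", "b"],
        )
        with pytest.raises(ValidationError):
            roi_average(erp, {"medial_fronto_central": []})


class TestGroupAverage:
    def test_single_session_is_its_own_mean_with_zero_se(self, rng):
        erp = average_epochs(_epochs_from(rng.normal(size=(3, 2, 40))))
        g = group_average([erp])
        assert np.allclose(g.data, erp.data)
        assert np.allclose(g.se, 0.0)

    def test_identical_sessions_have_zero_se(self, rng):
        erp = average_epochs(_epochs_from(rng.normal(size=(3, 2, 40))))
        g = group_average([erp, erp, erp])
        assert np.allclose(g.se, 0.0)

    def test_matches_bruteforce(self, rng):
        erps = [
            average_epochs(_epochs_from(rng.normal(size=(3, 2, 40))))
            for _ in range(5)
        ]
        g = group_average(erps)
        stack = np.stack([e.data for e in erps])
        assert np.allclose(g.data, stack.mean(axis=0))
        assert np.allclose(g.se, stack.std(axis=0, ddof=1) / np.sqrt(5))

    def test_mismatched_shapes_rejected(self, rng):
        a = average_epochs(_epochs_from(rng.normal(size=(2, 2, 40))))
        b = average_epochs(_epochs_from(rng.normal(size=(2, 3, 40))))
        with pytest.raises(ValidationError):
            group_average([a, b])

    def test_topographic_export_shape(self, rng):
        erp = average_epochs(_epochs_from(rng.normal(size=(2, 4, 200))))
        df = topographic_frame(erp, [50.0, 77.0, 100.0])
        assert df.shape == (3, 4)
        assert list(df.index) == [50.0, 77.0, 100.0]


class TestStability:
    def test_noiseless_session_stable_at_smallest_grid_value(self, noiseless_session, montage64):
        ep = extract_epochs(noiseless_session.recording)
        res = stability_curve(
            ep, "medial_fronto_central", (50.0, 100.0), roi_map=montage64,
            n_grid=[10, 20, 50, ep.n_trials],
        )
        assert res.n_stable == 10
        assert res.stable

    def test_zero_tolerance_never_stabilizes_earlier(self, short_session, montage64):
        """tolerance = 0 is the degenerate case: it can only push the stable
        trial count later (estimates must match the reference exactly)."""
        ep = extract_epochs(short_session.recording)
        grid = [10, 20, 40, 80, 160, ep.n_trials]
        kw = dict(roi_map=montage64, n_grid=grid)
        res0 = stability_curve(ep, "medial_fronto_central", (50.0, 100.0), tolerance=0.0, **kw)
        res2 = stability_curve(ep, "medial_fronto_central", (50.0, 100.0), tolerance=2.0, **kw)
        assert res0.n_stable >= res2.n_stable
        if not np.any(res0.estimates[:-1] == res0.reference):
            assert res0.n_stable == ep.n_trials and not res0.stable

    def test_flat_window_rejected(self):
        data = np.zeros((20, 1, 200))
        ep = _epochs_from(data)
        with pytest.raises(ValidationError):
            stability_curve(ep, "C0", (50.0, 100.0))

    def test_estimates_computed_on_prefix_averages(self, rng):
        data = rng.normal(size=(50, 1, 200))
        ep = _epochs_from(data)
        res = stability_curve(ep, "C0", (50.0, 100.0), n_grid=[10, 50], tolerance=1e9)
        t = ep.times_ms
        mask = (t >= 50) & (t < 100)
        manual = data[:10, 0, :].mean(axis=0)
        assert res.estimates[0] == t[mask][np.argmax(manual[mask])]


class TestPooledZscore:
    def test_pooled_statistics_shared_across_sessions(self, rng):
        from dbserp import zscore_erps_pooled

        erps = [
            average_epochs(_epochs_from(rng.normal(3.0, 2.0, size=(2, 2, 60))))
            for _ in range(4)
        ]
        zs = zscore_erps_pooled(erps)
        pooled = np.concatenate([z.data for z in zs], axis=1)
        assert np.allclose(pooled.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(pooled.std(axis=1), 1.0)
        # per-session traces need NOT be individually standardized
        per_session_sds = [z.data.std(axis=1) for z in zs]
        assert not all(np.allclose(sd, 1.0) for sd in per_session_sds)
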