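"""Unit tests for montage, filtering, resampling, and epoch extraction."""

import numpy as np
import pandas as pd
import pytest

from syncnet.preprocess import (
    BipolarRecording,
    RawRecording,
    bipolar_montage,
    epoch_encoding,
    epoch_retrieval,
    notch_filter,
    resample_to_analysis_rate,
    search_window_starts,
)


def _electrodes(rows):
    return pd.DataFrame(rows, columns=["channel", "lead", "contact", "roi"])


def _raw(n_ch, n_samp, fs=500.0, rng=None):
    rng = rng or np.random.default_rng(0)
    return RawRecording(
        data=rng.standard_normal((n_ch, n_samp)), fs=fs,
        channels=[f"c{i}" for i in range(n_ch)],
    )


class TestBipolarMontage:
    def test_three_contact_strip_yields_two_adjacent_pairs(self):
        raw = _raw(3, 1000)
        elec = _electrodes(
            [("c0", "s1", 0, "L-insula"), ("c1", "s1", 1, "L-insula"),
             ("c2", "s1", 2, "L-insula")]
        )
        bip = bipolar_montage(raw, elec)
        assert list(bip.pairs["pair"]) == ["c0-c1", "c1-c2"]
        assert np.allclose(bip.data[0], raw.data[0] - raw.data[1])

    def test_four_contact_depth_yields_three_pairs(self):
        raw = _raw(4, 100)
        elec = _electrodes([(f"c{i}", "d1", i, "R-uncus") for i in range(4)])
        assert bipolar_montage(raw, elec).data.shape[0] == 3

    def test_identical_contacts_give_zero_signal(self):
        raw = _raw(2, 100)
        raw.data[1] = raw.data[0]
        elec = _electrodes([("c0", "s", 0, "L-cuneus"), ("c1", "s", 1, "L-cuneus")])
        assert np.all(bipolar_montage(raw, elec).data == 0)

    def test_pairs_never_cross_leads_and_label_conflicts_dropped(self):
        raw = _raw(4, 100)
        elec = _electrodes(
            [("c0", "s1", 0, "L-insula"), ("c1", "s1", 1, "L-insula"),
             ("c2", "s2", 0, "R-insula"), ("c3", "s2", 1, "R-cuneus")]
        )
        bip = bipolar_montage(raw, elec)
        assert list(bip.pairs["pair"]) == ["c0-c1"]  # s2 pair has roi conflict

    def test_unknown_channels_rejected(self):
        raw = _raw(1, 100)
        elec = _electrodes([("c0", "s", 0, "L-insula"), ("cX", "s", 1, "L-insula")])
        with pytest.raises(ValueError, match="absent"):
            bipolar_montage(raw, elec)


class TestNotchFilter:
    def _pure_tone(self, freq, fs=500.0, dur=4.0):
        t = np.arange(int(dur * fs)) / fs
        return BipolarRecording(
            data=np.sin(2 * np.pi * freq * t)[None], fs=fs,
            pairs=pd.DataFrame({"pair": ["p"], "anode": "a", "cathode": "b",
                                "lead": "l", "roi": "L-insula",
                                "hemisphere": "L"}),
        )

    def test_60hz_attenuated_below_5pct(self):
        sig = self._pure_tone(60.0)
        out = notch_filter(sig)
        core = slice(200, -200)  # avoid edge transients
        assert np.sqrt(np.mean(out.data[0, core] ** 2)) < 0.05 * np.sqrt(
            np.mean(sig.data[0, core] ** 2)
        )

    def test_10hz_preserved_within_1pct(self):
        sig = self._pure_tone(10.0)
        out = notch_filter(sig)
        core = slice(200, -200)
        r = np.sqrt(np.mean(out.data[0, core] ** 2)) / np.sqrt(
            np.mean(sig.data[0, core] ** 2)
        )
        assert abs(r - 1) < 0.01

    def test_zero_in_zero_out(self):
        sig = self._pure_tone(10.0)
        sig.data[:] = 0
        assert np.all(notch_filter(sig).data == 0)

    def test_low_sampling_rate_rejected(self):
        raw = _raw(1, 4000, fs=500.0)
        elec = _electrodes([("c0", "s", 0, "L-insula")])
        sig = BipolarRecording(data=raw.data, fs=100.0, pairs=elec)
        with pytest.raises(ValueError, match="too low"):
            notch_filter(sig)


class TestResample:
    def _sig(self, fs, n):
        return BipolarRecording(
            data=np.random.default_rng(1).standard_normal((2, n)), fs=fs,
            pairs=pd.DataFrame({"pair": ["a", "b"]}),
        )

    def test_two_to_one_decimation_length(self):
        out = resample_to_analysis_rate(self._sig(1000.0, 2000), 500.0)
        assert out.data.shape[-1] == 1000
        assert out.fs == 500.0

    def test_identity_at_target_rate(self):
        sig = self._sig(500.0, 1000)
        assert resample_to_analysis_rate(sig, 500.0) is sig

    def test_sinusoid_preserved_through_4x_decimation(self):
        fs = 2000.0
        t = np.arange(8000) / fs
        sig = BipolarRecording(
            data=np.sin(2 * np.pi * 5.0 * t)[None], fs=fs,
            pairs=pd.DataFrame({"pair": ["p"]}),
        )
        out = resample_to_analysis_rate(sig, 500.0)
        ideal = np.sin(2 * np.pi * 5.0 * np.arange(2000) / 500.0)
        core = slice(50, -50)
        c = np.corrcoef(out.data[0, core], ideal[core])[0, 1]
        assert c > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_to_analysis_rate(self._sig(500.0, 100), 1000.0)


def _bip_for_epochs(n_samp=60000, fs=500.0):
    return BipolarRecording(
        data=np.random.default_rng(2).standard_normal((2, n_samp)), fs=fs,
        pairs=pd.DataFrame({"pair": ["p0", "p1"], "roi": ["L-insula", "R-insula"]}),
    )


class TestEpochEncoding:
    def test_epoch_geometry(self):
        bip = _bip_for_epochs()
        onsets = 3000.0 + np.arange(12) * 2500.0
        ev = pd.DataFrame({"onset_ms": onsets, "recalled": [True, False] * 6})
        ep = epoch_encoding(bip, ev)
        # 3600 ms analysis span + 2 x 1000 ms buffers at 500 Hz
        assert ep.data.shape == (2, 12, 2800)
        assert ep.span_ms == (-1000.0, 2600.0)
        assert ep.n_dropped == 0

    def test_event_too_close_to_edge_dropped(self):
        bip = _bip_for_epochs()
        ev = pd.DataFrame({"onset_ms": [1500.0, 10000.0], "recalled": [True, True]})
        ep = epoch_encoding(bip, ev)
        assert ep.n_trials == 1 and ep.n_dropped == 1

    def test_empty_event_table_gives_empty_epochs(self):
        ep = epoch_encoding(
            _bip_for_epochs(), pd.DataFrame({"onset_ms": [], "recalled": []})
        )
        assert ep.n_trials == 0


class TestEpochRetrieval:
    def _events(self, vocs, start=0.0, end=30000.0):
        rows = [
            {"event_type": "recall_start", "onset_ms": start},
            {"event_type": "recall_end", "onset_ms": end},
        ]
        rows += [{"event_type": "vocalization", "onset_ms": v} for v in vocs]
        return pd.DataFrame(rows)

    def test_retrieval_windows_precede_vocalizations(self):
        bip = _bip_for_epochs(n_samp=20000)
        ev = self._events([5000.0, 20000.0], 3000.0, 38000.0)
        bip2 = _bip_for_epochs(n_samp=25000)
        ep = epoch_retrieval(bip2, ev)
        ret = ep.anchors_ms[ep.condition]
        assert set(ret) == {5000.0, 20000.0}
        assert ep.span_ms == (-500.0, 0.0)

    def test_search_window_tiling_respects_quiet_rule(self):
        # silent stretch 8-12 s (vocal activity before 8, vocalization at 12)
        starts = search_window_starts(
            np.array([7000.0, 12000.0]), 0.0, 30000.0, voc_duration_ms=1000.0
        )
        in_stretch = starts[(starts >= 8000.0) & (starts < 12000.0)]
        # windows must end >= 2 s before the 12 s vocalization
        assert in_stretch.size > 0
        assert np.all(in_stretch + 500.0 + 2000.0 <= 12000.0)

    def test_window_followed_by_vocalization_within_2s_rejected(self):
        # vocalization 1 s after a candidate window end
        starts = search_window_starts(np.array([1500.0]), 0.0, 4000.0)
        assert 0.0 not in starts

    def test_no_search_windows_fails(self):
        bip = _bip_for_epochs(n_samp=5000)
        ev = self._events([2500.0, 5000.0, 7500.0], 2000.0, 8000.0)
        with pytest.raises(ValueError, match="search"):
            epoch_retrieval(bip, ev)


def test_preprocessing_chain_is_linear():
    """Montage + notch + resample commutes with signal addition."""
    rng = np.random.default_rng(3)
    elec = _electrodes(
        [("c0", "s", 0, "L-insula"), ("c1", "s", 1, "L-insula")]
    )
    x = rng.standard_normal((2, 4000))
    y = rng.standard_normal((2, 4000))

    def chain(data):
        raw = RawRecording(data=data, fs=1000.0, channels=["c0", "c1"])
        return resample_to_analysis_rate(notch_filter(bipolar_montage(raw, elec))).data

    assert np.allclose(chain(x) + chain(y), chain(x + y), atol=1e-10)
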