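"""Preprocessing contracts: filtering, epoching, wavelet-packet band selection."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from clrnet.io import EpochSet, RawRecording
from clrnet.preprocess import (
    FilterSpec,
    PipelineConfig,
    WPDConfig,
    bandpass,
    extract_epochs,
    preprocess_pipeline,
    remove_eog,
    select_channels,
    wpd_band_edges,
    wpd_decompose,
    wpd_inverse,
    wpd_reconstruct,
)


def _sine_rec(freq, fs=250.0, dur=10.0, name="C3"):
    t = np.arange(int(dur * fs)) / fs
    return RawRecording(np.sin(2 * np.pi * freq * t)[None, :], [name], fs)


class TestBandpass:
    def test_stopband_attenuation(self):
        rec = _sine_rec(50.0)
        out = bandpass(rec, FilterSpec())
        rms_in = np.sqrt((rec.signal**2).mean())
        rms_out = np.sqrt((out.signal**2).mean())
        assert rms_out <= 0.05 * rms_in

    def test_passband_preserved(self):
        rec = _sine_rec(15.0)
        out = bandpass(rec, FilterSpec())
        core = slice(250, -250)  # ignore filter edge transients
        rms_in = np.sqrt((rec.signal[:, core] ** 2).mean())
        rms_out = np.sqrt((out.signal[:, core] ** 2).mean())
        assert rms_out >= 0.90 * rms_in

    def test_zero_signal_and_metadata(self):
        rec = RawRecording(np.zeros((2, 1000)), ["a", "b"], 250.0, events=[(10, 1)])
        out = bandpass(rec)
        assert np.allclose(out.signal, 0.0)
        assert out.channel_names == rec.channel_names and out.events == rec.events

    def test_band_edge_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(RawRecording(np.zeros((1, 100)), ["a"], 50.0), FilterSpec())


class TestRemoveEog:
    def test_25_to_22_channels(self, tiny_subject):
        rec, _, _ = tiny_subject
        out = remove_eog(rec)
        assert rec.n_channels == 25 and out.n_channels == 22
        assert not any(c.startswith("EOG") for c in out.channel_names)

    def test_eeg_rows_bit_identical(self, tiny_subject):
        rec, _, _ = tiny_subject
        out = remove_eog(rec)
        keep = [i for i, c in enumerate(rec.channel_names) if not c.startswith("EOG")]
        assert np.array_equal(out.signal, rec.signal[keep])
        assert out.channel_names == [rec.channel_names[i] for i in keep]

    def test_strict_missing_channel(self):
        rec = RawRecording(np.zeros((2, 10)), ["C3", "C4"], 250.0)
        with pytest.raises(ValueError, match="EOG-left"):
            remove_eog(rec)
        assert remove_eog(rec, strict=False) == rec


class TestExtractEpochs:
    def test_750_samples_at_250hz(self, tiny_subject):
        rec, _, _ = tiny_subject
        epochs = extract_epochs(remove_eog(rec))
        assert epochs.n_samples == 750
        assert epochs.n_trials == len(rec.events)

    def test_constant_signal(self):
        rec = RawRecording(np.ones((1, 2000)), ["a"], 250.0, events=[(0, 2)])
        e = extract_epochs(rec)
        assert np.all(e.data == 1.0) and list(e.labels) == [2]

    def test_ramp_index_arithmetic(self):
        fs = 250.0
        sig = np.arange(4000, dtype=float)[None, :]
        rec = RawRecording(sig, ["a"], fs, events=[(100, 0), (2000, 3)])
        e = extract_epochs(rec, window=(3.0, 6.0))
        start = 100 + round(3 * fs)
        assert e.data[0, 0, 0] == start  # half-open [onset+750, ...)
        assert e.data[0, 0, -1] == start + 749
        assert e.data[1, 0, 0] == 2000 + 750

    def test_window_past_end_lists_trials(self):
        rec = RawRecording(np.zeros((1, 2000)), ["a"], 250.0, events=[(0, 0), (900, 1)])
        with pytest.raises(ValueError, match=r"trials \[1\]"):
            extract_epochs(rec)

    def test_unknown_cue_needs_side_car(self):
        rec = RawRecording(np.zeros((1, 2000)), ["a"], 250.0, events=[(0, -1)])
        with pytest.raises(ValueError, match="side-car"):
            extract_epochs(rec)
        e = extract_epochs(rec, labels=[2])
        assert list(e.labels) == [2]


class TestBandEdges:
    def test_printed_edges_at_250hz(self):
        edges = wpd_band_edges(250.0, 16)
        assert edges[0] == (0.0, 7.8125)
        assert edges[1] == (7.8125, 15.625)
        assert edges[2] == (15.625, 23.4375)

    def test_degenerate_single_band(self):
        assert wpd_band_edges(2.0, 1) == [(0.0, 1.0)]

    @pytest.mark.parametrize("n", [2, 4, 8, 16, 32])
    def test_bands_tile_nyquist_without_overlap(self, n):
        edges = wpd_band_edges(250.0, n)
        assert edges[0][0] == 0.0 and edges[-1][1] == 125.0
        for (a, b), (c, d) in zip(edges, edges[1:]):
            assert b == c and b > a and d > c

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            wpd_band_edges(250.0, 12)


class TestWPD:
    def test_leaves_match_pywt_frequency_order(self, rng):
        """Dual route: vectorized packet tree vs pywt's WaveletPacket."""
        x = rng.standard_normal(750)
        leaves, _ = wpd_decompose(x, "db4", 5)
        wp = pywt.WaveletPacket(x, "db4", mode="symmetric", maxlevel=5)
        ref = [node.data for node in wp.get_level(5, order="freq")]
        assert len(leaves) == 32
        for mine, theirs in zip(leaves, ref):
            np.testing.assert_allclose(mine, theirs, atol=1e-12)

    @pytest.mark.parametrize("n_samples", [750, 512, 301])
    def test_perfect_reconstruction_all_leaves(self, rng, n_samples):
        x = rng.standard_normal((3, 2, n_samples))
        leaves, lengths = wpd_decompose(x, "db4", 5)
        back = wpd_inverse(leaves, lengths, "db4")[..., :n_samples]
        rel = np.sqrt(((back - x) ** 2).mean()) / np.sqrt((x**2).mean())
        assert rel < 1e-8

    def test_full_band_reconstruct_is_identity(self, rng):
        e = EpochSet(rng.standard_normal((2, 3, 750)), [0, 1], 250.0, ["a", "b", "c"])
        cfg = WPDConfig(retained_band=(0.0, 125.0), output_samples=None)
        out = wpd_reconstruct(e, cfg)
        rel = np.sqrt(((out.data - e.data) ** 2).mean()) / e.data.std()
        assert rel < 1e-8

    def test_shape_750_to_240(self, rng):
        e = EpochSet(
            rng.standard_normal((4, 22, 750)),
            rng.integers(0, 4, 4),
            250.0,
            [f"ch{i}" for i in range(22)],
        )
        out = wpd_reconstruct(e)
        assert out.data.shape == (4, 22, 240)
        assert out.fs == pytest.approx(80.0)
        assert np.array_equal(out.labels, e.labels)

    def test_band_selectivity_spectral_oracle(self):
        """In-band tones survive, out-of-band tones are removed.

        Thresholds frozen from the measured behaviour of the db4
        level-5 tree: 10 Hz sits in the transition band just above the
        7.8125 Hz leaf edge and keeps ~0.88 of its energy; 12 Hz is
        mid-leaf; 40 Hz is far outside the retained band.
        """
        t = np.arange(750) / 250.0
        cfg = WPDConfig(output_samples=None)

        def retained_fraction(freq):
            s = np.sin(2 * np.pi * freq * t)
            e = EpochSet(s[None, None, :], [0], 250.0, ["C3"])
            out = wpd_reconstruct(e, cfg)
            return (out.data**2).sum() / (s**2).sum()

        assert retained_fraction(10.0) >= 0.85
        assert retained_fraction(12.0) >= 0.95
        assert retained_fraction(40.0) <= 0.10

    def test_energy_monotone_in_band_width(self, rng):
        x = rng.standard_normal((1, 1, 750))
        e = EpochSet(x, [0], 250.0, ["C3"])
        widths = [(7.8125, 15.625), (7.8125, 23.4375), (3.90625, 46.875), (0.0, 125.0)]
        energies = []
        for band in widths:
            out = wpd_reconstruct(e, WPDConfig(retained_band=band, output_samples=None))
            energies.append((out.data**2).sum())
        assert all(a <= b + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_empty_band_and_short_epoch_rejected(self, rng):
        e = EpochSet(rng.standard_normal((1, 1, 750)), [0], 250.0, ["C3"])
        with pytest.raises(ValueError, match="no leaves"):
            wpd_reconstruct(e, WPDConfig(retained_band=(8.0, 9.0)))
        short = EpochSet(rng.standard_normal((1, 1, 16)), [0], 250.0, ["C3"])
        with pytest.raises(ValueError, match="shorter"):
            wpd_reconstruct(short, WPDConfig(level=5))

    @given(st.integers(1, 5))
    @settings(max_examples=5, deadline=None)
    def test_perfect_reconstruction_any_level(self, level):
        rng = np.random.default_rng(level)
        x = rng.standard_normal((1, 1, 300))
        leaves, lengths = wpd_decompose(x, "db4", level)
        back = wpd_inverse(leaves, lengths, "db4")[..., :300]
        assert np.sqrt(((back - x) ** 2).mean()) < 1e-8


class TestSelectChannels:
    def test_subset_and_identity(self, tiny_epochs):
        two = select_channels(tiny_epochs, ["C3", "C4"])
        assert two.n_channels == 2 and two.channel_names == ["C3", "C4"]
        same = select_channels(tiny_epochs, tiny_epochs.channel_names)
        assert same == tiny_epochs

    def test_rows_equal_originals(self, tiny_epochs):
        sub = select_channels(tiny_epochs, ["C4", "C3"])  # order respected
        i3 = tiny_epochs.channel_names.index("C3")
        i4 = tiny_epochs.channel_names.index("C4")
        assert np.array_equal(sub.data[:, 0], tiny_epochs.data[:, i4])
        assert np.array_equal(sub.data[:, 1], tiny_epochs.data[:, i3])

    def test_unknown_channel_named(self, tiny_epochs):
        with pytest.raises(ValueError, match="Cpzq"):
            select_channels(tiny_epochs, ["C3", "Cpzq"])


class TestPipeline:
    def test_pipeline_matches_manual_composition(self, tiny_subject):
        rec, _, _ = tiny_subject
        cfg = PipelineConfig()
        via_pipeline = preprocess_pipeline(rec, cfg)
        manual = wpd_reconstruct(
            extract_epochs(remove_eog(bandpass(rec, cfg.filter_spec)), cfg.epoch_window),
            cfg.wpd,
        )
        assert via_pipeline == manual

    def test_zero_signal_gives_zero_epochs(self):
        from clrnet.simulate import IV2A_CHANNELS

        n = 25 * 250 * 8
        rec = RawRecording(
            np.zeros((25, 2500)), list(IV2A_CHANNELS), 250.0, events=[(100, 0)]
        )
        out = preprocess_pipeline(rec)
        assert np.allclose(out.data, 0.0)

    def test_stage_name_attached_to_errors(self):
        rec = RawRecording(np.zeros((2, 1000)), ["C3", "C4"], 250.0)
        with pytest.raises(ValueError, match=r"\[remove_eog\]"):
            preprocess_pipeline(rec)

    def test_trial_order_and_labels_preserved(self, tiny_subject):
        rec, gt, _ = tiny_subject
        out = preprocess_pipeline(rec)
        assert np.array_equal(out.labels, gt["labels"])
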