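"""Hypnogram files, stage remapping, preparation rules, containers, EDF."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sleepmt as smt
from sleepmt.dataio import (
    RK_VOCAB,
    convert_epoch_length_20_to_30,
    load_recording,
    load_tfimages,
    read_edf,
    read_hypnogram,
    remap_stages,
    save_recording,
    save_tfimages,
    trim_to_inbed,
    write_hypnogram,
)
from sleepmt.stages import AASM5, StageSequence


class TestHypnogramIO:
    def test_read_three_rows(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("epoch_index,stage\n0,W\n1,N2\n2,REM\n")
        seq = read_hypnogram(p)
        assert seq.labels == ("W", "N2", "REM")

    @given(
        codes=st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=40)
    )
    def test_round_trip_identity(self, codes, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("hyp")
        seq = StageSequence.from_codes(codes)
        for name in ("h.csv", "h.tsv"):
            write_hypnogram(seq, tmp / name)
            assert read_hypnogram(tmp / name).labels == seq.labels

    def test_non_monotonic_index_rejected(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("epoch_index,stage\n0,W\n2,N2\n1,REM\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            read_hypnogram(p)

    def test_unknown_stage_lists_valid_tokens(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("epoch_index,stage\n0,W\n1,S7\n")
        with pytest.raises(KeyError, match="N3"):
            read_hypnogram(p)


class TestRemapStages:
    def test_rk_merge_and_exclusion(self):
        seq = StageSequence(("W", "N4", "MOVEMENT", "REM"), vocab=RK_VOCAB)
        out, kept = remap_stages(seq, "rk_to_5class")
        assert out.labels == ("W", "N3", "REM")
        np.testing.assert_array_equal(kept, [0, 1, 3])
        assert out.vocab.labels == AASM5.labels

    def test_aasm_passthrough_identity(self):
        seq = StageSequence(("W", "N1", "N2", "N3", "REM"))
        out, kept = remap_stages(seq, "aasm_passthrough")
        assert out.labels == seq.labels
        np.testing.assert_array_equal(kept, np.arange(5))

    def test_all_movement_gives_empty_with_warning(self):
        seq = StageSequence(("MOVEMENT", "UNKNOWN"), vocab=RK_VOCAB)
        with pytest.warns(UserWarning, match="empty"):
            out, kept = remap_stages(seq, "rk_to_5class")
        assert len(out) == 0 and kept.size == 0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            remap_stages(StageSequence(("W",)), "weird")


class TestTrimToInbed:
    def test_full_range_is_identity(self, small_recording):
        out = trim_to_inbed(small_recording, 0, len(small_recording))
        assert out.stages == small_recording.stages

    def test_window_keeps_expected_count(self, small_recording):
        out = trim_to_inbed(small_recording, 2, 5)
        assert len(out) == 3
        assert out.stages.labels == small_recording.stages.labels[2:5]

    def test_alignment_for_random_bounds(self, small_recording):
        rng = np.random.default_rng(0)
        for _ in range(10):
            off = int(rng.integers(0, len(small_recording) - 1))
            on = int(rng.integers(off + 1, len(small_recording) + 1))
            out = trim_to_inbed(small_recording, off, on)
            assert len(out.epochs) == len(out.stages) == on - off

    def test_inverted_bounds_rejected(self, small_recording):
        with pytest.raises(ValueError):
            trim_to_inbed(small_recording, 5, 2)


class TestEpochConversion:
    def test_20s_epoch_becomes_3000_samples(self):
        fs = 100.0
        labels = StageSequence(("W", "N1", "N2", "N3", "REM"))
        signal = np.arange(5 * 2000, dtype=float)[None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epochs, seq = convert_epoch_length_20_to_30(signal, labels, fs)
        assert all(ep.samples.shape[1] == 3000 for ep in epochs)

    def test_interior_epochs_preserved_boundaries_dropped(self):
        labels = StageSequence.from_codes([0, 1, 2, 3, 4])
        signal = np.zeros((1, 5 * 2000))
        with pytest.warns(UserWarning, match="margin"):
            epochs, seq = convert_epoch_length_20_to_30(signal, labels, 100.0)
        assert len(epochs) == 3
        assert seq.labels == labels.labels[1:4]

    def test_central_samples_equal_original_epoch(self):
        labels = StageSequence.from_codes([0, 1, 2])
        signal = np.arange(3 * 2000, dtype=float)[None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epochs, _ = convert_epoch_length_20_to_30(signal, labels, 100.0)
        # only the middle epoch survives; its central 2000 samples are epoch 1
        np.testing.assert_array_equal(
            epochs[0].samples[0, 500:2500], signal[0, 2000:4000]
        )


class TestContainers:
    def test_recording_round_trip(self, small_recording, tmp_path):
        save_recording(small_recording, tmp_path, name="rec")
        back = load_recording(tmp_path, name="rec")
        assert back.stages == small_recording.stages
        np.testing.assert_array_equal(
            back.signal_matrix(), small_recording.signal_matrix()
        )
        assert back.channels == small_recording.channels

    def test_tfimage_round_trip(self, small_recording, tmp_path):
        values = smt.featurize_recording(small_recording)
        save_tfimages(values, small_recording.stages, tmp_path, name="tf")
        back_vals, back_stages = load_tfimages(tmp_path, name="tf")
        np.testing.assert_array_equal(back_vals, values)
        assert back_stages.labels == small_recording.stages.labels

    def test_truncated_container_rejected(self, small_recording, tmp_path):
        save_recording(small_recording, tmp_path, name="rec")
        # truncate the signal array behind the manifest's back
        with np.load(tmp_path / "rec.npz") as data:
            signals = data["signals"]
        np.savez(tmp_path / "rec.npz", signals=signals[:-2])
        with pytest.raises(ValueError, match="truncated"):
            load_recording(tmp_path, name="rec")


def write_minimal_edf(path, data: np.ndarray, fs: int, labels) -> None:
    """Write a minimal single-record EDF file (synthetic test fixture)."""
    n_ch, n_samp = data.shape
    dur = n_samp / fs
    header = bytearray()
    header += b"0".ljust(8)
    header += b"synthetic patient".ljust(80)[:80]
    header += b"synthetic recording".ljust(80)[:80]
    header += b"01.01.20".ljust(8)
    header += b"00.00.00".ljust(8)
    header += str(256 + 256 * n_ch).encode().ljust(8)
    header += b" ".ljust(44)
    header += b"1".ljust(8)  # one data record
    header += f"{dur:g}".encode().ljust(8)
    header += str(n_ch).encode().ljust(4)
    for lab in labels:
        header += lab.encode().ljust(16)[:16]
    for _ in labels:
        header += b"synthetic".ljust(80)
    for _ in labels:
        header += b"uV".ljust(8)
    for _ in labels:
        header += b"-1000".ljust(8)  # physical min
    for _ in labels:
        header += b"1000".ljust(8)  # physical max
    for _ in labels:
        header += b"-32768".ljust(8)
    for _ in labels:
        header += b"32767".ljust(8)
    for _ in labels:
        header += b" ".ljust(80)  # prefiltering
    for _ in labels:
        header += str(n_samp).encode().ljust(8)
    for _ in labels:
        header += b" ".ljust(32)
    scaled = np.clip(data / 1000.0 * 32767, -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(bytes(header))
        f.write(scaled.tobytes())


@pytest.fixture(scope="module")
def edf_file(tmp_path_factory):
    pytest.importorskip("mne")
    tmp = tmp_path_factory.mktemp("edf")
    fs = 256
    t = np.arange(60 * fs) / fs
    data = np.stack(
        [np.sin(2 * np.pi * 5.0 * t) * 100, np.cos(2 * np.pi * 2.0 * t) * 50]
    )
    path = tmp / "synthetic.edf"
    write_minimal_edf(path, data, fs, ["EEG Fpz-Cz", "EOG horizontal"])
    return path


class TestReadEDF:
    def test_resampled_length(self, edf_file):
        data, fs = read_edf(edf_file, ["EEG Fpz-Cz", "EOG horizontal"])
        assert fs == 100.0
        assert data.shape == (2, 6000)

    def test_missing_channel_lists_available(self, edf_file):
        with pytest.raises(KeyError, match="EEG Fpz-Cz"):
            read_edf(edf_file, ["EMG chin"])

    def test_tone_survives_resampling(self, edf_file):
        from scipy.signal import welch

        data, fs = read_edf(edf_file, ["EEG Fpz-Cz"])
        f, psd = welch(data[0], fs=fs, nperseg=1024)
        assert abs(f[int(np.argmax(psd))] - 5.0) < 0.2
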