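"""Referencing, band-limiting and segmentation contracts."""

import numpy as np
import pytest

from eegad.filters import (
    attenuation_db,
    band_taps,
    design_highpass,
    design_lowpass,
    design_notch,
)
from eegad.montage import CHANNELS_1020
from eegad.preprocess import (
    Recording,
    apply_bandlimit,
    common_average_reference,
    read_recording_csv,
    segment,
    write_recording_csv,
)

FS = 200.0


def make_recording(data, fs=FS, mask=(), meta=None):
    labels = CHANNELS_1020[: data.shape[0]]
    return Recording(data=data, fs=fs, labels=labels,
                     artifact_mask=list(mask), meta=meta or {})


# ---------------------------------------------------------------------------
# common average reference


def test_car_removes_constant_offset():
    rec = make_recording(np.full((19, 400), 7.5))
    out = common_average_reference(rec)
    assert np.allclose(out.data, 0.0)


def test_car_column_means_are_zero(rng):
    rec = make_recording(rng.normal(size=(19, 500)))
    out = common_average_reference(rec)
    assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)


def test_car_single_channel_signal_algebra(rng):
    """A signal on one channel keeps 18/19 of it; others get -1/19."""
    s = rng.normal(size=300)
    data = np.zeros((19, 300))
    data[4] = s
    out = common_average_reference(make_recording(data))
    assert np.allclose(out.data[4], s * 18 / 19)
    assert np.allclose(out.data[0], -s / 19)


def test_car_is_idempotent(rng):
    rec = make_recording(rng.normal(size=(19, 400)))
    once = common_average_reference(rec)
    twice = common_average_reference(once)
    assert np.allclose(once.data, twice.data, rtol=1e-9, atol=1e-12)


def test_car_rejects_single_channel():
    rec = Recording(data=np.zeros((1, 100)), fs=FS, labels=("Cz",))
    with pytest.raises(ValueError):
        common_average_reference(rec)


# ---------------------------------------------------------------------------
# band limiting


def tone(freq, fs=FS, seconds=20.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(x ** 2))


def test_notch_attenuates_50hz_tone_by_30db():
    rec = make_recording(np.tile(tone(50.0), (19, 1)))
    out = apply_bandlimit(rec)
    mid = slice(1000, 3000)  # avoid edges
    att = 20 * np.log10(rms(out.data[0, mid]) / rms(rec.data[0, mid]))
    assert att <= -30
    assert attenuation_db(None, 50.0, FS, sos=design_notch(FS)) <= -30


def test_slow_drift_attenuated_by_30db():
    assert attenuation_db(design_highpass(FS), 0.1, FS) <= -30


def test_10hz_tone_preserved_within_half_db():
    rec = make_recording(np.tile(tone(10.0), (19, 1)))
    out = apply_bandlimit(rec)
    mid = slice(1000, 3000)
    att = 20 * np.log10(rms(out.data[0, mid]) / rms(rec.data[0, mid]))
    assert abs(att) <= 0.5


def test_lowpass_design_attenuates_stopband():
    assert attenuation_db(design_lowpass(FS), 70.0, FS) <= -30


def test_band_filter_passes_own_band_rejects_others():
    alpha = band_taps(FS, "alpha")
    delta = band_taps(FS, "delta")
    assert abs(attenuation_db(alpha, 10.0, FS)) <= 0.5
    assert attenuation_db(delta, 10.0, FS) <= -30


def test_bandlimit_is_linear(rng):
    x = make_recording(rng.normal(size=(19, 2000)))
    y = make_recording(rng.normal(size=(19, 2000)))
    a, b = 2.5, -1.25
    combo = make_recording(a * x.data + b * y.data)
    lhs = apply_bandlimit(combo).data
    rhs = a * apply_bandlimit(x).data + b * apply_bandlimit(y).data
    assert np.allclose(lhs, rhs, atol=1e-8)


def test_bandlimit_preserves_length(rng):
    rec = make_recording(rng.normal(size=(19, 1777)))
    assert apply_bandlimit(rec).data.shape == (19, 1777)


def test_bandlimit_rejects_low_fs():
    rec = Recording(data=np.zeros((19, 1000)), fs=100.0, labels=CHANNELS_1020)
    with pytest.raises(ValueError):
        apply_bandlimit(rec)


# ---------------------------------------------------------------------------
# segmentation


def test_segment_counts_without_mask(rng):
    rec = make_recording(rng.normal(size=(19, int(63 * FS))))
    assert len(segment(rec, 12)) == 5
    rec = make_recording(rng.normal(size=(19, int(60 * FS))))
    assert len(segment(rec, 5)) == 12


def test_segment_drops_epochs_overlapping_artifacts(rng):
    rec = make_recording(rng.normal(size=(19, int(60 * FS))),
                         mask=[(12.0, 13.0)])
    epochs = segment(rec, 10)
    assert len(epochs) == 5
    assert [e.t0 for e in epochs] == [0.0, 20.0, 30.0, 40.0, 50.0]


def test_segment_shorter_than_window_is_empty(rng):
    rec = make_recording(rng.normal(size=(19, int(4 * FS))))
    assert segment(rec, 5) == []


def test_segment_conserves_samples(rng):
    """Epoch samples + artifact-dropped + tail = recording samples."""
    n = int(47.3 * FS)
    rec = make_recording(rng.normal(size=(19, n)), mask=[(7.5, 8.5)])
    win = 5
    epochs = segment(rec, win)
    n_win = int(win * FS)
    n_candidates = n // n_win
    dropped = n_candidates - len(epochs)
    tail = n - n_candidates * n_win
    assert len(epochs) * n_win + dropped * n_win + tail == n


def test_segment_epochs_are_disjoint_and_ordered(rng):
    rec = make_recording(rng.normal(size=(19, int(36 * FS))))
    epochs = segment(rec, 6)
    starts = [e.t0 for e in epochs]
    assert starts == sorted(starts)
    assert all(b - a >= 6 for a, b in zip(starts, starts[1:]))


def test_segment_carries_subject_metadata(rng):
    rec = make_recording(rng.normal(size=(19, int(10 * FS))),
                         meta={"subject_id": "S001", "group": "mild"})
    (ep,) = segment(rec, 10)
    assert ep.subject_id == "S001" and ep.group == "mild"


# ---------------------------------------------------------------------------
# containers and I/O


def test_recording_validation():
    with pytest.raises(ValueError):
        Recording(data=np.zeros((2, 10)), fs=FS, labels=("a", "a"))
    with pytest.raises(ValueError):
        Recording(data=np.full((2, 10), np.nan), fs=FS, labels=("a", "b"))
    with pytest.raises(ValueError):
        Recording(data=np.zeros((2, 10)), fs=FS, labels=("a", "b"),
                  artifact_mask=[(5.0, 99.0)])


def test_csv_round_trip(tmp_path, rng):
    rec = make_recording(rng.normal(size=(19, 250)),
                         meta={"subject_id": "S9"})
    path = tmp_path / "rec.csv"
    write_recording_csv(rec, path)
    back = read_recording_csv(path, meta={"subject_id": "S9"})
    assert back.fs == rec.fs
    assert back.labels == rec.labels
    assert np.allclose(back.data, rec.data, atol=1e-4)
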