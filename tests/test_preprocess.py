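"""Filtering, referencing, epoching, two-level normalization and
minority-class augmentation."""

import numpy as np
import pytest

from mcieeg import preprocess as pp


def make_rec(data, fs=256.0, names=None, sid="s0", label="HC"):
    data = np.asarray(data, dtype=float)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return pp.Recording(data=data, fs=fs, channel_names=names,
                        subject_id=sid, label=label)


def sinusoid(freq, fs, seconds, n_ch=1):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


# ---------------------------------------------------------------------------
# band-pass + resample


def test_stopband_sinusoid_strongly_attenuated():
    rec = make_rec(sinusoid(50.0, 256.0, 10.0))
    out = pp.bandpass_resample(rec, 0.5, 40.0, 100.0)
    rms_in = np.sqrt(np.mean(rec.data**2))
    rms_out = np.sqrt(np.mean(out.data**2))
    assert rms_out < 0.05 * rms_in
    # spectral check on the output: no residual 50 Hz is representable at
    # 100 Hz anyway, so verify total out-of-band energy is tiny
    spec = np.abs(np.fft.rfft(out.data[0]))
    assert spec.max() < 0.05 * len(out.data[0])


def test_passband_sinusoid_preserved_and_resampled_length():
    rec = make_rec(sinusoid(10.0, 256.0, 10.0))
    out = pp.bandpass_resample(rec, 0.5, 40.0, 100.0)
    assert out.fs == 100.0
    assert out.data.shape[1] == round(rec.data.shape[1] * 100 / 256)
    freqs = np.fft.rfftfreq(out.data.shape[1], 1 / 100.0)
    spec = np.abs(np.fft.rfft(out.data[0]))
    assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.2)
    # amplitude preserved within transition-band ripple
    assert np.abs(out.data[0, 200:-200]).max() == pytest.approx(1.0, abs=0.05)


def test_constant_signal_removed_by_highpass():
    rec = make_rec(np.full((2, 2560), 7.0))
    out = pp.bandpass_resample(rec, 0.5, 40.0, 100.0)
    assert np.abs(out.data).max() < 0.05


def test_aliasing_band_rejected():
    rec = make_rec(sinusoid(10.0, 256.0, 4.0))
    with pytest.raises(ValueError):
        pp.bandpass_resample(rec, 0.5, 60.0, 100.0)


# ---------------------------------------------------------------------------
# referencing and channel handling


def test_average_reference_zero_mean(rng):
    rec = make_rec(rng.standard_normal((20, 1000)))
    out = pp.rereference_average(rec)
    assert np.abs(out.data.mean(axis=0)).max() < 1e-10


def test_average_reference_antisymmetric_pair_unchanged(rng):
    x = rng.standard_normal(500)
    rec = make_rec(np.vstack([x, -x]))
    out = pp.rereference_average(rec)
    np.testing.assert_allclose(out.data, rec.data, atol=1e-12)


def test_average_reference_constant_rows():
    rec = make_rec(np.array([[1.0], [2.0], [3.0]]) * np.ones((3, 10)))
    out = pp.rereference_average(rec)
    np.testing.assert_allclose(out.data[:, 0], [-1.0, 0.0, 1.0])


def test_single_channel_reference_error():
    with pytest.raises(ValueError):
        pp.rereference_average(make_rec(np.ones((1, 100))))


def test_drop_poz_leaves_19(rng):
    from mcieeg.simulate import MONTAGE_20

    rec = make_rec(rng.standard_normal((20, 100)), names=list(MONTAGE_20))
    out = pp.drop_channels(rec, ["POz"])
    assert len(out.channel_names) == 19
    assert "POz" not in out.channel_names
    # order preserved
    assert out.channel_names == [c for c in MONTAGE_20 if c != "POz"]


def test_drop_nothing_is_identity(rng):
    rec = make_rec(rng.standard_normal((4, 50)))
    out = pp.drop_channels(rec, [])
    np.testing.assert_array_equal(out.data, rec.data)


def test_drop_unknown_label_errors(rng):
    rec = make_rec(rng.standard_normal((4, 50)))
    with pytest.raises(KeyError, match="Xx"):
        pp.drop_channels(rec, ["Xx"])


# ---------------------------------------------------------------------------
# epoching


def test_300s_at_100hz_yields_100_epochs(rng):
    rec = make_rec(rng.standard_normal((3, 30000)), fs=100.0)
    eps = pp.epoch(rec, 3.0)
    assert eps.epochs.shape == (100, 3, 300)
    assert set(eps.subject_ids) == {"s0"}


def test_single_epoch_shape(rng):
    rec = make_rec(rng.standard_normal((19, 300)), fs=100.0)
    eps = pp.epoch(rec, 3.0)
    assert eps.epochs.shape == (1, 19, 300)


def test_short_recording_zero_epochs_warns(rng):
    rec = make_rec(rng.standard_normal((2, 290)), fs=100.0)
    with pytest.warns(UserWarning):
        eps = pp.epoch(rec, 3.0)
    assert len(eps) == 0


def test_trailing_remainder_discarded(rng):
    rec = make_rec(rng.standard_normal((2, 750)), fs=100.0)
    eps = pp.epoch(rec, 3.0)
    assert eps.epochs.shape[0] == 2


# ---------------------------------------------------------------------------
# normalization


def epochs_for(subjects, n_ep=4, n_ch=3, n_s=100, gain=None, seed=0):
    rng = np.random.default_rng(seed)
    sets = []
    for k, sid in enumerate(subjects):
        data = rng.standard_normal((n_ch, n_ep * n_s))
        if gain is not None:
            data = data * gain[k]
        sets.append(pp.epoch(make_rec(data, fs=100.0, sid=sid), n_s / 100.0))
    return pp.concat_epochsets(sets)


def test_stage1_pooled_stats_zero_mean_unit_sd():
    eps = epochs_for(["a"])
    out = pp.normalize_two_level(eps)
    pooled = out.epochs.transpose(1, 0, 2).reshape(3, -1)
    np.testing.assert_allclose(pooled.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(pooled.std(axis=1), 1.0, atol=1e-6)


def test_gain_invariance_between_subjects():
    base = epochs_for(["a"], seed=3)
    scaled = pp.EpochSet(
        epochs=base.epochs * 10.0, fs=base.fs,
        channel_names=base.channel_names,
        subject_ids=np.array(["b"] * len(base)),
        labels=base.labels.copy(),
    )
    both = pp.concat_epochsets([base, scaled])
    out = pp.normalize_two_level(both)
    a = out.epochs[out.subject_ids == "a"]
    b = out.epochs[out.subject_ids == "b"]
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_stage1_idempotent():
    eps = epochs_for(["a", "b"], seed=5)
    once = pp.normalize_two_level(eps)
    twice = pp.normalize_two_level(once)
    np.testing.assert_allclose(twice.epochs, once.epochs, atol=1e-9)


def test_constant_channel_zeroed_and_flagged():
    eps = epochs_for(["a"], seed=6)
    eps.epochs[:, 1, :] = 4.2
    out = pp.normalize_two_level(eps)
    assert np.all(out.epochs[:, 1, :] == 0.0)
    assert any("zero_variance" in f for f in out.flags)


# ---------------------------------------------------------------------------
# augmentation


def imbalanced_epochs(n_hc=10, n_mci=4, seed=0):
    sets = []
    for i in range(n_hc):
        sets.append(pp.epoch(make_rec(
            np.random.default_rng(seed + i).standard_normal((3, 300)),
            fs=100.0, sid=f"hc{i}", label="HC"), 3.0))
    for i in range(n_mci):
        sets.append(pp.epoch(make_rec(
            np.random.default_rng(seed + 100 + i).standard_normal((3, 300)),
            fs=100.0, sid=f"mci{i}", label="MCI"), 3.0))
    return pp.concat_epochsets(sets)


def test_augmentation_balances_classes():
    eps = imbalanced_epochs()
    out = pp.augment_minority(eps, seed=1)
    _, counts = np.unique(out.labels, return_counts=True)
    assert abs(int(counts[0]) - int(counts[1])) <= 1


def test_augmentation_preserves_subject_ids():
    eps = imbalanced_epochs()
    out = pp.augment_minority(eps, seed=1)
    assert set(out.subject_ids) == set(eps.subject_ids)  # no new subjects
    aug = out.is_augmented
    assert aug.sum() == len(out) - len(eps)
    assert all(s.startswith("mci") for s in out.subject_ids[aug])


def test_augmentation_deterministic():
    eps = imbalanced_epochs()
    a = pp.augment_minority(eps, seed=7)
    b = pp.augment_minority(eps, seed=7)
    np.testing.assert_array_equal(a.epochs, b.epochs)


def test_balanced_input_unchanged():
    eps = imbalanced_epochs(n_hc=4, n_mci=4)
    out = pp.augment_minority(eps, seed=1)
    assert len(out) == len(eps)


def test_single_class_errors():
    eps = imbalanced_epochs(n_hc=4, n_mci=1)
    eps = pp.EpochSet(
        epochs=eps.epochs[eps.labels == "HC"], fs=eps.fs,
        channel_names=eps.channel_names,
        subject_ids=eps.subject_ids[eps.labels == "HC"],
        labels=eps.labels[eps.labels == "HC"],
    )
    with pytest.raises(ValueError):
        pp.augment_minority(eps, seed=0)


# ---------------------------------------------------------------------------
# pipeline composition


def test_pipeline_shape_contract(tiny_cohort):
    _, recs = tiny_cohort
    one = [recs[0]]
    eps = pp.preprocess_recordings(one)
    # 6 epochs x 3 s at 256 Hz in -> same epoch count at 100 Hz out
    assert eps.epochs.shape == (6, 19, 300)
    assert "POz" not in eps.channel_names


def test_amplitude_rejection():
    eps = imbalanced_epochs(n_hc=3, n_mci=3)
    eps.epochs[2] *= 100.0
    out = pp.reject_epochs_by_amplitude(eps, threshold_uv=50.0)
    assert len(out) == len(eps) - 1
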