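from __future__ import annotations

import struct

import numpy as np
import pandas as pd
import pytest
from scipy.signal import welch

from lattice123.data import (
    BANDS,
    EpochCollection,
    SynthConfig,
    generate_synthetic,
    read_recording,
)


def _band_power(x, rate, band):
    f, p = welch(x, fs=rate, nperseg=min(1024, x.size))
    lo, hi = BANDS[band]
    mask = (f >= lo) & (f < hi)
    return np.trapezoid(p[mask], f[mask])


def write_minimal_edf(path, data, rate):
    """Hand-rolled EDF writer: dimensionless integer signals, 1-s records.

    data: (n_channels, n_samples) of integers within int16 range; n_samples
    must be a multiple of rate so each record holds exactly `rate` samples.
    """
    data = np.asarray(data)
    ns, n_samples = data.shape
    assert n_samples % rate == 0
    n_records = n_samples // rate

    def pad(value, width):
        s = str(value)
        assert len(s) <= width
        return s.ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (ns + 1), 8),
            pad("", 44),
            pad(n_records, 8),
            pad(1, 8),  # record duration in seconds
            pad(ns, 4),
        ]
    )
    labels = [f"sig{i}" for i in range(ns)]
    sig_hdr = b"".join(
        [
            b"".join(pad(lb, 16) for lb in labels),
            b"".join(pad("", 80) for _ in labels),  # transducer
            b"".join(pad("", 8) for _ in labels),  # physical dimension (none)
            b"".join(pad(-32768, 8) for _ in labels),  # physical min
            b"".join(pad(32767, 8) for _ in labels),  # physical max
            b"".join(pad(-32768, 8) for _ in labels),  # digital min
            b"".join(pad(32767, 8) for _ in labels),  # digital max
            b"".join(pad("", 80) for _ in labels),  # prefiltering
            b"".join(pad(rate, 8) for _ in labels),  # samples per record
            b"".join(pad("", 32) for _ in labels),  # reserved
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_records):
            block = data[:, r * rate : (r + 1) * rate].astype("<i2")
            fh.write(struct.pack(f"<{ns * rate}h", *block.reshape(-1).tolist()))


def test_generate_synthetic_shapes_and_determinism():
    cfg = SynthConfig(
        n_channels=2, n_epochs_healthy=4, n_epochs_ad=2, n_samples=500, seed=5
    )
    a = generate_synthetic(cfg)
    b = generate_synthetic(cfg)
    np.testing.assert_array_equal(a.epochs, b.epochs)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.epochs.shape == (6, 2, 500)
    assert sorted(np.unique(a.labels, return_counts=True)[1].tolist()) == [2, 4]
    assert a.sampling_rate == 250.0
    c = generate_synthetic(
        SynthConfig(
            n_channels=2, n_epochs_healthy=4, n_epochs_ad=2, n_samples=500, seed=6
        )
    )
    assert not np.array_equal(a.epochs, c.epochs)


def test_synthetic_class_spectral_profiles():
    cfg = SynthConfig(n_channels=1, n_epochs_healthy=6, n_epochs_ad=6, seed=0)
    coll = generate_synthetic(cfg)
    healthy = coll.epochs[coll.labels == "healthy", 0, :]
    ad = coll.epochs[coll.labels == "AD", 0, :]
    h_alpha = np.mean([_band_power(x, 250.0, "alpha") for x in healthy])
    a_alpha = np.mean([_band_power(x, 250.0, "alpha") for x in ad])
    h_theta = np.mean([_band_power(x, 250.0, "theta") for x in healthy])
    a_theta = np.mean([_band_power(x, 250.0, "theta") for x in ad])
    assert h_alpha > 2 * a_alpha  # healthy keeps alpha
    assert a_theta > 2 * h_theta  # AD slows toward theta


def test_synth_config_validation():
    with pytest.raises(ValueError):
        SynthConfig(n_channels=0)
    with pytest.raises(ValueError):
        SynthConfig(noise_floor=-1.0)
    with pytest.raises(ValueError):
        SynthConfig(healthy_powers={"alpha": -2.0})


def test_collection_accessors_and_validation():
    coll = EpochCollection(epochs=np.zeros((2, 3, 10)), labels=np.array(["a", "b"]))
    assert coll.n_epochs == 2 and coll.n_channels == 3 and coll.n_samples == 10
    assert coll.channel(1).shape == (2, 10)
    assert coll.channel_names == ("ch01", "ch02", "ch03")
    with pytest.raises(ValueError, match="labels must align"):
        EpochCollection(epochs=np.zeros((2, 3, 10)), labels=np.array(["a"]))
    with pytest.raises(ValueError, match="n_epochs"):
        EpochCollection(epochs=np.zeros((2, 10)), labels=np.array(["a", "b"]))


def test_read_csv_recording(tmp_path):
    rng = np.random.default_rng(0)
    data = rng.integers(-100, 100, size=(3, 450)).astype(float)
    rec = tmp_path / "rec.csv"
    pd.DataFrame(data).to_csv(rec, header=False, index=False)
    labels = tmp_path / "labels.csv"
    pd.DataFrame({"epoch": [0, 1, 2, 3], "label": ["h", "h", "d", "d"]}).to_csv(
        labels, index=False
    )
    coll = read_recording(rec, epoch_length=100, labels_path=labels)
    assert coll.epochs.shape == (4, 3, 100)  # remainder of 50 samples dropped
    assert coll.labels.tolist() == ["h", "h", "d", "d"]
    np.testing.assert_allclose(coll.epochs[1, 2], data[2, 100:200])


def test_read_csv_with_channel_names(tmp_path):
    data = np.arange(2 * 200).reshape(2, 200).astype(float)
    rec = tmp_path / "named.csv"
    with open(rec, "w") as fh:
        for i, row in enumerate(data):
            fh.write(f"Fp{i + 1}," + ",".join(str(v) for v in row) + "\n")
    labels = tmp_path / "labels.csv"
    pd.DataFrame({"label": ["x"]}).to_csv(labels, index=False)
    coll = read_recording(rec, epoch_length=100, labels_path=labels)
    assert coll.channel_names == ("Fp1", "Fp2")
    assert coll.labels.tolist() == ["x", "x"]  # recording label broadcast


def test_read_recording_requires_labels(tmp_path):
    rec = tmp_path / "rec.csv"
    pd.DataFrame(np.zeros((2, 100))).to_csv(rec, header=False, index=False)
    with pytest.raises(ValueError, match="labels file"):
        read_recording(rec, epoch_length=50)


def test_read_recording_empty_warns(tmp_path):
    rec = tmp_path / "short.csv"
    pd.DataFrame(np.zeros((2, 30))).to_csv(rec, header=False, index=False)
    with pytest.warns(UserWarning, match="shorter than one epoch"):
        coll = read_recording(rec, epoch_length=100)
    assert coll.n_epochs == 0


def test_read_recording_unknown_format(tmp_path):
    rec = tmp_path / "rec.csv"
    pd.DataFrame(np.zeros((2, 100))).to_csv(rec, header=False, index=False)
    with pytest.raises(ValueError, match="unknown format"):
        read_recording(rec, format="fif")


def test_edf_and_csv_ingestion_agree(tmp_path):
    pytest.importorskip("mne")
    rng = np.random.default_rng(3)
    rate = 100
    data = rng.integers(-2000, 2000, size=(2, 4 * rate))
    edf = tmp_path / "rec.edf"
    write_minimal_edf(edf, data, rate)
    csv = tmp_path / "rec.csv"
    pd.DataFrame(data.astype(float)).to_csv(csv, header=False, index=False)
    labels = tmp_path / "labels.csv"
    pd.DataFrame({"epoch": range(4), "label": ["h", "d", "h", "d"]}).to_csv(
        labels, index=False
    )
    from_edf = read_recording(edf, epoch_length=rate, labels_path=labels)
    from_csv = read_recording(
        csv, epoch_length=rate, labels_path=labels, sampling_rate=rate
    )
    assert from_edf.sampling_rate == rate
    np.testing.assert_allclose(from_edf.epochs, from_csv.epochs)
    np.testing.assert_array_equal(from_edf.labels, from_csv.labels)
    with pytest.raises(ValueError, match="Hz"):
        read_recording(edf, epoch_length=rate, labels_path=labels, sampling_rate=250)
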