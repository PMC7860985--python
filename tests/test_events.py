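import struct

import numpy as np
import pandas as pd
import pytest

from cytofp.errors import (
    ChannelMismatchError,
    EmptyInputError,
    InsufficientEventsError,
    MissingChannelError,
)
from cytofp.events import (
    EventMatrix,
    ExperimentSet,
    concatenate_training,
    read_events,
    subsample_events,
)

from conftest import make_em


class TestReadEvents:
    def test_csv_identity_read_through(self, simple_csv):
        em = read_events(simple_csv)
        assert em.channels == ["FSC-H", "SSC-H", "FL1-H"]
        assert em.n_events == 3
        assert em.events[0, 0] == 100.0
        assert not em.transformed

    def test_csv_projection(self, simple_csv):
        em = read_events(simple_csv, channel_subset=["FL1-H"])
        assert em.n_channels == 1
        np.testing.assert_array_equal(em.events[:, 0], [300.0, 310.0, 320.0])

    def test_missing_channel_lists_available(self, simple_csv):
        with pytest.raises(MissingChannelError) as exc:
            read_events(simple_csv, channel_subset=["FL9-H"])
        assert "FL9-H" in str(exc.value)
        assert "FSC-H" in str(exc.value)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("FSC-H,SSC-H\n")
        with pytest.raises(EmptyInputError):
            read_events(str(p))

    def test_row_order_preserved(self, simple_csv):
        em = read_events(simple_csv)
        assert list(em.events[:, 0]) == [100.0, 110.0, 120.0]

    def test_csv_roundtrip_bit_exact(self, tmp_path, rng):
        em = make_em(rng.normal(size=(50, 3)) * 1234.56789)
        out = tmp_path / "rt.csv"
        em.to_csv(str(out))
        back = read_events(str(out))
        np.testing.assert_array_equal(back.events, em.events)


def _write_fcs(path, channels, data, datatype="F", little_endian=True):
    """Minimal FCS 3.0 writer used only to exercise the reader."""
    n, d = data.shape
    byteord = "1,2,3,4" if little_endian else "4,3,2,1"
    width = {"F": 32, "D": 64}[datatype]
    kv = {
        "$MODE": "L", "$DATATYPE": datatype, "$BYTEORD": byteord,
        "$PAR": str(d), "$TOT": str(n),
    }
    for i, c in enumerate(channels, start=1):
        kv[f"$P{i}N"] = c
        kv[f"$P{i}B"] = str(width)
    text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    fmt = ("<" if little_endian else ">") + ("f" if datatype == "F" else "d")
    blob = b"".join(struct.pack(fmt, v) for v in data.ravel())
    data_end = data_start + len(blob) - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}{0:8d}{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header + text.encode() + blob)


class TestFCS:
    @pytest.mark.parametrize("datatype,little", [("F", True), ("F", False), ("D", True)])
    def test_fcs_roundtrip(self, tmp_path, rng, datatype, little):
        data = rng.uniform(0, 1e4, size=(25, 3)).astype(
            np.float32 if datatype == "F" else np.float64
        )
        p = tmp_path / "t.fcs"
        _write_fcs(str(p), ["FSC-H", "SSC-H", "FL1-H"], data, datatype, little)
        em = read_events(str(p))
        assert em.channels == ["FSC-H", "SSC-H", "FL1-H"]
        np.testing.assert_allclose(em.events, data.astype(float), rtol=1e-6)

    def test_fcs_channel_subset(self, tmp_path, rng):
        data = rng.uniform(0, 100, size=(10, 2)).astype(np.float32)
        p = tmp_path / "t.fcs"
        _write_fcs(str(p), ["FSC-H", "FL1-H"], data)
        em = read_events(str(p), channel_subset=["FL1-H"])
        np.testing.assert_allclose(em.events[:, 0], data[:, 1], rtol=1e-6)


class TestSubsample:
    def test_full_sample_is_permutation(self, rng):
        em = make_em(rng.normal(size=(1000, 2)))
        sub = subsample_events(em, 1000, seed=7)
        assert sub.n_events == 1000
        orig = sorted(map(tuple, em.events))
        got = sorted(map(tuple, sub.events))
        assert orig == got

    def test_determinism(self, rng):
        em = make_em(rng.normal(size=(1000, 2)))
        a = subsample_events(em, 100, seed=3)
        b = subsample_events(em, 100, seed=3)
        np.testing.assert_array_equal(a.events, b.events)

    def test_different_seeds_differ(self, rng):
        em = make_em(rng.normal(size=(1000, 2)))
        a = subsample_events(em, 100, seed=3)
        b = subsample_events(em, 100, seed=4)
        assert not np.array_equal(a.events, b.events)

    def test_uniform_inclusion_frequency(self):
        # 500 repeated draws of 100/1000: per-row inclusion ~ Binomial(500, 0.1)
        n, k, reps = 1000, 100, 500
        em = make_em(np.arange(n, dtype=float).reshape(-1, 1))
        counts = np.zeros(n)
        for s in range(reps):
            sub = subsample_events(em, k, seed=s)
            counts[sub.events[:, 0].astype(int)] += 1
        freq = counts / reps
        assert freq.mean() == pytest.approx(0.1, abs=1e-12)
        se = np.sqrt(0.1 * 0.9 / reps)
        within = np.mean(np.abs(freq - 0.1) <= 3 * se)
        assert within >= 0.985  # ~99.7% expected under uniformity
        assert np.all(np.abs(freq - 0.1) <= 6 * se)

    def test_insufficient_strict(self, rng):
        em = make_em(rng.normal(size=(10, 2)))
        with pytest.raises(InsufficientEventsError):
            subsample_events(em, 11, seed=0)

    def test_take_all_policy(self, rng):
        em = make_em(rng.normal(size=(10, 2)))
        sub = subsample_events(em, 11, seed=0, policy="take-all")
        assert sub.n_events == 10

    def test_provenance_carried(self, rng):
        em = make_em(
            rng.normal(size=(10, 2)),
            row_provenance=np.array([f"r{i}" for i in range(10)], dtype=object),
        )
        sub = subsample_events(em, 4, seed=0)
        for row, tag in zip(sub.events, sub.row_provenance):
            i = int(tag[1:])
            np.testing.assert_array_equal(row, em.events[i])


class TestConcatenateTraining:
    def test_n_cells_formula_three_samples(self, rng):
        members = [
            make_em(rng.normal(size=(80, 2)), sample_id=f"s{i}") for i in range(3)
        ]
        out = concatenate_training(ExperimentSet(members), n_cells_min=50, seed=0)
        assert out.n_events == 3 * 1 * 50

    def test_n_cells_formula_replicates(self, rng):
        members = [
            make_em(rng.normal(size=(30, 2)), sample_id="s0", replicate_id=str(r))
            for r in range(2)
        ]
        out = concatenate_training(ExperimentSet(members), n_cells_min=10, seed=0)
        assert out.n_events == 1 * 2 * 10

    def test_channel_mismatch(self, rng):
        a = make_em(rng.normal(size=(10, 2)), channels=["FL1-H", "FSC-H"])
        b = make_em(rng.normal(size=(10, 1)), channels=["FL1-H"], sample_id="s2")
        with pytest.raises(ChannelMismatchError):
            concatenate_training(ExperimentSet([a, b]), n_cells_min=5, seed=0)

    def test_provenance_records_samples(self, rng):
        members = [
            make_em(rng.normal(size=(20, 2)), sample_id=f"s{i}") for i in range(2)
        ]
        out = concatenate_training(ExperimentSet(members), n_cells_min=10, seed=0)
        assert list(out.row_provenance) == ["s0"] * 10 + ["s1"] * 10


class TestExperimentSet:
    def test_from_manifest(self, tmp_path, rng):
        for i in range(2):
            for r in range(2):
                make_em(rng.uniform(0, 100, size=(30, 2)),
                        channels=["FSC-H", "FL1-H"]).to_csv(
                    str(tmp_path / f"s{i}_r{r}.csv")
                )
        manifest = tmp_path / "manifest.csv"
        rows = ["path,sample_id,replicate_id"]
        for i in range(2):
            for r in range(2):
                rows.append(f"s{i}_r{r}.csv,s{i},{r}")
        manifest.write_text("\n".join(rows) + "\n")
        exp = ExperimentSet.from_manifest(str(manifest))
        assert exp.sample_ids == ["s0", "s1"]
        assert exp.n_replicates("s0") == 2

    def test_manifest_missing_columns(self, tmp_path):
        manifest = tmp_path / "m.csv"
        manifest.write_text("path\nfoo.csv\n")
        with pytest.raises(ValueError, match="manifest"):
            ExperimentSet.from_manifest(str(manifest))
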