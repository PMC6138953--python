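"""Time-series I/O, windowing, and cross-session similarity."""

import itertools

import numpy as np
import pytest

from dynspdcm.data import (
    ConnectivityMatrix,
    RegionalTimeSeries,
    WindowingScheme,
    cross_session_similarity,
    load_timeseries,
    segment_windows,
)
from dynspdcm.errors import (
    DuplicateRegionError,
    EmptyTimeSeriesError,
    MissingFileError,
    NonNumericCellError,
    RaggedRowsError,
    WindowExceedsSeriesError,
)

from conftest import write_tsv


class TestLoadTimeseries:
    def test_shape_passthrough(self, tmp_path):
        rows = [[float(i + j) for j in range(4)] for i in range(30)]
        p = write_tsv(tmp_path / "ts.tsv", ["r1", "r2", "r3", "r4"], rows)
        ts = load_timeseries(p, tr=0.72)
        assert ts.data.shape == (30, 4)
        assert ts.region_names == ["r1", "r2", "r3", "r4"]
        assert ts.tr == 0.72

    def test_header_only_is_empty(self, tmp_path):
        p = write_tsv(tmp_path / "ts.tsv", ["a", "b"], [])
        with pytest.raises(EmptyTimeSeriesError):
            load_timeseries(p, tr=1.0)

    def test_duplicate_region(self, tmp_path):
        p = write_tsv(tmp_path / "ts.tsv", ["a", "a"], [[1.0, 2.0]])
        with pytest.raises(DuplicateRegionError):
            load_timeseries(p, tr=1.0)

    def test_ragged_rows(self, tmp_path):
        p = tmp_path / "ts.tsv"
        p.write_text("a\tb\n1\t2\n3\n")
        with pytest.raises(RaggedRowsError):
            load_timeseries(p, tr=1.0)

    def test_non_numeric_cell(self, tmp_path):
        p = write_tsv(tmp_path / "ts.tsv", ["a", "b"], [[1.0, "x"]])
        with pytest.raises(NonNumericCellError):
            load_timeseries(p, tr=1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MissingFileError):
            load_timeseries(tmp_path / "nope.tsv", tr=1.0)

    def test_roundtrip_tsv(self, tmp_path, small_ts):
        p = tmp_path / "round.tsv"
        small_ts.to_tsv(p)
        back = load_timeseries(p, tr=small_ts.tr)
        np.testing.assert_allclose(back.data, small_ts.data)


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "n_scans,L,O,expected",
        [(1200, 200, 100, 11), (3000, 200, 0, 15), (200, 200, 100, 1)],
    )
    def test_window_counts(self, n_scans, L, O, expected):
        ts = RegionalTimeSeries(np.zeros((n_scans, 2)) + np.arange(n_scans)[:, None] % 7,
                                0.72, ["a", "b"])
        wins = segment_windows(ts, WindowingScheme(L, O))
        assert len(wins) == expected
        assert all(w.n_scans == L for w in wins)

    def test_identity_window(self):
        gen = np.random.default_rng(1)
        ts = RegionalTimeSeries(gen.standard_normal((200, 2)), 0.72, ["a", "b"])
        (w,) = segment_windows(ts, WindowingScheme(200, 100))
        np.testing.assert_array_equal(w.data, ts.data)

    def test_window_exceeds_series(self):
        ts = RegionalTimeSeries(np.ones((50, 2)) * [[1, 2]], 1.0, ["a", "b"])
        with pytest.raises(WindowExceedsSeriesError):
            segment_windows(ts, WindowingScheme(100, 0))

    @pytest.mark.parametrize("L", [50, 100, 200])
    def test_count_matches_closed_form(self, L):
        gen = np.random.default_rng(0)
        for O in range(0, L, 17):
            n = int(gen.integers(L, 4 * L))
            ts = RegionalTimeSeries(gen.standard_normal((n, 2)), 1.0, ["a", "b"])
            W = (n - L) // (L - O) + 1
            assert len(segment_windows(ts, WindowingScheme(L, O))) == W

    def test_concatenation_reconstructs_truncated_input(self):
        gen = np.random.default_rng(3)
        ts = RegionalTimeSeries(gen.standard_normal((517, 3)), 1.0, ["a", "b", "c"])
        wins = segment_windows(ts, WindowingScheme(100, 0))
        recon = np.vstack([w.data for w in wins])
        np.testing.assert_array_equal(recon, ts.data[: len(wins) * 100])


class TestCrossSessionSimilarity:
    def test_identical_matrices(self):
        gen = np.random.default_rng(2)
        m = ConnectivityMatrix(gen.standard_normal((5, 5)), "log_scaled_diagonal")
        assert cross_session_similarity([m] * 4) == pytest.approx(1.0)

    def test_anti_proportional(self):
        gen = np.random.default_rng(2)
        a = gen.standard_normal((4, 4))
        sims = cross_session_similarity(
            [ConnectivityMatrix(a, "log_scaled_diagonal"),
             ConnectivityMatrix(-2.0 * a, "log_scaled_diagonal")]
        )
        assert sims == pytest.approx(-1.0)

    def test_matches_bruteforce_pairwise_mean(self):
        gen = np.random.default_rng(7)
        mats = [gen.standard_normal((8, 8)) for _ in range(3)]
        expected = np.mean(
            [np.corrcoef(a.ravel(), b.ravel())[0, 1]
             for a, b in itertools.combinations(mats, 2)]
        )
        got = cross_session_similarity(
            [ConnectivityMatrix(m, "log_scaled_diagonal") for m in mats]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        gen = np.random.default_rng(11)
        mats = [gen.standard_normal((6, 6)) for _ in range(4)]
        perm = gen.permutation(6)
        base = cross_session_similarity(mats)
        permuted = cross_session_similarity([m[np.ix_(perm, perm)] for m in mats])
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            cross_session_similarity([np.eye(3)])
        with pytest.raises(ValueError):
            cross_session_similarity([np.eye(3), np.eye(4)])


class TestConnectivityMatrix:
    def test_log_scaled_roundtrip(self):
        a = np.array([[-0.6, 0.2], [0.1, -0.4]])
        m = ConnectivityMatrix(a, "rate")
        ls = m.to_log_scaled()
        assert ls.convention == "log_scaled_diagonal"
        np.testing.assert_allclose(ls.effective_rate(), a, atol=1e-12)
        np.testing.assert_allclose(np.diag(ls.values), np.log([0.6 / 0.5, 0.4 / 0.5]))

    def test_stability(self):
        assert ConnectivityMatrix(np.array([[-0.5, 0.0], [0.0, -0.5]]), "rate").is_stable()
        assert not ConnectivityMatrix(np.array([[0.1, 0.0], [0.0, -0.5]]), "rate").is_stable()
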