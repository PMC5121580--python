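"""Alignment, range scaling, TIC and file round-trips."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dartlda import (
    PeakSpectrum,
    align_spectra,
    apply_column_scaling,
    combine_scans,
    range_scale_columns,
    range_scale_rows,
    total_ion_current,
)
from dartlda import io as dio

from .conftest import write_minimal_mzml


def _spec(sid, pairs, label="c"):
    return PeakSpectrum.from_pairs(sid, label, pairs)


class TestPeakSpectrum:
    def test_rejects_unsorted_or_duplicate_mz(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PeakSpectrum("s", "c", [100.0, 99.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            PeakSpectrum("s", "c", [100.0, 100.0], [1.0, 1.0])

    def test_rejects_negative_intensity_and_nonpositive_mz(self):
        with pytest.raises(ValueError, match="nonnegative"):
            PeakSpectrum("s", "c", [100.0], [-1.0])
        with pytest.raises(ValueError, match="positive"):
            PeakSpectrum("s", "c", [0.0], [1.0])


class TestAlignment:
    def test_single_spectrum_is_identity(self):
        s = _spec("a", [(93.049, 10.0), (185.063, 5.0)])
        m = align_spectra([s], 0.01)
        np.testing.assert_array_equal(m.mz_axis, s.mz)
        np.testing.assert_array_equal(m.X[0], s.intensity)

    def test_close_peaks_merge_into_weighted_centroid_column(self):
        a = _spec("a", [(93.049, 10.0)])
        b = _spec("b", [(93.052, 30.0)])
        m = align_spectra([a, b], 0.01)
        assert m.n_variables == 1
        expected = (93.049 * 10 + 93.052 * 30) / 40
        assert m.mz_axis[0] == pytest.approx(expected)
        np.testing.assert_array_equal(m.X, [[10.0], [30.0]])

    def test_distant_peaks_stay_separate_with_zero_fill(self):
        a = _spec("a", [(93.049, 10.0)])
        b = _spec("b", [(93.20, 30.0)])
        m = align_spectra([a, b], 0.01)
        assert m.n_variables == 2
        np.testing.assert_array_equal(m.X, [[10.0, 0.0], [0.0, 30.0]])

    def test_matches_brute_force_gap_clustering_and_sample_order_invariance(self):
        # well-gapped random instances: greedy centroid sweep must agree with
        # an all-pairs clustering by gap threshold, independent of sample order
        rng = np.random.default_rng(42)
        for _ in range(20):
            centers = np.cumsum(rng.uniform(0.5, 3.0, size=8)) + 50
            spectra = []
            for i in range(4):
                pairs = [
                    (c + rng.uniform(-0.004, 0.004), rng.uniform(1, 100))
                    for c in centers
                    if rng.random() > 0.3
                ]
                if pairs:
                    spectra.append(_spec(f"s{i}", pairs))
            if not spectra:
                continue
            m = align_spectra(spectra, 0.01)
            # oracle: cluster pooled peaks wherever consecutive gaps exceed tol
            mz_all = np.sort(np.concatenate([s.mz for s in spectra]))
            groups = np.split(mz_all, np.flatnonzero(np.diff(mz_all) > 0.01) + 1)
            assert m.n_variables == len(groups)
            shuffled = [spectra[j] for j in rng.permutation(len(spectra))]
            m2 = align_spectra(shuffled, 0.01)
            np.testing.assert_allclose(m2.mz_axis, m.mz_axis)

    def test_rejects_empty_input_and_bad_tolerance(self):
        with pytest.raises(ValueError):
            align_spectra([], 0.01)
        with pytest.raises(ValueError):
            align_spectra([_spec("a", [(100.0, 1.0)])], 0.0)


def _matrix(X, state="raw"):
    from dartlda import AlignedMatrix

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    return AlignedMatrix(
        np.arange(p) + 100.0, X, [f"s{i}" for i in range(n)], ["c"] * n,
        scaling_state=state,
    )


class TestRangeScaling:
    @pytest.mark.parametrize(
        "row,lo,hi,expected",
        [
            ([2.0, 4.0, 6.0], 0.0, 1.0, [0.0, 0.5, 1.0]),
            ([5.0, 5.0, 5.0], 0.0, 1.0, [0.0, 0.0, 0.0]),  # degenerate -> lo
            ([2.0, 4.0, 6.0], -1.0, 1.0, [-1.0, 0.0, 1.0]),
        ],
    )
    def test_row_scaling_examples(self, row, lo, hi, expected):
        m = range_scale_rows(_matrix([row]), lo, hi)
        np.testing.assert_allclose(m.X[0], expected)
        assert m.scaling_state == "row_scaled"

    def test_column_scaling_and_heldout_extrapolation(self):
        m = range_scale_columns(_matrix([[0.0], [1.0], [2.0]]), 0.0, 1.0)
        np.testing.assert_allclose(m.X[:, 0], [0.0, 0.5, 1.0])
        held = m.col_scaling.apply(np.array([[3.0]]))
        assert held[0, 0] == pytest.approx(1.5)  # outside [0,1] is permitted

    def test_constant_column_maps_to_lo(self):
        m = range_scale_columns(_matrix([[7.0], [7.0], [7.0]]), 0.0, 1.0)
        np.testing.assert_array_equal(m.X[:, 0], [0.0, 0.0, 0.0])

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            range_scale_rows(_matrix([[1.0, 2.0]]), 1.0, 1.0)
        with pytest.raises(ValueError):
            range_scale_columns(_matrix([[1.0], [2.0]]), 2.0, 0.0)

    def test_row_then_column_preserves_shape_and_state(self):
        m = _matrix(np.arange(12.0).reshape(3, 4) ** 1.3)
        out = range_scale_columns(range_scale_rows(m))
        assert out.X.shape == m.X.shape
        assert out.labels == m.labels
        assert out.scaling_state == "row_then_column_scaled"
        # every non-degenerate column attains both endpoints
        inner = range_scale_rows(m).X
        nondeg = (inner.max(axis=0) - inner.min(axis=0)) > 0
        np.testing.assert_allclose(out.X.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.X[:, nondeg].max(axis=0), 1.0, atol=1e-12)

    @given(
        st.lists(
            st.lists(
                st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
                min_size=3,
                max_size=6,
            ),
            min_size=2,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_row_scaling_idempotent_and_invertible(self, rows):
        X = np.asarray(rows)
        m1 = range_scale_rows(_matrix(X))
        m2 = range_scale_rows(m1)
        np.testing.assert_allclose(m2.X, m1.X, atol=1e-9)  # idempotent
        nondeg = (X.max(axis=1) - X.min(axis=1)) > 0
        back = m1.row_scaling.invert(m1.X)
        np.testing.assert_allclose(back[nondeg], X[nondeg], rtol=1e-9, atol=1e-6)

    def test_column_scaling_inverse_recovers_raw(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 100, size=(6, 4))
        m = range_scale_columns(_matrix(X))
        np.testing.assert_allclose(m.col_scaling.invert(m.X), X, rtol=1e-12)

    def test_apply_column_scaling_to_heldout_matrix(self):
        X = np.arange(8.0).reshape(4, 2)
        train = range_scale_columns(_matrix(X[:3]))
        held = apply_column_scaling(_matrix(X[3:]), train.col_scaling)
        np.testing.assert_allclose(held.X, train.col_scaling.apply(X[3:]))


class TestTIC:
    def test_per_scan_sums(self):
        scans = [
            _spec("t0", [(100.0, 1.0), (101.0, 2.0), (102.0, 3.0)]),
            _spec("t1", []),
            _spec("t2", [(100.0, 10.0)]),
        ]
        tic = total_ion_current(scans)
        np.testing.assert_allclose(tic[:, 1], [6.0, 0.0, 10.0])
        np.testing.assert_allclose(tic[:, 0], [0.0, 1.0, 2.0])

    def test_combine_scans_averages_aligned_intensities(self):
        scans = [
            _spec("s", [(100.0, 2.0), (200.0, 4.0)]),
            _spec("s", [(100.001, 4.0), (200.0, 0.0)]),
        ]
        avg = combine_scans(scans, "sample1")
        assert avg.sample_id == "sample1"
        np.testing.assert_allclose(avg.intensity, [3.0, 2.0])


class TestIO:
    def test_peak_list_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(50, 800, 20))
        s = PeakSpectrum("x", "glycerol", mz, rng.uniform(0, 1e4, 20), 23.0)
        path = dio.write_peak_list(s, tmp_path / "x.tsv")
        back = dio.read_peak_list(path, "x", "glycerol", 23.0)
        np.testing.assert_array_equal(back.mz, s.mz)
        np.testing.assert_array_equal(back.intensity, s.intensity)

    def test_dataset_manifest_roundtrip(self, tmp_path):
        spectra = [
            _spec("a", [(93.049, 1.0)], "glycerol"),
            _spec("b", [(281.248, 2.0)], "castor"),
        ]
        manifest = dio.write_dataset(spectra, tmp_path)
        back = dio.read_dataset(manifest)
        assert [s.sample_id for s in back] == ["a", "b"]
        assert [s.class_label for s in back] == ["glycerol", "castor"]
        np.testing.assert_array_equal(back[0].mz, spectra[0].mz)

    def test_matrix_roundtrip_bit_exact(self, tmp_path, parchment_matrix):
        prefix = tmp_path / "matrix"
        dio.write_matrix(parchment_matrix, prefix)
        back = dio.read_matrix(prefix)
        np.testing.assert_array_equal(back.mz_axis, parchment_matrix.mz_axis)
        np.testing.assert_array_equal(back.X, parchment_matrix.X)
        assert back.labels == parchment_matrix.labels

    def test_read_minimal_centroid_mzml(self, tmp_path):
        path = write_minimal_mzml(
            tmp_path / "mini.mzML",
            [([93.049, 185.063], [100.0, 50.0]), ([93.05, 200.1], [80.0, 20.0])],
        )
        spectra = dio.read_mzml(path, "glycerol")
        assert len(spectra) == 2
        np.testing.assert_allclose(spectra[0].mz, [93.049, 185.063])
        np.testing.assert_allclose(spectra[1].intensity, [80.0, 20.0])
        assert all(s.class_label == "glycerol" for s in spectra)
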