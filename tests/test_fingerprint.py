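"""Cycle slicing, nearest-neighbour resize, averaging, image rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carotidprint as cp
from carotidprint.fingerprint import (CycleSpectrum, average_spectra,
                                      default_colormap_lut,
                                      render_cycle_image, resize_cycle,
                                      segment_spectrum, CYCLE_TIME_LEN)


def make_spec(n_freqs=5, n_samples=100, seed=0):
    rng = np.random.default_rng(seed)
    return cp.CWTSpectrum(rng.random((n_freqs, n_samples)),
                          np.geomspace(200, 1, n_freqs), 16000.0)


class TestSegmentSpectrum:
    def test_slices_match_cycle_widths(self):
        spec = make_spec()
        mats = segment_spectrum(spec, [(0, 30), (30, 75)])
        assert [m.shape[1] for m in mats] == [30, 45]
        assert np.array_equal(mats[0], spec.magnitude[:, :30])

    def test_empty_boundaries(self):
        assert segment_spectrum(make_spec(), []) == []

    def test_full_cover_conserves_width(self):
        spec = make_spec(n_samples=90)
        mats = segment_spectrum(spec, [(0, 40), (40, 90)])
        assert sum(m.shape[1] for m in mats) == 90

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            segment_spectrum(make_spec(n_samples=50), [(10, 60)])


class TestResizeCycle:
    def test_two_columns_to_four_duplicates(self):
        mat = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = resize_cycle(mat, target_len=4).magnitude
        assert np.array_equal(out, [[1, 1, 2, 2], [3, 3, 4, 4]])

    def test_identity_when_already_target_width(self):
        rng = np.random.default_rng(1)
        mat = rng.random((4, CYCLE_TIME_LEN))
        assert np.array_equal(resize_cycle(mat).magnitude, mat)

    def test_constant_stays_constant(self):
        out = resize_cycle(np.full((3, 7), 2.5), target_len=20).magnitude
        assert np.all(out == 2.5)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            resize_cycle(np.empty((3, 0)))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(w_in=st.integers(1, 300), w_out=st.integers(1, 300))
    def test_index_map_matches_definition(self, w_in, w_out):
        mat = np.arange(w_in, dtype=float)[None, :]
        out = resize_cycle(mat, target_len=w_out).magnitude[0]
        expected = [min(int(np.floor((j + 0.5) * w_in / w_out)), w_in - 1)
                    for j in range(w_out)]
        assert np.array_equal(out, np.asarray(expected, dtype=float))


class TestAverageSpectra:
    def cyc(self, mat):
        return resize_cycle(mat, target_len=8)

    def test_mean_of_identical_inputs_is_input(self):
        a = self.cyc(np.full((2, 8), 3.0))
        fp = average_spectra([a, a])
        assert np.array_equal(fp.magnitude, a.magnitude)
        assert fp.n_cycles == 2

    def test_linearity(self):
        rng = np.random.default_rng(2)
        base = rng.random((3, 8))
        fp = average_spectra([self.cyc(base), self.cyc(3.0 * base)])
        assert np.allclose(fp.magnitude, 2.0 * base)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            average_spectra([])
        a = self.cyc(np.ones((2, 8)))
        b = resize_cycle(np.ones((3, 8)), target_len=8)
        with pytest.raises(ValueError):
            average_spectra([a, b])


class TestRenderCycleImage:
    def cyc(self, mat):
        return CycleSpectrum(np.asarray(mat), np.arange(len(mat)), {})

    def test_shape_and_range(self):
        rng = np.random.default_rng(3)
        img = render_cycle_image(self.cyc(rng.random((9, CYCLE_TIME_LEN))))
        assert img.pixels.shape == (134, 134, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_constant_cycle_uniform_color(self):
        img = render_cycle_image(self.cyc(np.full((5, CYCLE_TIME_LEN), 4.0)))
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(4)
        mat = rng.random((9, CYCLE_TIME_LEN))
        a = render_cycle_image(self.cyc(mat)).pixels
        b = render_cycle_image(self.cyc(10.0 * mat)).pixels
        assert np.array_equal(a, b)

    def test_all_zero_renders_zero_color(self):
        lut = default_colormap_lut()
        img = render_cycle_image(self.cyc(np.zeros((5, CYCLE_TIME_LEN))))
        assert np.all(img.pixels == lut[0])

    def test_lut_shape_and_range(self):
        lut = default_colormap_lut()
        assert lut.shape == (256, 3)
        assert lut.min() >= 0.0 and lut.max() <= 1.0


class TestFingerprintSimilarity:
    def test_same_user_more_similar_than_different(self, fingerprint_corpus):
        """Intra-user fingerprint correlation exceeds inter-user."""
        def corr(a, b):
            return np.corrcoef(a.magnitude.ravel(), b.magnitude.ravel())[0, 1]

        users = sorted({k[0] for k in fingerprint_corpus})
        intra = [corr(fingerprint_corpus[(u, "L", 0)],
                      fingerprint_corpus[(u, "L", 1)]) for u in users]
        inter = [corr(fingerprint_corpus[(a, "L", 0)],
                      fingerprint_corpus[(b, "L", 0)])
                 for a in users for b in users if a < b]
        assert min(intra) > max(inter)

    def test_left_right_sides_highly_correlated(self, fingerprint_corpus):
        def corr(a, b):
            return np.corrcoef(a.magnitude.ravel(), b.magnitude.ravel())[0, 1]

        users = sorted({k[0] for k in fingerprint_corpus})
        for u in users:
            assert corr(fingerprint_corpus[(u, "L", 0)],
                        fingerprint_corpus[(u, "R", 0)]) > 0.9
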